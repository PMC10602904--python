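"""Region averaging and feature-matrix assembly.

Channel-level coherence spectra are averaged over four scalp regions
(anterior, posterior, left, right — five 10/20 electrodes each), then laid
out as one row per instance (participant × condition) with one column per
(region, frequency bin, parameter ∈ {amplitude, time}).  With the full
62-bin grid this is 4 × 62 × 2 = 496 features; with the default cohort of
24 + 20 participants × 2 conditions, 88 instances.

Column order is fixed and versioned in the file sidecar: the amplitude block
first (region-major in the order anterior, posterior, left, right; bins
ascending within a region), then the time block in the same order — so
ranked-feature indices are comparable across runs.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entrainment import CoherenceSpectrum, FrequencyGrid

__all__ = [
    "RegionMap",
    "RegionSpectrum",
    "FeatureMatrix",
    "region_average",
    "assemble",
    "zscale",
    "apply_scaling",
    "feature_name",
    "parse_feature_name",
]

REGION_ORDER = ("anterior", "posterior", "left", "right")
PARAM_ORDER = ("amplitude", "time")


@dataclass(frozen=True)
class RegionMap:
    """Four disjoint electrode sets over the 10/20 montage."""

    anterior: tuple[str, ...] = ("F3", "F4", "Fz", "FC1", "FC2")
    posterior: tuple[str, ...] = ("P7", "P8", "P3", "P4", "Pz")
    left: tuple[str, ...] = ("C3", "FC5", "T7", "CP1", "CP5")
    right: tuple[str, ...] = ("C4", "FC6", "T8", "CP2", "CP6")

    def __post_init__(self) -> None:
        all_ch = [c for r in REGION_ORDER for c in getattr(self, r)]
        if len(set(all_ch)) != len(all_ch):
            raise ValueError("regions must be disjoint")

    def __getitem__(self, region: str) -> tuple[str, ...]:
        if region not in REGION_ORDER:
            raise KeyError(f"unknown region {region!r}")
        return getattr(self, region)

    def items(self):
        return ((r, getattr(self, r)) for r in REGION_ORDER)

    def to_dict(self) -> dict[str, list[str]]:
        return {r: list(getattr(self, r)) for r in REGION_ORDER}


@dataclass
class RegionSpectrum:
    """Region-averaged coherence: (4, n_bins) amplitude and time arrays."""

    amplitude: np.ndarray
    time_ms: np.ndarray
    grid: FrequencyGrid
    regions: tuple[str, ...] = REGION_ORDER
    meta: dict = field(default_factory=dict)


def region_average(spec: CoherenceSpectrum,
                   region_map: RegionMap | None = None) -> RegionSpectrum:
    """Average channel-level peaks over the four scalp regions.

    Per region × bin, amplitude is the mean of the member channels' peak
    amplitudes and time the mean of their peak lags (plain means — lags are
    delays, not phases, so circular statistics do not apply).
    """
    region_map = region_map or RegionMap()
    labels = spec.channel_labels
    amp = np.empty((len(REGION_ORDER), len(spec.grid)))
    tms = np.empty_like(amp)
    for k, (region, members) in enumerate(region_map.items()):
        idx = [labels.index(c) for c in members if c in labels]
        missing = [c for c in members if c not in labels]
        if missing:
            raise ValueError(
                f"region {region!r}: channels {missing} absent from spectrum")
        if not idx:
            raise ValueError(f"region {region!r} has no available channels")
        amp[k] = spec.amplitude[idx].mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tms[k] = np.nanmean(spec.time_ms[idx], axis=0)
    return RegionSpectrum(amp, tms, spec.grid, meta=dict(spec.meta))


def feature_name(param: str, region: str, bin_center_hz: float) -> str:
    return f"{param}|{region}|{bin_center_hz:.1f}"


def parse_feature_name(name: str) -> tuple[str, str, float]:
    """Inverse of :func:`feature_name` -> (param, region, bin_center_hz)."""
    param, region, center = name.split("|")
    return param, region, float(center)


@dataclass
class FeatureMatrix:
    """Instances × features with labels and (optional) scaling parameters.

    ``values``: DataFrame indexed by instance id, columns named
    ``param|region|bin``.  ``labels``: per-instance (participant, group,
    condition).  ``scaling``: per-column (mean, sd) used by the most recent
    :func:`zscale`, stored so held-out rows can be transformed without
    refitting.
    """

    values: pd.DataFrame
    labels: pd.DataFrame
    grid: FrequencyGrid | None = None
    region_map: RegionMap | None = None
    scaling: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("values and labels must share an index")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def columns_for_subset(self, subset: str) -> list[str]:
        """Feature columns for a named subset of parameter types."""
        if subset == "amplitude_and_time":
            return list(self.values.columns)
        if subset in ("amplitude_only", "time_only"):
            prefix = subset.split("_")[0]
            return [c for c in self.values.columns
                    if c.startswith(prefix + "|")]
        raise ValueError(f"unknown feature subset {subset!r}")

    def select_rows(self, mask: np.ndarray | pd.Series) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[mask], self.labels.loc[mask],
                             grid=self.grid, region_map=self.region_map,
                             scaling=self.scaling)

    # --- persistence: CSV plus JSON sidecar -------------------------------
    def to_csv(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        joined = pd.concat([self.labels, self.values], axis=1)
        joined.to_csv(path, index_label="instance")
        sidecar = {
            "feature_names": list(self.values.columns),
            "label_columns": list(self.labels.columns),
            "grid_centers_hz": (list(map(float, self.grid.centers))
                                if self.grid is not None else None),
            "grid_bandwidth_hz": (self.grid.bandwidth_hz
                                  if self.grid is not None else None),
            "region_map": (self.region_map.to_dict()
                           if self.region_map is not None else None),
            "scaling": (self.scaling.to_dict(orient="list")
                        if self.scaling is not None else None),
            "content_sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | pathlib.Path) -> "FeatureMatrix":
        path = pathlib.Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        joined = pd.read_csv(path, index_col="instance")
        labels = joined[sidecar["label_columns"]]
        values = joined[sidecar["feature_names"]]
        grid = None
        if sidecar.get("grid_centers_hz"):
            grid = FrequencyGrid(np.array(sidecar["grid_centers_hz"]),
                                 sidecar["grid_bandwidth_hz"])
        rmap = (RegionMap(**{k: tuple(v) for k, v in
                             sidecar["region_map"].items()})
                if sidecar.get("region_map") else None)
        scaling = (pd.DataFrame(sidecar["scaling"])
                   if sidecar.get("scaling") else None)
        return cls(values, labels, grid=grid, region_map=rmap,
                   scaling=scaling)


def assemble(instances: list[tuple[dict, RegionSpectrum]]) -> FeatureMatrix:
    """Build the instances × features matrix from region spectra.

    ``instances`` pairs a metadata dict (must contain participant, group,
    condition) with that instance's RegionSpectrum.  Rows are sorted by
    (group, participant, condition); columns follow the fixed ordering
    documented in the module docstring.  A missing or NaN amplitude cell is
    an error naming the offending (instance, region, bin).
    """
    if not instances:
        raise ValueError("no instances to assemble")
    grid = instances[0][1].grid
    names = ([feature_name("amplitude", r, c)
              for r in REGION_ORDER for c in grid.centers]
             + [feature_name("time", r, c)
                for r in REGION_ORDER for c in grid.centers])
    rows, labels = [], []
    for meta, rs in instances:
        if rs.amplitude.shape != (len(REGION_ORDER), len(grid)):
            raise ValueError(f"instance {meta}: spectrum shape mismatch")
        bad = np.argwhere(~np.isfinite(rs.amplitude))
        if len(bad):
            r, b = bad[0]
            raise ValueError(
                f"instance {meta}: missing amplitude cell "
                f"(region={REGION_ORDER[r]}, bin={grid.centers[b]:.1f} Hz)")
        rows.append(np.concatenate([rs.amplitude.ravel(),
                                    rs.time_ms.ravel()]))
        labels.append({k: meta[k] for k in ("participant", "group",
                                            "condition")})
    labels = pd.DataFrame(labels)
    order = labels.sort_values(["group", "participant",
                                "condition"]).index
    values = pd.DataFrame(np.asarray(rows), columns=names).loc[order]
    labels = labels.loc[order]
    values.index = pd.RangeIndex(len(values))
    labels.index = pd.RangeIndex(len(labels))
    return FeatureMatrix(values, labels, grid=grid,
                         region_map=instances[0][1].meta.get("region_map"))


def zscale(m: FeatureMatrix,
           fit_rows: np.ndarray | None = None) -> FeatureMatrix:
    """Column-wise standardisation to mean 0, SD 1.

    Statistics are computed on ``fit_rows`` only (default: all rows) and
    applied to every row, then stored in ``scaling`` so held-out data can be
    transformed with training-fold statistics — the leakage-free reading of
    global scaling.  Zero-SD columns scale to all zeros with a warning,
    never a division by zero.
    """
    if fit_rows is None:
        fit = m.values
    else:
        fit = m.values.loc[fit_rows]
        if len(fit) == 0:
            raise ValueError("fit_rows selects no rows")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=0)
    dead = sd <= 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} constant feature column(s) "
                      "scaled to zero", stacklevel=2)
    safe_sd = sd.where(~dead, 1.0)
    scaled = (m.values - mean) / safe_sd
    scaled.loc[:, dead] = 0.0
    scaling = pd.DataFrame({"mean": mean, "sd": sd})
    return FeatureMatrix(scaled, m.labels.copy(), grid=m.grid,
                         region_map=m.region_map, scaling=scaling)


def apply_scaling(m: FeatureMatrix, scaling: pd.DataFrame) -> FeatureMatrix:
    """Apply previously fitted scaling parameters to (held-out) rows."""
    sd = scaling["sd"]
    dead = sd <= 0
    safe_sd = sd.where(~dead, 1.0)
    scaled = (m.values - scaling["mean"]) / safe_sd
    scaled.loc[:, dead] = 0.0
    return FeatureMatrix(scaled, m.labels.copy(), grid=m.grid,
                         region_map=m.region_map, scaling=scaling)
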