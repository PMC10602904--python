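"""Information-based feature ranking."""

import numpy as np
import pandas as pd
import pytest

from entrainflow.features import FeatureMatrix
from entrainflow.ufs import (discretize, entropy_bits, loo_entropy_scores,
                             mi_score, mutual_information_bits, rank)


def _matrix(values, columns=None):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"amplitude|left|{i}.0"
                          for i in range(values.shape[1])]
    labels = pd.DataFrame({"participant":
                           [f"a{i:02d}" for i in range(len(values))],
                           "group": "a", "condition": "direct"})
    return FeatureMatrix(pd.DataFrame(values, columns=columns), labels)


class TestMI:
    def test_exact_copy_of_balanced_binary_label_is_one_bit(self):
        y = np.array([0, 1] * 22)
        assert mi_score(y.astype(float), y) == pytest.approx(1.0)

    def test_permuted_feature_below_permutation_null(self, rng):
        y = np.array([0, 1] * 44)
        x = rng.permutation(y.astype(float) + rng.normal(0, 0.1, 88))
        observed = mi_score(x, y)
        null = [mi_score(rng.permutation(x), y) for _ in range(500)]
        # the observed statistic is itself a null draw; the 99th percentile
        # keeps the check sharp without a built-in 5% false-alarm rate
        assert observed <= np.quantile(null, 0.99) + 1e-9

    def test_noisy_copy_scores_strictly_between(self, rng):
        y = np.array([0, 1] * 44)
        flipped = y.copy()
        idx = rng.choice(88, size=9, replace=False)
        flipped[idx] = 1 - flipped[idx]
        mid = mi_score(flipped.astype(float), y)
        assert 0.05 < mid < 1.0
        # brute-force MI from the 2x2 contingency table
        joint = np.zeros((2, 2))
        for a, b in zip(flipped, y):
            joint[a, b] += 1
        joint /= joint.sum()
        pa, pb = joint.sum(1), joint.sum(0)
        expected = sum(joint[i, j] * np.log2(joint[i, j]
                                             / (pa[i] * pb[j]))
                       for i in range(2) for j in range(2)
                       if joint[i, j] > 0)
        assert mid == pytest.approx(expected)

    def test_invariant_to_monotone_transform(self, rng):
        y = rng.integers(0, 2, 60)
        x = rng.normal(size=60) + y
        assert mi_score(x, y) == pytest.approx(
            mi_score(np.exp(x), y))

    def test_single_class_warns_and_returns_zero(self, rng):
        with pytest.warns(UserWarning):
            assert mi_score(rng.random(20), np.zeros(20)) == 0.0


class TestLooEntropy:
    def test_duplicate_columns_rank_below_unique_informative_column(self,
                                                                    rng):
        a = rng.random(60)
        unique = rng.random(60)
        m = _matrix(np.column_stack([a, a, unique]),
                    ["amplitude|left|1.0", "amplitude|left|2.0",
                     "amplitude|left|3.0"])
        scores = loo_entropy_scores(m)
        assert scores["amplitude|left|3.0"] > scores["amplitude|left|1.0"]
        assert scores["amplitude|left|3.0"] > scores["amplitude|left|2.0"]
        # a duplicate's unique information is 0 up to the plug-in MI bias,
        # ~(B-1)^2 / (2 N ln 2) bits per remaining pairwise term
        n_bins = int(np.ceil(np.sqrt(60)))
        bias = (n_bins - 1) ** 2 / (2 * 60 * np.log(2))
        assert abs(scores["amplitude|left|1.0"]) < 1.5 * bias

    def test_matches_brute_force_pairwise_estimator(self, rng):
        x = rng.random((40, 3))
        x[:, 2] = (x[:, 0] > 0.5) ^ (x[:, 1] > 0.5)  # XOR-style column
        m = _matrix(x)
        n_bins = 4
        scores = loo_entropy_scores(m, n_bins=n_bins)
        codes = np.column_stack([discretize(x[:, j], n_bins)
                                 for j in range(3)])
        for f in range(3):
            expected = entropy_bits(codes[:, f]) - sum(
                mutual_information_bits(codes[:, f], codes[:, k])
                for k in range(3) if k != f)
            assert scores.iloc[f] == pytest.approx(expected, abs=1e-9)

    def test_independent_noise_columns_score_alike(self):
        per_seed = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = _matrix(rng.random((40, 6)))
            per_seed.append(loo_entropy_scores(m).to_numpy())
        per_seed = np.array(per_seed)
        null_sd = per_seed.std()
        spread = per_seed.max(axis=1) - per_seed.min(axis=1)
        assert np.all(spread < 4 * null_sd)

    def test_two_feature_matrix_warns_but_scores_both(self, rng):
        m = _matrix(rng.random((30, 2)))
        with pytest.warns(UserWarning, match="degenerate"):
            scores = loo_entropy_scores(m)
        assert len(scores) == 2
        assert np.all(np.isfinite(scores))


class TestRank:
    def test_full_ranking_is_a_permutation(self, rng):
        m = _matrix(rng.random((30, 8)))
        ranked = rank(m, rng.integers(0, 2, 30), method="mi", top_k=8)
        assert sorted(ranked.order) == sorted(m.values.columns)

    def test_top_k_beyond_feature_count_warns(self, rng):
        m = _matrix(rng.random((30, 4)))
        with pytest.warns(UserWarning, match="clipped"):
            rank(m, rng.integers(0, 2, 30), top_k=10)

    def test_tie_break_prefers_lower_bin_then_region_order(self):
        values = np.zeros((20, 3))
        m = _matrix(values, ["time|right|2.0", "amplitude|anterior|2.0",
                             "amplitude|left|1.0"])
        ranked = rank(m, np.array([0, 1] * 10), method="mi")
        assert ranked.order == ["amplitude|left|1.0",
                                "amplitude|anterior|2.0", "time|right|2.0"]

    def test_report_table_mirrors_bin_range_layout(self, rng):
        m = _matrix(rng.random((20, 3)),
                    ["amplitude|posterior|1.0", "time|left|0.4",
                     "amplitude|right|9.6"])
        ranked = rank(m, rng.integers(0, 2, 20))
        table = ranked.table(top_k=3)
        assert list(table.columns[:4]) == ["rank", "region",
                                           "frequency_bin_hz",
                                           "parameter_type"]
        assert set(table["frequency_bin_hz"]) <= {"0.8–1.0", "0.2–0.4",
                                                  "9.4–9.6"}

    def test_coherence_amplitude_monotone_in_injected_snr(self):
        """The causal chain UFS rests on: stronger embedded entrainment
        produces larger peak coherence at the cell's region and bin."""
        from entrainflow.entrainment import coherence_spectrum, default_grid
        from entrainflow.features import region_average
        from entrainflow.synth import (EntrainmentCell, SynthSpec, make_eeg,
                                       make_flow_series)
        grid = default_grid()
        j = grid.index_of(1.0)
        amps = []
        for snr in (0.0, 2.0, 5.0, 10.0):
            cells = ([EntrainmentCell("a", "left", 1.0, 200.0, snr)]
                     if snr > 0 else [])
            spec = SynthSpec(entrainment_cells=cells, seed=41)
            flow = make_flow_series(spec, 0)
            rec = make_eeg(spec, flow, "a01", "direct")
            onset = rec.events[0][0]
            keep = [i for i, c in enumerate(rec.channel_labels)
                    if c not in ("M1", "M2", "HEOG", "VEOG")]
            trial = rec.data[keep, onset:onset + 2500]
            cs = coherence_spectrum(flow, trial, 500.0,
                                    [rec.channel_labels[i] for i in keep],
                                    grid=grid)
            rs = region_average(cs)
            amps.append(rs.amplitude[2, j])  # left region, 1.0 Hz bin
        assert np.all(np.diff(amps) > 0), amps
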