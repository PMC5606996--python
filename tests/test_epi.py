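"""Promoter-window peak assignment, H3K9ac scores, IE statistic, robustness."""

import numpy as np
import pandas as pd
import pytest

from ordgene import (
    assign_peaks,
    gamma_robustness,
    h3k9ac_score,
    h3k9ac_scores,
    interaction_effect,
)
from ordgene.synthetic import simulate_peak_landscape


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "m_value"])


def _promoters(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


class TestAssignPeaks:
    def test_boundary_overlap_assigned(self):
        peaks = _peaks([("chr1", 89950, 90010, 1.0)])
        promoters = _promoters([("g", "chr1", 100000, "+")])
        # window [90000, 110000): peak [89950, 90010) overlaps its first 10 bp
        assert assign_peaks(peaks, promoters) == {"g": [0]}

    def test_half_open_window_end_excluded(self):
        peaks = _peaks([("chr1", 110000, 110100, 1.0)])
        promoters = _promoters([("g", "chr1", 100000, "+")])
        # window end 110000 is exclusive; a peak starting there does not overlap
        assert assign_peaks(peaks, promoters) == {}

    def test_peak_ending_at_window_start_excluded(self):
        peaks = _peaks([("chr1", 89000, 90000, 1.0)])
        promoters = _promoters([("g", "chr1", 100000, "+")])
        assert assign_peaks(peaks, promoters) == {}

    def test_peak_may_serve_multiple_genes(self):
        peaks = _peaks([("chr1", 99000, 101000, 1.0)])
        promoters = _promoters(
            [("a", "chr1", 95000, "+"), ("b", "chr1", 105000, "-")]
        )
        mapping = assign_peaks(peaks, promoters)
        assert mapping == {"a": [0], "b": [0]}

    def test_matches_brute_force_all_pairs(self, rng):
        n_peaks, n_genes, w = 200, 50, 10000
        peaks = _peaks(
            [
                (
                    f"chr{rng.integers(1, 3)}",
                    int(s := rng.integers(0, 500000)),
                    int(s + rng.integers(1, 2000)),
                    float(rng.normal()),
                )
                for _ in range(n_peaks)
            ]
        )
        promoters = _promoters(
            [
                (
                    f"g{i}",
                    f"chr{rng.integers(1, 3)}",
                    int(rng.integers(0, 500000)),
                    str(rng.choice(["+", "-"])),
                )
                for i in range(n_genes)
            ]
        )
        expected = {}
        for _, g in promoters.iterrows():
            lo, hi = g.tss - w, g.tss + w
            hits = [
                i
                for i, p in peaks.iterrows()
                if p.chrom == g.chrom and p.start < hi and p.end > lo
            ]
            if hits:
                expected[g.gene_id] = hits
        assert assign_peaks(peaks, promoters, window=w) == expected

    def test_no_shared_chromosome_warns_empty(self):
        peaks = _peaks([("chr1", 0, 100, 1.0)])
        promoters = _promoters([("g", "chrX", 50, "+")])
        with pytest.warns(UserWarning, match="chromosome"):
            assert assign_peaks(peaks, promoters) == {}

    def test_invalid_peak_rejected(self):
        peaks = _peaks([("chr1", 100, 100, 1.0)])
        promoters = _promoters([("g", "chr1", 50, "+")])
        with pytest.raises(ValueError, match="start >= end"):
            assign_peaks(peaks, promoters)


class TestH3k9acScore:
    def test_single_peak(self):
        peaks = _peaks([("chr1", 95000, 95500, 1.2)])
        mapping = {"g": [0]}
        assert h3k9ac_score("g", mapping, peaks) == pytest.approx(1.2)

    def test_sum_of_m_values(self):
        peaks = _peaks(
            [
                ("chr1", 95000, 95500, 0.5),
                ("chr1", 96000, 96500, -0.2),
                ("chr1", 97000, 97500, 1.0),
            ]
        )
        assert h3k9ac_score("g", {"g": [0, 1, 2]}, peaks) == pytest.approx(1.3)

    def test_missing_gene_rejected(self):
        with pytest.raises(KeyError):
            h3k9ac_score("nope", {}, _peaks([]))

    def test_split_peak_additivity(self):
        whole = _peaks([("chr1", 95000, 96000, 0.9)])
        split = _peaks(
            [("chr1", 95000, 95500, 0.4), ("chr1", 95500, 96000, 0.5)]
        )
        promoters = _promoters([("g", "chr1", 100000, "+")])
        s1 = h3k9ac_scores(assign_peaks(whole, promoters), whole)
        s2 = h3k9ac_scores(assign_peaks(split, promoters), split)
        assert s1["g"] == pytest.approx(s2["g"])

    def test_landscape_truth_recovered(self):
        peaks, promoters, truth = simulate_peak_landscape(
            n_genes=30, peaks_per_gene=(0, 3), n_decoys=15, seed=5
        )
        scores = h3k9ac_scores(assign_peaks(peaks, promoters), peaks)
        assert set(scores.index) == set(truth.index)
        np.testing.assert_allclose(
            scores.sort_index(), truth.sort_index(), atol=1e-12
        )

    def test_decoys_only_landscape_scores_absent(self):
        peaks, promoters, truth = simulate_peak_landscape(
            n_genes=10, peaks_per_gene=(0, 0), n_decoys=12, seed=6
        )
        assert len(truth) == 0
        assert assign_peaks(peaks, promoters) == {}


class TestInteractionEffect:
    def test_zero_inputs_zero_ie(self):
        table = interaction_effect([0.0, 1.0], [0.0, 1.0])
        assert table.loc["gene_0", "ie"] == 0.0

    def test_forced_arithmetic(self):
        table = interaction_effect([1.0, 0.0], [2.0, 0.0])
        assert table.loc["gene_0", "ie"] == pytest.approx(5.0)  # 1 + 2 + 1*2

    def test_zscore_population_sd_and_strict_selection(self):
        # IE values [0, 5, 10]: z = [-1.2247, 0, +1.2247]; only z>0 selected
        table = interaction_effect([0.0, 5.0, 10.0], [0.0, 0.0, 0.0],
                                   gammas=(0.0, 1.0, 0.0, 0.0))
        z = table.sort_index()["ie_z"].to_numpy()
        np.testing.assert_allclose(z, [-1.224744871, 0.0, 1.224744871], atol=1e-8)
        selected = table.sort_index()["selected"].to_numpy()
        assert selected.tolist() == [False, False, True]  # z = 0 is NOT selected

    def test_rank_descends_with_ie_z(self):
        table = interaction_effect([3.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert list(table["rank"]) == [1, 2, 3]
        assert table["ie_z"].is_monotonic_decreasing

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            interaction_effect([1.0], [1.0])

    @pytest.mark.parametrize("a, b", [(2.5, 0.0), (1.0, 3.0), (0.3, -1.0)])
    def test_selection_invariant_under_positive_affine_ie_maps(self, a, b, rng):
        x1, x2 = rng.normal(size=12), rng.normal(size=12)
        base = interaction_effect(x1, x2).sort_index()
        scaled = interaction_effect(x1, x2, gammas=(b, a, a, a)).sort_index()
        pd.testing.assert_series_equal(base["selected"], scaled["selected"])
        np.testing.assert_allclose(base["ie_z"], scaled["ie_z"], atol=1e-9)


class TestGammaRobustness:
    def test_scaling_sampler_always_identical(self, rng):
        x1, x2 = rng.normal(size=20), rng.normal(size=20)
        frac = gamma_robustness(
            x1, x2, n_iter=50, sampler=lambda r: r.uniform(0.1, 5.0) * np.ones(3),
            seed=0,
        )
        assert frac == 1.0

    def test_deterministic_under_fixed_seed(self, rng):
        x1, x2 = rng.normal(size=15), rng.normal(size=15)
        f1 = gamma_robustness(x1, x2, n_iter=40, seed=123)
        f2 = gamma_robustness(x1, x2, n_iter=40, seed=123)
        assert f1 == f2

    def test_well_separated_candidates_are_stable(self):
        # candidates with widely separated, same-sign coordinates: the IE
        # ordering survives any positive gamma draw, so selection is stable
        rng = np.random.default_rng(9)
        x1 = np.concatenate([rng.uniform(0.1, 0.3, 10), rng.uniform(3.0, 4.0, 10)])
        x2 = np.concatenate([rng.uniform(0.1, 0.3, 10), rng.uniform(3.0, 4.0, 10)])
        frac = gamma_robustness(x1, x2, n_iter=100, seed=1)
        assert frac >= 0.9
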