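"""Tn5 cut shifting, tabulation, profiles and the per-base dose test."""

import numpy as np
import pandas as pd
import pytest

import c9wta as c
from c9wta.footprint import BaseBySampleMatrix, _size_factors


def cuts_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "strand"])


def peaks_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"])


def nb_matrix(rng, mu, n_samples, peak="pk"):
    """BaseBySampleMatrix from a (bases x samples) NB mean array."""
    alpha = 0.1
    lam = rng.gamma(1 / alpha, np.asarray(mu) * alpha)
    counts = rng.poisson(lam)
    samples = [f"s{i}" for i in range(n_samples)]
    df = pd.DataFrame(counts, columns=samples)
    df.index = pd.MultiIndex.from_product(
        [[peak], range(len(df))], names=["peak", "offset"]
    )
    totals = df.sum(axis=0).to_frame().T
    totals.index = [peak]
    return BaseBySampleMatrix(counts=df, peak_totals=totals)


class TestShiftCuts:
    def test_plus_strand_shift(self):
        out = c.shift_cuts(cuts_frame([("s1", "chr9", 100, "+")]))
        assert out["pos"].iloc[0] == 105

    def test_minus_strand_shift(self):
        out = c.shift_cuts(cuts_frame([("s1", "chr9", 200, "-")]))
        assert out["pos"].iloc[0] == 196

    def test_unknown_strand_errors(self):
        with pytest.raises(ValueError):
            c.shift_cuts(cuts_frame([("s1", "chr9", 50, ".")]))


class TestTabulateCuts:
    def test_counting(self):
        cuts = cuts_frame([("s1", "chr9", 105, "+")] * 3)
        mat = c.tabulate_cuts(cuts, peaks_frame([("chr9", 100, 110, "pk")]))
        assert mat.counts.loc[("pk", 5), "s1"] == 3
        assert mat.peak_totals.loc["pk", "s1"] == 3

    def test_halfopen_end_excluded(self):
        cuts = cuts_frame([("s1", "chr9", 110, "+"), ("s1", "chr9", 109, "+")])
        mat = c.tabulate_cuts(cuts, peaks_frame([("chr9", 100, 110, "pk")]))
        assert mat.peak_totals.loc["pk", "s1"] == 1

    def test_empty_cuts_zero_matrix(self):
        cuts = cuts_frame([])
        mat = c.tabulate_cuts(
            cuts, peaks_frame([("chr9", 0, 20, "pk")]), samples=["s1", "s2"]
        )
        assert mat.counts.shape == (20, 2)
        assert (mat.counts == 0).all().all()

    def test_cut_count_conservation(self, small_cohort):
        shifted = c.shift_cuts(small_cohort.cuts)
        mat = c.tabulate_cuts(shifted, small_cohort.peaks)
        in_peak = 0
        for _, pk in small_cohort.peaks.iterrows():
            in_peak += (
                (shifted["chrom"] == pk["chrom"])
                & (shifted["pos"] >= pk["start"])
                & (shifted["pos"] < pk["end"])
            ).sum()
        assert mat.counts.to_numpy().sum() == in_peak


class TestGenotypeProfiles:
    def test_single_sample_normalization(self):
        counts = pd.DataFrame({"s1": [5, 45]}, dtype=int)
        counts.index = pd.MultiIndex.from_product([["pk"], [0, 1]])
        totals = pd.DataFrame({"s1": [50]}, index=["pk"])
        mat = BaseBySampleMatrix(counts, totals)
        prof = c.genotype_profiles(mat, {"s1": 0}, "pk")
        assert prof[0].iloc[0] == pytest.approx(0.1)

    def test_identical_samples_idempotent_average(self):
        counts = pd.DataFrame({"s1": [4, 6], "s2": [4, 6]}, dtype=int)
        counts.index = pd.MultiIndex.from_product([["pk"], [0, 1]])
        totals = pd.DataFrame({"s1": [10], "s2": [10]}, index=["pk"])
        mat = BaseBySampleMatrix(counts, totals)
        prof = c.genotype_profiles(mat, {"s1": 1, "s2": 1}, "pk")
        assert list(prof[1]) == pytest.approx([0.4, 0.6])

    def test_depth_scaling_invariance(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(5, size=30)
        counts = pd.DataFrame({"s1": base, "s2": base * 7})
        counts.index = pd.MultiIndex.from_product([["pk"], range(30)])
        totals = counts.sum().to_frame().T
        totals.index = ["pk"]
        mat = BaseBySampleMatrix(counts, totals)
        prof = c.genotype_profiles(mat, {"s1": 0, "s2": 1}, "pk")
        assert np.allclose(prof[0], prof[1])

    def test_planted_footprint_depletion_ratio(self, small_cohort, default_params):
        """Dose-2 vs dose-0 profile ratio inside the planted footprint is
        ~0.5 (2x depletion) within 20%."""
        from c9wta.haplotypes import alt_dose

        shifted = c.shift_cuts(small_cohort.cuts)
        mat = c.tabulate_cuts(shifted, small_cohort.peaks)
        dose = {
            s: alt_dose(t, "rs2492816") for s, t in small_cohort.genotypes.items()
        }
        pk = default_params.footprint_peak
        prof = c.genotype_profiles(mat, dose, pk)
        a, b = default_params.footprint_interval
        ratio = (prof[2].iloc[a:b] / prof[0].iloc[a:b]).mean()
        # normalisation slightly lifts the raw 0.5 depletion
        assert 0.4 <= ratio <= 0.6

    def test_all_zero_total_errors(self):
        counts = pd.DataFrame({"s1": [0, 0]}, dtype=int)
        counts.index = pd.MultiIndex.from_product([["pk"], [0, 1]])
        totals = pd.DataFrame({"s1": [0]}, index=["pk"])
        with pytest.raises(ValueError):
            c.genotype_profiles(
                BaseBySampleMatrix(counts, totals), {"s1": 0}, "pk"
            )


class TestStackAndFilter:
    def _mat(self, rows, samples):
        counts = pd.DataFrame(rows, columns=samples, dtype=int)
        counts.index = pd.MultiIndex.from_product([["pk"], range(len(counts))])
        totals = counts.sum().to_frame().T
        totals.index = ["pk"]
        return BaseBySampleMatrix(counts, totals)

    def test_mean_threshold_strict(self):
        samples = [f"s{i}" for i in range(10)]
        rows = [
            [2, 1, 1, 1, 1, 1, 1, 2, 1, 1],  # mean 1.2 kept
            [1, 1, 1, 1, 1, 1, 1, 1, 1, 0],  # mean 0.9 removed
            [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],  # mean exactly 1.0 kept
        ]
        out = c.stack_and_filter([self._mat(rows, samples)])
        means = out.counts.mean(axis=1).to_numpy()
        assert len(out.counts) == 2
        assert set(np.round(means, 6)) == {1.2, 1.0}

    def test_sample_mismatch_errors(self):
        m1 = self._mat([[2, 2]], ["a", "b"])
        m2 = self._mat([[2, 2]], ["a", "c"])
        with pytest.raises(ValueError):
            c.stack_and_filter([m1, m2])


class TestPerBaseDoseTest:
    def test_constant_dose_errors(self):
        rng = np.random.default_rng(0)
        mat = nb_matrix(rng, np.full((5, 10), 5.0), 10)
        with pytest.raises(ValueError):
            c.per_base_dose_test(mat, {f"s{i}": 1 for i in range(10)})

    def test_planted_bases_rank_top(self):
        """10 bases with a 2-fold per-allele increase among 200 null bases:
        at least 8 land in the top 20 by adjusted p."""
        rng = np.random.default_rng(8)
        n = 200
        doses = rng.choice([0, 1, 2], size=n, p=[0.35, 0.48, 0.17])
        n_bases = 210
        mu = np.full((n_bases, n), 5.0)
        planted = list(range(10))
        for b in planted:
            mu[b] = 5.0 * 2.0 ** doses
        mat = nb_matrix(rng, mu, n)
        dose_map = {f"s{i}": int(doses[i]) for i in range(n)}
        res = c.per_base_dose_test(mat, dose_map)
        top20 = res.nsmallest(20, "adj_p")["offset"].tolist()
        assert len(set(top20) & set(planted)) >= 8
        # sign of the detected effect matches the planted direction
        det = res[res["offset"].isin(planted)]
        assert (det["log2fc"] > 0).all()

    def test_null_raw_p_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(21)
        mat = nb_matrix(rng, np.full((300, 120), 5.0), 120)
        doses = rng.choice([0, 1, 2], size=120, p=[0.35, 0.48, 0.17])
        res = c.per_base_dose_test(mat, {f"s{i}": int(doses[i]) for i in range(120)})
        pvals = res["p"].dropna()
        assert kstest(pvals, "uniform").pvalue > 1e-3
        # BH at q=0.05 makes few or no null discoveries
        assert (res["adj_p"] < 0.05).sum() <= max(1, 0.05 * len(res))

    def test_size_factors_recover_depth(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(50, size=(40, 6)).astype(float)
        scale = np.array([0.5, 1, 1, 1, 1, 2.0])
        counts = pd.DataFrame(np.round(base * scale), dtype=int,
                              columns=[f"s{i}" for i in range(6)])
        sf = _size_factors(counts)
        assert sf.iloc[5] / sf.iloc[0] == pytest.approx(4.0, rel=0.1)
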