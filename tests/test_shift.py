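import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import feshift as fs
from feshift.shift import _ks_asymptotic_p, _ks_statistic


def brute_force_ks_p(a, b):
    """Permutation-enumeration p-value: fraction of all label assignments
    with D at least as large as observed."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    d_obs = _ks_statistic(a, b)
    idx = range(pooled.size)
    count = total = 0
    for comb in itertools.combinations(idx, a.size):
        chosen = set(comb)
        x = pooled[list(comb)]
        y = pooled[[i for i in idx if i not in chosen]]
        total += 1
        if _ks_statistic(x, y) >= d_obs - 1e-12:
            count += 1
    return count / total


def brute_force_hypergeom_p(n_universe, annotation, n_hits, min_overlap):
    """Exhaustively enumerate all hit sets of the given size."""
    universe = list(range(n_universe))
    annotation = set(annotation)
    count = total = 0
    for hits in itertools.combinations(universe, n_hits):
        total += 1
        if len(annotation & set(hits)) >= min_overlap:
            count += 1
    return count / total


class TestWaterfall:
    def test_ascending_rank(self):
        fc = pd.Series({"A": -2.0, "B": 0.0, "C": -3.0})
        table = fs.rank_waterfall(fc)
        assert list(table.index) == ["C", "A", "B"]
        assert table.loc["A", "rank"] == 2

    def test_ties_broken_lexicographically(self):
        fc = pd.Series({"Z": 1.0, "A": 1.0, "M": 1.0})
        table = fs.rank_waterfall(fc)
        assert list(table.index) == ["A", "M", "Z"]

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fs.rank_waterfall(pd.Series(dtype=float))
        with pytest.raises(ValueError):
            fs.rank_waterfall(pd.Series({"A": np.nan}))

    def test_set_annotation_columns(self):
        fc = pd.Series({"A": -1.0, "B": 1.0})
        sets = fs.GeneSetCollection({"S": {"a"}})
        table = fs.rank_waterfall(fc, sets)
        assert table.loc["A", "S"]
        assert not table.loc["B", "S"]


class TestKsTwoSample:
    def test_disjoint_supports(self):
        res = fs.ks_two_sample([1, 2], [3, 4])
        assert res.statistic == 1.0

    def test_identical_samples(self):
        res = fs.ks_two_sample([1, 2, 5], [1, 2, 5])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_interleaved_half(self):
        res = fs.ks_two_sample([1, 3], [2, 4])
        assert res.statistic == 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            fs.ks_two_sample([], [1.0])

    def test_exact_p_matches_permutation_enumeration(self):
        """For n <= 8 the exact-mode p-value equals full enumeration of all
        pooled-sample label assignments (distinct values, no ties)."""
        rng = np.random.default_rng(42)
        for _ in range(8):
            n_a, n_b = rng.integers(2, 9, size=2)
            pooled = rng.normal(size=int(n_a + n_b))
            a, b = pooled[:n_a], pooled[n_a:]
            res = fs.ks_two_sample(a, b, mode="exact")
            oracle = brute_force_ks_p(a, b)
            assert res.statistic == pytest.approx(_ks_statistic(a, b))
            assert res.pvalue == pytest.approx(oracle, abs=1e-9)

    def test_statistic_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        a, b = rng.normal(size=80), rng.normal(0.5, 1.2, size=60)
        res = fs.ks_two_sample(a, b, mode="asymp")
        ref = stats.ks_2samp(a, b, method="asymp")
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)

    def test_asymptotic_series_matches_kolmogorov_sf(self):
        from scipy import special

        for lam in (0.3, 0.8, 1.3, 2.0):
            n = 200  # n_eff = 100
            d = lam / math.sqrt(100)
            assert _ks_asymptotic_p(d, n, n) == pytest.approx(
                float(special.kolmogorov(lam)), abs=1e-12)

    @given(st.lists(st.integers(-1000, 1000), min_size=3, max_size=12,
                    unique=True),
           st.lists(st.integers(-1000, 1000), min_size=3, max_size=12,
                    unique=True),
           st.sampled_from(["exp", "cube", "affine"]))
    @settings(deadline=None, max_examples=40)
    def test_d_invariant_under_monotone_transform(self, a, b, transform):
        fn = {"exp": lambda x: np.exp(x / 100.0),
              "cube": lambda x: np.asarray(x, float) ** 3,
              "affine": lambda x: 2.0 * np.asarray(x, float) + 1.0}[transform]
        a, b = np.array(a, float), np.array(b, float)
        d0 = _ks_statistic(a, b)
        d1 = _ks_statistic(fn(a), fn(b))
        assert d0 == pytest.approx(d1, abs=1e-12)


class TestPathwayShiftReport:
    def test_noise_free_all_members_down(self, noise_free_tmt):
        res = fs.quantify(noise_free_tmt.peptides, noise_free_tmt.impurity,
                          noise_free_tmt.design, sn_min=0.0)
        sets = fs.default_sim_genesets(noise_free_tmt.config)
        report = fs.pathway_shift_report(res.proteins["log10_fc"], sets)
        assert report.loc["FES", "n_down"] == report.loc["FES", "n_in_set"]
        assert report.loc["FES", "direction"] == -1
        assert report.loc["FES", "p"] < 1e-4

    def test_unshifted_set_is_unremarkable(self, noise_free_tmt):
        res = fs.quantify(noise_free_tmt.peptides, noise_free_tmt.impurity,
                          noise_free_tmt.design, sn_min=0.0)
        sets = fs.default_sim_genesets(noise_free_tmt.config)
        report = fs.pathway_shift_report(res.proteins["log10_fc"], sets)
        assert report.loc["LSU", "D"] < report.loc["FES", "D"]

    def test_missing_set_skipped_with_warning(self):
        fc = pd.Series({"A": -1.0, "B": 0.5, "C": 0.1})
        sets = fs.GeneSetCollection({"GONE": {"ZZZ"}, "HERE": {"A"}})
        with pytest.warns(UserWarning, match="GONE"):
            report = fs.pathway_shift_report(fc, sets)
        assert list(report.index) == ["HERE"]

    def test_null_pvalues_calibrated(self):
        """Sets drawn uniformly from the background give approximately
        uniform p-values: mean near 1/2 and rejection rates at or below the
        nominal levels (the discrete exact null is slightly conservative)."""
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(500):
            fc = pd.Series(rng.normal(size=400),
                           index=[f"P{i}" for i in range(400)])
            members = rng.choice(fc.index, size=30, replace=False)
            res = fs.ks_two_sample(fc[members],
                                   fc[~fc.index.isin(members)])
            pvals.append(res.pvalue)
        pvals = np.asarray(pvals)
        assert 0.45 <= pvals.mean() <= 0.60
        assert (pvals <= 0.05).mean() <= 0.08  # valid at the 5% level
        assert 0.10 <= (pvals <= 0.20).mean() <= 0.27

    def test_inclusive_background_mode(self):
        rng = np.random.default_rng(5)
        fc = pd.Series(rng.normal(size=100),
                       index=[f"P{i}" for i in range(100)])
        sets = fs.GeneSetCollection({"S": set(fc.index[:20])})
        excl = fs.pathway_shift_report(fc, sets, inclusive=False)
        incl = fs.pathway_shift_report(fc, sets, inclusive=True)
        # self-overlap dilutes the inclusive-mode distance
        assert incl.loc["S", "D"] <= excl.loc["S", "D"] + 1e-12


class TestHypergeometric:
    def test_closed_form_complete_overlap(self):
        universe = [f"g{i}" for i in range(10)]
        annotation = universe[:5]
        p, overlap, expected = fs.enrich_hypergeometric(
            annotation, annotation, universe)
        assert overlap == 5
        assert p == pytest.approx(1 / math.comb(10, 5), rel=1e-9)
        assert expected == pytest.approx(2.5)

    def test_zero_overlap_upper_tail_is_one(self):
        universe = [f"g{i}" for i in range(10)]
        p, overlap, _ = fs.enrich_hypergeometric(
            universe[:3], universe[8:], universe)
        assert overlap == 0
        assert p == 1.0

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            fs.enrich_hypergeometric(["x"], ["g1"], ["g1", "g2"])

    def test_matches_exhaustive_enumeration(self):
        """All configurations with universe size <= 12 agree with counting
        every possible hit set."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            n_u = int(rng.integers(4, 13))
            n_ann = int(rng.integers(1, n_u))
            n_hits = int(rng.integers(1, n_u))
            universe = [f"g{i}" for i in range(n_u)]
            annotation = list(rng.choice(universe, size=n_ann, replace=False))
            hits = list(rng.choice(universe, size=n_hits, replace=False))
            p, overlap, _ = fs.enrich_hypergeometric(hits, annotation, universe)
            oracle = brute_force_hypergeom_p(
                n_u, [universe.index(g) for g in annotation], n_hits, overlap)
            assert p == pytest.approx(oracle, abs=1e-12)

    def test_collection_bh_properties(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(60)]
        sets = fs.GeneSetCollection(
            {f"S{k}": set(rng.choice(universe, size=10, replace=False))
             for k in range(8)})
        hits = list(rng.choice(universe, size=15, replace=False))
        table = fs.enrich_collection(hits, sets, universe)
        assert (table["q"] >= table["p"] - 1e-12).all()
        assert (table["q"].diff().dropna() >= -1e-12).all()  # sorted by p

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_bh_adjustment_bounds(self, pvals):
        q = fs.bh_adjust(pvals)
        assert (q >= np.asarray(pvals) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
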