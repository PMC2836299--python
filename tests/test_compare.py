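import numpy as np
import pandas as pd
import pytest

from acghdiff import (
    ComparisonConfig,
    GroupComparison,
    GroupDesign,
    aggregate_regions,
    chi2_2x2,
    compare_groups,
    fisher_2x2,
    significance_threshold,
)
from acghdiff.model import GAIN, LOSS, MISSING, NEUTRAL, BacClone, CloneMap
from conftest import make_calls


class TestChi2:
    @pytest.mark.parametrize(
        "a,n1,b,n2,printed",
        [
            (18, 24, 1, 35, "5.68551E-09"),
            (13, 24, 19, 35, "9.92806E-01"),
            (21, 24, 1, 35, "3.98705E-11"),
            (14, 24, 1, 35, "1.52990E-06"),
            (16, 24, 0, 35, "1.52947E-08"),
        ],
    )
    def test_reference_tables(self, a, n1, b, n2, printed):
        """Uncorrected Pearson chi-square reproduces the reference 2x2
        P-values to six significant digits."""
        _, p, degenerate = chi2_2x2(a, n1, b, n2)
        assert not degenerate
        assert f"{p:.5E}" == printed

    def test_identical_proportions(self):
        chi2, p, degenerate = chi2_2x2(12, 24, 12, 24)
        assert chi2 == 0.0 and p == 1.0 and not degenerate

    def test_degenerate_margins(self):
        assert chi2_2x2(0, 24, 0, 35) == (0.0, 1.0, True)
        assert chi2_2x2(24, 24, 35, 35) == (0.0, 1.0, True)

    def test_symmetry(self):
        t1 = chi2_2x2(18, 24, 1, 35)
        swapped_groups = chi2_2x2(1, 35, 18, 24)
        swapped_columns = chi2_2x2(24 - 18, 24, 35 - 1, 35)
        assert t1[0] == pytest.approx(swapped_groups[0])
        assert t1[1] == pytest.approx(swapped_groups[1])
        assert t1[0] == pytest.approx(swapped_columns[0])

    @pytest.mark.parametrize("args", [(-1, 24, 0, 35), (25, 24, 0, 35),
                                      (0, 0, 0, 35)])
    def test_rejects_invalid_counts(self, args):
        with pytest.raises(ValueError):
            chi2_2x2(*args)

    def test_fisher_agrees_in_ranking(self):
        """Cross-oracle: chi-square and Fisher exact give nearly identical
        significance orderings over random small tables."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(42)
        p_chi, p_fis = [], []
        while len(p_chi) < 200:
            n1, n2 = rng.integers(5, 40, size=2)
            a, b = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            if a + b == 0 or a + b == n1 + n2:
                continue
            p_chi.append(chi2_2x2(a, n1, b, n2)[1])
            p_fis.append(fisher_2x2(a, n1, b, n2)[1])
        rho = spearmanr(p_chi, p_fis).statistic
        assert rho > 0.99


class TestThreshold:
    def test_exact_quotient(self):
        cfg = ComparisonConfig(alpha=0.05, m=4030)
        thr = significance_threshold(cfg)
        assert thr == 0.05 / 4030
        assert thr == pytest.approx(1.2407e-5, rel=1e-4)

    def test_no_correction(self):
        assert significance_threshold(ComparisonConfig(alpha=0.05, m=1)) == 0.05

    def test_monotone_in_m(self):
        thrs = [significance_threshold(ComparisonConfig(m=m))
                for m in (1, 10, 100, 4030)]
        assert all(a > b for a, b in zip(thrs, thrs[1:]))

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            ComparisonConfig(alpha=0.0)
        with pytest.raises(ValueError):
            ComparisonConfig(m=0)
        with pytest.raises(ValueError):
            ComparisonConfig(aberration_type="inversion")


def _toy_comparison():
    n1, n2 = 6, 6
    samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    design = GroupDesign(pd.Series(["A"] * n1 + ["B"] * n2, index=samples))
    rows = [
        [GAIN] * 6 + [NEUTRAL] * 6,          # strong gain difference
        [GAIN, MISSING] + [NEUTRAL] * 4 + [NEUTRAL] * 6,  # informative 5 vs 6
        [MISSING] * 6 + [NEUTRAL] * 6,       # no informative samples in A
        [NEUTRAL] * 12,                      # degenerate
    ]
    calls = make_calls(rows, samples, ["c1", "c2", "c3", "c4"])
    return calls, design


class TestCompareGroups:
    def test_counts_use_informative_denominators(self):
        calls, design = _toy_comparison()
        res = compare_groups(calls, design, ComparisonConfig(m=4)).set_index("clone_id")
        assert res.loc["c2", "n_g1"] == 5
        assert res.loc["c2", "count_g1"] == 1
        assert "c3" not in res.index
        assert res.attrs["n_excluded"] == 1
        assert bool(res.loc["c4", "degenerate"]) is True
        assert res.loc["c4", "p_value"] == 1.0

    def test_sorted_by_p_and_reproducible(self):
        calls, design = _toy_comparison()
        cfg = ComparisonConfig(m=4)
        r1 = compare_groups(calls, design, cfg)
        r2 = compare_groups(calls, design, cfg)
        assert (r1["p_value"].diff().dropna() >= 0).all()
        assert r1.equals(r2)

    def test_label_swap_leaves_p_unchanged(self):
        calls, design = _toy_comparison()
        swapped = GroupDesign(design.assignments.map({"A": "B", "B": "A"}))
        r1 = compare_groups(calls, design, ComparisonConfig(m=4)).set_index("clone_id")
        r2 = compare_groups(calls, swapped, ComparisonConfig(m=4)).set_index("clone_id")
        assert np.allclose(r1["p_value"], r2.loc[r1.index, "p_value"])

    def test_significant_count_nonincreasing_in_m(self, breast_calls):
        calls, design = breast_calls
        counts = []
        for m in (50, 500, 4030):
            res = compare_groups(calls, design,
                                 ComparisonConfig(aberration_type="loss", m=m))
            counts.append(int(res["significant"].sum()))
        assert counts[0] >= counts[1] >= counts[2] > 0

    def test_fisher_flag_switches_test(self):
        calls, design = _toy_comparison()
        chi = compare_groups(calls, design, ComparisonConfig(m=4)).set_index("clone_id")
        fis = compare_groups(calls, design,
                             ComparisonConfig(m=4, use_fisher=True)).set_index("clone_id")
        assert fis.loc["c1", "p_value"] == pytest.approx(
            fisher_2x2(6, 6, 0, 6)[1])
        assert chi.loc["c1", "p_value"] != fis.loc["c1", "p_value"]


def _region_fixture(positions_mb, significant, chrom="1"):
    clones = [BacClone(f"r{i}", chrom, int(p * 1e6), int(p * 1e6) + 200_000)
              for i, p in enumerate(positions_mb)]
    cmap = CloneMap(clones)
    res = pd.DataFrame(
        {
            "clone_id": [c.clone_id for c in clones],
            "count_g1": 5, "n_g1": 6, "count_g2": 0, "n_g2": 6,
            "chi2": 8.0,
            "p_value": [1e-8 if s else 0.5 for s in significant],
            "significant": significant,
        }
    )
    return res, cmap


class TestAggregateRegions:
    def test_merges_within_gap(self):
        res, cmap = _region_fixture([1, 2, 3], [True, True, True])
        regions = aggregate_regions(res, cmap, max_gap_bp=3_000_000)
        assert len(regions) == 1
        assert regions.loc[0, "start_bp"] == 1_000_000
        assert regions.loc[0, "end_bp"] == 3_200_000
        assert regions.loc[0, "n_clones"] == 3
        assert regions.loc[0, "min_p"] == pytest.approx(1e-8)

    def test_splits_beyond_gap(self):
        res, cmap = _region_fixture([1, 11], [True, True])
        regions = aggregate_regions(res, cmap, max_gap_bp=3_000_000)
        assert len(regions) == 2

    def test_ignores_non_significant(self):
        res, cmap = _region_fixture([1, 2, 3], [True, False, True])
        regions = aggregate_regions(res, cmap, max_gap_bp=500_000)
        assert len(regions) == 2

    def test_empty_results(self):
        res, cmap = _region_fixture([1], [False])
        assert aggregate_regions(res, cmap).empty


class TestGroupComparisonEstimator:
    def test_matches_functional_api(self):
        calls, design = _toy_comparison()
        # sklearn orientation: samples x clones of call codes
        codes = calls.state.to_numpy().T.astype(float)
        codes[calls.state.to_numpy().T == MISSING] = np.nan
        est = GroupComparison(aberration_type="gain", m=4)
        est.fit(codes, design.assignments.to_numpy())
        res = compare_groups(calls, design, ComparisonConfig(m=4))
        fitted = est.results_.set_index("feature_index")
        assert len(fitted) == len(res)
        assert fitted.loc[0, "p_value"] == pytest.approx(
            res.set_index("clone_id").loc["c1", "p_value"])
        assert est.threshold_ == 0.05 / 4
        support = est.get_support()
        assert support.shape == (4,)
        assert support[0] and not support[3]

    def test_sklearn_params(self):
        from sklearn.base import clone as sk_clone

        est = sk_clone(GroupComparison(alpha=0.01, m=100))
        assert est.get_params()["alpha"] == 0.01
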