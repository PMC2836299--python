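import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from acghdiff import (
    AberrationSpec,
    CohortSpec,
    breast_cohort_spec,
    build_default_clone_map,
    expected_log2,
    simulate_cohort,
)
from acghdiff.genome import CHROM_LENGTH_MB, MB, cytoband
from acghdiff.simulate import CELL_LINE, TISSUE, cell_line_specific_regions, shared_regions
from acghdiff.validation import clones_in_region, null_cohort_spec


class TestDefaultMap:
    def test_clone_count_matches_4k_array(self, default_map):
        assert abs(default_map.m - 4030) / 4030 <= 0.05
        assert default_map.m == 4030  # exact by construction

    def test_halving_spacing(self, default_map):
        half = build_default_clone_map(2 * MB)
        # per-chromosome rounding allows one clone of slack per chromosome
        assert abs(half.m - default_map.m / 2) <= len(CHROM_LENGTH_MB)

    def test_deterministic(self, default_map):
        assert build_default_clone_map() == default_map

    def test_spacing_too_large(self):
        with pytest.raises(ValueError, match="shortest chromosome"):
            build_default_clone_map(100_000 * MB)

    def test_cytobands_flank_centromere(self):
        # first band on each side of the chromosome 1 centromere
        assert cytoband("1", 164 * MB) == "1p11"
        assert cytoband("1", 166 * MB) == "1q11"


class TestExpectedLog2:
    @pytest.mark.parametrize(
        "cn,c,expected",
        [
            (2, 0.0, 0.0),
            (2, 0.4, 0.0),
            (1, 0.0, -1.0),
            (3, 0.10, 0.5361),  # log2(1.45)
            (6, 0.10, 1.4854),  # log2(2.80), still above the amp threshold
        ],
    )
    def test_closed_form(self, cn, c, expected):
        assert expected_log2(cn, c) == pytest.approx(expected, abs=1e-4)

    def test_homozygous_deletion_clamped(self):
        assert expected_log2(0, 0.0) == -5.0
        assert math.isfinite(expected_log2(0, 0.0))

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            expected_log2(-1, 0.0)
        with pytest.raises(ValueError):
            expected_log2(2, 1.0)

    @given(
        cn=st.integers(min_value=0, max_value=10).filter(lambda v: v != 2),
        c1=st.floats(0.0, 0.98),
        c2=st.floats(0.0, 0.98),
    )
    @settings(max_examples=100, deadline=None)
    def test_contamination_attenuates_signal(self, cn, c1, c2):
        lo, hi = sorted((c1, c2))
        if hi - lo < 1e-9:
            return
        assert abs(expected_log2(cn, hi)) < abs(expected_log2(cn, lo)) + 1e-12


class TestSimulateCohort:
    def test_seed_determinism(self):
        spec = breast_cohort_spec(seed=3)
        r1, d1, t1 = simulate_cohort(spec)
        r2, d2, t2 = simulate_cohort(breast_cohort_spec(seed=3))
        assert r1.equals(r2)
        assert t1.copy_number.equals(t2.copy_number)
        assert t1.segments.equals(t2.segments)

    def test_planted_region_means_match_dilution_model(self, default_map):
        spec = CohortSpec(
            group_sizes={"A": 6, "B": 6},
            aberrations=[
                AberrationSpec("2", 10 * MB, 40 * MB, "gain",
                               {"A": 1.0, "B": 0.0})
            ],
            passenger_rate=0.0,
            missing_rate=0.0,
            noise_sd=0.05,
            seed=11,
        )
        ratios, design, truth = simulate_cohort(spec)
        region = clones_in_region(default_map, spec.aberrations[0])
        for sid in design.samples("A"):
            c = truth.contamination[sid]
            assert ratios.loc[region, sid].mean() == pytest.approx(
                expected_log2(3, c), abs=0.05
            )
        b_mean = ratios.loc[region, design.samples("B")].to_numpy().mean()
        assert b_mean == pytest.approx(0.0, abs=0.05)

    def test_noise_only_gain_fraction_matches_gaussian_tail(self):
        ratios, _, _ = simulate_cohort(null_cohort_spec(seed=5))
        vals = ratios.to_numpy()
        obs = vals[~np.isnan(vals)]
        rate = (obs > 0.25).mean()
        expected = sps.norm.sf(0.25 / 0.10)
        se = math.sqrt(expected * (1 - expected) / obs.size)
        assert abs(rate - expected) <= 3 * se

    def test_missingness_independent_of_state(self):
        spec = breast_cohort_spec(seed=9)
        ratios, _, truth = simulate_cohort(spec)
        missing = ratios.isna().to_numpy()
        aberrant = truth.copy_number.to_numpy() != 2
        r_ab = missing[aberrant].mean()
        r_ne = missing[~aberrant].mean()
        se = math.sqrt(0.02 * 0.98 / min(aberrant.sum(), (~aberrant).sum()))
        assert abs(r_ab - r_ne) <= 4 * se

    def test_carrier_frequency_converges_to_prevalence(self):
        # pool planted-region carriage over several cohorts (binomial CI)
        target = None
        carriers = trials = 0
        for seed in range(5):
            spec = breast_cohort_spec(seed=seed)
            ab = next(a for a in spec.aberrations if a.name == "20q11_gain")
            target = ab.prevalence[CELL_LINE]
            _, design, truth = simulate_cohort(spec)
            seg = truth.segments
            hit = seg[(seg["chrom"] == ab.chrom)
                      & (seg["start_bp"] == ab.start_bp)
                      & (seg["origin"] == "planted")]["sample_id"]
            cell = [s for s in design.samples(CELL_LINE)]
            carriers += sum(s in set(hit) for s in cell)
            trials += len(cell)
        phat = carriers / trials
        assert abs(phat - target) <= 3 * math.sqrt(target * (1 - target) / trials)

    def test_contamination_bounded(self):
        spec = breast_cohort_spec(seed=2)
        _, _, truth = simulate_cohort(spec)
        c = truth.contamination.to_numpy()
        assert (c >= 0).all() and (c <= spec.contamination_max).all()


class TestBreastCohortSpec:
    def test_group_sizes(self):
        assert breast_cohort_spec().group_sizes == {CELL_LINE: 24, TISSUE: 35}

    def test_her2_amplicon_prevalences(self):
        spec = breast_cohort_spec()
        amp = next(a for a in spec.aberrations if a.kind == "amplification")
        assert amp.prevalence[CELL_LINE] == pytest.approx(0.417, abs=1e-3)
        assert amp.prevalence[TISSUE] == pytest.approx(0.171, abs=1e-3)

    def test_all_prevalences_valid(self):
        for ab in breast_cohort_spec().aberrations:
            for p in ab.prevalence.values():
                assert 0.0 <= p <= 1.0

    def test_region_classification(self):
        spec = breast_cohort_spec()
        assert len(cell_line_specific_regions(spec)) == 8
        assert len(shared_regions(spec)) == 4

    def test_yaml_round_trip(self, tmp_path):
        spec = breast_cohort_spec(seed=4)
        p = tmp_path / "spec.yaml"
        spec.to_yaml(p)
        back = CohortSpec.from_yaml(p)
        assert back.group_sizes == spec.group_sizes
        assert back.seed == 4
        assert back.aberrations == spec.aberrations
        r1, _, _ = simulate_cohort(spec)
        r2, _, _ = simulate_cohort(back)
        assert r1.equals(r2)


class TestSpecValidation:
    def test_rejects_bad_kinds_and_bounds(self):
        with pytest.raises(ValueError, match="unknown aberration kind"):
            AberrationSpec("1", 0, MB, "duplication", {"A": 0.5})
        with pytest.raises(ValueError, match="copy_number >= 3"):
            AberrationSpec("1", 0, MB, "gain", {"A": 0.5}, copy_number=2)
        with pytest.raises(ValueError, match="exceeds chromosome"):
            AberrationSpec("21", 0, 500 * MB, "gain", {"A": 0.5})
        with pytest.raises(ValueError, match="outside"):
            AberrationSpec("1", 0, MB, "gain", {"A": 1.5})

    def test_rejects_bad_cohort(self):
        with pytest.raises(ValueError, match="two groups"):
            CohortSpec(group_sizes={"A": 5})
        with pytest.raises(ValueError, match="noise_sd"):
            CohortSpec(group_sizes={"A": 5, "B": 5}, noise_sd=0.0)
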