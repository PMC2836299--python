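"""Simulation-based validation: parameter recovery and family-wise error.

These routines run the whole pipeline on synthetic cohorts where the truth
is known and summarize how well the clone-wise comparison recovers it.  The
per-clone chi-square at the emulated sample sizes (24 vs 35) sits close to
the Bonferroni cut-off for prevalence contrasts around 0.65-0.75 vs 0.03, so
single-cohort recovery of every region at once is intentionally marginal;
properties are therefore assessed per region across several seeded cohorts
and judged by majority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import call_matrix
from .compare import ComparisonConfig, aggregate_regions, compare_groups
from .genome import build_default_clone_map
from .model import CloneMap
from .simulate import (
    AberrationSpec,
    CohortSpec,
    breast_cohort_spec,
    cell_line_specific_regions,
    shared_regions,
    simulate_cohort,
)


def null_cohort_spec(seed: int = 0) -> CohortSpec:
    """A cohort with no planted events and no passengers: pure noise."""
    return CohortSpec(group_sizes={"cell_line": 24, "tissue": 35},
                      aberrations=[], passenger_rate=0.0, seed=seed)


def clones_in_region(clone_map: CloneMap, ab: AberrationSpec) -> pd.Index:
    mids = clone_map.midpoints()
    df = clone_map.df
    keep = (df["chrom"] == ab.chrom) & (mids >= ab.start_bp) & (mids < ab.end_bp)
    return clone_map.clone_ids[keep.to_numpy()]


def region_jaccard(regions: pd.DataFrame, ab: AberrationSpec, direction: str) -> float:
    """Jaccard between a planted interval and the union of the aggregated
    regions of the right chromosome/direction that overlap it."""
    overlaps = []
    for _, rr in regions.iterrows():
        if rr["chrom"] != ab.chrom or rr["direction"] != direction:
            continue
        if min(rr["end_bp"], ab.end_bp) > max(rr["start_bp"], ab.start_bp):
            overlaps.append((int(rr["start_bp"]), int(rr["end_bp"])))
    if not overlaps:
        return 0.0
    inter = sum(min(e, ab.end_bp) - max(s, ab.start_bp) for s, e in overlaps)
    union = (ab.end_bp - ab.start_bp) + sum(e - s for s, e in overlaps) - inter
    return inter / union


@dataclass
class RecoveryResult:
    """Per-region recovery tallies across seeded cohorts."""

    n_seeds: int
    recovered: dict[str, int]  # planted region -> seeds with >=1 significant clone
    jaccard_ok: dict[str, int]  # planted region -> seeds with Jaccard > 0.5
    shared_clean: dict[str, int]  # shared region -> seeds with no significant clone

    def majorities(self) -> dict[str, bool]:
        half = self.n_seeds / 2
        out = {f"recovered:{k}": v > half for k, v in self.recovered.items()}
        out.update({f"jaccard:{k}": v > half for k, v in self.jaccard_ok.items()})
        out.update({f"shared_clean:{k}": v > half for k, v in self.shared_clean.items()})
        return out


def evaluate_recovery(seeds, spec_factory=breast_cohort_spec,
                      jaccard_min: float = 0.5) -> RecoveryResult:
    """Run the pipeline over seeded cohorts and tally planted-region recovery.

    For each cell-line-specific planted region (strong one-sided prevalence
    contrast) a seed counts as recovery when at least one clone inside the
    region is Bonferroni-significant, and as localized when the aggregated
    significant regions overlap the planted interval with Jaccard >
    ``jaccard_min``.  Shared regions count as clean when they contain no
    significant clone.
    """
    seeds = list(seeds)
    spec0 = spec_factory(seed=0)
    clone_map = spec0.clone_map if spec0.clone_map is not None else build_default_clone_map()
    cl_regions = cell_line_specific_regions(spec0)
    sh_regions = shared_regions(spec0)
    recovered = {ab.name: 0 for ab in cl_regions}
    jaccard_ok = {ab.name: 0 for ab in cl_regions}
    shared_clean = {ab.name: 0 for ab in sh_regions}

    for seed in seeds:
        spec = spec_factory(seed=seed)
        ratios, design, _ = simulate_cohort(spec)
        calls = call_matrix(ratios)
        enriched_label = design.labels[0]  # cell_line sorts first
        results, regions = {}, {}
        for kind in ("gain", "loss"):
            cfg = ComparisonConfig(aberration_type=kind, m=clone_map.m)
            results[kind] = compare_groups(calls, design, cfg, clone_map=clone_map)
            regions[kind] = aggregate_regions(results[kind], clone_map)
        for ab in cl_regions:
            res = results[ab.kind]
            sig = set(res.loc[res["significant"], "clone_id"])
            if sig & set(clones_in_region(clone_map, ab)):
                recovered[ab.name] += 1
            if region_jaccard(regions[ab.kind], ab, enriched_label) > jaccard_min:
                jaccard_ok[ab.name] += 1
        for ab in sh_regions:
            res = results[ab.kind]
            sig = set(res.loc[res["significant"], "clone_id"])
            if not (sig & set(clones_in_region(clone_map, ab))):
                shared_clean[ab.name] += 1
    return RecoveryResult(len(seeds), recovered, jaccard_ok, shared_clean)


def family_wise_error(seeds, alpha: float = 0.05) -> float:
    """Proportion of null cohorts with any Bonferroni-significant clone.

    Gains and losses are both tested (the pipeline's two standing analyses);
    a cohort counts as a family-wise error if either run flags any clone.
    """
    seeds = list(seeds)
    clone_map = build_default_clone_map()
    n_bad = 0
    for seed in seeds:
        ratios, design, _ = simulate_cohort(null_cohort_spec(seed))
        calls = call_matrix(ratios)
        any_sig = False
        for kind in ("gain", "loss"):
            cfg = ComparisonConfig(alpha=alpha, aberration_type=kind, m=clone_map.m)
            res = compare_groups(calls, design, cfg)
            any_sig |= bool(res["significant"].any())
        n_bad += any_sig
    return n_bad / len(seeds)
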