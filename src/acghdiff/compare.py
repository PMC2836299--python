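"""Clone-by-clone 2x2 comparison of aberration frequencies between groups.

The per-clone test is the Pearson chi-square on [[a, n1-a], [b, n2-b]]
WITHOUT Yates continuity correction, two-sided with 1 df — the flavor that
reproduces the printed P-values of the emulated study exactly from its
printed counts (e.g. 18/24 vs 1/35 -> 5.68551E-09).  Family-wise error is
controlled by Bonferroni at alpha/m, with m the clone count of the array.
Fisher's exact test is available as an option, not the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .model import GAIN, LOSS, CallMatrix, CloneMap, GroupDesign, chrom_sort_key
from .stats import _group_count_frame


@dataclass(frozen=True)
class ComparisonConfig:
    """Settings of the clone-wise comparison."""

    alpha: float = 0.05
    m: int | None = None  # multiple-testing universe; None -> clone count
    aberration_type: str = "gain"  # gain | loss | amplification
    use_fisher: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1")
        if self.aberration_type not in ("gain", "loss", "amplification"):
            raise ValueError(f"unknown aberration_type {self.aberration_type!r}")


def chi2_2x2(a: int, n1: int, b: int, n2: int) -> tuple[float, float, bool]:
    """Uncorrected Pearson chi-square on a 2x2 frequency table.

    Returns (chi2, two-sided P with 1 df, degenerate).  A table with an empty
    margin (no aberrant sample anywhere, or aberrant everywhere) carries no
    contrast and is returned as (0, 1, True).
    """
    if not (0 <= a <= n1 and 0 <= b <= n2) or n1 <= 0 or n2 <= 0:
        raise ValueError(f"invalid 2x2 counts a={a} n1={n1} b={b} n2={n2}")
    if a + b == 0 or a + b == n1 + n2:
        return 0.0, 1.0, True
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), False


def fisher_2x2(a: int, n1: int, b: int, n2: int) -> tuple[float, float, bool]:
    """Two-sided Fisher exact P for the same table (odds ratio as statistic)."""
    if not (0 <= a <= n1 and 0 <= b <= n2) or n1 <= 0 or n2 <= 0:
        raise ValueError(f"invalid 2x2 counts a={a} n1={n1} b={b} n2={n2}")
    if a + b == 0 or a + b == n1 + n2:
        return 0.0, 1.0, True
    stat, p = sps.fisher_exact([[a, n1 - a], [b, n2 - b]], alternative="two-sided")
    return float(stat), float(p), False


def significance_threshold(cfg: ComparisonConfig, default_m: int | None = None) -> float:
    """Bonferroni cut-off alpha/m (exact quotient, no rounding)."""
    m = cfg.m if cfg.m is not None else default_m
    if m is None:
        raise ValueError("m unknown: set ComparisonConfig.m or pass default_m")
    return cfg.alpha / m


RESULT_COLUMNS = ["clone_id", "aberration_type", "count_g1", "n_g1", "count_g2",
                  "n_g2", "chi2", "p_value", "significant", "degenerate"]


def compare_groups(calls: CallMatrix, design: GroupDesign,
                   cfg: ComparisonConfig = ComparisonConfig(),
                   clone_map: CloneMap | None = None) -> pd.DataFrame:
    """Test every clone for a frequency difference between the two groups.

    Group 1 is the lexicographically first group label.  Clones with zero
    informative samples in either group are excluded (their count is in the
    frame's ``attrs['n_excluded']``).  The result is sorted by ascending P
    (ties keep genome order) and flagged significant when P < alpha/m with m
    defaulting to the clone count of the matrix.
    """
    counts = _group_count_frame(calls, design)
    g1, g2 = design.labels
    key = {"gain": "n_gain", "loss": "n_loss", "amplification": "n_amp"}[cfg.aberration_type]
    a = counts[g1][key]
    b = counts[g2][key]
    n1 = counts[g1]["n_informative"]
    n2 = counts[g2]["n_informative"]
    testable = (n1 > 0) & (n2 > 0)
    thr = significance_threshold(cfg, default_m=len(calls.clone_ids))
    test = fisher_2x2 if cfg.use_fisher else chi2_2x2

    rows = []
    for i in np.flatnonzero(testable):
        chi2, p, degenerate = test(int(a[i]), int(n1[i]), int(b[i]), int(n2[i]))
        rows.append((calls.clone_ids[i], cfg.aberration_type, int(a[i]), int(n1[i]),
                     int(b[i]), int(n2[i]), chi2, p, p < thr, degenerate))
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if clone_map is not None:
        ann = clone_map.df
        out["cytoband"] = ann["cytoband"].reindex(out["clone_id"]).to_numpy()
        out["genes"] = [";".join(g) for g in ann["genes"].reindex(out["clone_id"])]
    else:
        out["cytoband"] = ""
        out["genes"] = ""
    out = out.sort_values("p_value", kind="mergesort", ignore_index=True)
    out.attrs["n_excluded"] = int((~testable).sum())
    out.attrs["threshold"] = thr
    out.attrs["groups"] = (g1, g2)
    return out


def aggregate_regions(results: pd.DataFrame, clone_map: CloneMap,
                      max_gap_bp: int = 3_000_000) -> pd.DataFrame:
    """Merge significant clones into regions.

    Clones of the same chromosome and direction (enriched in group 1 vs
    group 2) are merged when separated by at most ``max_gap_bp``.  Returns a
    frame with one row per region: span, cytoband span, direction, member
    count and the minimum P among members.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be >= 0")
    sig = results[results["significant"]].copy()
    if sig.empty:
        return pd.DataFrame(columns=["chrom", "start_bp", "end_bp", "cytoband_span",
                                     "direction", "n_clones", "min_p", "clone_ids"])
    ann = clone_map.df
    sig["chrom"] = ann["chrom"].reindex(sig["clone_id"]).to_numpy()
    sig["start_bp"] = ann["start_bp"].reindex(sig["clone_id"]).to_numpy()
    sig["end_bp"] = ann["end_bp"].reindex(sig["clone_id"]).to_numpy()
    sig["cytoband"] = ann["cytoband"].reindex(sig["clone_id"]).to_numpy()
    g1, g2 = results.attrs.get("groups", ("group1", "group2"))
    freq1 = sig["count_g1"] / sig["n_g1"]
    freq2 = sig["count_g2"] / sig["n_g2"]
    sig["direction"] = np.where(freq1 > freq2, g1, g2)
    sig = sig.sort_values(["chrom", "start_bp"],
                          key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
                          kind="mergesort")

    regions = []
    for (chrom, direction), grp in sig.groupby(["chrom", "direction"], sort=False):
        grp = grp.sort_values("start_bp", kind="mergesort")
        current: list[pd.Series] = []
        last_end = None
        for _, row in grp.iterrows():
            if current and row["start_bp"] - last_end > max_gap_bp:
                regions.append(_close_region(current, chrom, direction))
                current = []
            current.append(row)
            last_end = row["end_bp"]
        if current:
            regions.append(_close_region(current, chrom, direction))
    out = pd.DataFrame(regions)
    out = out.sort_values(["chrom", "start_bp"],
                          key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
                          kind="mergesort", ignore_index=True)
    return out


def _close_region(members: list[pd.Series], chrom: str, direction: str) -> dict:
    bands = [m["cytoband"] for m in members if m["cytoband"]]
    if not bands:
        span = ""
    elif bands[0] == bands[-1]:
        span = bands[0]
    else:
        span = f"{bands[0]}-{bands[-1]}"
    return dict(
        chrom=chrom,
        start_bp=int(min(m["start_bp"] for m in members)),
        end_bp=int(max(m["end_bp"] for m in members)),
        cytoband_span=span,
        direction=direction,
        n_clones=len(members),
        min_p=float(min(m["p_value"] for m in members)),
        clone_ids=[m["clone_id"] for m in members],
    )


class GroupComparison(BaseEstimator):
    """Sklearn-style estimator: clone-wise two-group frequency testing.

    ``fit(X, y)`` takes call codes with samples as rows and clones as columns
    (the output of :class:`~acghdiff.calling.DCNACaller`) and binary group
    labels ``y``; it computes one uncorrected Pearson chi-square per clone
    and Bonferroni-flags significance.

    Fitted attributes
    -----------------
    results_ : DataFrame sorted by ascending P (one row per testable clone)
    threshold_ : float, the Bonferroni cut-off alpha/m
    classes_ : the two group labels, sorted
    """

    def __init__(self, aberration_type: str = "gain", alpha: float = 0.05,
                 m: int | None = None, use_fisher: bool = False):
        self.aberration_type = aberration_type
        self.alpha = alpha
        self.m = m
        self.use_fisher = use_fisher

    def fit(self, X, y):
        from .calling import codes_to_call_matrix

        X = np.asarray(X.to_numpy() if hasattr(X, "to_numpy") else X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be samples x clones with one label per sample")
        self.n_features_in_ = X.shape[1]
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
        clone_ids = [f"f{j}" for j in range(X.shape[1])]
        calls = codes_to_call_matrix(X, clone_ids, sample_ids)
        design = GroupDesign(pd.Series(y.astype(str), index=sample_ids))
        cfg = ComparisonConfig(alpha=self.alpha, m=self.m,
                               aberration_type=self.aberration_type,
                               use_fisher=self.use_fisher)
        res = compare_groups(calls, design, cfg)
        # restore feature order for the fitted attributes
        order = res["clone_id"].str.removeprefix("f").astype(int)
        self.results_ = res.assign(feature_index=order.to_numpy())
        self.threshold_ = res.attrs["threshold"]
        self.classes_ = np.array(design.labels)
        self.pvalues_ = np.full(X.shape[1], np.nan)
        self.pvalues_[self.results_["feature_index"]] = self.results_["p_value"]
        return self

    def get_support(self) -> np.ndarray:
        """Boolean mask of Bonferroni-significant clones, in feature order."""
        if not hasattr(self, "results_"):
            raise AttributeError("GroupComparison is not fitted")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        sig = self.results_[self.results_["significant"]]
        mask[sig["feature_index"]] = True
        return mask
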