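"""Per-clone frequency profiles, per-sample aberration burden, and
frequent-amplification listings.

All denominators are "informative" counts: the number of non-missing samples
for that clone within a group.  This is what produces the varying
denominators (23/24, 33/35, ...) seen in real BAC-array reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import GAIN, LOSS, MISSING, CallMatrix, GroupDesign


def _group_count_frame(calls: CallMatrix, design: GroupDesign) -> dict[str, dict[str, np.ndarray]]:
    """Per group: per-clone counts of gains, losses, amps and informative."""
    design.check_samples(calls.sample_ids)
    state = calls.state.to_numpy()
    amp = calls.amplified.to_numpy()
    out: dict[str, dict[str, np.ndarray]] = {}
    for g in design.labels:
        cols = calls.sample_ids.get_indexer(
            [s for s in design.samples(g) if s in calls.sample_ids]
        )
        s = state[:, cols]
        out[g] = {
            "n_gain": (s == GAIN).sum(axis=1),
            "n_loss": (s == LOSS).sum(axis=1),
            "n_amp": amp[:, cols].sum(axis=1),
            "n_informative": (s != MISSING).sum(axis=1),
        }
    return out


def clone_frequencies(calls: CallMatrix, design: GroupDesign) -> pd.DataFrame:
    """Tidy frame, one row per clone per group, with aberration frequencies.

    Frequencies divide by the informative denominator; a clone with zero
    informative samples in a group gets NaN (undefined), never 0.
    """
    counts = _group_count_frame(calls, design)
    frames = []
    for g in design.labels:
        c = counts[g]
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = c["n_informative"].astype(float)
            denom[denom == 0] = np.nan
            df = pd.DataFrame(
                {
                    "clone_id": calls.clone_ids,
                    "group": g,
                    "n_gain": c["n_gain"],
                    "n_loss": c["n_loss"],
                    "n_amp": c["n_amp"],
                    "n_informative": c["n_informative"],
                    "freq_gain": c["n_gain"] / denom,
                    "freq_loss": c["n_loss"] / denom,
                    "freq_amp": c["n_amp"] / denom,
                }
            )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def ttest_from_summary(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int,
                       equal_var: bool = True) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries; returns (t, df, two-sided P).

    The default is the classic pooled-variance Student test; ``equal_var=False``
    switches to Welch.  SDs are sample SDs (n-1 denominator).
    """
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass
class BurdenSummary:
    """Aberration burden per sample with group summaries and t-tests."""

    per_sample: pd.DataFrame  # sample_id, group, n_gain_clones, n_loss_clones, n_amp_clones
    group_summary: pd.DataFrame  # group x (metric, mean/sd/n)
    tests: pd.DataFrame  # metric, t, df, p_value (may be empty if a group < 2)


_BURDEN_METRICS = ("n_gain_clones", "n_loss_clones", "n_amp_clones")


def sample_burden(calls: CallMatrix, design: GroupDesign,
                  equal_var: bool = True) -> BurdenSummary:
    """Count aberrant clones per sample and contrast group means.

    Missing cells contribute to no count.  SDs use the n-1 denominator; the
    between-group contrast is a two-sided pooled-variance Student t-test
    (Welch behind ``equal_var=False``).
    """
    design.check_samples(calls.sample_ids)
    state = calls.state
    per_sample = pd.DataFrame(
        {
            "sample_id": calls.sample_ids,
            "group": design.assignments.reindex(calls.sample_ids).to_numpy(),
            "n_gain_clones": (state == GAIN).sum(axis=0).to_numpy(),
            "n_loss_clones": (state == LOSS).sum(axis=0).to_numpy(),
            "n_amp_clones": calls.amplified.sum(axis=0).to_numpy(),
        }
    )
    rows = []
    for g in design.labels:
        sub = per_sample[per_sample["group"] == g]
        for metric in _BURDEN_METRICS:
            rows.append(dict(group=g, metric=metric, mean=sub[metric].mean(),
                             sd=sub[metric].std(ddof=1), n=len(sub)))
    group_summary = pd.DataFrame(rows)

    tests = []
    g1, g2 = design.labels
    n1 = (per_sample["group"] == g1).sum()
    n2 = (per_sample["group"] == g2).sum()
    if min(n1, n2) < 2:
        import warnings

        warnings.warn("a group has fewer than 2 samples; t-tests skipped")
    else:
        for metric in _BURDEN_METRICS:
            a = per_sample.loc[per_sample["group"] == g1, metric]
            b = per_sample.loc[per_sample["group"] == g2, metric]
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
                t, df, p = 0.0, float(n1 + n2 - 2), 1.0
            else:
                t, df, p = ttest_from_summary(
                    a.mean(), a.std(ddof=1), n1, b.mean(), b.std(ddof=1), n2,
                    equal_var=equal_var,
                )
            tests.append(dict(metric=metric, t=t, df=df, p_value=p))
    return BurdenSummary(per_sample=per_sample, group_summary=group_summary,
                         tests=pd.DataFrame(tests, columns=["metric", "t", "df", "p_value"]))


def frequent_amplifications(calls: CallMatrix, design: GroupDesign,
                            min_count: int = 1) -> pd.DataFrame:
    """Per-group list of clones amplified in at least ``min_count`` samples.

    Sorted by descending count, then genome position (the row order of the
    call matrix, which follows the clone map).  Percentages are count over
    the full group size, reported at full precision.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = _group_count_frame(calls, design)
    sizes = design.group_sizes()
    frames = []
    for g in design.labels:
        n_amp = counts[g]["n_amp"]
        pos = np.arange(len(n_amp))
        keep = n_amp >= min_count
        df = pd.DataFrame(
            {
                "group": g,
                "clone_id": calls.clone_ids[keep],
                "count": n_amp[keep],
                "n_group": sizes[g],
                "pct": 100.0 * n_amp[keep] / sizes[g],
                "_pos": pos[keep],
            }
        ).sort_values(["count", "_pos"], ascending=[False, True], kind="mergesort")
        frames.append(df.drop(columns="_pos"))
    return pd.concat(frames, ignore_index=True)
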