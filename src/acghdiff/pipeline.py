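"""End-to-end orchestration: simulate/load -> call -> stats -> compare -> report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as aio
from .calling import call_matrix
from .compare import ComparisonConfig, aggregate_regions, compare_groups, significance_threshold
from .model import CallMatrix, CloneMap, GroupDesign, Thresholds
from .simulate import CohortSpec, simulate_cohort
from .stats import clone_frequencies, frequent_amplifications, sample_burden

log = logging.getLogger("acghdiff")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``cohort_spec`` (simulate the inputs) or all three input paths
    must be given.
    """

    out_dir: str | Path
    clone_map_path: str | Path | None = None
    matrix_path: str | Path | None = None
    design_path: str | Path | None = None
    cohort_spec: CohortSpec | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    alpha: float = 0.05
    m: int | None = None
    max_gap_bp: int = 3_000_000
    min_amp_count: int = 1
    use_fisher: bool = False

    def validate(self) -> None:
        have_paths = self.matrix_path is not None and self.design_path is not None
        if self.cohort_spec is None and not have_paths:
            raise ValueError(
                "RunConfig needs either a cohort_spec or matrix_path + design_path"
            )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order and write all tables under ``cfg.out_dir``.

    Returns the machine-readable run summary (also written as summary.json).
    Identical config and seed produce byte-identical outputs.  On a stage
    failure the partial outputs stay on disk next to a FAILED marker naming
    the stage.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if cfg.cohort_spec is not None:
            stage = "simulate"
            spec = cfg.cohort_spec
            ratios, design, truth = simulate_cohort(spec)
            clone_map = spec.clone_map
            if clone_map is None:
                from .genome import build_default_clone_map

                clone_map = build_default_clone_map()
            aio.write_clone_map(clone_map, out / "clone_map.tsv")
            aio.write_ratio_matrix(ratios, out / "log2_ratios.tsv")
            aio.write_design(design, out / "design.tsv")
            truth.segments.to_csv(out / "truth_segments.tsv", sep="\t", index=False)
            truth.contamination.rename("contamination").to_frame().to_csv(
                out / "truth_samples.tsv", sep="\t", index_label="sample_id"
            )
            spec.to_yaml(out / "cohort_spec.yaml")
            seed = spec.seed
        else:
            stage = "load"
            clone_map = (
                aio.read_clone_map(cfg.clone_map_path)
                if cfg.clone_map_path
                else None
            )
            ratios = aio.read_ratio_matrix(cfg.matrix_path, clone_map)
            design = aio.read_design(cfg.design_path)
            seed = None
        design.check_samples(ratios.columns)

        stage = "call"
        calls = call_matrix(ratios, cfg.thresholds)
        aio.write_call_matrix(calls, out / "calls.tsv")

        stage = "stats"
        freqs = clone_frequencies(calls, design)
        freqs.to_csv(out / "frequencies.tsv", sep="\t", index=False,
                     float_format="%.6g")
        burden = sample_burden(calls, design)
        burden.per_sample.to_csv(out / "burden_per_sample.tsv", sep="\t", index=False)
        burden.group_summary.to_csv(out / "burden_summary.tsv", sep="\t",
                                    index=False, float_format="%.6g")
        burden.tests.to_csv(out / "burden_tests.tsv", sep="\t", index=False,
                            float_format="%.6g")
        amps = frequent_amplifications(calls, design, cfg.min_amp_count)
        amps.to_csv(out / "amplifications.tsv", sep="\t", index=False,
                    float_format="%.6g")

        stage = "compare"
        m_default = cfg.m if cfg.m is not None else (clone_map.m if clone_map else len(calls.clone_ids))
        summary_cmp = {}
        for ab_type in ("gain", "loss", "amplification"):
            ccfg = ComparisonConfig(alpha=cfg.alpha, m=m_default,
                                    aberration_type=ab_type,
                                    use_fisher=cfg.use_fisher)
            res = compare_groups(calls, design, ccfg, clone_map=clone_map)
            aio.write_results_table(res, out / f"comparison_{ab_type}.tsv")
            if clone_map is not None:
                regions = aggregate_regions(res, clone_map, cfg.max_gap_bp)
                aio.write_regions_table(regions, out / f"regions_{ab_type}.tsv")
                n_regions = len(regions)
            else:
                n_regions = None
            summary_cmp[ab_type] = {
                "clones_tested": len(res),
                "clones_excluded": res.attrs["n_excluded"],
                "significant": int(res["significant"].sum()),
                "regions": n_regions,
            }

        stage = "report"
        g1, g2 = design.labels
        summary = {
            "groups": {g1: len(design.samples(g1)), g2: len(design.samples(g2))},
            "clones": int(len(calls.clone_ids)),
            "m": int(m_default),
            "alpha": cfg.alpha,
            "bonferroni_threshold": significance_threshold(
                ComparisonConfig(alpha=cfg.alpha, m=m_default)
            ),
            "seed": seed,
            "thresholds": {
                "gain_cut": cfg.thresholds.gain_cut,
                "loss_cut": cfg.thresholds.loss_cut,
                "amp_cut": cfg.thresholds.amp_cut,
            },
            "comparisons": summary_cmp,
            "burden": {
                row["group"] + "." + row["metric"]: {
                    "mean": round(float(row["mean"]), 6),
                    "sd": round(float(row["sd"]), 6) if pd.notna(row["sd"]) else None,
                    "n": int(row["n"]),
                }
                for _, row in burden.group_summary.iterrows()
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        (out / "report.txt").write_text(render_report(summary))
        marker = out / "FAILED"
        if marker.exists():
            marker.unlink()
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def render_report(summary: dict) -> str:
    """Human-readable run report from the machine summary."""
    lines = ["aCGH two-group comparison run", "=" * 32]
    groups = summary["groups"]
    lines.append("samples: " + ", ".join(f"{g} n={n}" for g, n in groups.items()))
    lines.append(f"clones: {summary['clones']} (m = {summary['m']})")
    lines.append(
        f"Bonferroni threshold: alpha {summary['alpha']} / m = "
        f"{summary['bonferroni_threshold']:.4E}"
    )
    if summary.get("seed") is not None:
        lines.append(f"seed: {summary['seed']}")
    lines.append("")
    for ab, s in summary["comparisons"].items():
        lines.append(
            f"{ab:14s} tested {s['clones_tested']:5d}  significant {s['significant']:4d}"
            + (f"  regions {s['regions']}" if s["regions"] is not None else "")
        )
    lines.append("")
    lines.append("aberration burden (mean +/- SD clones per sample):")
    for key, v in summary["burden"].items():
        sd = f" +/- {v['sd']:.1f}" if v["sd"] is not None else ""
        lines.append(f"  {key:28s} {v['mean']:8.1f}{sd}  (n={v['n']})")
    return "\n".join(lines) + "\n"


def plot_frequency_tracks(freqs: pd.DataFrame, clone_map: CloneMap, path: str | Path) -> None:
    """Genome-track plot: per-group gain frequency up, loss frequency down."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(dict.fromkeys(freqs["group"]))
    fig, axes = plt.subplots(len(groups), 1, figsize=(14, 3 * len(groups)),
                             sharex=True, squeeze=False)
    ann = clone_map.df
    # cumulative genome coordinate for the x axis
    offsets = {}
    cursor = 0
    for chrom in dict.fromkeys(ann["chrom"]):
        offsets[chrom] = cursor
        cursor += int(ann.loc[ann["chrom"] == chrom, "end_bp"].max())
    x = ann["start_bp"].to_numpy() + ann["chrom"].map(offsets).to_numpy()
    for ax, g in zip(axes.ravel(), groups):
        sub = freqs[freqs["group"] == g].set_index("clone_id").reindex(ann.index)
        ax.fill_between(x, 0, sub["freq_gain"], color="green", step="mid",
                        label="gain")
        ax.fill_between(x, 0, -sub["freq_loss"], color="red", step="mid",
                        label="loss")
        ax.set_ylim(-1, 1)
        ax.set_ylabel(f"{g}\nfrequency")
        ax.axhline(0, color="k", lw=0.5)
        for chrom, off in offsets.items():
            ax.axvline(off, color="grey", lw=0.3)
        ax.legend(loc="upper right", fontsize=8)
    axes.ravel()[-1].set_xlabel("genome position (concatenated chromosomes)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
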