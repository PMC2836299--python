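"""Synthetic two-group aCGH cohorts with planted aberrations.

The generator emulates a ~1 Mb BAC array study of breast-cancer cell lines
versus microdissected primary tumors: segmental gains (3 copies), losses
(1 copy) and amplifications (6 copies) planted with per-group prevalences,
diluted by residual normal-cell contamination (<= 10%), measured with
homoscedastic Gaussian noise on the log2 scale, and thinned by per-cell
dropout.  Ground truth (per-sample segments, integer copy number per clone,
contamination) is returned so calling and testing can be validated by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import CHROM_LENGTH_MB, MB, build_default_clone_map, chrom_length_bp
from .model import CloneMap, GroupDesign

_DEFAULT_COPY_NUMBER = {"gain": 3, "loss": 1, "amplification": 6}

#: Dilution order: when segments overlap within one sample, the later kind
#: in this tuple wins (amplification > loss > gain).
_KIND_PRECEDENCE = ("gain", "loss", "amplification")


def expected_log2(copy_number, contamination, floor: float = -5.0):
    """Expected log2 ratio of a tumor copy number diluted by normal cells.

    A fraction ``contamination`` of cells is diploid, so the measured ratio
    is ((1-c)*CN + c*2) / 2.  The result is clamped below at ``floor`` (a
    homozygous deletion in a pure sample would otherwise be -inf).
    """
    cn = np.asarray(copy_number, dtype=float)
    c = np.asarray(contamination, dtype=float)
    if (cn < 0).any():
        raise ValueError("copy number must be >= 0")
    if ((c < 0) | (c >= 1)).any():
        raise ValueError("contamination must be in [0, 1)")
    ratio = ((1.0 - c) * cn + 2.0 * c) / 2.0
    with np.errstate(divide="ignore"):
        out = np.maximum(np.log2(ratio), floor)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class AberrationSpec:
    """One recurrent segmental event with per-group carrier probabilities."""

    chrom: str
    start_bp: int
    end_bp: int
    kind: str  # gain | loss | amplification
    prevalence: dict[str, float]
    copy_number: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _DEFAULT_COPY_NUMBER:
            raise ValueError(f"unknown aberration kind {self.kind!r}")
        if self.copy_number is None:
            self.copy_number = _DEFAULT_COPY_NUMBER[self.kind]
        cn = self.copy_number
        if self.kind == "gain" and cn < 3:
            raise ValueError("gain needs copy_number >= 3")
        if self.kind == "loss" and cn > 1:
            raise ValueError("loss needs copy_number <= 1")
        if self.kind == "amplification" and cn < 5:
            raise ValueError("amplification needs copy_number >= 5")
        if not (0 <= self.start_bp < self.end_bp):
            raise ValueError(f"invalid region [{self.start_bp}, {self.end_bp})")
        if self.chrom in CHROM_LENGTH_MB and self.end_bp > chrom_length_bp(self.chrom):
            raise ValueError(f"{self.name or self.kind}: region exceeds chromosome {self.chrom}")
        for g, p in self.prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence for group {g!r} outside [0,1]: {p}")


@dataclass
class CohortSpec:
    """Full generative description of a synthetic two-group cohort."""

    group_sizes: dict[str, int]
    aberrations: list[AberrationSpec] = field(default_factory=list)
    contamination_max: float = 0.10
    noise_sd: float = 0.10
    missing_rate: float = 0.02
    passenger_rate: float = 2.0
    passenger_length_bp: tuple[float, float] = (1 * MB, 20 * MB)
    seed: int = 0
    clone_map: CloneMap | None = None

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 2:
            raise ValueError("exactly two groups required")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("each group must be non-empty")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for p, label in ((self.contamination_max, "contamination_max"),
                         (self.missing_rate, "missing_rate")):
            if not (0.0 <= p < 1.0):
                raise ValueError(f"{label} outside [0,1): {p}")
        if self.passenger_rate < 0:
            raise ValueError("passenger_rate must be >= 0")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "group_sizes": dict(self.group_sizes),
            "aberrations": [
                {k: v for k, v in asdict(ab).items() if v not in ("", None)}
                for ab in self.aberrations
            ],
            "contamination_max": self.contamination_max,
            "noise_sd": self.noise_sd,
            "missing_rate": self.missing_rate,
            "passenger_rate": self.passenger_rate,
            "passenger_length_bp": list(self.passenger_length_bp),
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        d["aberrations"] = [AberrationSpec(**ab) for ab in d.get("aberrations", [])]
        if "passenger_length_bp" in d:
            d["passenger_length_bp"] = tuple(d["passenger_length_bp"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What the simulator actually planted, for parameter-recovery tests."""

    copy_number: pd.DataFrame  # clones x samples, integer CN (baseline 2)
    segments: pd.DataFrame  # sample_id, chrom, start_bp, end_bp, kind, copy_number, origin
    contamination: pd.Series  # per sample

    def segments_of(self, sample_id: str) -> pd.DataFrame:
        return self.segments[self.segments["sample_id"] == sample_id]


def _sample_ids(group_sizes: Mapping[str, int]) -> tuple[list[str], list[str]]:
    ids, groups = [], []
    for g, n in group_sizes.items():
        for i in range(n):
            ids.append(f"{g}_{i + 1:02d}")
            groups.append(g)
    return ids, groups


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroupDesign, GroundTruth]:
    """Simulate a cohort; fully reproducible from ``spec.seed``.

    Random draws happen in a fixed order (per sample: contamination, planted
    event carriage, passenger segments; then noise; then missingness), so the
    same spec always yields a bit-identical matrix.
    """
    rng = np.random.default_rng(spec.seed)
    clone_map = spec.clone_map if spec.clone_map is not None else build_default_clone_map()
    sample_ids, groups = _sample_ids(spec.group_sizes)
    n_samples = len(sample_ids)
    m = clone_map.m

    mids = clone_map.midpoints().to_numpy()
    chroms = clone_map.df["chrom"].to_numpy()
    chrom_names = list(dict.fromkeys(chroms))
    chrom_rows = {c: np.flatnonzero(chroms == c) for c in chrom_names}
    chrom_len = {c: chrom_length_bp(c) if c in CHROM_LENGTH_MB
                 else int(clone_map.df.loc[chroms == c, "end_bp"].max())
                 for c in chrom_names}
    chrom_weights = np.array([chrom_len[c] for c in chrom_names], dtype=float)
    chrom_weights /= chrom_weights.sum()

    cn = np.full((m, n_samples), 2, dtype=np.int16)
    contamination = np.empty(n_samples)
    seg_rows: list[dict] = []
    lo_len, hi_len = spec.passenger_length_bp

    for j, (sid, grp) in enumerate(zip(sample_ids, groups)):
        contamination[j] = rng.uniform(0.0, spec.contamination_max)
        carried: list[tuple[str, int, int, str, int, str]] = []
        for ab in spec.aberrations:
            if rng.random() < ab.prevalence.get(grp, 0.0):
                carried.append((ab.chrom, ab.start_bp, ab.end_bp, ab.kind,
                                ab.copy_number, "planted"))
        n_passengers = rng.poisson(spec.passenger_rate)
        for _ in range(n_passengers):
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_weights)]
            length = int(np.exp(rng.uniform(np.log(lo_len), np.log(hi_len))))
            length = min(length, chrom_len[chrom])
            start = int(rng.uniform(0, chrom_len[chrom] - length))
            kind = "gain" if rng.random() < 0.5 else "loss"
            carried.append((chrom, start, start + length, kind,
                            _DEFAULT_COPY_NUMBER[kind], "passenger"))
        # resolve overlaps: amplification > loss > gain
        for kind_pass in _KIND_PRECEDENCE:
            for chrom, start, end, kind, copies, origin in carried:
                if kind != kind_pass:
                    continue
                rows = chrom_rows.get(chrom)
                if rows is None:
                    continue
                inside = rows[(mids[rows] >= start) & (mids[rows] < end)]
                cn[inside, j] = copies
        for chrom, start, end, kind, copies, origin in carried:
            seg_rows.append(dict(sample_id=sid, chrom=chrom, start_bp=start,
                                 end_bp=end, kind=kind, copy_number=copies,
                                 origin=origin))

    values = expected_log2(cn, contamination[np.newaxis, :])
    values = values + rng.normal(0.0, spec.noise_sd, size=(m, n_samples))
    missing = rng.random((m, n_samples)) < spec.missing_rate
    values[missing] = np.nan

    ratios = pd.DataFrame(values, index=clone_map.clone_ids, columns=sample_ids)
    design = GroupDesign(pd.Series(groups, index=sample_ids))
    truth = GroundTruth(
        copy_number=pd.DataFrame(cn, index=clone_map.clone_ids, columns=sample_ids),
        segments=pd.DataFrame(
            seg_rows,
            columns=["sample_id", "chrom", "start_bp", "end_bp", "kind",
                     "copy_number", "origin"],
        ),
        contamination=pd.Series(contamination, index=sample_ids, name="contamination"),
    )
    return ratios, design, truth


CELL_LINE = "cell_line"
TISSUE = "tissue"


def breast_cohort_spec(seed: int = 0) -> CohortSpec:
    """Bundled two-group breast-cancer cohort: 24 cell lines vs 35 tumors.

    Planted regions mirror the recurrent events of the emulated study on the
    stylized genome: gains of distal 1q and 8q22 plus losses of 17p and 11q23
    shared by both groups; gains of 20q11, 20q13 and 5p14-15 plus losses of
    4p13-p16, 18q12, 18q21, Xq21 and Xq26-q28 recurrent almost exclusively in
    the cell lines; and a narrow HER2-locus style amplicon on 17q12 that is
    amplified in both groups but more often in cell lines (41.7% vs 17.1%).
    """
    A = AberrationSpec
    shared = {
        CELL_LINE: 0.54, TISSUE: 0.54,
    }
    shared_hi = {CELL_LINE: 0.625, TISSUE: 0.63}
    cl_gain = {CELL_LINE: 0.75, TISSUE: 0.03}
    aberrations = [
        # shared events, similar prevalence in both groups
        A("1", 310 * MB, 326 * MB, "gain", dict(shared), name="1q_distal_gain"),
        A("8", 118 * MB, 132 * MB, "gain", dict(shared_hi), name="8q22_gain"),
        A("17", 2 * MB, 28 * MB, "loss", dict(shared), name="17p_loss"),
        A("11", 115 * MB, 130 * MB, "loss", dict(shared_hi), name="11q23_loss"),
        # cell-line-specific gains (~0.75 vs ~0.03)
        A("20", 38 * MB, 48 * MB, "gain", dict(cl_gain), name="20q11_gain"),
        A("20", 62 * MB, 80 * MB, "gain", dict(cl_gain), name="20q13_gain"),
        A("5", 5 * MB, 30 * MB, "gain", dict(cl_gain), name="5p14_15_gain"),
        # cell-line-specific losses (prevalences follow the strongest
        # recurrent clone per region in the emulated study)
        A("4", 10 * MB, 55 * MB, "loss",
          {CELL_LINE: 0.667, TISSUE: 0.03}, name="4p13_p16_loss"),
        A("18", 30 * MB, 45 * MB, "loss",
          {CELL_LINE: 0.70, TISSUE: 0.03}, name="18q12_loss"),
        A("18", 50 * MB, 66 * MB, "loss",
          {CELL_LINE: 0.75, TISSUE: 0.03}, name="18q21_loss"),
        A("X", 95 * MB, 110 * MB, "loss",
          {CELL_LINE: 0.75, TISSUE: 0.03}, name="Xq21_loss"),
        A("X", 160 * MB, 200 * MB, "loss",
          {CELL_LINE: 0.667, TISSUE: 0.03}, name="Xq26_q28_loss"),
        # HER2-amplicon analogue: amplified in both groups, unequally
        A("17", 38 * MB, 42 * MB, "amplification",
          {CELL_LINE: 0.417, TISSUE: 0.171}, name="17q12_amplicon"),
    ]
    return CohortSpec(
        group_sizes={CELL_LINE: 24, TISSUE: 35},
        aberrations=aberrations,
        seed=seed,
    )


def cell_line_specific_regions(spec: CohortSpec,
                               min_prevalence: float = 0.6,
                               max_other: float = 0.03) -> list[AberrationSpec]:
    """Planted gain/loss regions with a strong one-sided prevalence contrast."""
    out = []
    for ab in spec.aberrations:
        if ab.kind == "amplification":
            continue
        ps = sorted(ab.prevalence.values())
        if ps[-1] >= min_prevalence and ps[0] <= max_other:
            out.append(ab)
    return out


def shared_regions(spec: CohortSpec, max_diff: float = 0.1) -> list[AberrationSpec]:
    out = []
    for ab in spec.aberrations:
        if ab.kind == "amplification":
            continue
        ps = sorted(ab.prevalence.values())
        if ps[-1] - ps[0] <= max_diff:
            out.append(ab)
    return out
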