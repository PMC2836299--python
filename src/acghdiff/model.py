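"""Shared data model for the aCGH comparison pipeline.

Containers are thin, validated wrappers around pandas objects.  All genomic
matrices are oriented clones x samples (rows follow the clone map order);
coordinates are 0-based half-open base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Chromosome order used everywhere (breast cohort: Y excluded by default).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

# Call-state codes stored in CallMatrix.state (int8).
LOSS: int = -1
NEUTRAL: int = 0
GAIN: int = 1
MISSING: int = -9

#: On-disk tokens for call states; amplified gains are written as "GA".
STATE_TOKENS: dict[int, str] = {LOSS: "L", NEUTRAL: "N", GAIN: "G", MISSING: "NA"}


def chrom_sort_key(chrom: str) -> int:
    try:
        return CHROMOSOMES.index(str(chrom))
    except ValueError:
        raise ValueError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class BacClone:
    """One BAC probe: an identified interval on a chromosome."""

    clone_id: str
    chrom: str
    start_bp: int
    end_bp: int
    cytoband: str = ""
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.chrom not in CHROMOSOMES:
            raise ValueError(f"clone {self.clone_id}: unknown chromosome {self.chrom!r}")
        if not (0 <= self.start_bp < self.end_bp):
            raise ValueError(
                f"clone {self.clone_id}: invalid interval [{self.start_bp}, {self.end_bp})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start_bp + self.end_bp) // 2


class CloneMap:
    """Ordered genomic scaffold of BAC clones.

    Rows are sorted by (chromosome, start); ``m`` (the clone count) is the
    multiple-testing universe of the downstream Bonferroni correction.
    """

    COLUMNS = ("clone_id", "chrom", "start_bp", "end_bp", "cytoband", "genes")

    def __init__(self, clones: Iterable[BacClone], genome_label: str = "stylized"):
        clones = sorted(clones, key=lambda c: (chrom_sort_key(c.chrom), c.start_bp))
        ids = [c.clone_id for c in clones]
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate clone_id {dupes[0]!r} in clone map")
        self.genome_label = genome_label
        self._clones = clones
        self.df = pd.DataFrame(
            {
                "clone_id": ids,
                "chrom": [c.chrom for c in clones],
                "start_bp": [c.start_bp for c in clones],
                "end_bp": [c.end_bp for c in clones],
                "cytoband": [c.cytoband for c in clones],
                "genes": [list(c.genes) for c in clones],
            }
        ).set_index("clone_id", drop=False)

    @property
    def m(self) -> int:
        """Number of clones — the multiple-testing universe."""
        return len(self._clones)

    @property
    def clone_ids(self) -> pd.Index:
        return self.df.index

    @property
    def clones(self) -> list[BacClone]:
        return list(self._clones)

    def midpoints(self) -> pd.Series:
        return ((self.df["start_bp"] + self.df["end_bp"]) // 2).rename("midpoint_bp")

    def __len__(self) -> int:
        return self.m

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CloneMap):
            return NotImplemented
        return self._clones == other._clones

    def __repr__(self) -> str:
        return f"CloneMap(m={self.m}, genome={self.genome_label!r})"


class GroupDesign:
    """Assignment of every sample to one of exactly two groups."""

    def __init__(self, assignments: Mapping[str, str] | pd.Series):
        s = pd.Series(dict(assignments), dtype=object) if not isinstance(
            assignments, pd.Series
        ) else assignments.astype(object)
        if s.empty:
            raise ValueError("empty group design")
        labels = sorted(s.unique())
        if len(labels) != 2:
            raise ValueError(f"need exactly two group labels, got {labels}")
        self.assignments = s
        self.labels: tuple[str, str] = (labels[0], labels[1])

    def samples(self, label: str) -> list[str]:
        if label not in self.labels:
            raise KeyError(label)
        return list(self.assignments.index[self.assignments == label])

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples(g)) for g in self.labels}

    def check_samples(self, sample_ids: Sequence[str]) -> None:
        missing = set(sample_ids) - set(self.assignments.index)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")

    def __repr__(self) -> str:
        sizes = self.group_sizes()
        return f"GroupDesign({sizes})"


@dataclass
class CallMatrix:
    """Per clone x sample categorical copy-number state plus amplification flag.

    ``state`` holds int8 codes (LOSS/NEUTRAL/GAIN/MISSING); ``amplified`` is
    boolean and may only be True where ``state`` is GAIN.
    """

    state: pd.DataFrame
    amplified: pd.DataFrame

    def __post_init__(self) -> None:
        if self.state.shape != self.amplified.shape:
            raise ValueError("state and amplified shapes differ")
        if not (
            self.state.index.equals(self.amplified.index)
            and self.state.columns.equals(self.amplified.columns)
        ):
            raise ValueError("state and amplified are not aligned")
        bad = np.asarray(self.amplified) & (np.asarray(self.state) != GAIN)
        if bad.any():
            raise ValueError("amplified flag set on a non-gain cell")

    @property
    def clone_ids(self) -> pd.Index:
        return self.state.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.state.columns

    def missing_mask(self) -> pd.DataFrame:
        return self.state == MISSING

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallMatrix):
            return NotImplemented
        return self.state.equals(other.state) and self.amplified.equals(other.amplified)


@dataclass(frozen=True)
class Thresholds:
    """Log2-ratio cut-offs of the calling rule.

    Strict inequalities throughout: value > gain_cut is a gain, value <
    loss_cut a loss, value > amp_cut additionally an amplification.
    """

    gain_cut: float = 0.25
    loss_cut: float = -0.25
    amp_cut: float = 1.0

    def __post_init__(self) -> None:
        if not (self.loss_cut < 0.0 < self.gain_cut < self.amp_cut):
            raise ValueError(
                f"require loss_cut < 0 < gain_cut < amp_cut, got "
                f"({self.loss_cut}, {self.gain_cut}, {self.amp_cut})"
            )


def validate_ratio_matrix(values: pd.DataFrame, clone_map: CloneMap | None = None) -> pd.DataFrame:
    """Check a clones x samples log2-ratio frame: finite-or-NaN, known clones.

    Returns the frame reordered to clone-map order (restricted to its rows).
    """
    arr = values.to_numpy(dtype=float, copy=False)
    if np.isinf(arr).any():
        raise ValueError("log2-ratio matrix contains infinite values")
    if clone_map is not None:
        unknown = values.index.difference(clone_map.clone_ids)
        if len(unknown):
            raise ValueError(f"clones not present in clone map: {list(unknown[:5])}")
        order = [cid for cid in clone_map.clone_ids if cid in values.index]
        values = values.loc[order]
    return values
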