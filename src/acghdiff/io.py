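"""Readers and writers for every table the pipeline touches.

All files are UTF-8, tab-delimited, with '#'-prefixed comment lines ignored.
Coordinates are 0-based half-open.  Missing measurements are an empty cell or
"NA" on input and are always written back as "NA".
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    GAIN,
    LOSS,
    MISSING,
    NEUTRAL,
    STATE_TOKENS,
    BacClone,
    CallMatrix,
    CloneMap,
    GroupDesign,
    validate_ratio_matrix,
)

_NA_TOKENS = ("NA", "")

CLONE_MAP_HEADER = ("clone_id", "chrom", "start_bp", "end_bp", "cytoband", "genes")


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    """Non-comment, non-blank lines with their 1-based line numbers."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            out.append((lineno, stripped))
    return out


def _parse_coord(token: str, lineno: int, path: str | Path) -> int:
    try:
        value = int(token)
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: malformed coordinate {token!r}"
        ) from None
    if value < 0:
        raise ValueError(f"{path}:{lineno}: negative coordinate {value}")
    return value


def read_clone_map(path: str | Path, genome_label: str = "file") -> CloneMap:
    """Read a clone map from a headered TSV or a 4-column BED dialect.

    TSV columns: clone_id, chrom, start_bp, end_bp, cytoband, genes
    (semicolon-joined).  BED columns: chrom, start, end, clone_id (cytoband
    and genes left empty).  Input row order is irrelevant; the returned map
    is sorted by (chrom, start).
    """
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty clone map")
    first_fields = lines[0][1].split("\t")
    clones: list[BacClone] = []
    seen: set[str] = set()

    def _add(clone: BacClone, lineno: int) -> None:
        if clone.clone_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate clone_id {clone.clone_id!r}")
        seen.add(clone.clone_id)
        clones.append(clone)

    if first_fields[0] == "clone_id":  # headered TSV dialect
        if tuple(first_fields[: len(CLONE_MAP_HEADER)]) != CLONE_MAP_HEADER:
            raise ValueError(f"{path}: unexpected clone-map header {first_fields}")
        for lineno, line in lines[1:]:
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns")
            cid, chrom = fields[0], fields[1]
            start = _parse_coord(fields[2], lineno, path)
            end = _parse_coord(fields[3], lineno, path)
            cyto = fields[4] if len(fields) > 4 else ""
            genes = tuple(g for g in (fields[5].split(";") if len(fields) > 5 and fields[5] else []) if g)
            try:
                clone = BacClone(cid, chrom, start, end, cyto, genes)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            _add(clone, lineno)
    else:  # BED dialect: chrom, start, end, clone_id
        for lineno, line in lines:
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs 4 columns")
            chrom = fields[0].removeprefix("chr")
            start = _parse_coord(fields[1], lineno, path)
            end = _parse_coord(fields[2], lineno, path)
            try:
                clone = BacClone(fields[3], chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            _add(clone, lineno)
    return CloneMap(clones, genome_label=genome_label)


def write_clone_map(clone_map: CloneMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        fh.write("\t".join(CLONE_MAP_HEADER) + "\n")
        for c in clone_map.clones:
            fh.write(
                f"{c.clone_id}\t{c.chrom}\t{c.start_bp}\t{c.end_bp}\t{c.cytoband}\t"
                + ";".join(c.genes)
                + "\n"
            )


def _read_tsv_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype=str,
        keep_default_na=False,
        na_values=[],
    )


def read_ratio_matrix(path: str | Path, clone_map: CloneMap | None = None) -> pd.DataFrame:
    """Read a clones x samples log2-ratio matrix.

    First column is clone_id; every other column is one sample.  Empty cells
    and "NA" are missing.  Clones must be known to ``clone_map`` when one is
    given, and the result follows the map's ordering.
    """
    raw = _read_tsv_frame(path)
    if raw.columns[0] != "clone_id":
        raise ValueError(f"{path}: first column must be clone_id, got {raw.columns[0]!r}")
    raw = raw.set_index("clone_id")
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate clone_id {dup!r}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        parsed = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col].str.strip()):
            if cell in _NA_TOKENS:
                parsed[i] = math.nan
                continue
            try:
                parsed[i] = float(cell)  # exact round trip, unlike the fast parser
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} for clone "
                    f"{raw.index[i]!r}, sample {col!r}"
                ) from None
        values[col] = parsed
    return validate_ratio_matrix(values, clone_map)


def write_ratio_matrix(values: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("clone_id\t" + "\t".join(map(str, values.columns)) + "\n")
        arr = values.to_numpy(dtype=float)
        for cid, row in zip(values.index, arr):
            cells = ["NA" if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(cid) + "\t" + "\t".join(cells) + "\n")


def read_design(path: str | Path) -> GroupDesign:
    """Read a sample -> group table (columns sample_id, group)."""
    df = _read_tsv_frame(path)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ValueError(f"{path}: expected columns sample_id, group")
    return GroupDesign(pd.Series(df["group"].values, index=df["sample_id"].values))


def write_design(design: GroupDesign, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in design.assignments.items():
            fh.write(f"{sid}\t{grp}\n")


_TOKEN_TO_STATE = {"L": (LOSS, False), "N": (NEUTRAL, False), "G": (GAIN, False),
                   "GA": (GAIN, True), "NA": (MISSING, False)}


def write_call_matrix(calls: CallMatrix, path: str | Path) -> None:
    """Write calls with states encoded as L/N/G/GA/NA (GA = amplified gain)."""
    state = calls.state.to_numpy()
    amp = calls.amplified.to_numpy()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("clone_id\t" + "\t".join(map(str, calls.sample_ids)) + "\n")
        for i, cid in enumerate(calls.clone_ids):
            tokens = [
                "GA" if amp[i, j] else STATE_TOKENS[int(state[i, j])]
                for j in range(state.shape[1])
            ]
            fh.write(str(cid) + "\t" + "\t".join(tokens) + "\n")


def read_call_matrix(path: str | Path) -> CallMatrix:
    raw = _read_tsv_frame(path).set_index("clone_id")
    state = pd.DataFrame(index=raw.index, columns=raw.columns, dtype="int8")
    amp = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    for col in raw.columns:
        try:
            pairs = [_TOKEN_TO_STATE[t] for t in raw[col]]
        except KeyError as exc:
            raise ValueError(f"{path}: unknown call token {exc.args[0]!r}") from None
        state[col] = np.array([p[0] for p in pairs], dtype="int8")
        amp[col] = [p[1] for p in pairs]
    return CallMatrix(state=state, amplified=amp)


RESULTS_COLUMNS = (
    "clone_id",
    "cytoband",
    "genes",
    "count_g1",
    "n_g1",
    "count_g2",
    "n_g2",
    "chi2",
    "p_value",
    "significant",
)


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write clone-comparison results; P-values in scientific notation with
    six significant digits (e.g. 5.68551E-09)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULTS_COLUMNS) + "\n")
        for _, row in results.iterrows():
            genes = row.get("genes", "")
            if isinstance(genes, (list, tuple)):
                genes = ";".join(genes)
            fh.write(
                "\t".join(
                    [
                        str(row["clone_id"]),
                        str(row.get("cytoband", "")),
                        str(genes),
                        str(int(row["count_g1"])),
                        str(int(row["n_g1"])),
                        str(int(row["count_g2"])),
                        str(int(row["n_g2"])),
                        f"{row['chi2']:.6g}",
                        f"{row['p_value']:.5E}",
                        str(bool(row["significant"])),
                    ]
                )
                + "\n"
            )


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                     na_values=[], dtype=str)
    for col in ("count_g1", "n_g1", "count_g2", "n_g2"):
        df[col] = df[col].astype(int)
    for col in ("chi2", "p_value"):
        df[col] = df[col].astype(float)
    df["significant"] = df["significant"].map({"True": True, "False": False})
    return df


def write_regions_table(regions: pd.DataFrame, path: str | Path) -> None:
    cols = ("chrom", "start_bp", "end_bp", "cytoband_span", "direction",
            "n_clones", "min_p")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in regions.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start_bp'])}\t{int(row['end_bp'])}\t"
                f"{row['cytoband_span']}\t{row['direction']}\t{int(row['n_clones'])}\t"
                f"{row['min_p']:.5E}\n"
            )
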