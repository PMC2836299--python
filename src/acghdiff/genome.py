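"""Stylized human genome used by the default clone map.

The scaffold mimics a ~1 Mb BAC array over autosomes 1-22 plus X.  Chromosome
lengths keep roughly human proportions but are scaled so the default 1 Mb
tiling yields exactly 4030 clones, the size of the classic 4K BAC array the
package emulates.  Cytoband names are stylized (fixed-width bands counted
outward from a per-chromosome centromere), good enough to name regions like
"20q13"; they are not a real ideogram.
"""

from __future__ import annotations

from .model import BacClone, CloneMap

MB = 1_000_000

#: Stylized chromosome lengths in Mb (autosomes + X; sum = 4030).
CHROM_LENGTH_MB: dict[str, int] = {
    "1": 330, "2": 324, "3": 266, "4": 255, "5": 242, "6": 228, "7": 212,
    "8": 195, "9": 187, "10": 180, "11": 179, "12": 176, "13": 152,
    "14": 141, "15": 133, "16": 119, "17": 105, "18": 101, "19": 85,
    "20": 83, "21": 63, "22": 67, "X": 207,
}

#: Centromere position as a fraction of chromosome length (acrocentrics small).
CENTROMERE_FRACTION: dict[str, float] = {
    "1": 0.50, "2": 0.39, "3": 0.46, "4": 0.26, "5": 0.27, "6": 0.35,
    "7": 0.38, "8": 0.31, "9": 0.35, "10": 0.30, "11": 0.40, "12": 0.27,
    "13": 0.15, "14": 0.16, "15": 0.17, "16": 0.41, "17": 0.30, "18": 0.23,
    "19": 0.42, "20": 0.44, "21": 0.28, "22": 0.30, "X": 0.39,
}

#: Width of one stylized cytogenetic band.
BAND_WIDTH_BP: int = 10 * MB

#: Nominal BAC insert size; each clone covers this much sequence.
CLONE_LENGTH_BP: int = 200_000


def chrom_length_bp(chrom: str) -> int:
    return CHROM_LENGTH_MB[chrom] * MB


def centromere_bp(chrom: str) -> int:
    return int(CENTROMERE_FRACTION[chrom] * chrom_length_bp(chrom))


def cytoband(chrom: str, pos_bp: int) -> str:
    """Stylized band name at a position, e.g. ``"20q12"``.

    Bands are BAND_WIDTH_BP wide and numbered outward from the centromere
    starting at 11, mirroring cytogenetic convention (p11/q11 flank the
    centromere, higher numbers toward the telomeres).
    """
    length = chrom_length_bp(chrom)
    if not (0 <= pos_bp < length):
        raise ValueError(f"position {pos_bp} outside chromosome {chrom}")
    cen = centromere_bp(chrom)
    if pos_bp < cen:
        arm, dist = "p", cen - pos_bp - 1
    else:
        arm, dist = "q", pos_bp - cen
    band = 11 + dist // BAND_WIDTH_BP
    return f"{chrom}{arm}{band}"


def arm_interval(chrom: str, arm: str) -> tuple[int, int]:
    """Half-open bp interval of a chromosome arm of the stylized genome."""
    cen = centromere_bp(chrom)
    if arm == "p":
        return 0, cen
    if arm == "q":
        return cen, chrom_length_bp(chrom)
    raise ValueError(f"unknown arm {arm!r}")


def build_default_clone_map(spacing_bp: int = MB) -> CloneMap:
    """Deterministically tile the stylized genome with BAC clones.

    One clone starts every ``spacing_bp`` along each chromosome; the clone
    itself spans CLONE_LENGTH_BP.  At the default 1 Mb spacing the map has
    exactly 4030 clones.
    """
    if spacing_bp <= 0:
        raise ValueError("spacing must be positive")
    shortest = min(CHROM_LENGTH_MB.values()) * MB
    if spacing_bp > shortest:
        raise ValueError(
            f"spacing {spacing_bp} exceeds the shortest chromosome ({shortest} bp)"
        )
    clones: list[BacClone] = []
    for chrom in CHROM_LENGTH_MB:
        length = chrom_length_bp(chrom)
        idx = 0
        start = 0
        while start + CLONE_LENGTH_BP <= length:
            end = start + CLONE_LENGTH_BP
            clones.append(
                BacClone(
                    clone_id=f"BAC_{chrom}_{idx:04d}",
                    chrom=chrom,
                    start_bp=start,
                    end_bp=end,
                    cytoband=cytoband(chrom, (start + end) // 2),
                )
            )
            idx += 1
            start += spacing_bp
    return CloneMap(clones, genome_label="stylized-4030")
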