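"""Packaged genome reference tables.

Autosome lengths are hg19 assembly constants; centromere intervals are
approximate hg19 acen intervals. The packaged cytoband map is *synthetic*:
it carries the standard major-band names but lays them out with uniform
band widths within each arm, so band-resolved coordinates are band-level
approximations, not ideogram measurements. Users may substitute their own
assembly/band tables via the ``path`` arguments; all files are TSV with
0-based half-open coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Acrocentric autosomes (minute p arms bearing only rDNA stalks/satellites).
ACROCENTRIC = frozenset({"13", "14", "15", "21", "22"})


class ReferenceError(ValueError):
    """Raised when a reference table is malformed or a lookup fails."""


class BandResolutionError(ReferenceError):
    """Raised when an ISCN band label cannot be mapped to coordinates."""


@dataclass(frozen=True)
class ChromosomeRecord:
    """One autosome: length and centromere interval (0-based half-open)."""

    name: str
    length_bp: int
    cen_start_bp: int
    cen_end_bp: int

    def __post_init__(self) -> None:
        if not (0 < self.cen_start_bp < self.cen_end_bp < self.length_bp):
            raise ReferenceError(
                f"chromosome {self.name}: centromere interval "
                f"[{self.cen_start_bp}, {self.cen_end_bp}) must lie strictly "
                f"inside (0, {self.length_bp})"
            )

    @property
    def is_acrocentric(self) -> bool:
        return self.name in ACROCENTRIC

    @property
    def p_arm_length(self) -> int:
        """Length of the p arm (pter to centromere start)."""
        return self.cen_start_bp

    @property
    def q_arm_length(self) -> int:
        """Length of the q arm (centromere end to qter)."""
        return self.length_bp - self.cen_end_bp

    def arm_length(self, arm: str) -> int:
        if arm == "p":
            return self.p_arm_length
        if arm == "q":
            return self.q_arm_length
        raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")


ChromosomeTable = Mapping[str, ChromosomeRecord]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("quadseg").joinpath("data", name)))


def load_chromosome_table(path: str | Path | None = None) -> dict[str, ChromosomeRecord]:
    """Load the autosome table (chrom, length, cen_start, cen_end TSV).

    With ``path=None`` the packaged hg19-derived table is used.
    """
    path = _data_path("chromosomes_hg19.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"chrom", "length", "cen_start", "cen_end"}
    if missing := required - set(df.columns):
        raise ReferenceError(f"chromosome table {path} missing columns: {sorted(missing)}")
    table: dict[str, ChromosomeRecord] = {}
    for row in df.itertuples(index=False):
        chrom = str(row.chrom).removeprefix("chr")
        if chrom in table:
            raise ReferenceError(f"duplicate chromosome {chrom!r} in {path}")
        table[chrom] = ChromosomeRecord(
            name=chrom,
            length_bp=int(row.length),
            cen_start_bp=int(row.cen_start),
            cen_end_bp=int(row.cen_end),
        )
    return table


def load_band_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a cytoband map (chrom, start, end, band TSV, 0-based half-open).

    With ``path=None`` the packaged synthetic major-band map is used.
    """
    path = _data_path("cytobands_synthetic.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "band": str})
    if missing := {"chrom", "start", "end", "band"} - set(df.columns):
        raise ReferenceError(f"band table {path} missing columns: {sorted(missing)}")
    df = df.copy()
    df["chrom"] = df["chrom"].str.removeprefix("chr")
    return df


def resolve_band_position(
    chromosome: str,
    band_label: str,
    band_table: pd.DataFrame,
    *,
    anchor: str = "midpoint",
) -> int:
    """Map an ISCN band label on a chromosome to a bp coordinate.

    Returns the band interval's midpoint by default (``anchor`` may also be
    ``"start"`` or ``"end"``). A sub-band query (e.g. ``q21.3``) not present
    in the table falls back to its parent major band with a logged warning.
    """
    chromosome = chromosome.removeprefix("chr")
    rows = band_table[band_table["chrom"] == chromosome]
    if rows.empty:
        raise BandResolutionError(f"no bands mapped for chromosome {chromosome!r}")
    hit = rows[rows["band"] == band_label]
    if hit.empty and "." in band_label:
        parent = band_label.split(".")[0]
        hit = rows[rows["band"] == parent]
        if not hit.empty:
            logger.warning(
                "band %s%s not in table; falling back to parent band %s%s",
                chromosome, band_label, chromosome, parent,
            )
    if hit.empty:
        same_arm = sorted(b for b in rows["band"] if b[0] == band_label[0])
        raise BandResolutionError(
            f"band {band_label!r} unknown on chromosome {chromosome}; "
            f"known bands on that arm: {', '.join(same_arm) or '(none)'}"
        )
    start, end = int(hit.iloc[0]["start"]), int(hit.iloc[0]["end"])
    if anchor == "midpoint":
        return (start + end) // 2
    if anchor == "start":
        return start
    if anchor == "end":
        return end
    raise ValueError(f"anchor must be midpoint/start/end, got {anchor!r}")
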