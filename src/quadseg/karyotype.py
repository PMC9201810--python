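"""ISCN reciprocal-translocation karyotypes and quadrivalent geometry.

A reciprocal translocation t(a;b) exchanges the segments distal to one
breakpoint on each of two autosomes. The geometry of the resulting meiotic
quadrivalent is summarised by the segment lengths and ratios used as model
covariates: translocated segments (TS), centric segments (CS), the
longest/shortest ratios TSR and CSR, and TAR, the translocated segment as a
fraction of its chromosome arm. Index 1 refers to the longer of the two
chromosomes involved.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .reference import (
    ACROCENTRIC,
    BandResolutionError,
    ChromosomeTable,
    resolve_band_position,
)

logger = logging.getLogger(__name__)


class KaryotypeError(ValueError):
    """Malformed or unsupported karyotype input."""


class UnsupportedKaryotypeError(KaryotypeError):
    """Valid ISCN but outside the supported grammar (e.g. sex-chromosome t)."""


_AUTOSOMES = {str(i) for i in range(1, 23)}

# 46,XX,t(2;5)(q21;q13) — one two-chromosome t() token, optional sex prefix.
_ISCN_RE = re.compile(
    r"^\s*(?:46,(?P<sex>X[XY]),)?"
    r"t\((?P<c1>[^;()]+);(?P<c2>[^;()]+)\)"
    r"\((?P<b1>[pq][\d.]+);(?P<b2>[pq][\d.]+)\)\s*$"
)


@dataclass(frozen=True)
class Breakpoint:
    """A translocation breakpoint on one autosome arm, in bp (0-based)."""

    chromosome: str
    arm: str  # "p" | "q"
    position_bp: int
    band_label: str | None = None

    def validate(self, chrom_table: ChromosomeTable) -> None:
        """Check the position lies strictly inside the stated arm."""
        rec = chrom_table.get(self.chromosome)
        if rec is None:
            raise KaryotypeError(f"chromosome {self.chromosome!r} not in reference table")
        if self.arm not in ("p", "q"):
            raise KaryotypeError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.arm == "p":
            ok = 0 < self.position_bp < rec.cen_start_bp
        else:
            ok = rec.cen_end_bp < self.position_bp < rec.length_bp
        if not ok:
            raise KaryotypeError(
                f"breakpoint {self.chromosome}{self.arm} at {self.position_bp} bp "
                f"is not strictly inside the {self.arm} arm "
                f"(centromere [{rec.cen_start_bp}, {rec.cen_end_bp}), "
                f"length {rec.length_bp})"
            )


@dataclass(frozen=True)
class ReciprocalTranslocation:
    """A two-autosome reciprocal translocation carrier."""

    carrier_id: str
    carrier_sex: str  # "female" | "male"
    bp1: Breakpoint
    bp2: Breakpoint
    carrier_age: float | None = None

    def __post_init__(self) -> None:
        if self.bp1.chromosome == self.bp2.chromosome:
            raise KaryotypeError("breakpoints must lie on two distinct chromosomes")
        for bp in (self.bp1, self.bp2):
            if bp.chromosome not in _AUTOSOMES:
                raise UnsupportedKaryotypeError(
                    f"only autosomal translocations are supported, got "
                    f"chromosome {bp.chromosome!r}"
                )
        if self.carrier_sex not in ("female", "male"):
            raise KaryotypeError(f"carrier_sex must be female/male, got {self.carrier_sex!r}")

    @property
    def chromosomes(self) -> tuple[str, str]:
        return (self.bp1.chromosome, self.bp2.chromosome)

    def breakpoint_for(self, chromosome: str) -> Breakpoint:
        for bp in (self.bp1, self.bp2):
            if bp.chromosome == chromosome:
                return bp
        raise KeyError(chromosome)


@dataclass(frozen=True)
class QuadrivalentMetrics:
    """Quadrivalent geometry covariates; index 1 = the longer chromosome.

    All lengths in bp. ``per_chromosome`` maps each chromosome label to its
    (size, ts, cs, tar) tuple so the values can also be read in input order
    — the index-1/2 labelling is a reporting convention, not a physical one.
    """

    chrom1: str
    chrom2: str
    size1: int
    size2: int
    ts1: int
    ts2: int
    cs1: int
    cs2: int
    tsr: float
    csr: float
    tar1: float
    tar2: float
    acr_involved: bool
    per_chromosome: dict[str, tuple[int, int, int, float]] = field(compare=False)

    def as_row(self) -> dict[str, float]:
        """Flat dict of the covariates as used by the cohort statistics."""
        return {
            "size1": self.size1, "size2": self.size2,
            "ts1": self.ts1, "ts2": self.ts2,
            "cs1": self.cs1, "cs2": self.cs2,
            "tsr": self.tsr, "csr": self.csr,
            "tar1": self.tar1, "tar2": self.tar2,
            "acr_involved": self.acr_involved,
        }


def parse_iscn_karyotype(
    text: str,
    band_table: pd.DataFrame,
    *,
    carrier_id: str = "",
    sex: str | None = None,
    age: float | None = None,
) -> ReciprocalTranslocation:
    """Parse an ISCN karyotype like ``46,XX,t(2;5)(q21;q13)``.

    Band labels are resolved to bp via the band table (interval midpoints).
    Sex is taken from the 46,XX/46,XY prefix when present, else from the
    ``sex`` argument.
    """
    m = _ISCN_RE.match(text)
    if m is None:
        frag = _offending_fragment(text)
        raise KaryotypeError(f"cannot parse karyotype {text!r}: unexpected fragment {frag!r}")
    c1, c2 = m.group("c1").strip(), m.group("c2").strip()
    for c in (c1, c2):
        if c not in _AUTOSOMES:
            raise UnsupportedKaryotypeError(
                f"karyotype {text!r}: chromosome {c!r} is not an autosome "
                f"(sex-chromosome and non-numeric translocations unsupported)"
            )
    if c1 == c2:
        raise UnsupportedKaryotypeError(
            f"karyotype {text!r}: both breakpoints on chromosome {c1}"
        )
    if m.group("sex") is not None:
        sex = "female" if m.group("sex") == "XX" else "male"
    if sex is None:
        raise KaryotypeError(
            f"karyotype {text!r} has no 46,XX/46,XY prefix and no sex was supplied"
        )
    bps = []
    for c, b in ((c1, m.group("b1")), (c2, m.group("b2"))):
        arm, label = b[0], b
        pos = resolve_band_position(c, label, band_table)
        bps.append(Breakpoint(chromosome=c, arm=arm, position_bp=pos, band_label=label))
    return ReciprocalTranslocation(
        carrier_id=carrier_id, carrier_sex=sex, bp1=bps[0], bp2=bps[1], carrier_age=age
    )


def _offending_fragment(text: str) -> str:
    """Best-effort localisation of the part of the string that broke parsing."""
    m = re.search(r"t\([^)]*\)(\([^)]*\))?", text)
    if m is None:
        return text.strip()[:40] or "(empty)"
    return m.group(0)


def format_iscn(tr: ReciprocalTranslocation) -> str:
    """Format back to ISCN; inverse of :func:`parse_iscn_karyotype` when
    both breakpoints carry band labels."""
    for bp in (tr.bp1, tr.bp2):
        if bp.band_label is None:
            raise KaryotypeError(
                f"breakpoint {bp.chromosome}{bp.arm} has no band label; "
                f"cannot format as ISCN"
            )
    sx = "XX" if tr.carrier_sex == "female" else "XY"
    return (
        f"46,{sx},t({tr.bp1.chromosome};{tr.bp2.chromosome})"
        f"({tr.bp1.band_label};{tr.bp2.band_label})"
    )


def _segments(bp: Breakpoint, rec) -> tuple[int, int, float]:
    """(ts, cs, tar) for one breakpoint: ts runs breakpoint -> telomere of
    its arm, cs is the centromere-bearing remainder, tar = ts / arm length."""
    if bp.arm == "q":
        ts = rec.length_bp - bp.position_bp
    else:
        ts = bp.position_bp
    cs = rec.length_bp - ts
    tar = ts / rec.arm_length(bp.arm)
    return ts, cs, tar


def compute_metrics(
    tr: ReciprocalTranslocation, chrom_table: ChromosomeTable
) -> QuadrivalentMetrics:
    """Compute quadrivalent geometry covariates for a translocation.

    Index 1 is assigned to the longer chromosome regardless of the order the
    breakpoints were given in; ``acr_involved`` is true when either
    chromosome is acrocentric (13/14/15/21/22).
    """
    tr.bp1.validate(chrom_table)
    tr.bp2.validate(chrom_table)
    per: dict[str, tuple[int, int, float]] = {}
    for bp in (tr.bp1, tr.bp2):
        rec = chrom_table[bp.chromosome]
        if rec.is_acrocentric and bp.arm == "p":
            logger.warning(
                "breakpoint on the p arm of acrocentric chromosome %s: "
                "Robertsonian-like events are outside the supported population",
                bp.chromosome,
            )
        per[bp.chromosome] = _segments(bp, rec)
    # index 1 = longer chromosome (ties broken by numeric label)
    ordered = sorted(
        tr.chromosomes,
        key=lambda c: (-chrom_table[c].length_bp, int(c)),
    )
    c1, c2 = ordered
    ts1, cs1, tar1 = per[c1]
    ts2, cs2, tar2 = per[c2]
    return QuadrivalentMetrics(
        chrom1=c1,
        chrom2=c2,
        size1=chrom_table[c1].length_bp,
        size2=chrom_table[c2].length_bp,
        ts1=ts1, ts2=ts2, cs1=cs1, cs2=cs2,
        tsr=max(ts1, ts2) / min(ts1, ts2),
        csr=max(cs1, cs2) / min(cs1, cs2),
        tar1=tar1, tar2=tar2,
        acr_involved=bool({c1, c2} & ACROCENTRIC),
        per_chromosome={
            c: (chrom_table[c].length_bp, per[c][0], per[c][1], per[c][2])
            for c in tr.chromosomes
        },
    )
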