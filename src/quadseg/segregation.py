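"""Enumeration of quadrivalent segregation products.

In a reciprocal-translocation carrier the two normal chromosomes (A, B) and
the two derivatives (der(A) = CS_A + TS_B, der(B) = CS_B + TS_A) pair as a
quadrivalent at meiosis I. Anaphase I distributes the four centromeres to
the two poles through one of five disjunction modes — alternate, adjacent-1,
adjacent-2, 3:1 and 4:0 — giving 16 chromosome compositions; counting each
composition with and without an interstitial-crossover (recombinant)
chromatid gives the classical 32 gamete karyotypes. Only the two alternate,
non-recombinant products are genetically balanced.

Every product is summarised by a segment-dosage vector over the four
quadrivalent segments (CS_A, TS_A, CS_B, TS_B); adding the balanced
contribution of the non-carrier gamete yields the embryo signature the CNV
classifier matches against. Recombination never creates a dosage outside
the non-recombinant set, so dosage-level classification over the 16-class
table is complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .karyotype import ReciprocalTranslocation
from .reference import ChromosomeTable

#: Canonical mode labels in reporting order.
MODES = ("alternate", "adjacent-1", "adjacent-2", "3:1", "4:0")

# Quadrivalent members and their segment content as (cs_a, ts_a, cs_b, ts_b).
_MEMBER_DOSAGE = {
    "A": (1, 1, 0, 0),
    "der(A)": (1, 0, 0, 1),
    "B": (0, 0, 1, 1),
    "der(B)": (0, 1, 1, 0),
}

# Interstitial crossover exchanges the translocated segment between a
# chromosome and its pairing partner: A <-> der(A), B <-> der(B).
_EXCHANGE = {"A": "der(A)", "der(A)": "A", "B": "der(B)", "der(B)": "B"}

# The 16 chromosome compositions grouped by disjunction mode.
_COMPOSITIONS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("alternate", ("A", "B")),
    ("alternate", ("der(A)", "der(B)")),
    ("adjacent-1", ("A", "der(B)")),
    ("adjacent-1", ("der(A)", "B")),
    ("adjacent-2", ("A", "der(A)")),
    ("adjacent-2", ("B", "der(B)")),
    ("3:1", ("A", "der(A)", "B")),
    ("3:1", ("A", "der(A)", "der(B)")),
    ("3:1", ("A", "B", "der(B)")),
    ("3:1", ("der(A)", "B", "der(B)")),
    ("3:1", ("A",)),
    ("3:1", ("der(A)",)),
    ("3:1", ("B",)),
    ("3:1", ("der(B)",)),
    ("4:0", ("A", "der(A)", "B", "der(B)")),
    ("4:0", ()),
)


@dataclass(frozen=True)
class SegmentDosage:
    """Copy counts of the four quadrivalent segments."""

    cs_a: int
    ts_a: int
    cs_b: int
    ts_b: int

    def __post_init__(self) -> None:
        for v in self.as_tuple():
            if not 0 <= v <= 4:
                raise ValueError(f"segment dosage out of range 0..4: {self.as_tuple()}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.cs_a, self.ts_a, self.cs_b, self.ts_b)

    def __add__(self, other: "SegmentDosage") -> "SegmentDosage":
        return SegmentDosage(*(a + b for a, b in zip(self.as_tuple(), other.as_tuple())))


BALANCED_GAMETE = SegmentDosage(1, 1, 1, 1)
BALANCED_EMBRYO = SegmentDosage(2, 2, 2, 2)


@dataclass(frozen=True)
class GameteClass:
    """One segregation product: mode, chromosome composition, dosage.

    ``recombinant`` marks the variant in which one chromatid carries an
    interstitial crossover; its dosage is that of the composition with one
    member replaced by its exchange partner. ``subtype`` distinguishes the
    3:1 tertiary/interchange products (pooled as "3:1" in statistics).
    """

    mode: str
    composition: tuple[str, ...]
    recombinant: bool
    dosage: SegmentDosage
    subtype: str | None = None

    @property
    def n_chromosomes(self) -> int:
        return len(self.composition)

    @property
    def balanced(self) -> bool:
        return self.dosage == BALANCED_GAMETE


def _composition_dosage(composition: tuple[str, ...], recombinant: bool) -> SegmentDosage:
    members = list(composition)
    if recombinant and members:
        # The crossover chromatid is represented by replacing one member
        # with its exchange partner — canonically the first member (in the
        # order A, der(A), B, der(B)) whose partner is absent from the
        # pole. When a pole contains both members of a pair (adjacent-2,
        # 4:0), the exchange is internal to the pole and dosage-neutral at
        # this model's MI-pole resolution, so the dosage is unchanged;
        # chromatid-level MII sampling is deliberately out of scope.
        order = list(_MEMBER_DOSAGE)
        members.sort(key=order.index)
        for i, m in enumerate(members):
            if _EXCHANGE[m] not in members:
                members[i] = _EXCHANGE[m]
                break
    totals = [0, 0, 0, 0]
    for m in members:
        for i, v in enumerate(_MEMBER_DOSAGE[m]):
            totals[i] += v
    return SegmentDosage(*totals)


def _subtype(mode: str, composition: tuple[str, ...]) -> str | None:
    if mode != "3:1":
        return None
    normals = sum(1 for m in composition if "(" not in m)
    if len(composition) == 3:
        # both normals present -> interchange trisomy; else tertiary
        return "interchange trisomy" if normals == 2 else "tertiary trisomy"
    return "interchange monosomy" if normals == 0 else "tertiary monosomy"


def enumerate_gamete_classes(include_recombinants: bool = False) -> list[GameteClass]:
    """All gamete classes of a generic two-autosome quadrivalent.

    Without recombinants: the 16 chromosome compositions (2 alternate,
    2 adjacent-1, 2 adjacent-2, 8 of mode 3:1, 2 of mode 4:0). With
    recombinants each composition appears in both recombinant states, for
    the classical count of 32. Deterministic, stable ordering.
    """
    out: list[GameteClass] = []
    for mode, comp in _COMPOSITIONS:
        for rec in (False, True) if include_recombinants else (False,):
            out.append(
                GameteClass(
                    mode=mode,
                    composition=comp,
                    recombinant=rec,
                    dosage=_composition_dosage(comp, rec),
                    subtype=_subtype(mode, comp),
                )
            )
    return out


@dataclass(frozen=True)
class EmbryoSignature:
    """Expected embryo segment dosage for a gamete class (carrier gamete
    plus a balanced non-carrier gamete)."""

    gamete: GameteClass
    dosage: SegmentDosage

    @property
    def balanced(self) -> bool:
        return self.dosage == BALANCED_EMBRYO


def embryo_signature(g: GameteClass) -> EmbryoSignature:
    """Embryo dosage = gamete dosage + (1,1,1,1) from the partner gamete."""
    return EmbryoSignature(gamete=g, dosage=g.dosage + BALANCED_GAMETE)


@dataclass(frozen=True)
class SegmentIntervals:
    """Genomic intervals of the four quadrivalent segments (0-based
    half-open), keyed ``cs_a``/``ts_a``/``cs_b``/``ts_b``; ``chrom_a`` is
    ``tr.bp1.chromosome``."""

    chrom_a: str
    chrom_b: str
    intervals: dict[str, tuple[str, int, int]]


def segment_intervals(
    tr: ReciprocalTranslocation, chrom_table: ChromosomeTable
) -> SegmentIntervals:
    """Bind the abstract quadrivalent segments to genomic intervals.

    The translocated segment runs from the breakpoint to the telomere of
    its arm; the centric segment is the centromere-bearing remainder of the
    chromosome (the centromere's own extent is not modelled separately).
    """
    tr.bp1.validate(chrom_table)
    tr.bp2.validate(chrom_table)
    iv: dict[str, tuple[str, int, int]] = {}
    for key, bp in (("a", tr.bp1), ("b", tr.bp2)):
        length = chrom_table[bp.chromosome].length_bp
        if bp.arm == "q":
            iv[f"cs_{key}"] = (bp.chromosome, 0, bp.position_bp)
            iv[f"ts_{key}"] = (bp.chromosome, bp.position_bp, length)
        else:
            iv[f"ts_{key}"] = (bp.chromosome, 0, bp.position_bp)
            iv[f"cs_{key}"] = (bp.chromosome, bp.position_bp, length)
    return SegmentIntervals(
        chrom_a=tr.bp1.chromosome, chrom_b=tr.bp2.chromosome, intervals=iv
    )


@dataclass(frozen=True)
class SignatureEntry:
    """One distinct embryo dosage with its mode and expected CNV intervals.

    ``intervals`` lists (chromosome, start, end, expected_copy_number) for
    every region deviating from 2 copies, with same-copy-number adjacent
    segments merged (so a whole-chromosome imbalance is one interval).
    """

    dosage: SegmentDosage
    mode: str
    balanced: bool
    subtype: str | None
    intervals: tuple[tuple[str, int, int, int], ...]


def _expected_intervals(
    dosage: SegmentDosage, seg: SegmentIntervals
) -> tuple[tuple[str, int, int, int], ...]:
    out: list[tuple[str, int, int, int]] = []
    pairs = {
        "cs_a": dosage.cs_a, "ts_a": dosage.ts_a,
        "cs_b": dosage.cs_b, "ts_b": dosage.ts_b,
    }
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for key, cn in pairs.items():
        if cn == 2:
            continue
        chrom, start, end = seg.intervals[key]
        by_chrom.setdefault(chrom, []).append((start, end, cn))
    for chrom, items in by_chrom.items():
        items.sort()
        merged: list[list[int]] = []
        for start, end, cn in items:
            if merged and merged[-1][1] == start and merged[-1][2] == cn:
                merged[-1][1] = end
            else:
                merged.append([start, end, cn])
        out.extend((chrom, s, e, cn) for s, e, cn in merged)
    out.sort()
    return tuple(out)


def signature_table(
    tr: ReciprocalTranslocation, chrom_table: ChromosomeTable
) -> dict[tuple[int, int, int, int], SignatureEntry]:
    """Map each distinct embryo dosage to its mode and expected intervals.

    The 16 non-recombinant classes produce 15 distinct embryo dosages: the
    two balanced alternate products collapse to the single (2,2,2,2) entry
    and the 14 unbalanced signatures are pairwise distinct.
    """
    seg = segment_intervals(tr, chrom_table)
    table: dict[tuple[int, int, int, int], SignatureEntry] = {}
    for g in enumerate_gamete_classes(include_recombinants=False):
        sig = embryo_signature(g)
        key = sig.dosage.as_tuple()
        if key in table:
            if table[key].mode != g.mode:  # pragma: no cover - enumeration guard
                raise AssertionError(f"dosage collision across modes at {key}")
            continue
        table[key] = SignatureEntry(
            dosage=sig.dosage,
            mode=g.mode,
            balanced=sig.balanced,
            subtype=g.subtype,
            intervals=_expected_intervals(sig.dosage, seg),
        )
    return table


def iter_signature_rows(
    table: dict[tuple[int, int, int, int], SignatureEntry]
) -> Iterator[dict[str, object]]:
    """Flatten a signature table into report rows (stable order)."""
    for key in sorted(table, reverse=True):
        e = table[key]
        yield {
            "dosage": "/".join(map(str, key)),
            "mode": e.mode,
            "balanced": e.balanced,
            "subtype": e.subtype or "",
            "intervals": ";".join(
                f"{c}:{s}-{en}x{cn}" for c, s, en, cn in e.intervals
            ),
        }
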