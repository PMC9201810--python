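"""Per-embryo segregation-mode inference from CNV segment calls.

Each blastocyst's comprehensive-chromosome-screening profile is reduced to
a dosage vector over the four quadrivalent segments and matched against the
15 distinct embryo signatures of the carrier's translocation. Residual
calls that match no segment are either incidental whole-chromosome
aneuploidies (mitotic or meiosis-independent errors on uninvolved
chromosomes — they do not veto the quadrivalent mode call) or, if partial
and on an involved chromosome, evidence that the profile is inconsistent
with any segregation product, in which case the embryo is "not determined"
(ND). A balanced profile cannot be distinguished from a normal one, so
alternate calls merge both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .karyotype import ReciprocalTranslocation
from .reference import ChromosomeTable
from .segregation import (
    SegmentDosage,
    SignatureEntry,
    segment_intervals,
    signature_table,
)

logger = logging.getLogger(__name__)

#: Default boundary-matching tolerance: platform resolution (1-4 Mb) plus
#: band-midpoint uncertainty in the karyotype-derived breakpoints.
DEFAULT_TOL_BP = 5_000_000

#: Platform detection floor: segmental events below this are not callable.
MIN_SEGMENT_BP = 1_000_000


class CNVInputError(ValueError):
    """Malformed CNV profile input."""


@dataclass(frozen=True)
class CNVCall:
    """One copy-number segment call, 0-based half-open."""

    chromosome: str
    start_bp: int
    end_bp: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise CNVInputError(
                f"CNV call on {self.chromosome}: start {self.start_bp} >= end {self.end_bp}"
            )
        if self.copy_number < 0:
            raise CNVInputError(f"negative copy number {self.copy_number}")

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class EmbryoCNVProfile:
    """All CNV calls of one biopsied blastocyst (empty = euploid profile)."""

    embryo_id: str
    carrier_id: str
    calls: tuple[CNVCall, ...]

    def validate(self) -> None:
        by_chrom: dict[str, list[CNVCall]] = {}
        for c in self.calls:
            by_chrom.setdefault(c.chromosome, []).append(c)
        for chrom, calls in by_chrom.items():
            calls = sorted(calls, key=lambda c: c.start_bp)
            for prev, cur in zip(calls, calls[1:]):
                if cur.start_bp < prev.end_bp:
                    raise CNVInputError(
                        f"embryo {self.embryo_id}: overlapping calls on "
                        f"chromosome {chrom} "
                        f"([{prev.start_bp},{prev.end_bp}) and "
                        f"[{cur.start_bp},{cur.end_bp}))"
                    )


@dataclass(frozen=True)
class SegregationCall:
    """Inferred segregation mode of one embryo."""

    embryo_id: str
    carrier_id: str
    mode: str  # alternate | adjacent-1 | adjacent-2 | 3:1 | 4:0 | ND
    balanced: bool
    incidental_aneuploidy: bool
    matched_dosage: SegmentDosage | None
    max_breakpoint_deviation_bp: int
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.balanced and self.mode != "alternate":
            raise ValueError("balanced=True requires mode=alternate")
        if self.mode == "ND" and self.matched_dosage is not None:
            raise ValueError("ND calls carry no matched dosage")


@dataclass(frozen=True)
class BreakpointEstimate:
    """CNV-refined breakpoint position for one chromosome arm."""

    chromosome: str
    arm: str
    position_bp: int
    n_supporting_embryos: int
    dispersion_bp: float  # median absolute deviation


class BreakpointEstimationUnavailable(RuntimeError):
    """No unbalanced embryo provides a boundary on the relevant arm."""


def _filter_calls(calls: tuple[CNVCall, ...], embryo_id: str) -> list[CNVCall]:
    kept = []
    for c in calls:
        if c.copy_number > 4:
            logger.warning(
                "embryo %s: dropping call %s:%d-%d with copy number %d > 4",
                embryo_id, c.chromosome, c.start_bp, c.end_bp, c.copy_number,
            )
            continue
        if c.length < MIN_SEGMENT_BP:
            logger.warning(
                "embryo %s: dropping sub-floor call %s:%d-%d (%d bp < %d)",
                embryo_id, c.chromosome, c.start_bp, c.end_bp, c.length, MIN_SEGMENT_BP,
            )
            continue
        kept.append(c)
    return kept


def profile_to_dosage(
    p: EmbryoCNVProfile,
    tr: ReciprocalTranslocation,
    chrom_table: ChromosomeTable,
    tol_bp: int = DEFAULT_TOL_BP,
) -> tuple[SegmentDosage, list[CNVCall], int]:
    """Reduce a CNV profile to a quadrivalent segment-dosage vector.

    Each call whose boundaries match a segment interval (or the union of a
    chromosome's two segments, i.e. the whole chromosome) within ``tol_bp``
    contributes its copy-number deviation to the matched segment(s);
    unmatched calls are returned as residuals. Returns
    ``(dosage, residuals, max_boundary_deviation_bp)`` where the deviation
    is over matched calls only.
    """
    p.validate()
    seg = segment_intervals(tr, chrom_table)
    # candidate targets: each segment alone, plus whole-chromosome unions
    targets: list[tuple[tuple[str, ...], str, int, int]] = []
    for key, (chrom, s, e) in seg.intervals.items():
        targets.append(((key,), chrom, s, e))
    for label, chrom in (("a", seg.chrom_a), ("b", seg.chrom_b)):
        targets.append(
            ((f"cs_{label}", f"ts_{label}"), chrom, 0, chrom_table[chrom].length_bp)
        )
    delta = {"cs_a": 0, "ts_a": 0, "cs_b": 0, "ts_b": 0}
    residuals: list[CNVCall] = []
    max_dev = 0
    for call in _filter_calls(p.calls, p.embryo_id):
        best: tuple[int, tuple[str, ...]] | None = None
        for keys, chrom, s, e in targets:
            if call.chromosome != chrom:
                continue
            dev = max(abs(call.start_bp - s), abs(call.end_bp - e))
            if dev <= tol_bp and (best is None or dev < best[0]):
                best = (dev, keys)
        if best is None:
            residuals.append(call)
            continue
        dev, keys = best
        max_dev = max(max_dev, dev)
        for k in keys:
            delta[k] += call.copy_number - 2
    try:
        dosage = SegmentDosage(
            *(2 + delta[k] for k in ("cs_a", "ts_a", "cs_b", "ts_b"))
        )
    except ValueError:  # deviations pushed a segment outside 0..4
        dosage = None  # type: ignore[assignment]
    if dosage is None:
        # report as an impossible vector via residuals: push all matched
        # calls back so the classifier lands on ND
        return SegmentDosage(2, 2, 2, 2), list(p.calls), 0
    return dosage, residuals, max_dev


def _is_whole_chromosome(call: CNVCall, chrom_table: ChromosomeTable, tol_bp: int) -> bool:
    rec = chrom_table.get(call.chromosome)
    if rec is None:
        return False
    return call.start_bp <= tol_bp and abs(call.end_bp - rec.length_bp) <= tol_bp


def classify(
    p: EmbryoCNVProfile,
    tr: ReciprocalTranslocation,
    chrom_table: ChromosomeTable,
    tol_bp: int = DEFAULT_TOL_BP,
    table: dict[tuple[int, int, int, int], SignatureEntry] | None = None,
) -> SegregationCall:
    """Classify one embryo's CNV profile into a segregation mode.

    The dosage vector is matched exactly against the 15-entry signature
    table. Whole-chromosome residuals on uninvolved chromosomes set
    ``incidental_aneuploidy`` without changing the mode call; partial
    residuals on involved chromosomes, or a dosage matching no signature,
    yield ND. ``table`` may be precomputed (it depends only on ``tr``).
    """
    if table is None:
        table = signature_table(tr, chrom_table)
    dosage, residuals, max_dev = profile_to_dosage(p, tr, chrom_table, tol_bp)
    involved = set(tr.chromosomes)
    incidental = False
    nd = False
    for r in residuals:
        if _is_whole_chromosome(r, chrom_table, tol_bp) and r.chromosome not in involved:
            incidental = True
        else:
            nd = True
    entry = table.get(dosage.as_tuple())
    if nd or entry is None:
        return SegregationCall(
            embryo_id=p.embryo_id, carrier_id=p.carrier_id, mode="ND",
            balanced=False, incidental_aneuploidy=incidental,
            matched_dosage=None, max_breakpoint_deviation_bp=max_dev,
        )
    return SegregationCall(
        embryo_id=p.embryo_id, carrier_id=p.carrier_id, mode=entry.mode,
        balanced=entry.balanced, incidental_aneuploidy=incidental,
        matched_dosage=dosage, max_breakpoint_deviation_bp=max_dev,
        subtype=entry.subtype,
    )


def classify_profiles(
    profiles: list[EmbryoCNVProfile],
    tr: ReciprocalTranslocation,
    chrom_table: ChromosomeTable,
    tol_bp: int = DEFAULT_TOL_BP,
) -> list[SegregationCall]:
    """Classify many profiles of one carrier (signature table computed once)."""
    table = signature_table(tr, chrom_table)
    return [classify(p, tr, chrom_table, tol_bp, table=table) for p in profiles]


def estimate_breakpoints(
    profiles: list[EmbryoCNVProfile],
    tr: ReciprocalTranslocation,
    chrom_table: ChromosomeTable,
    tol_bp: int = DEFAULT_TOL_BP,
) -> tuple[BreakpointEstimate, BreakpointEstimate]:
    """Refine the two breakpoints from the unbalanced embryos' CNV calls.

    For each involved chromosome, every CNV-call boundary lying on the
    breakpoint arm within ``tol_bp`` of the karyotype-derived position is
    collected across profiles; the estimate is the median, with the median
    absolute deviation as dispersion. Raises
    :class:`BreakpointEstimationUnavailable` when a chromosome has no
    supporting boundary (callers fall back to band midpoints).
    """
    out: list[BreakpointEstimate] = []
    for bp in (tr.bp1, tr.bp2):
        obs: list[int] = []
        support = 0
        for p in profiles:
            hits = [
                b
                for c in p.calls
                if c.chromosome == bp.chromosome
                for b in (c.start_bp, c.end_bp)
                if abs(b - bp.position_bp) <= tol_bp
            ]
            if hits:
                support += 1
                obs.extend(hits)
        if not obs:
            raise BreakpointEstimationUnavailable(
                f"no CNV boundary within {tol_bp} bp of breakpoint "
                f"{bp.chromosome}{bp.arm}:{bp.position_bp} in any profile"
            )
        arr = np.asarray(obs, dtype=float)
        med = float(np.median(arr))
        out.append(
            BreakpointEstimate(
                chromosome=bp.chromosome,
                arm=bp.arm,
                position_bp=int(round(med)),
                n_supporting_embryos=support,
                dispersion_bp=float(np.median(np.abs(arr - med))),
            )
        )
    return out[0], out[1]
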