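"""End-to-end glue: classify a cohort's profiles and build the embryo-level
analysis table that feeds the statistics battery."""

from __future__ import annotations

import pandas as pd

from .classifier import DEFAULT_TOL_BP, EmbryoCNVProfile, SegregationCall, classify_profiles
from .karyotype import ReciprocalTranslocation, compute_metrics
from .reference import ChromosomeTable
from .simulate import SimulatedCohort


def classify_cohort(
    carriers: dict[str, ReciprocalTranslocation],
    profiles: list[EmbryoCNVProfile],
    chrom_table: ChromosomeTable,
    tol_bp: int = DEFAULT_TOL_BP,
) -> list[SegregationCall]:
    """Classify all profiles, grouping by carrier so each carrier's
    signature table is built once. Profiles for unknown carriers raise."""
    by_carrier: dict[str, list[EmbryoCNVProfile]] = {}
    for p in profiles:
        if p.carrier_id not in carriers:
            raise KeyError(f"profile {p.embryo_id}: unknown carrier {p.carrier_id!r}")
        by_carrier.setdefault(p.carrier_id, []).append(p)
    calls: list[SegregationCall] = []
    for cid, group in by_carrier.items():
        calls.extend(classify_profiles(group, carriers[cid], chrom_table, tol_bp))
    return calls


def build_cohort_table(
    carriers: dict[str, ReciprocalTranslocation],
    calls: list[SegregationCall],
    chrom_table: ChromosomeTable,
) -> pd.DataFrame:
    """One row per classified embryo with its carrier's covariates.

    Columns: carrier_id, sex, age, acr_involved, size1/2, ts1/2, cs1/2,
    tsr, csr, tar1/2, embryo_id, mode, balanced, incidental_aneuploidy.
    """
    cov: dict[str, dict] = {}
    for cid, tr in carriers.items():
        m = compute_metrics(tr, chrom_table)
        row = {"carrier_id": cid, "sex": tr.carrier_sex, "age": tr.carrier_age}
        row.update(m.as_row())
        cov[cid] = row
    rows = []
    for c in calls:
        row = dict(cov[c.carrier_id])
        row.update(
            embryo_id=c.embryo_id,
            mode=c.mode,
            balanced=c.balanced,
            incidental_aneuploidy=c.incidental_aneuploidy,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def classified_table_from_simulation(
    sim: SimulatedCohort,
    chrom_table: ChromosomeTable,
    tol_bp: int = DEFAULT_TOL_BP,
) -> pd.DataFrame:
    """Simulated cohort -> classified embryo-level table (full pipeline)."""
    calls = classify_cohort(sim.translocations, sim.profiles, chrom_table, tol_bp)
    return build_cohort_table(sim.translocations, calls, chrom_table)


def calls_to_frame(calls: list[SegregationCall]) -> pd.DataFrame:
    rows = [
        {
            "embryo_id": c.embryo_id,
            "carrier_id": c.carrier_id,
            "mode": c.mode,
            "balanced": c.balanced,
            "incidental_aneuploidy": c.incidental_aneuploidy,
            "matched_dosage": "/".join(map(str, c.matched_dosage.as_tuple()))
            if c.matched_dosage
            else "",
            "max_breakpoint_deviation_bp": c.max_breakpoint_deviation_bp,
        }
        for c in calls
    ]
    cols = [
        "embryo_id", "carrier_id", "mode", "balanced",
        "incidental_aneuploidy", "matched_dosage", "max_breakpoint_deviation_bp",
    ]
    return pd.DataFrame(rows, columns=cols)
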