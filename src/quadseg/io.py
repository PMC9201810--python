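"""Tabular input/output: carrier tables, CNV call tables, report writing.

The canonical tabular dialect is TSV (UTF-8, tab separators, ``.``
decimal) because ISCN karyotype strings contain commas. All genomic
coordinates in files are 0-based half-open unless a reader is told
otherwise (``one_based=True``).
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .classifier import CNVCall, EmbryoCNVProfile
from .karyotype import (
    Breakpoint,
    KaryotypeError,
    ReciprocalTranslocation,
    parse_iscn_karyotype,
)
from .reference import BandResolutionError, ChromosomeTable


class SchemaError(ValueError):
    """Input file lacks required structure (wrong columns, duplicates)."""


@dataclasses.dataclass
class RejectedRow:
    line_number: int  # 1-based, counting the header as line 1
    reason: str


def _infer_arm(chromosome: str, pos: int, chrom_table: ChromosomeTable) -> str:
    rec = chrom_table[chromosome]
    if pos < rec.cen_start_bp:
        return "p"
    if pos >= rec.cen_end_bp:
        return "q"
    raise KaryotypeError(
        f"position {pos} on chromosome {chromosome} falls inside the "
        f"centromere interval"
    )


def read_carrier_table(
    path: str | Path,
    band_table: pd.DataFrame,
    chrom_table: ChromosomeTable,
) -> tuple[list[ReciprocalTranslocation], list[RejectedRow]]:
    """Read a carrier TSV into translocations.

    Requires columns ``carrier_id`` and ``sex`` plus either ``karyotype``
    (ISCN) or explicit ``chrom1, pos1, chrom2, pos2`` coordinates
    (0-based); ``age`` is optional. Rows that fail to parse are collected
    as rejects with their line numbers; duplicate carrier ids are a hard
    schema error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = set(df.columns)
    if "carrier_id" not in cols or "sex" not in cols:
        raise SchemaError(f"{path}: required columns carrier_id, sex; found {sorted(cols)}")
    has_karyotype = "karyotype" in cols
    has_coords = {"chrom1", "pos1", "chrom2", "pos2"} <= cols
    if not (has_karyotype or has_coords):
        raise SchemaError(
            f"{path}: need either a karyotype column or chrom1/pos1/chrom2/pos2"
        )
    dupes = df["carrier_id"][df["carrier_id"].duplicated()].unique()
    if len(dupes):
        raise SchemaError(f"{path}: duplicate carrier_id: {', '.join(dupes)}")

    carriers: list[ReciprocalTranslocation] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        d = row._asdict()
        age = float(d["age"]) if d.get("age") else None
        sex = d["sex"].strip().lower() or None
        try:
            if has_karyotype and d.get("karyotype"):
                tr = parse_iscn_karyotype(
                    d["karyotype"], band_table,
                    carrier_id=d["carrier_id"], sex=sex, age=age,
                )
            elif has_coords:
                bps = []
                for k in ("1", "2"):
                    chrom = d[f"chrom{k}"].removeprefix("chr")
                    pos = int(d[f"pos{k}"])
                    bps.append(
                        Breakpoint(
                            chromosome=chrom,
                            arm=_infer_arm(chrom, pos, chrom_table),
                            position_bp=pos,
                        )
                    )
                if sex is None:
                    raise KaryotypeError("missing sex")
                tr = ReciprocalTranslocation(
                    carrier_id=d["carrier_id"], carrier_sex=sex,
                    bp1=bps[0], bp2=bps[1], carrier_age=age,
                )
            else:
                raise KaryotypeError("row has neither karyotype nor coordinates")
            tr.bp1.validate(chrom_table)
            tr.bp2.validate(chrom_table)
        except (KaryotypeError, BandResolutionError, KeyError, ValueError) as exc:
            rejects.append(RejectedRow(line, f"{type(exc).__name__}: {exc}"))
            continue
        carriers.append(tr)
    return carriers, rejects


def read_cnv_table(
    path: str | Path,
    chrom_table: ChromosomeTable,
    *,
    one_based: bool = False,
) -> tuple[list[EmbryoCNVProfile], list[RejectedRow]]:
    """Read a BED-like CNV call TSV grouped into per-embryo profiles.

    Required columns: embryo_id, carrier_id, chrom, start, end,
    copy_number. An embryo listed with no rows elsewhere simply has an
    empty (euploid) profile — callers decide the embryo universe.
    Overlapping calls on one chromosome reject the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"embryo_id", "carrier_id", "chrom", "start", "end", "copy_number"}
    if missing := required - set(df.columns):
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")

    rejects: list[RejectedRow] = []
    rows_ok: dict[tuple[str, str], list[tuple[int, CNVCall]]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        d = row._asdict()
        chrom = d["chrom"].removeprefix("chr")
        try:
            start, end = int(d["start"]), int(d["end"])
            if one_based:
                start -= 1
            if chrom not in chrom_table:
                raise ValueError(f"unknown chromosome {chrom!r}")
            call = CNVCall(
                chromosome=chrom, start_bp=start, end_bp=end,
                copy_number=int(d["copy_number"]),
            )
        except ValueError as exc:
            rejects.append(RejectedRow(line, str(exc)))
            continue
        rows_ok.setdefault((d["embryo_id"], d["carrier_id"]), []).append((line, call))

    profiles: list[EmbryoCNVProfile] = []
    for (eid, cid), items in rows_ok.items():
        kept: list[tuple[int, CNVCall]] = []
        by_chrom: dict[str, list[tuple[int, CNVCall]]] = {}
        for line, call in items:
            by_chrom.setdefault(call.chromosome, []).append((line, call))
        for chrom, group in by_chrom.items():
            group.sort(key=lambda lc: lc[1].start_bp)
            last_end = -1
            for line, call in group:
                if call.start_bp < last_end:
                    rejects.append(
                        RejectedRow(
                            line,
                            f"embryo {eid}: overlapping call on chromosome {chrom}",
                        )
                    )
                    continue
                last_end = call.end_bp
                kept.append((line, call))
        profiles.append(
            EmbryoCNVProfile(
                embryo_id=eid, carrier_id=cid,
                calls=tuple(c for _, c in sorted(kept)),
            )
        )
    return profiles, rejects


@dataclasses.dataclass
class RunManifest:
    """Provenance record written last (acts as the success marker)."""

    tool_version: str = __version__
    timestamp: str = ""
    input_digests: dict[str, str] = dataclasses.field(default_factory=dict)
    config: dict = dataclasses.field(default_factory=dict)
    row_counts: dict[str, int] = dataclasses.field(default_factory=dict)

    def check_conservation(self) -> None:
        rc = self.row_counts
        if {"read", "parsed", "rejected"} <= rc.keys():
            if rc["read"] != rc["parsed"] + rc["rejected"]:
                raise ValueError(
                    f"row-count conservation violated: read {rc['read']} != "
                    f"parsed {rc['parsed']} + rejected {rc['rejected']}"
                )


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_reports(
    results: dict[str, pd.DataFrame | dict | list],
    out_dir: str | Path,
    manifest: RunManifest | None = None,
) -> list[Path]:
    """Write result tables/objects deterministically and the manifest last.

    DataFrames become TSV, everything else JSON. Column order and row
    order are whatever the caller fixed — nothing is reordered here, so
    identical inputs yield byte-identical report files (the manifest's
    timestamp is the only non-deterministic output).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise NotADirectoryError(out)
    written: list[Path] = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = out / f"{name}.tsv"
            obj.to_csv(p, sep="\t", index=False)
        else:
            p = out / f"{name}.json"
            p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
        written.append(p)
    if manifest is not None:
        manifest.check_conservation()
        if not manifest.timestamp:
            manifest.timestamp = datetime.datetime.now(datetime.UTC).isoformat()
        p = out / "manifest.json"
        p.write_text(json.dumps(dataclasses.asdict(manifest), indent=2, default=str) + "\n")
        written.append(p)
    return written
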