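"""Classify embryo CNV profiles into segregation modes and refine the
carrier's breakpoints from the unbalanced embryos.

Three synthetic biopsies of a t(2;5)(q21;q13) carrier: an adjacent-1
product (reciprocal gain/loss of the two translocated segments), a
balanced profile with an incidental trisomy 16 (counted as alternate but
not transferable-normal), and an uninterpretable profile (ND).
"""

from quadseg import (
    CNVCall,
    EmbryoCNVProfile,
    classify_profiles,
    estimate_breakpoints,
    load_band_table,
    load_chromosome_table,
    parse_iscn_karyotype,
)

chrom_table = load_chromosome_table()
tr = parse_iscn_karyotype("46,XX,t(2;5)(q21;q13)", load_band_table(), carrier_id="C1")
bp2, bp5 = tr.bp1.position_bp, tr.bp2.position_bp
len2, len5 = chrom_table["2"].length_bp, chrom_table["5"].length_bp

profiles = [
    # gain of 2q-ter segment, loss of 5q-ter segment (boundaries +-1.5 Mb)
    EmbryoCNVProfile("E1", "C1", (
        CNVCall("2", bp2 - 1_500_000, len2, 3),
        CNVCall("5", bp5 + 1_200_000, len5, 1),
    )),
    # no quadrivalent imbalance, whole-chromosome trisomy 16
    EmbryoCNVProfile("E2", "C1", (
        CNVCall("16", 0, chrom_table["16"].length_bp, 3),
    )),
    # mid-arm fragment matching no quadrivalent segment
    EmbryoCNVProfile("E3", "C1", (
        CNVCall("2", 30_000_000, 55_000_000, 3),
    )),
]

for call in classify_profiles(profiles, tr, chrom_table):
    dosage = (
        "/".join(map(str, call.matched_dosage.as_tuple()))
        if call.matched_dosage else "-"
    )
    print(f"{call.embryo_id}: mode={call.mode:<11} balanced={call.balanced!s:<5} "
          f"incidental_aneuploidy={call.incidental_aneuploidy!s:<5} dosage={dosage}")

est2, est5 = estimate_breakpoints(profiles[:1], tr, chrom_table)
print(f"\nbreakpoint refined from unbalanced embryos: "
      f"chr{est2.chromosome}{est2.arm} at {est2.position_bp/1e6:.1f} Mb "
      f"(band midpoint was {bp2/1e6:.1f} Mb, "
      f"{est2.n_supporting_embryos} supporting embryo)")
print("\nE1's reciprocal segmental imbalance is the adjacent-1 hallmark; E2")
print("counts as alternate segregation but is not transferable-normal; E3")
print("matches no segregation product and lands in ND.")
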