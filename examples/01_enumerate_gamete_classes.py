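"""Enumerate the segregation products of a reciprocal-translocation
quadrivalent and show each product's expected embryo CNV signature.

A carrier of t(2;5)(q21;q13) forms a quadrivalent whose five disjunction
modes yield 16 chromosome compositions (32 counting recombinant status).
Only the two alternate products are balanced; every unbalanced product has
a distinct segment-dosage signature, which is what makes CNV-based mode
classification unambiguous.
"""

import pandas as pd

from quadseg import (
    enumerate_gamete_classes,
    load_band_table,
    load_chromosome_table,
    parse_iscn_karyotype,
    signature_table,
)
from quadseg.segregation import iter_signature_rows

classes = enumerate_gamete_classes(include_recombinants=True)
print(f"{len(classes)} gamete classes counting recombinant status "
      f"({len(enumerate_gamete_classes(False))} compositions)")
balanced = [g for g in classes if g.balanced and not g.recombinant]
print(f"balanced non-recombinant gametes: {len(balanced)} "
      f"({', '.join('+'.join(g.composition) for g in balanced)})")
neutral_rec = [g for g in classes if g.balanced and g.recombinant]
print(f"(plus {len(neutral_rec)} recombinant adjacent-1 products that are "
      f"copy-neutral, hence indistinguishable from alternate by CNV)\n")

tr = parse_iscn_karyotype("46,XX,t(2;5)(q21;q13)", load_band_table())
table = signature_table(tr, load_chromosome_table())
df = pd.DataFrame(iter_signature_rows(table))
print(f"{len(table)} distinct embryo signatures for t(2;5)(q21;q13)")
print(df.to_string(index=False))
print("\nEach row: segment dosage (CS2/TS2/CS5/TS5), the segregation mode it"
      "\nimplies, and the genomic gains/losses a biopsy would show.")
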