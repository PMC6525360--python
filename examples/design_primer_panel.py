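"""Design a tailed primer pair from a population alignment.

Builds a toy two-genome alignment of a single-copy gene whose polymorphism
is confined to a central (intron-like) region, finds invariant 20-nt
windows passing GC and Wallace-rule Tm screens, and picks the window pair
enclosing the most polymorphic columns within a 300-400 nt variable region.
"""

import numpy as np

from poolcross import PopulationAlignment, design_panel
from poolcross.design import candidates_to_panel

rng = np.random.default_rng(4)

# invariant backbone with ~50% GC so primer windows pass the screens
n_cols = 520
base = "".join(
    ("GC"[rng.integers(0, 2)] if i % 2 else "AT"[rng.integers(0, 2)])
    for i in range(n_cols)
)
# polymorphism confined to columns 160-470
other = list(base)
for p in rng.choice(range(160, 470), size=12, replace=False):
    other[p] = "ACGT"[("ACGT".index(other[p]) + 1) % 4]
alignment = PopulationAlignment("toy_gene", [base, "".join(other)])

candidates, undesignable = design_panel([alignment])
for cand in candidates:
    fw, rv = cand.forward_window, cand.reverse_window
    print(f"gene {cand.gene_id}:")
    print(f"  forward window {fw.start_1based}-{fw.end_1based}  Tm {fw.tm:.0f}C  GC {fw.gc:.0%}")
    print(f"  reverse window {rv.start_1based}-{rv.end_1based}  Tm {rv.tm:.0f}C  GC {rv.gc:.0%}")
    print(f"  variable region {cand.variable_region_length} nt enclosing "
          f"{cand.polymorphic_columns} polymorphic columns")
    for v in cand.variants:
        tag = f"het({v.het_base})" if v.is_het else "plain"
        print(f"  {v.direction:>7} {tag:>6}: {v.full_primer}")
for gene in undesignable:
    print(f"gene {gene}: no feasible primer pair")

panel = candidates_to_panel(candidates)
print(f"\nre-parsed as an analysis panel: amplicons {panel.amplicon_ids}, "
      f"expected fragment length {panel.fragment_length('toy_gene')} nt")
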