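"""Prioritize the encoded published cohort tables end to end.

Builds the 18-variant, 11-patient worked-example cohort (the printed
AIS-literature-gene and dual-evidence tables), runs the consequence /
rarity / classification cascade, intersects with the packaged 56-gene
AIS panel, and prints the run report.  Expect 7 dual-evidence variants
(SGCD, CLCN1, DPYS x2, MYBPC3, MYO7A, NDUFAF5) and 11 AIS-panel
variants with TBX1 contributing two.
"""

import scoliovar as sv
from scoliovar import worked_example as we

cohort = we.cohort()
result = sv.run_pipeline(cohort, sv.load_ais_gene_list())
print(sv.render_report(result))
print(
    "Patient Pt9 pathogenic variants:",
    ", ".join(
        result.rare_table.variant(k).gene for k in result.profiles["Pt9"].pathogenic
    ),
)
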