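"""Over-representation analysis of a selected gene list.

A one-sided hypergeometric test asks, per gene set, whether the selection
overlaps the set more than chance sampling from the universe would allow.
"""

from cellrules import GeneSetCollection, ora

universe = {f"g{i}" for i in range(20)}
sets = GeneSetCollection(
    {
        "T_marker": ("planted marker program", {f"g{i}" for i in range(5)}),
        "T_other": ("unrelated program", {f"g{i}" for i in range(10, 18)}),
    },
    universe,
)

selected = {"g0", "g1", "g2", "g3", "g4"}   # exactly the marker program
rows = ora(selected, sets, alpha=0.001)
for r in rows:
    print(f"{r.term_id}: overlap {r.overlap}/{r.term_size}, "
          f"p = {r.p_value:.3e}")
# Picking all 5 of a 5-gene term out of a 20-gene universe has
# p = 1/C(20,5) = 6.45e-05 < 0.001, so only T_marker is reported.
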