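"""Characterise interspecific divergence of a four-species marker family.

Generates a synthetic AT-biased coding-gene family, then prints the base
composition per species (overall and by codon position) and the uncorrected
p-distance matrix computed with pairwise deletion.  High A+T with the third
codon position most biased, and all pairwise p-distances near 0.19, mirror
what a mitochondrial COI family of congeneric insects looks like.
"""

from specprime import base_composition, p_distance_matrix
from specprime.compstats import records_to_trivial_alignment
from specprime.fixtures import SyntheticFamilySpec, generate_family

records, _ = generate_family(SyntheticFamilySpec(seed=1))

print("Base composition (percent of unambiguous bases):")
table = base_composition(records)
print(f"{'species':<8}{'class':<6}{'A%':>7}{'T%':>7}{'G%':>7}{'C%':>7}{'A+T%':>8}")
for row in table.rows:
    print(f"{row.species:<8}{row.position_class:<6}"
          f"{row.a_pct:>7.2f}{row.t_pct:>7.2f}{row.g_pct:>7.2f}{row.c_pct:>7.2f}"
          f"{100 - row.gc_pct:>8.2f}")

print("\nUncorrected p-distance (pairwise deletion), species consensus:")
dm = p_distance_matrix(records_to_trivial_alignment(records))
print(" " * 6 + "".join(f"{sp:>8}" for sp in dm.labels))
for i, sp in enumerate(dm.labels):
    print(f"{sp:<6}" + "".join(f"{dm.p[i][j]:>8.3f}" for j in range(len(dm.labels))))
print("\nEvery off-diagonal value above ~0.17 signals clear interspecific "
      "divergence;\nthe matrix is symmetric with a zero diagonal.")
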