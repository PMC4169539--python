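"""Pairwise Fst, the indistinct threshold, and isolation by distance.

Computes the Hudson pairwise Fst matrix between all populations, lists
pairs below the 0.001 threshold (treated downstream as interchangeable for
assignment scoring), and regresses Fst on great-circle kilometres.
"""

from eurostruct import (
    allele_frequencies,
    default_config,
    fst_vs_distance,
    indistinct_groups,
    pairwise_fst,
    simulate_dataset,
)

cfg = default_config(n_snps=4000, seed=1, size_scale=0.35)
cohort = simulate_dataset(cfg)
fm = pairwise_fst(allele_frequencies(cohort))

print("lower-triangle Fst (3 decimals):")
print(fm.to_lower_triangle_frame().to_string(na_rep=""))

pairs, closure = indistinct_groups(fm)
print("\npairs below the 0.001 indistinct threshold:")
for pair in sorted(sorted(p) for p in pairs):
    print(f"  {pair[0]}-{pair[1]}  Fst={fm.value(*pair):.4f}")
print("transitive closure (diagnostic only):", [sorted(c) for c in closure if len(c) > 1])

r2, mr, mp = fst_vs_distance(fm, cfg.geo, n_perm=999, seed=1)
print(f"\nFst vs km: OLS r^2 = {r2:.3f}, Mantel r = {mr:.2f}, p = {mp:.4g}")
print("Genetic distance increases with geographic distance (isolation by")
print("distance), with the drifted outlier inflating its whole row.")
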