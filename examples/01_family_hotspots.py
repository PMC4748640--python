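"""Detect shared mutational hotspots in a simulated protein family.

Builds a 10-member homologous family, plants a hotspot carrying 30% of all
somatic mutations on one consensus column, and runs the full pipeline:
alignment -> consensus -> pooling -> bootstrap Gamma null -> per-position
q-values gated on Trident conservation.
"""

from famhotspot import CohortSpec, FamilySpec, analyze, generate_cohort, generate_family

records, true_aln = generate_family(FamilySpec(n_members=10, length=150, seed=1))
cohort = CohortSpec(
    n_samples=60,
    background_rate=1.0,
    hotspot_columns=((40, 0.3),),  # column 40 takes 30% of all mutations
    seed=2,
)
mutations, truth = generate_cohort(cohort, records, true_aln)

result = analyze(records, mutations, seed=3, aln=true_aln)
hs = result.hotspots

print(f"pooled mutations: N = {result.profile.N} over K = {true_aln.K} columns")
print(f"profile entropy H = {hs.H_obs:.4f}, global p = {hs.global_p:.3g}")
print("significant hotspot columns (q < 0.05):")
for _, row in hs.significant().iterrows():
    genes = sorted({g for g, *_ in row["contributors"]})
    print(
        f"  column {int(row['column'])}: n={int(row['n_mut'])} "
        f"q={row['q']:.3g} trident={row['trident']:.2f} genes={','.join(genes)}"
    )
# The global p near 0 says the profile is non-random; the per-column q
# pinpoints the planted column 40, contributed by many different members --
# none of which would be significant on its own.
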