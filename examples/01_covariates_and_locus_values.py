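"""Dosage-to-covariate conversion and genotypic values at one locus.

Builds the diploid and tetraploid bi-allelic genotype classes, converts raw
allele dosages to the scaled additive and dominance covariates, and evaluates
locus-level and two-locus epistatic genotypic values for a small effect set.
"""

import numpy as np

from polybreed import additive_covariate, dominance_covariate, epistatic_pair_values, locus_values

print("Covariates per B1 dosage (t), diploid then tetraploid:")
for ploidy in (2, 4):
    for t in range(ploidy + 1):
        ta, td = additive_covariate(t, ploidy), dominance_covariate(t, ploidy)
        print(f"  ploidy {ploidy}  t={t}:  t_a={ta:+.2f}  t_d={td:.2f}")
# t_a runs from -1 (no copies) to +1 (all copies); t_d peaks at 1 for the
# balanced heterozygote and vanishes for homozygotes.

a_col, d_col = np.array([-0.2, 0.3]), np.array([0.1, 0.05])
print("\nTetraploid locus values with a=(-0.2, 0.3), d=(0.1, 0.05):")
for t in range(5):
    a, d = locus_values([t, 4 - t], a_col, d_col, ploidy=4)
    print(f"  dosage ({t},{4 - t}):  a={a:+.3f}  d={d:.3f}")
# the additive value moves linearly from -(a2-a1) to +(a2-a1); the dominance
# value is proportional to the heterozygosity of the genotype.

rng = np.random.default_rng(1)
aa, ad, da, dd = rng.normal(scale=0.1, size=(4, 4))
v_aa, v_ad, v_dd = epistatic_pair_values([1, 1], [1, 1], aa, ad, da, dd, ploidy=2)
print(f"\nDiploid double heterozygote epistasis: aa={v_aa:+.3f} ad+da={v_ad:+.3f} dd={v_dd:+.3f}")
print("(additive x additive vanishes because the additive covariate of a")
print(" heterozygote is zero; dd equals the sum of the four pair effects)")
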