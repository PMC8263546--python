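"""Build orthogonal relationship matrices from simulated clone genotypes.

Simulates a small panel of clones, constructs the additive (G_A), dominance
(G_D) and additive-by-additive epistatic (G_AA) relationship matrices from
observed genotype frequencies, and computes each clone's average genome-wide
heterozygosity.
"""

import numpy as np

import clonalgp as cg

cfg = cg.SimConfig(n_clones=200, n_snps=1000, seed=7, missing_rate=0.01)
g = cg.simulate_genotypes(cfg)
g, qc = cg.apply_qc(g)  # alternate-allele frequency >= 1%, call rates >= 90%
print(f"after QC: {g.n_clones} clones x {g.n_snps} SNPs "
      f"({len(qc.dropped_snps)} SNPs dropped)")

kernels = cg.standard_kernel_set(g, ("G_A", "G_D", "G_AA"))
for name, k in kernels.items():
    off = k.values[~np.eye(k.n, dtype=bool)]
    print(f"{name}: mean diagonal {np.mean(np.diag(k.values)):.6f}, "
          f"off-diagonal range [{off.min():.3f}, {off.max():.3f}]")
# every kernel is standardised so its diagonal averages exactly 1; off-diagonal
# entries are genomic relationships between clone pairs on that gene-action scale

het = cg.heterozygosity(g)
print(f"heterozygosity: mean {het.values.mean():+.4f}, "
      f"range [{het.values.min():+.3f}, {het.values.max():+.3f}]")
# Het_k is 1 for a clone heterozygous at every locus of an HWE population and
# negative for clones more homozygous than expected; it is the covariate used
# to capture directional dominance
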