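"""Differential screens: ANOVA+BH gene screen, FC+VIP metabolite screen.

Also shows the small transforms used around the screens: log10(FPKM+1),
2^-ddCt for qPCR, and relative anthocyanin shares.
"""

import petalnet as pn

ds = pn.generate_timecourse(
    pn.SimConfig(n_tf=50, n_structural=30, n_metabolites=10, rng_seed=42, noise_sd=0.1)
)

genes = pn.de_genes(ds.expression)
print(f"differential genes: {int(genes.passes.sum())} / {len(genes)} "
      f"(mean FPKM > 0.5, |log2FC| >= 1, BH-adjusted p < 0.05)")

mets = pn.de_metabolites(ds.metabolites)
print(f"differential metabolites: {int(mets.passes.sum())} / {len(mets)} "
      f"(FC > 2 or < 0.5, VIP > 1)")
print(mets[["fc_max", "vip", "passes"]].head(4).round(3))

pca = pn.metabolite_pca(ds.metabolites, subset=list(mets.index[mets.passes]))
print(f"PCA of differential metabolites: PC1 {100*pca.variance_fractions[0]:.1f}%, "
      f"PC1+PC2 {100*pca.variance_fractions[:2].sum():.1f}% of variance")

# qPCR: a target amplifying 4 cycles earlier (relative to the reference)
# than in the calibrator is 2^4 = 16-fold up
print("2^-ddCt for Ct (20, 18, 24, 18):", pn.ddct(pn.QpcrMeasurement(20, 18, 24, 18)))
# shares of two pigments with contents 7.2 and 6.2 (arbitrary units)
print("relative shares of (7.2, 6.2):", pn.relative_share([7.2, 6.2]).round(2))
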