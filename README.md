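# petalnet

Regulatory-network inference for petal-color change over a staged
flower-opening time course.

Many ornamentals open dark and fade: anthocyanin pigments accumulate in
the bud and are lost as the flower opens.  `petalnet` is a Python library
for working out *which* transcription factors drive that program from a
four-stage (T1 bud → T4 fading), replicated transcriptome–metabolome
experiment.  It is aimed at plant systems biologists who have an FPKM
matrix, a flavonoid metabolite table, gene role annotations (TF family /
pathway enzyme class), promoter sequences and motif models — and who want
the whole chain from differential screening to a time-ordered regulatory
network with motif-based confirmation, plus Ks-based dating of
whole-genome duplications on the side.

## The core models

* **Differential screens.**  Genes: mean FPKM > 0.5, |log₂FC| ≥ 1 between
  the extreme stage means, and one-way ANOVA across stages on
  log₁₀(FPKM+1) at Benjamini–Hochberg FDR < 0.05.  Metabolites: extreme
  stage-mean fold change > 2 (or < 0.5) and PLS-DA variable importance
  VIP > 1, with VIPⱼ = √(p·Σₐ SSₐ wⱼₐ² / Σₐ SSₐ) and Σⱼ VIPⱼ² = p.
* **Time-ordered gene co-expression network (TO-GCN).**  Edges between
  differential features at Pearson correlation ≥ 0.90 (gene–gene) and
  ≥ 0.73 (metabolite–gene).  Anchored at a seed TF known to act first (a
  MYB, strictly decreasing T1→T4), every gene gets level
  L = 1 + shortest-path distance from the seed; metabolites inherit the
  level of their best-correlated gene.  Levels map onto stages through the
  majority peak stage of their genes.
* **Sub-networks.**  Direct regulators (same- or earlier-level TF
  neighbours of a structural gene), hierarchical upstream TF chains
  (exactly one level back per link), metabolite–gene layers
  (high-confidence above PCC 0.9), and per-edge confirmation by promoter
  motif hits.
* **Motif scanning.**  2 kb strand-aware promoters; PWM log-odds scores in
  bits with *exact* background p-values by dynamic programming over a
  discretized score lattice; hits at p ≤ 10⁻⁴.
* **WGD dating.**  Ks-distribution peaks by Gaussian KDE;
  γ = Ks/(2·t) calibrated on a dated divergence; age = Ks_peak/(2γ).

A synthetic-data generator plants a known 8-level cascade (profiles,
edges, metabolite responses, promoter motif instances) so the entire
pipeline is testable end to end without any download; see
`docs/methods.md` for the model and its limits.

## Worked example

```python
import petalnet as pn

cfg = pn.SimConfig(n_tf=50, n_structural=30, n_metabolites=10,
                   rng_seed=42, noise_sd=0.1)
ds  = pn.generate_timecourse(cfg)       # planted 8-level cascade
res = pn.run_pipeline(ds)               # screens + edges + BFS levels

print(res.togcn.graph.number_of_nodes(), res.togcn.graph.number_of_edges())
print(pn.level_stage_map(res.togcn, ds.expression))
print(pn.level_recovery(res.togcn, ds.truth))
print(pn.regulator_recovery(res.togcn, ds.truth))
```

prints

```
90 1500
{1: 'T1', 2: 'T1', 3: 'T2', 4: 'T2', 5: 'T3', 6: 'T3', 7: 'T4', 8: 'T4'}
1.0
(0.9095238095238095, 0.0)
```

— a 90-node, 1500-edge network whose eight levels map two-per-stage onto
the four opening stages; all planted levels recovered and 91% of the
planted direct-regulator edges found with no false discoveries.  Dating a
whole-genome duplication from its Ks peak:

```python
d = pn.date_wgd(ks_wgd=0.25, ks_div=0.2, t_div=43.20)
print(d.gamma, d.age_wgd)   # 0.0023148... 54.0
```

With the lilac–ash divergence (Ks 0.2 at 43.20 Mya) as calibration, the
shared Ks 0.25 duplication peak dates to 54 Mya — before the family split.

The `examples/` directory holds one short script per capability
(simulation, screening, network, sub-network + motif confirmation,
promoter scanning, WGD dating); each prints what it computes and says
what the numbers mean.

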