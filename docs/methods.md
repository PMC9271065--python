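# Methods

`petalnet` reconstructs the regulatory program of petal-color change over a
four-stage flower-opening time course (T1 bud, T2 initial opening, T3 full
opening, T4 fading), integrating an FPKM expression matrix, a flavonoid
metabolite relative-content matrix, gene role annotations, promoter
sequences and motif models.  This note records the models, the parameter
choices, and what the synthetic benchmark does and does not demonstrate.

## Differential screens

**Genes.**  A gene is differential when (i) its overall mean FPKM exceeds
0.5, (ii) the log2 fold change between the most extreme pair of stage means
has magnitude >= 1, and (iii) a per-gene one-way ANOVA across the four
stages on log10(FPKM+1) values is significant at Benjamini–Hochberg
adjusted p < 0.05.  Count-based negative-binomial DE models are out of
scope here (the package consumes FPKM, not read counts); the
ANOVA-on-log-FPKM screen preserves the published FDR and fold-change
thresholds while being exact on the data the package actually handles.
Constant genes have an undefined F statistic and are assigned p = 1.
A pseudocount of 0.01 (configurable) is added to both stage means before
any ratio, so fold changes are defined for zero means.

**Metabolites.**  A metabolite is differential when its extreme stage-mean
fold change is > 2 or < 0.5 *and* its variable importance in projection
(VIP) exceeds 1 (strict).  Because no specific stage pair is designated,
the fold change is taken between the extreme stage-mean pair.  VIP comes
from a PLS-DA: a two-component PLS2 regression of the one-hot stage
membership on the centered, unit-variance metabolite matrix, with

VIP_j = sqrt( p · Σ_a SS_a w_ja² / Σ_a SS_a ),

where p is the number of metabolites, w_a the unit x-weight vectors and
SS_a = (t_a·t_a)(q_a·q_a) the response variance captured by component a.
Σ_j VIP_j² = p identically.  A full OPLS-DA (orthogonal-component
deflation) is deliberately not implemented: for a screening use the VIP
ranking of single-orthogonal-component OPLS-DA coincides with PLS-DA, and
the simpler model is exactly testable against a step-by-step NIPALS oracle
(agreement to 1e-8 requires tight convergence; the implementation runs
NIPALS to tol 1e-18).  Note that VIP > 1 is a *relative* cut — the mean of
VIP² is 1 by construction — so it is only meaningful when the matrix
contains non-differential metabolites as contrast.

Small helpers: log10(x+1) (0 maps to 0), the 2^-ddCt relative-expression
statistic, relative shares (percent of a compound subset's total), and a
PCA biplot of the differential metabolites (centered, unit-variance scaled
by default — whether to scale is a flag, scaled being the default because
relative contents span orders of magnitude across compounds).

## Time-ordered co-expression network

Edges connect differential features whose Pearson correlation (PCC)
reaches 0.90 for gene–gene pairs and 0.73 for metabolite–gene pairs,
boundaries inclusive; metabolite–metabolite pairs never form edges, and
only positive correlations count (the cutoffs are positive; negative-edge
support is out of scope).  The 0.90 cutoff applies to *all* gene–gene
pairs, TF–TF included, since upstream TF chains require TF–TF edges and no
separate cutoff exists.  Correlations are computed over the 12 replicate
samples by default (configurable to the 4 stage means) and on the
log10(x+1) scale by default (configurable to raw): log10(FPKM+1) is the
package's standard expression scale, and on it multiplicative replicate
noise is homoscedastic, so sample correlations are not attenuated by the
expression level — on the raw scale the correlation of two genes with
identical profiles is biased downward by noise roughly in proportion to
mean²/variance of the profile, which makes a fixed 0.90 cutoff
substantially stricter for flat profiles.

Levels are assigned breadth-first from a seed transcription factor chosen
to act first (a MYB with strictly decreasing expression T1→T4): the seed
is L1, and every gene reachable on the gene–gene subgraph gets level
1 + shortest-path distance.  This equals the "min assigned neighbour + 1"
rule and is deterministic given the edge set.  The exact level-assignment
rule of published time-ordered networks is not fully specified in the
sources this design follows; BFS reproduces the qualitative level/stage
correspondence and is stated here as this package's rule.  Genes
unreachable from the seed stay unassigned and are reported.  Metabolites
are terminal annotations: each inherits the level of its highest-PCC gene
neighbour and never propagates a level, which prevents metabolite-mediated
shortcuts between genes.

Each level maps to the majority peak stage of its gene nodes (peak = stage
of maximal mean, ties toward the earlier stage), with a monotone repair:
a later level mapping to an earlier stage than its predecessor inherits
the predecessor's stage.

## Sub-networks

A **direct regulator** of a structural gene is a TF neighbour at the same
or an earlier level; later-level TFs are excluded by the time ordering.
**Upstream chains** extend each direct regulator backwards through TF–TF
edges whose level decreases by exactly one per link (a flag relaxes this
to any strictly earlier level); chains are maximal (extended as far as
possible up to the requested depth), enumerated in lexicographic order and
capped (default 1000 per target) against combinatorial blow-up.
**Metabolite links** are the metabolite's gene neighbours; links with
PCC > 0.9 are flagged high confidence.  **Motif confirmation** marks a
regulator edge confirmed when some motif of the regulator's TF family hits
the target's promoter at the scan threshold; families without a motif are
marked unconfirmable, never dropped — confirmation annotates topology, it
never changes it.

## Promoter extraction and motif scanning

Promoters are the 2000 bases (configurable) upstream of the annotated
feature start: for plus-strand genes the window ending immediately before
the start; for minus-strand genes the window starting immediately after
the end, reverse complemented.  Annotation input uses 1-based inclusive
coordinates (the GFF3 convention) and is converted to 0-based half-open
internally.  Without UTR annotation the feature start is the anchor.
Truncation at contig edges is flagged.

A PWM stores per-column base probabilities; 0.01 pseudocount is added to
every cell (then columns renormalized) so log-odds scores are finite.
Windows are scored as Σ log2(p_b,i / background_b) in bits.  The p-value
of a score is exact: per-column score distributions under the background
are convolved on a lattice of 1/1000-bit bins, giving the full null
distribution of the window score; the tail at the (rounded) observed score
is the p-value.  Rounding the total score to the lattice rather than
summing pre-rounded columns introduces at most w/2 bins (0.005 bits at
w = 10) of inconsistency, far below any decision threshold in use; the
enumeration tests pin the convention.  The default background is the
promoter set's empirical base composition; scanning reports every window
on both strands with p <= threshold (default 1e-4), skipping windows that
contain N.  Expected background hits per promoter are
2·(L−w+1)·p_attained, where p_attained is the largest attainable tail mass
<= the threshold — the discrete score lattice makes the attained level
slightly conservative, and the calibration test accounts for that.

## WGD dating

Peaks of a Ks distribution are modes of a Gaussian KDE evaluated on a
2000-point grid over the window (0.05, 2.0) — the lower bound excludes the
near-zero allelic/tandem peak, the upper bound saturated values; both are
configurable.  Bandwidth is Silverman's rule by default, with a fixed
bandwidth override for exact reproducibility (Silverman's factor depends
on n, so e.g. duplicating the sample shifts the mode slightly).  Dating:
gamma = Ks_div / (2·t_div) from an independently dated divergence, then
age = Ks_peak / (2·gamma).  Computing Ks from codon alignments and synteny
detection are out of scope; Ks values are consumed as input.

## The synthetic generator

The generator emulates the *structure* of a staged flowering study so that
every downstream stage is testable against planted truth: 4 stages × 3
replicates; one seed MYB alone at level 1; the other TFs filling levels
2..8 and structural genes levels 3..8 round-robin; metabolites as scaled
copies (plus noise) of their producing enzyme's profile; promoters of
i.i.d. background bases carrying one sampled site per (regulator family,
target); one JASPAR-style PWM per TF family (0.95 consensus probability,
width 10).  Noise is multiplicative log-normal (sd 0.1 by default on the
natural-log scale — replicate dispersion is not empirically calibrated),
and a single integer-seeded generator drives all randomness, making output
byte-identical across runs.

The eight level-anchor profiles are frozen constants obtained by
constrained optimization.  Centered four-stage profiles form a
3-dimensional space, and a chain of 8 unit profiles must satisfy, on the
log10(FPKM+1) scale: adjacent correlation >= ~0.92 (so adjacent-level
edges survive the 0.90 cutoff under noise), non-adjacent < 0.85 (no
level-skipping edges), peak stages T1,T1,T2,T2,T3,T3,T4,T4 with margin,
and a strictly decreasing seed.  This is a tight spherical-code problem:
the four stage-argmax regions are the Voronoi cells of a regular
tetrahedron on the profile sphere, and the feasible chains thread a narrow
corridor near a triple point.  Mean FPKM profiles are
scale · 30 · exp(2.5·q) (per-gene log-normal scale, ~75-fold dynamic range
— typical of strongly stage-specific genes), which keeps correlations on
the log scale exactly equal to the designed dot products.  An uneven
level-to-stage pattern (three levels at T1) is infeasible with usable
margins, and no more than 8 mutually distinguishable levels exist at all,
hence `n_levels <= 8`.

`edge_density` = 1 by default: every (same-level or previous-level TF) →
target pair is a true regulator edge.  This is the honest ground truth for
what a co-expression network can resolve — genes sharing a level are
exactly proportional in the noiseless limit, so no correlation method can
single out a subset of them as regulators.  The same identifiability limit
applies to metabolite links: a metabolite correlates identically with
every gene of its enzyme's level (and above 0.73 with genes up to two
levels away), so metabolite-link recovery is asserted as "the producing
enzyme is always among the links, and links stay within two planted
levels", not as exact equality.

**What passing the benchmark shows — and does not.**  The generator
produces clean level structure, homogeneous noise, and motifs planted only
for true regulators.  Passing therefore shows the pipeline's machinery is
correct (edges, levels, chains, scanning, screens) at realistic noise, not
that the method would recover regulation in real tissue, where profiles
are not grouped into discrete levels, noise is gene-dependent, indirect
correlations abound, and promoter occupancy is unobserved.  Real-data
figures at genome scale (thousands of nodes, hundreds of thousands of
edges) are deliberately replaced by this parameter-recovery benchmark at
desk scale: the reference configuration is 50 TFs + 30 structural genes +
10 planted and 10 null metabolites, which runs the full pipeline in a few
seconds.

## Numerical choices and degenerate inputs

* Correlation of a constant vector is undefined: `pcc` raises; the edge
  builder drops constant features with a warning.
* Peak-stage ties break toward the earlier stage; level-stage maps are
  monotone-repaired.
* The BH step assigns constant genes p = 1 rather than excluding them, so
  the correction is over all tested genes.
* `relative_share` requires a positive total; all-zero input is an error.
* PCA drops constant metabolites with a warning; variance fractions are
  over all retained components and sum to 1.
* KDE peak extraction requires >= 30 values inside the window.
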