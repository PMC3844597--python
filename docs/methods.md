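# Methods

## Scope and data model

`drugsig` analyses drug × time-course expression experiments: a probes ×
samples matrix with a sample sheet assigning each array a drug, a
time-point (default 1/2/4/8 h), a replicate index, a hybridization
batch, and a vehicle flag.  The reference design is an 18-drug
psychotropic panel with two vehicle solvents (saline, Tween 80) and a
naive group, three replicate arrays per drug × time cell — 12 arrays
per drug — and a two-batch structure mimicking two array versions.

## Preprocessing

Raw intensities go through quantile normalization (reference = row-rank
means; ties receive the average of the tied reference values), log2
transform (floored at 1.0 to avoid negative intensities; applied only
when the input is declared linear-scale), and per-probe z-score
standardization within each hybridization batch.  The z-score uses the
population (divide-by-n) standard deviation — a deliberate small-n
convention so that a batch of three arrays standardizes reproducibly —
and removes any per-batch affine distortion exactly.  Probes constant
within a batch map to 0 with a warning.  Missing values are rejected,
not imputed.  Background subtraction is a pass-through hook: bead-level
processing is out of scope and synthetic data carry no background.
Quantile normalization is applied jointly over all samples; normalizing
per batch before pooling is a reasonable alternative the package does
not implement.

## ANOVA screen

Each probe is tested with a balanced two-way fixed-effects ANOVA:
treatment (every drug plus both vehicle groups as levels; the naive
group is excluded) × time, with interaction.  Sums of squares are the
standard balanced decomposition (types I/II/III coincide), vectorised
across probes; P values come from the F upper tail.  Unbalanced designs
are rejected rather than silently switching SS types.  The drug
main-effect P values are corrected by Bonferroni and Benjamini-Hochberg
(via statsmodels).  `estimate_true_positives` reports
`TP(q) = R(q)·(1 − q)` over an FDR grid with the grid maximum as a
plateau summary; this estimator is an approximation chosen for
transparency, not a published formula.

## genes2mind score

Fold changes are computed per (probe, drug, time) against the drug's
matched vehicle group (configurable: `matched` follows the per-drug
control solvent; `always_saline` forces the saline group), with a
two-sided equal-variance two-sample t-test on replicate log2 values.
The score is

    score(i,j) = 10 · (−log2 p_ij) · log2(f_ij + 1) · foldmean_i/foldsd_i

Design choices the formula leaves open, and how they are resolved here:

- the fold-magnitude term is `f = 2^|log2fc| − 1`, symmetric in
  direction, so that swapping drug and vehicle labels flips only the
  sign of the score; direction is carried by the sign of `foldmean`
  (the mean signed log2 fold change across the four time-points);
- `foldmean/foldsd` uses the sample (n−1) standard deviation, making
  the ratio behave like a consistency t-statistic across the
  time-course;
- aggregation: drug-level score = per-time score of largest magnitude,
  transcript-level (global) score = drug-level score of largest
  magnitude; ranking is by |global score| with lexicographic probe-id
  tie-breaks;
- `foldsd = 0` (identical fold change at every time-point) makes the
  ratio undefined; such entries carry a NaN sentinel and are excluded
  from ranking with a warning.

Default selection thresholds: top 300 transcripts, score > 1.8 for the
threshold mode, score > 10 for per-drug regulation counts.

## Drug space

Drug profiles are rows of signed log2 fold changes over the selected
transcripts × time-points (transcript-major, time-minor column order).
Classification uses (a) agglomerative clustering with Euclidean
distance and complete linkage — the common defaults where no method is
otherwise specified — exported as a Newick dendrogram with
merge-height-difference branch lengths; and (b) PCA on column-centered,
unscaled profiles (fold changes share units), three components by
default, drugs as observations.  Component signs are fixed by making
the largest-|loading| feature positive.  Per-transcript correlation
with each component uses the transcript's per-drug summary — the signed
log2fc at the time of maximum |log2fc| — against the component scores;
zero-variance transcripts return NaN.

## Co-expression map and networks

Transcript profiles for the map are group-mean log2 fold changes per
(drug, time) — drug-response curves, not per-sample values.  Distance
is `d = 1 − ρ` with ρ the Spearman correlation (rank-transform +
Pearson); constant profiles get the neutral sentinel distance 1.0 with
a warning.  The minimal spanning tree is built by Kruskal's algorithm
with edges pre-sorted lexicographically so equal-weight ties resolve
deterministically.  Networks are single-linkage clusters of the
selected transcripts under walk-length (tree-path edge count), cut at
internode distance 4, computed as connected components of the
walk-length-thresholded graph; components below `min_network_size`
(default 10) are reported unassigned, and networks are numbered in
decreasing size order.

All-pairs correlation makes the map O(n²) in transcripts; a few
thousand transcripts is the practical range, and the shipped analyses
use maps of 600–2000 transcripts.

## Mechanism inference

The bilinear model `E[t, d] = Σ_m A[m, t]·B[d, m]` links transcript
responses to pharmacological mechanism engagement.  `B` derives from
binding constants as `B = max(0, pKi − 5)` (pKi = −log10 Ki[M]; the
floor of 5 treats Ki weaker than 10 µM as no engagement); direction of
effect (agonist vs antagonist) is folded into the mechanism definition,
not into B's sign.  `A` is estimated by per-transcript least squares
(minimum-norm under rank deficiency; optional ridge, default 0).  The
model is reduced to the union over mechanisms of the 50 transcripts of
largest |A| (ties by transcript id), and a query drug's activation
vector solves the reduced least-squares problem with signed,
unconstrained activations.  The per-drug transcript summary feeding E
is the same max-|log2fc| summary used in drug space.  Leave-one-out
validation refits A without each drug and reports the cosine similarity
between predicted activations and the drug's true binding row plus the
rank of its strongest true mechanism; a drug whose true mechanisms are
all unengaged by the remaining panel is flagged unpredictable.

## Synthetic data generator

The generator emulates the study design above with a bilinear signal
model: expected log2 expression = baseline (uniform on 6–12) +
`Σ_m A[m,p]·B[d,m]·shape_d(t)` + batch effect, with i.i.d. Gaussian
replicate noise.  Key parameters, defaults, and rationale:

- **Time-response shape**: log-normal impulse
  `exp(−(ln t − ln t_peak)²/(2w²))`, unit height at the drug's peak
  time (assigned round-robin over 1/2/4/8 h), width `w = 1.0`
  ln-hours — broad enough that induction spans neighbouring sampled
  time-points, as real immediate-early-gene time-courses do.
- **Amplitude**: 2.0 log2 units at peak per unit engagement in the
  study configuration (≈4-fold induction, typical of activity-dependent
  genes in striatum).
- **Noise**: `noise_sd = 0.3` log2 units per replicate array, a
  realistic between-replicate spread for pooled-sample arrays.
- **Planted co-expression modules**: each network's members share
  sensitivity (gains uniform on 0.8–1.2) to one mechanism *group*; the
  default three groups are (DAT, MAO), (DRD2, HRH1) and (GABAA, OPRM1,
  HTR1A) — broad, drug-disjoint subsets of the panel (dopaminergic
  tone; D2/H1 blockade; inhibitory Gi/Cl-coupled signalling).  Breadth
  is essential: the Spearman correlation between two module members is
  bounded by the fraction of profile cells their shared signal
  occupies, so a module driven by only one or two drugs cannot rise
  above the rank-noise floor.
- **Down-regulation**: the up:down split of affected transcripts
  (default 90:10) is realised by planting the down-regulated fraction
  as scattered singleton responders (one mechanism each, negative
  sensitivity) outside the modules.  Each module is therefore
  coherently up- or down-regulated as a unit, which keeps within-module
  expected-profile correlations at 1 and — more importantly — avoids a
  rank-statistics artifact: a down-regulated module positively
  rank-correlates with every up-regulated module (the disjoint
  signal-cell indicators are negatively correlated and the sign flip
  makes the product positive), which would bridge otherwise unrelated
  modules on the tree.
- **Batch structure**: replicate 1 of each cell on batch "v1", the
  rest on "v2" (≈1:2, echoing a two-array-version study); batch shift
  and scale default to the identity so the noise-free data equal the
  returned mean surface exactly, and non-trivial affine distortions are
  opt-in (they are removed exactly by the per-batch z-score).
- **Naive group**: generated at a single pseudo-time-point by default
  (the sampling times of an untreated group are a design choice, so the
  flag `naive_collapsed` exposes it); the naive arm is excluded from
  the ANOVA treatment factor.
- The default binding fixture is a 14-drug × 13-mechanism panel
  assembled from published target annotations of the drug panel; the
  engagement values are synthetic stand-ins (real affinities enter via
  `ki_to_binding`).

What the generator does **not** emulate: probe-level effects (GC
content, cross-hybridisation), correlated noise between probes,
baseline co-expression among background transcripts (background probes
are independent noise, so the background of the synthetic tree is
structureless), drug pharmacokinetic differences beyond the peak-time
shift, and unbalanced designs.  Recovery results on synthetic data
therefore show that the estimators are correct under the model's
assumptions, not that real arrays satisfy those assumptions.

## Numerical and determinism choices

- Identical seeds give bit-identical generated matrices and pipeline
  summaries; all stochastic tests and the verification script derive
  sub-seeds from one master seed.
- MST ties, ranking ties, and reduced-set ties all break
  lexicographically.
- t-test P values on zero-variance cells are mapped to 1 (no
  evidence).
- P values are clipped at 1e-300 before log2 in the score to avoid
  infinities.

## Problem sizes in the shipped analyses

The test-suite and verification script run the screen at 1000 probes ×
240 arrays (200 null replicates for the family-wise-error check),
network recovery on maps of 1200 transcripts with planted modules of
100/40/30 (five replicate maps, median ARI reported), and mechanism
inference on an 8-drug / 4-mechanism panel with 160 transcripts (200
held-out replicates).  These sizes keep a full verification run under a
minute while leaving every estimator in its intended regime.

## Known limitations

- Walk-length network extraction can merge two genuine modules when
  their attachment points to the background tree happen to fall within
  the cutoff (observed in roughly one map in fifteen at the shipped
  sizes); on dense maps (background comparable in size to the
  selection) the fixed cutoff of 4 over-connects.  The median-over-maps
  ARI is reported for this reason.
- The true-positive curve `R(q)(1−q)` is a first-order estimate; it
  ignores the dependence structure across probes.
- The bilinear mechanism model is identifiable only for mechanisms
  engaged by the training panel; activation predictions for a query
  drug are meaningful only over mechanisms with non-zero rows in the
  reduced sensitivity matrix.
- Quantile normalization assumes identical intensity distributions
  across arrays and will attenuate genuine global shifts.
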