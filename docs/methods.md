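# Methods

## The classification model

Each patient sample is represented by the expression of a fixed, ordered
panel of 57 marker genes. The classifier never sees the raw values: within
each sample the 57 values are replaced by their ascending ranks (lowest
expression → rank 1). Ties are resolved by the average rule — every member
of a tied block receives the mean of the ranks the block spans — so each
profile sums to exactly 57·58/2 = 1653 regardless of ties. The average rule
was chosen over ordinal ranking because fragment-analysis data contain many
exact zeros (undetected genes), and averaging treats them symmetrically
instead of ordering them by their arbitrary position in the panel; ordinal
ranking remains available as a `tie_rule` option.

The rank transform is the normalization. A rank profile is invariant under
any strictly increasing transformation of the sample's values, so profiles
are comparable across platforms with different response curves, across labs,
and across patients, without a background cohort. This is an internal
normalization similar in effect to quantile normalization, but it requires
only the one sample at hand — the property that makes single-sample,
individualized diagnosis possible. The assumption it rests on is that the
*ordering* of marker-gene expression within a sample carries the subtype
signal; a platform whose response were non-monotone (e.g. signal inversion
at saturation) would break it.

Classification uses a support vector machine with an RBF kernel and
one-vs-one voting over the seven subtype classes, the behaviour of the
libsvm backend that both scikit-learn's `SVC` and R's `e1071::svm` share.
Both the soft-margin cost C and the kernel width γ are tuned, which is why
the RBF kernel is the default (a linear kernel has no γ and is offered as an
option). Feature scaling is deliberately disabled: ranks are already bounded
in [1, 57], and γ is always an explicit number from the grid, never a
data-dependent heuristic — a test asserts this, because silent auto-scaling
would re-introduce cohort dependence through the back door.

### Hyperparameter search

C and γ are selected by stratified k-fold cross-validation (default k = 10)
over a coarse power-of-two grid, C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵},
γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} (110 points), fully user-overridable. The same fold
partition, derived from the seed, is reused at every grid point so
accuracies are comparable across the grid. Samples are put in sorted-id
order before splitting, making the whole search a pure function of the
labeled set, the grid and the seed — not of input order. Ties in CV accuracy
resolve to the smallest C, then the smallest γ (the flattest, most regular
decision surface among the winners). A class with fewer samples than folds
triggers a warning and a reduced fold count rather than an error, since the
clinical cohort shape genuinely contains a five-sample class. Note that for
rank-valued features the informative γ region is the small end of the grid:
squared Euclidean distances between 57-dimensional rank profiles are of
order 10³–10⁴, so γ around 2⁻¹⁵…2⁻⁷ is where the kernel discriminates.

## Evaluation

Per-subtype performance is reported one-vs-rest: for subtype s, TP = true s
predicted s, FN = true s predicted otherwise, FP = other subtypes predicted
s, TN = the remainder, so every row sums to the cohort size. Accuracy =
(TP+TN)/(TP+FN+TN+FP), Sensitivity = TP/(TP+FN), Specificity = TN/(TN+FP).
Report percentages are rounded **half-up** to two decimals (98.125 → 98.13),
matching how printed diagnostic tables round, and deliberately not Python's
default banker's rounding; exact fractions are kept alongside. A metric with
an empty denominator is reported as undefined and rendered "—", never
coerced to 0 or 100. A micro-averaged overall accuracy is computed as a
labeled extension.

## Clustering

Unsupervised structure is assessed by hierarchical clustering of the rank
profiles: Euclidean distance on the 57-vectors with average linkage by
default (a common, robust choice for expression heatmaps), with Spearman
dissimilarity (on rank vectors, Pearson correlation *is* Spearman) and
complete/Ward linkage as options. Samples are processed in sorted-id order,
so the tree, the dendrogram leaf order and the exported leaf-ordered rank
matrix (written with the exact rank values, no rescaling) are deterministic
and input-order invariant. Agreement between the k=7 cut and the true
subtypes is scored with the adjusted Rand index (1 = identical partitions up
to relabeling, 0 = chance). Platform tags never enter the distance — mixing
cohorts from different platforms needs no harmonization beyond ranking.

## Fragment-analysis assay rules

The multiplex assay resolves amplicons by capillary electrophoresis:
fragment size identifies the gene, peak area measures expression. The
computational contracts:

- **Design validation.** Marker amplicon lengths must lie in 137–316 bp,
  within-panel lengths must differ pairwise by ≥ 4 bp, every panel carries
  the five reference controls (B2M, PSMC4, GUSB endogenous; KanR and
  pcDNA3.1(+) synthetic), and the marker amplicons must cover the 57-gene
  set. Violations are returned as report content, not exceptions, because a
  design check is a linting step.
- **Peak calling.** Each observed peak is assigned to the nearest expected
  length within ± 1.5 bp (default). The tolerance is below half the minimum
  design spacing, so nearest-neighbour assignment is unambiguous by
  construction; peaks matching nothing are reported as artifacts, two peaks
  claiming one amplicon is an error, and genes with no matched peak get
  area 0 — the "undetected = 0" convention the rank transform expects. The
  gene assayed by two amplicons (PBX1) gets the mean of its amplicon areas
  before ranking, the same averaging rule used for multiple microarray
  probes of one gene.
- **Control QC.** KanR is spiked before reverse transcription and monitors
  both RT and PCR, so a missing KanR peak is an RT/PCR failure; pcDNA3.1(+)
  enters at PCR and its absence with KanR present is flagged as a PCR
  anomaly; endogenous references below a threshold flag low RNA input.
- **Quantification.** Standard curves are fitted as log₁₀(area) =
  a + b·log₁₀(quantity) by least squares from ≥ 2 calibration points
  (b > 0 enforced); areas outside the calibrated range extrapolate with a
  warning. Gene quantities are normalized by the geometric mean of the three
  endogenous reference quantities, making the result invariant to global
  per-sample scaling — consistent with, and subsumed by, the downstream rank
  invariance. Zero areas pass through as zero quantity.

The bundled default panel is **synthetic**: the real amplicon table ships
with the commercial kit and is not public. `default_panel()` constructs a
rule-conforming stand-in (58 marker amplicons for 57 genes, panels of
20/19/19, 6 bp marker spacing from 140 bp, controls at 280–304 bp) whose
minimum spacing (6 bp) leaves the default jitter and tolerance identifiable.
Real panel files are read from CSV.

## The synthetic-data generator

The generator exists to give every pipeline stage a testable input with the
statistical structure the method assumes. Per gene g a baseline
log-expression β_g ~ U(3.0, 7.5) is drawn **from a fixed internal stream**,
not from the cohort seed: baselines are properties of the genes, and two
independently seeded cohorts must share them for train-on-one /
test-on-the-other experiments to be meaningful. A sample of subtype k has
log-expression β_g + Δ·1[g ∈ S_k] + ε, ε ~ N(0, σ²), with disjoint
signature sets S_k of 8 genes per subtype and signature strength Δ = 2σ by
default (σ = 1) — strong, clearly expressed subtypes, matching the regime in
which marker panels are curated in the first place.

The "Others" class has no signature of its own, but each Others sample
carries, with probability 2/12, a 0.75-strength copy of a random other
subtype's signature. This models the documented heterogeneity of
lesion-negative patients (some of whom resemble BCR-ABL1-positive disease —
the rate mirrors the 2-of-12 such samples seen clinically) and is what makes
Others the hardest class to recover, as tests assert.

Platforms are rendered from one latent draw by v → a·v^b (strictly
increasing), defaults: microarray (1.0, 1.0) and AFA (3.0, 0.4) — a
saturating, concave response such as a capillary-electrophoresis detector's
compression. The concave choice matters: it keeps the raw cross-platform
Pearson correlation visibly below 1 (≈ 0.92 per sample) while rank profiles
stay identical, which is precisely the premise the rank transform exploits;
a convex distortion would leave r ≈ 0.96+ through tail dominance and
demonstrate little. Dropout is threshold censoring on the transformed scale
(AFA default 12.0, ≈ 13% of values), value-dependent rather than random
per-cell, because undetected genes are the lowly expressed ones. Default
cohort shape copies the clinical cohort's class sizes (54 ETV6-RUNX1 down
to 5 MLL-rearrangement, n = 160). Simulated peak tables place one peak per
nonzero gene per amplicon at the expected length ± uniform jitter (default
0.5 bp), area equal to expression, controls injected at a fixed area unless
a QC-failure scenario names them.

What the generator does **not** emulate: correlated gene-gene expression
within subtypes, batch effects beyond a global monotone response,
probe-level microarray noise, PCR competition between amplicons in a
multiplex, or partial (sub-threshold but non-zero) detection. Passing tests
therefore show the pipeline's contracts and its behaviour under the stated
noise model, not clinical performance; models trained on the published
cohorts are out of scope because those data are not bundled.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is a pure function of (config, seed), and CV folds derive from
  the training seed. Identical seeds give byte-identical CV reports and
  exported matrices.
- Rank computation delegates to `scipy.stats.rankdata`; tests check it
  against an independent sort-and-scan oracle on a thousand tied vectors.
- Expression matrices must be finite and non-negative; missing values are
  rejected with the offending gene and sample named, never imputed — an
  undetected gene is an explicit 0, not a blank.
- Model files embed a format tag and version; truncated or foreign files
  raise a load error rather than mispredicting.
- Problem sizes in the test suite and acceptance script (cohorts of 40 per
  subtype for classifier performance, 160 for clustering, 200 mutated
  panels, 1000 rank vectors) were chosen as the smallest sizes at which the
  measured quantities are stable to the asserted precision.

## Known limitations

- The default panel is synthetic; results on it say nothing about the real
  assay's primer behaviour (mispriming, competition, efficiency).
- Subtype signatures are disjoint and additive in log-space; real marker
  panels overlap and interact, so real CV accuracy selection surfaces are
  rougher than the simulated ones.
- The one-vs-one SVM outputs hard labels only; no calibrated class
  probabilities or abstention threshold is provided.
- Series-matrix parsing reads the expression table block only; no GEO
  metadata, platform annotation or CEL-level processing.
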