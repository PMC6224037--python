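# Methods

This note documents the models, conventions and numerical choices behind
`mhcbench`, in the spirit of a statistical package's model documentation.
It states no empirical claim that the test suite does not itself compute.

## Affinity scale and classification

All binding strengths are compared on the normalised log scale
`y = 1 − log10(v nM)/log10(50000 nM)`, clamped to [0, 1] outside the
(1, 50000) nM assay window.  Clamping rather than erroring is deliberate:
curation already removes values above the ceiling, but external predictors
may emit extremes and should still be scoreable.  The inverse transform
`v = 50000^(1−y)` round-trips within 1e−9 relative error on the open
window.

The three-class partition uses the conventional thresholds (strong < 50 nM;
binder ≤ 500 nM for class I, ≤ 1000 nM for class II).  Equality at a cutoff
is undefined in common usage; we fix *strong iff v < 50* and *binder iff
v ≤ 500 (class II ≤ 1000)* so the three classes partition (0, ∞) and the
assignment is monotone in affinity.  This is a convention of this package,
not a community standard.

Allele names are canonicalised to a compact star/colon-free, locus-prefixed
form (`HLA-A*02:01 → HLA-A0201`); the accepted dialects are listed in the
error message of `normalize_allele_name`.  Synthetic allele ids (`SYN-…`)
pass through so simulated and real data flow through identical code.

## Curation

The filter chain runs in a fixed order — quantitative assays (KD/IC50/EC50)
only, ≤ 50000 nM, fixed peptide length, training-overlap removal,
optional allele-coverage filter — and logs the survivor count after each
step, so fixtures can pin every filter independently.  Overlap with
training data is keyed on (peptide, allele) by default: the same 9-mer can
be genuinely novel for a different allele.  A peptide-only key is available
by configuration.  Replicate (peptide, allele) measurements collapse to
their geometric mean, the natural average for log-scale data; the merge is
recorded in the provenance field.

## Metric suite

* **AUC** is the Mann–Whitney estimator (tied pairs credited ½), computed
  via scikit-learn; tests pin it to explicit pair counting.
* **VUS** is the empirical probability that a random
  (strong, weak, non-binder) score triple is ordered correctly.  A tied
  adjacent comparison earns multiplicative ½ credit (both tied: ¼); no
  community convention exists for ties here, and property tests use
  continuous scores where ties are absent.  The implementation factorises
  the triple sum over the weak scores (O(N log N) with sorted searches) and
  is pinned exactly to brute-force triple counting.  Chance level for
  continuous i.i.d. scores is 1/6.  Note one tempting "invariant" that is
  *false*: negating all scores does not give 1 − VUS, because the four
  middle orderings of a triple count in neither direction; the correct
  exact symmetry (negation plus swapping the outer class roles) is what the
  tests assert.
* **SPE / FNr** — strong-binder recall at the 50 nM threshold and its
  complement.  The field's naming is loose ("specificity"); we implement
  the operational definition: the fraction of measured < 50 nM binders
  whose predicted affinity is also < 50 nM.
* **SRCC** is Spearman's rank correlation with average-rank ties, computed
  on a shared "higher = stronger" orientation so a perfect predictor scores
  +1.
* **R²** is the coefficient of determination of an OLS fit of predicted on
  measured affinity, both on the normalised log scale by default (raw-nM
  behind a flag), matching how affinity regressions are conventionally
  plotted.
* **Confidence intervals** are percentile bootstrap (default 1000
  resamples, 95%), resampling peptides with replacement and stratified by
  class for the classification metrics so every resample keeps all classes.
  The estimator choice is ours; analytic (DeLong-type) variances are out of
  scope.
* **Allele-specific cutoffs**: the smallest measured value t such that
  ≥ 75% of an allele's binder affinities are ≤ t (lower-value convention of
  the empirical 75th percentile).
* Metrics that are mathematically undefined on an input (single class,
  constant vector, empty stratum) raise a typed error; the report
  aggregator converts that into a flagged empty cell rather than a number.
  Per-allele report rows with fewer than 10 records carry a low-n flag.
  Score-only tools (no predicted nM) get AUC/VUS/SRCC but flagged-absent
  SPE and R², since cross-scale comparison of absolute affinities is not
  meaningful.

## Pan-allele ANN

One-hot encoding of the 9-mer peptide concatenated with the allele's
34-residue binding-pocket pseudo-sequence gives 43 positions × 20 residues
= 860 inputs.  An unknown residue 'X' encodes as an all-zero block by
default (optional uniform 0.05 smoothing).  The network is a single hidden
layer of 64 tanh units (32 is the customary alternative) with dropout 0.1
during training only, a sigmoid output matching the [0, 1] target scale,
MSE loss and Adam (lr 1e−3, batch 128).  The reference layer diagram for
the predictor this re-implements is not published in text form; one hidden
tanh layer is the design of the forked predictor family and is our default,
configurable, not an inference about the original.

Defaults are pinned for reproducibility: 250 epochs, no early stopping,
one RNG (numpy `default_rng(seed)`) driving weight init, shuffling and
dropout masks; training is single-threaded numpy and bit-reproducible for
a fixed seed.  The test and acceptance suites train for 30–60 epochs
instead: on the synthetic fixtures the loss plateaus well before 250 and
the shorter runs keep the suite inside its time budget — this is a
scaled-down simulation, not a different model.

Censored training values (e.g. "> 50000") are excluded upstream; how the
original tools weighted such data is unstated, and we do not guess.

`leave_one_allele_out` removes every record of the target allele, trains
on the rest, asserts the exclusion, and evaluates on the held-out allele.
The expected qualitative pattern — accuracy maintained for alleles with a
near-identical binding pocket among the training alleles, degraded for
isolated alleles — is what the acceptance test pins.

## Elution benchmark

Decoy negatives are random proteome k-mers, rejected if they reach ≥ 8 of
9 identities to any excluded peptide under ungapped local alignment (all
overlap offsets; equal-length sequences make gaps unhelpful, and the
threshold is configurable).  "Cannot be aligned locally" is vague in
common usage; this is our declared operationalisation, cross-checked in
tests against a Smith–Waterman aligner with identity scoring.  Sampling is
position-uniform over the proteome, deduplicated, seeded, and fails loudly
with the achieved count if the proteome cannot supply enough decoys.

Percentile rank of a score is the percent of a background score
distribution that is strictly stronger (best score → rank 0); the default
background is the predictor's scores on 10 000 seeded random proteome
k-mers per allele.  A peptide is called presented when its rank is ≤ 2.0%
(a rank exactly at the cutoff counts positive).  FDr = FP/(FP+TP) among
predicted positives, FNr = FN/(FN+TP) among the truly eluted, grouped per
allele and dataset, with eluted-vs-decoy ROC/AUC alongside.

One structural point the synthetic design must respect: if decoys are
statistically exchangeable with the rank background, then at a 1:R
positive:negative ratio the expected FDr is ≈ R·0.02/(R·0.02 + TPr)
*regardless of predictor quality* — ≈ 0.5 at 1:50.  Real ligandome
benchmarks face the same confounder (random "negatives" that are in fact
presentable).  The generator therefore treats the full set of proteome
k-mers binding below 500 nM as the presentable repertoire: the eluted
positives are its strongest members (MS detection favours strong,
abundant ligands), and decoy exclusion screens against the whole
repertoire, so decoys are genuine negatives and FDr measures model error.
The verified-binder-negative design (negatives are confirmed binders, not
random decoys) is supported by ingesting pre-labelled records directly.

## Structure post-processing

Docking is out of scope; the module consumes per-decoy reweighted energy
scores and pairwise RMSDs.  Per-allele scores min–max normalise onto
[0, 1] with the lowest energy mapped to 1, so normalised scores correlate
positively with predicted binding; all-identical scores are undefined, not
0.5.  Clustering is greedy score-ordered leader clustering at a 2.5 Å
RMSD threshold: the published workflows name only the cutoff, and leader
clustering is the deterministic standard of docking suites.  Model
selection takes the lowest-scoring member of the largest cluster;
tie-breaks (equal sizes → lower best score; equal scores → lexicographic
id) make the whole pipeline invariant to input order.

## Synthetic world

Each allele family has a prototype 34-mer pseudo-sequence and a 9 × 20
PSSM whose anchor positions 2 and 9 carry weights with sd 1.0 versus 0.2
elsewhere — the anchor-dominated class-I motif shape.  Member alleles copy
the prototype with 3 pseudo-sequence substitutions and PSSM jitter
(sd 0.1); the first two members of a family share the prototype
pseudo-sequence exactly (an identical-pocket pair), and a singleton family
yields an isolated allele.  True affinity is
`log10(IC50) = offset − Σ_j pssm[j, residue_j] (+ coupling) + N(0, noise_sd)`
with offset 4.5 (so roughly a few percent of random peptides are binders,
the order of magnitude behind the conventional top-2% presentation
cutoff), noise sd 0.05 log10 units ("low noise"), values clamped to the
1–50000 nM assay window.  An optional nearest-neighbour residue-coupling
term (sd 0.3) adds non-additive structure that a purely linear scorer
cannot fit.  Measurement panels are sampled with a per-peptide enrichment
temperature in [0, 2.5] mixing motif-free background with motif-biased
binders; an explicit class-composition target is met exactly by quota
rejection.

What the generator does **not** emulate: realistic amino-acid background
frequencies, MS detectability bias, inter-laboratory assay offsets,
length polymorphism, or the phylogenetic structure of real HLA loci.  A
green recovery test therefore establishes that the implementations are
mutually consistent and that the pan-allele mechanism works when its
assumptions hold — not that any accuracy number transfers to real data.

## Reproducibility and limitations

Every stochastic component takes an explicit seed; CLI runs write a JSON
manifest with input hashes and parameters.  The packaged pseudo-sequence
table is a clearly-labelled synthetic stand-in (the reference
binding-pocket table is third-party data); real analyses must supply
their own.  The published headline benchmark figures for the 18 external
tools are not reproducible here by design — those tools and the
IEDB-scale blind sets are consumed as input tables, never re-implemented —
so the toolkit's correctness rests on the oracle, property and recovery
suites above.
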