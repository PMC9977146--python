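# Methods

## Scope and overall design

`shmclass` re-implements, as a tested pipeline, a repertoire-level analysis
for stratifying two clinical groups (internally `case` vs `control`, with
`case` the positive class) from bulk B-cell receptor heavy-chain sequencing.
The pipeline consumes AIRR Rearrangement TSVs with germline-aligned,
IMGT-gapped sequences; V(D)J alignment itself (IgBlast / Change-O style
preprocessing) is out of scope and assumed done upstream.  The stages are:

1. I/O and validation of repertoires, cohort manifests and germline
   references (`airr_io`);
2. clonal inference and clone-level abundances (`clones`);
3. per-repertoire 5-mer SHM targeting models, hotspot-motif dissection and
   3-mer collapse (`shm`);
4. non-SHM repertoire features: gene usage, CDR3 k-mers, cluster
   frequencies, Hill diversity, summary percentiles (`features`);
5. nested feature screening + elastic-net logistic regression evaluated by
   leave-one-out cross-validation, with shuffled-label nulls and
   cross-cohort transfer (`classify`, `pipeline`);
6. a synthetic cohort generator providing ground truth for every stage
   (`simulate`).

Because real cohorts of this kind are access-controlled, all quantitative
checks in the test suite and the acceptance script run on synthetic cohorts
whose generative conditions are stated below.

## The 5-mer targeting model

For each repertoire we estimate the empirical context-dependent mutation
profile in the S5F decomposition:

* **mutability** μ(w): for each of the 1024 ACGT 5-mers w,
  μ(w) ∝ m(w)/b(w), where m(w) is the number of observed mutations whose
  *germline* 5-mer context is w and b(w) is the number of informative
  germline positions centred in w; μ is normalised to sum to 1 over present
  5-mers (a probability that a mutation falls in context w);
* **substitution** σ(w, x): the empirical distribution of replacement bases
  x given a mutation in w (rows sum to 1 over the three non-centre bases);
* **targeting** τ(w, x) = μ(w)·σ(w, x).

Conventions and edge rules:

* positions are 1-based on the IMGT-gapped alignment; the gap character is
  `.` (`-` normalised on read);
* contexts are read from the gap-stripped germline; windows that run off
  either end of the sequence, or contain a non-ACGT character, are
  *uninformative* — no padding, no 3-mer fallback.  Absent means absent,
  and missing features are mean-imputed from training folds only;
* every mutation is counted against the unmutated germline context, also
  when several mutations fall in one sequence (the model therefore captures
  the combined effect of SHM targeting and selection, as any
  observed-vs-germline comparison does);
* a 5-mer needs `min_background = 10` informative occurrences (default,
  configurable) before its mutability is reported; below that the entry is
  absent rather than a high-variance estimate;
* `synonymous_only` restricts the mutation counts to synonymous mutations
  (codon frame = consecutive gapped-column triplets, IMGT gaps arriving in
  whole codons) while keeping the all-position background — a deliberate,
  simple estimator; the alternative (restricting the background to
  positions where a synonymous mutation is possible) would rescale, not
  reorder, the per-context values;
* region masks use the IMGT unique-numbering intervals on the gapped V
  coordinates (FR1 1–78, CDR1 79–114, FR2 115–165, CDR2 166–195,
  FR3 196–312); positions past 312 are `unknown`.

Hotspot classes partition the 1024 5-mers by their centre base: WA
(centre A preceded by W = A/T) and TW (centre T followed by W) form the
Polη class `WA/TW` (128 + 128 5-mers); WRC (centre C preceded by W, R) and
GYW (centre G followed by Y, W) form the AID class `WRC/GYW` (64 + 64); the
remaining 640 are neutral.

The 3-mer collapse averages the 16 constituent 5-mers of each central
3-mer, weighted by their background counts, and renormalises; it commutes
with global rescaling of the 5-mer model.

## Clonal inference

Clones are inferred per subject by grouping on (V gene, J gene, junction
length) — allele suffixes dropped, first call of multi-assignments used —
followed by single-linkage clustering of junction nucleotide sequences at
normalised Hamming distance ≤ 0.15 (default, configurable; N positions are
not mismatches).  Single linkage at a fixed cut equals transitive closure
over the ≤-threshold pair graph, which is how the brute-force test oracle
computes it.  Clone representatives (for representative-based SHM models)
are the member with the highest duplicate count, ties broken by sequence
id.  Clone abundances default to unique-sequence weighting — bulk gDNA
libraries sample cells roughly uniformly — with duplicate-count weighting
available.

## Classification protocol

For each feature table (subjects × named features):

1. **Leave-one-out**: each subject is predicted by a model trained on all
   others.  In the default `per_fold` scope, *everything* — t-test
   screening, imputation means, standardisation, penalty tuning — is
   computed on the training rows of that fold only; a `global` scope
   (screening once on all subjects) is provided to mirror protocols that
   fix a single feature list, at the cost of selection leakage.
2. **Screening**: two-sample pooled-variance Student's t-tests rank
   features; the `top_k` lowest p-values are kept (30 by default; 0 means
   no screening).  The t-tests are a ranking device, so no multiplicity
   correction is applied.
3. **Model**: logistic regression minimising mean negative log-likelihood
   plus λ·[α‖β‖₁ + (1−α)/2‖β‖₂²] on standardised features.  (α, λ) are
   chosen by 3-fold stratified inner CV minimising validation deviance over
   α ∈ {0, 0.5, 1} and a 12-point log-spaced λ path descending four decades
   from the data-driven λ_max; ties prefer stronger regularisation, then
   larger α.  The grid is deliberately compact — leave-one-out wrapped in
   label permutations multiplies fit counts by thousands, and on ~40-subject
   cohorts a finer grid changes the selected models only marginally — and is
   fully configurable (`ElasticNetTuning`).  Fitting uses scikit-learn's
   saga solver with a loose tolerance along the tuning path and a tight one
   for the final refit; when a penalty zeroes every coefficient the
   intercept is set to its closed-form optimum, the log-odds of the training
   prevalence.
4. **Metrics**: F1 (case positive), accuracy, sensitivity, specificity from
   the pooled LOO predictions, each with a 95% Clopper–Pearson interval
   treating the metric as a proportion of n subjects (an acknowledged
   approximation for F1).  Zero-denominator metrics are reported as
   undefined, never as 0.  Probability exactly 0.5 predicts control.
5. **Null calibration**: labels are permuted (class sizes preserved) and
   the entire pipeline rerun per permutation; with label-independent
   features the median null F1 is expected near 0.5.
6. **Transfer**: cross-cohort application fits on the full training cohort
   over the feature-name intersection and scores every test subject;
   test-missing features fall back to training means.

All randomness flows from one master seed through named SHA-256-derived
sub-seeds (`pipeline.derive_seed`), so every reported number is a
deterministic function of (config, seed).

## The synthetic cohort generator

The generator emulates what the estimators assume real data look like:

* **Germline**: a frozen-seed toy reference (10 V, 6 D, 4 J), synthetic by
  construction, with IGHV-like structure: V spans the 312 IMGT positions
  with whole-codon gap blocks inside CDR1/CDR2, ends in the conserved
  cysteine codon, and is stop-free in frame; J segments carry the conserved
  tryptophan codon.
* **VDJ recombination**: founders sample V + trimmed D + trimmed J with
  Poisson(4)-length N-insertions, junction padded to a whole codon count
  and resampled until stop-free (≤ 50 attempts).
* **Clonal expansion**: clone sizes follow a discrete power law with
  exponent 2.5 (default), truncated to fill the per-subject sequence count;
  members inherit the founder sequence and junction verbatim, so clone
  ground truth is exact.
* **SHM**: each sequence receives Poisson(15) mutations (a mucosal-memory
  order of magnitude), placed without replacement with probability
  proportional to the mutability of the *founder* germline context and
  substituted per the model's substitution row.  Contexts are not updated
  after each placement by default — matching the estimator's
  germline-context counting and making recovery exact in expectation — with
  a sequential context-updating mode available for robustness experiments.
* **Baseline model**: frozen-seed synthetic targeting model with
  class-level base rates (WA/TW ×4, WRC/GYW ×6 relative to neutral),
  per-5-mer lognormal jitter (σ = 0.5), and transition-biased Dirichlet
  substitution rows — hotspot-dominated, as in observed repertoires.
* **Group effect**: two modes.  `uniform` multiplies the mutability of one
  whole motif class by a factor and renormalises.  Because per-repertoire
  mutability is normalised to sum to 1, a uniform class-wide factor
  necessarily shifts *every other* 5-mer by the complementary factor, so
  both hotspot classes end up carrying group signal.  The `polarized` mode
  instead shifts specificity within the Polη class — WA contexts ×factor,
  TW contexts rescaled so the total WA/TW mass is unchanged — leaving
  non-WA/TW 5-mers and the overall mutation load untouched.  This is the
  mode used for hotspot-dissection experiments: it reproduces the motif
  phenomenology of interest (AAN/TAN mutability up, NTT/NTA down, overall
  SHM frequency unaltered) and makes "restrict to WRC/GYW" a genuine
  negative control.

What the generator does **not** model: allelic diversity and genotype
variation, isotypes and class switching, selection dynamics beyond the
targeting model, intra-clone junction variation before SHM, sequencing or
FFPE artefact noise, and UMI structure.  Passing tests therefore show that
the pipeline recovers the signals it targets under its own model
assumptions — not that those assumptions exhaust real repertoires.

## Problem sizes used by the test suite

The full-scale checks run two-group cohorts of 20 + 20 subjects with 2,000
sequences per subject — the size regime the analysis is designed for — with
25 label permutations for null calibration (20 per feature set in the
hotspot-dissection experiment) and recovery curves at 500/2,000/5,000
sequences.  The bundled `analysis/` scripts use smaller cohorts (8 + 8 ×
500) chosen to make every step quick to rerun interactively; all sizes are
plain config fields.

## Numerical and degenerate-input conventions

* Hill diversity D_q = (Σ pᵢ^q)^(1/(1−q)); q = 1 uses the Shannon limit
  exp(−Σ pᵢ ln pᵢ); q < 0 is rejected; zero-abundance clones are dropped.
* Percentiles use linear interpolation between order statistics.
* Frequency features renormalise over observed categories; cluster-feature
  columns are the union over subjects of triples/clusters reaching the
  frequency floor (10⁻³, inclusive) in at least one subject.
* Greedy centroid clustering for 85%-identity CDR3 clusters processes
  sequences in canonical order (descending pooled count, then lexical), so
  cluster assignment is deterministic; identity is matches/length, boundary
  inclusive.
* A repertoire with zero informative mutations yields a degenerate model
  (all-absent mutability); collapsing it raises rather than fabricating
  values.  Constant features are excluded before t-ranking; all-missing
  columns are dropped with a warning at fit time.
* Repertoires whose classes have fewer than two training subjects cannot be
  t-ranked; screening then returns all non-constant features with a
  warning, and penalty tuning falls back to a fixed mid-grid choice when
  stratified inner folds are infeasible.

## Known limitations

* The Clopper–Pearson interval on F1 treats a ratio of dependent counts as
  a binomial proportion; it is the conventional display, not an exact
  interval.
* The synonymous-only model shares the all-mutation background (see above).
* Single-linkage clone clustering is quadratic per (V, J, length) group;
  fine at bulk-repertoire group sizes, not tuned for million-sequence
  groups.
* LOO with heavy feature screening is known to be slightly pessimistic
  under the null (the held-out subject's class is underrepresented in
  training); the shuffled-label null makes this visible rather than hiding
  it, which is exactly its role.
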