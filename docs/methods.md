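# Methods

This note documents the scientific conventions, model assumptions and
design choices behind `verbgen`, in the spirit of a statistical methods
appendix.

## Task and coding model

One trial is one auditory presentation of a noun to one subject, who must
respond with an associated verb; each of the 50 nouns is presented twice.
Responses are coded into four mutually exclusive categories — *related
verb* (correct), *not-a-verb*, *unrelated verb*, *missing* — which
partition every subject's trials, so the four per-subject percentages sum
to 100 by construction.

In clinical practice this coding is done by human raters. The package
never overwrites a pre-assigned code; the rule-based auto-coder exists
for synthetic and exploratory data. Its rules, in order: an empty
response is *missing*; an explicitly rejected (noun, phrase) pair is
*unrelated verb* and an explicitly accepted one *related verb* (these
exception lists carry the adjudications human raters would make, e.g.
"be careful" rejected for knife/scissor, "do" accepted for laundry);
a response whose head-verb lemma is in the noun's reference lexicon is
*related* (phrasal responses match on the head: "take out" → take; a
leading "to" is stripped); a head lemma in the global verb vocabulary
(the lexicon's verbs ∪ the light-verb list ∪ a caller-supplied verb
list) is *unrelated verb*; anything else is *not-a-verb*. The default
reference lexicon for a noun is the set of verbs produced by at least one
control for that noun. Articulatory errors and phonological paraphasias
cannot be detected by text rules; they are expected to arrive as
pre-assigned codes or exception entries (the convention being
articulatory error → missing, interpretable paraphasia → correct).
Lemmatization is a bundled inflection table covering the light verbs and
a few frequent response verbs — deliberately a lookup, not a tagger,
since anything beyond surface-form normalization exceeds what a
transparent rule-based coder should do.

### Outlier screen

Subjects whose percentage correct falls **strictly** outside
mean ± 2·SD of their reference cohort are excluded. The default
reference cohorts are (a) all patients pooled and (b) controls; a
per-group mode exists. The screen is single-pass: means and SDs are
computed once on the full cohort and the rule applied once, never
iterated. SD is the sample SD (ddof = 1). A zero-variance cohort treats
any deviation from the constant mean as outside. "Outside" is read
strictly, so a subject exactly at the boundary is kept.

### Consistency measures

With each noun presented twice, *error consistency* is the percentage of
noun pairs with both presentations incorrect, over all pairs (nouns with
both presentations available); *error-type consistency* is, among those
consistently-erred pairs only, the percentage with the same error type
both times. A subject with no consistently-erred pairs has an undefined
type consistency, reported as absent and dropped from group means rather
than scored zero. Mean RT defaults to correct trials only (an all-trials
option exists); this choice is left configurable because the convention
varies across labs.

## Agreement indices

For each noun, control responses pooled over both presentations define a
distribution over verb lemmas. All verb responses (related and
unrelated) enter by default — the index describes *verbs generated*, not
verbs approved — with a flag to restrict to related verbs, and a
first-presentation-only mode for a per-subject-response reading.
Missing and not-a-verb trials never enter. Proportions are therefore
over responses, not subjects: a control answering twice contributes
twice.

* **Entropy** (bits): `E = Σᵢ pᵢ log₂(1/pᵢ)` over the k distinct verbs.
  0 ⇔ unanimity; 1 ⇔ two verbs at equal frequency; maximal (log₂ k) iff
  uniform.
* **ASI**: `100 · max count / n` — the modal response share.
* **CSI**: ratio of the top two response percentages. With a single
  distinct verb the runner-up is undefined; the package imputes one
  hypothetical dissenting response (p₂ = 100/n), which keeps CSI finite
  (it equals n) and consistent with finite published ranges. Ties for the
  modal verb are broken lexicographically for *reporting* only; all three
  indices are order-independent.

## Lexico-semantic features

*Unique-verb dispersion* counts distinct related-verb lemmas per noun and
cohort (a per-subject reduction is provided; per-noun is the default
reading of a "for each noun and each cohort" analysis). The *light-verb
percentage* is computed over a subject's related responses only and is
undefined (absent, not zero) for subjects with none. The *not-a-verb
decomposition* splits a subject's not-a-verb responses into (1) plain
repetitions of the stimulus noun (lemma equality) and (2) semantically
related nouns: cosine similarity of the response and stimulus embeddings
**strictly greater than** the threshold (default 0.3). Repetitions are
excluded from (2) — their similarity is trivially 1 and they are a
separate phenomenon. Responses or stimuli missing from the embedding
table are never silently dropped: they are logged and tallied in
`n_uncovered`, and the four counts always sum to the number of
not-a-verb trials. The threshold can be recalibrated as the median of
the pooled similarity values across all cohorts.

## Group statistics

* One-way ANOVA is the classical between-groups F (scipy); an all-equal
  input yields an explicit "undefined F" report instead of an exception.
* The error-pattern comparison is a mixed-design ANOVA — group between
  subjects, error type (not-a-verb / unrelated / missing) within, plus
  their interaction — because each subject contributes all three
  percentages (pingouin's mixed ANOVA; sphericity handling is pingouin's
  default). A single-group input reduces to a one-way repeated-measures
  design. Accuracy is excluded from the error factor since it is the
  linear complement of the three error percentages.
* Tukey HSD (statsmodels) provides pairwise contrasts from the pooled
  within-groups MS; for two groups it coincides with the pooled t-test
  (q = t·√2).
* Correlation families are Pearson with Bonferroni control:
  `p_adj = min(1, m·p)`, survival defined as `p ≤ α/m`, α = 0.05,
  m = 6 by-item (log frequency, phoneme count, semantic neighborhood,
  ASI, CSI, entropy) and m = 3 by-subject (single-word comprehension,
  phonemic/semantic fluency ratio, trails total time). Missing
  neuropsych scores are handled pairwise-complete with the per-row n
  reported; subjects with zero semantic fluency are excluded from the
  ratio. Item accuracies pool both presentations.

## Classification

Patients (never controls) are classified into the three variants from
their three error-type percentages by a decision tree with depth ≤ 2 —
at most two axis-aligned questions per patient, which is what makes the
classifier clinically readable. The tree is fitted by greedy recursive
binary splitting minimizing weighted Gini impurity; candidate thresholds
are midpoints between consecutive distinct sorted feature values;
recursion stops at the depth limit, a pure node, or fewer than two
samples. Determinism rules are part of the contract: among
equal-impurity splits the lowest threshold of the earliest feature wins,
and leaf-probability ties predict the lexicographically first class.

Performance is stratified 5-fold cross-validated accuracy (folds seeded;
the fold count drops with a warning if the smallest class is smaller
than k). Chance is estimated empirically: each of n_perm = 1000 label
permutations recomputes the full CV score, and
`p = (1 + #{null ≥ observed}) / (1 + n_perm)`, whose minimum is
1/(n_perm+1). The theoretical chance for three balanced classes is 1/3.
Gini, 5 folds and 1000 permutations are package defaults, all
configurable and recorded in the result object.

## Synthetic data generator

The generator emulates the *statistical structure* the analysis assumes,
at the study's own scale: 50 nouns × 2 presentations, 29 controls, and
patient cohorts of 19 (lvPPA), 28 (svPPA) and 24 (nfvPPA) — the
post-exclusion sizes. It makes no attempt at linguistic realism: the
vocabulary is synthetic tokens (`noun07`, `verb113`, and `noun07kin` for
the planted semantic associate of `noun07`) plus the real light-verb
list.

* **Stimuli.** Norms are drawn uniformly within the published stimulus
  ranges (e.g. log COCA frequency 3.4–8.3, age of acquisition
  1.49–4.17). Each noun gets a pool of k = 12 candidate verbs and a
  truncated-geometric popularity vector whose decay is found by
  bisection so the planted entropy hits a target drawn uniformly over
  the configured agreement range (default 0.1–2.7 bits, matching
  published control norms). Decay → 0 gives a single dominant verb
  (entropy → 0); decay → 1 gives near-uniform choice (entropy → log₂ k).
* **Controls** sample a verb per presentation from the popularity vector,
  with a small missing rate (default 2%) and lognormal RTs.
* **Patients.** Each subject draws an error mix around the cohort's
  published means/SDs: the three error components come from
  zero-truncated normals whose *locations are calibrated by bisection so
  the post-truncation means equal the planted means* — naive
  truncate-and-renormalize visibly biases components whose mean is
  within ~2 SDs of zero (e.g. an unrelated-verb rate of 2.1 ± 2.5)
  and would drag the cohort's realized accuracy several points off its
  target. Accuracy is the complement to 100; the published accuracy SDs
  are compositionally consistent with the error-component SDs (e.g.
  23.1 vs √(21.2² + 3² + 12²) = 24.5 for lvPPA), so second moments stay
  coherent. Item-level correctness is modulated through a logistic link
  by `frequency_effect · (freq_log − mean)`; the svPPA default slope of
  0.1 was sized (by simulation sweep at study scale) to plant a by-item
  frequency correlation of r ≈ 0.5. Related responses follow the noun's
  popularity vector at a cohort "dispersion" temperature (svPPA default
  3, flattening choice and raising unique-verb counts), with light-verb
  substitution at the cohort rate (defaults 8.7% svPPA vs ≈2%
  elsewhere). Not-a-verb responses are repetitions (25%), the noun's
  planted kin token (lvPPA 50%, svPPA 25%, nfvPPA 20%), or a random
  other noun. RTs are lognormal at the published per-variant moments.
* **Embeddings** are random unit vectors; planted pairs are constructed
  as `b = s·a + √(1−s²)·u` with u a unit vector orthogonal to a, so the
  realized cosine equals the target exactly. Kin tokens are planted at
  similarities drawn from 0.4–0.9, above the 0.3 threshold.
* **Neuropsych covariates** are toy scores: comprehension tracks task
  accuracy, trails time anti-correlates with it, fluencies are noisy —
  just enough structure for the by-subject correlation machinery to have
  signal.

Every generator is a pure function of (config, seed) via independent
numpy substreams; identical inputs give bit-identical outputs.

**What passing tests do and do not show.** The generator reproduces
group *moments*, planted effect sizes, and the response-distribution
structure; it does not simulate phonology, individual lexical knowledge,
longitudinal severity, rater disagreement, or realistic embedding
geometry. Pipeline results on synthetic cohorts therefore validate the
*machinery* (indices, statistics, classification, calibration), not
clinical effect sizes; published cohort-level numbers depending on the
original patient data are treated as generator parameters, never as
test expectations.

## Numerical and calibration choices

* Entropy uses scipy's entropy with base 2; exhaustive-enumeration tests
  pin it (and ASI/CSI) to the defining formulas to 1e-12 over all
  distributions with ≤ 5 verbs and counts ≤ 6.
* The tree's split search is validated against exhaustive split
  enumeration on small datasets, and its training accuracy against
  scikit-learn's reference implementation.
* The permutation-null calibration check runs 200 seeded permutation
  tests on label-independent features and requires the p-values to pass
  a KS uniformity test. It uses 40 subjects per class: the empirical
  permutation p is discrete and, under ties between null and observed
  scores, conservative by construction; at 40/class the CV-accuracy
  lattice (1/120 steps) is fine enough that this discreteness is
  negligible, so the check assesses the implementation rather than the
  lattice.
* The classification recovery check simulates 20 replicates of three
  cohorts at 20 subjects/group from the default error-mix moments with a
  1000-permutation null each; these sizes keep the default test run in
  the low minutes on one CPU while leaving the checks well-powered.

## Known limitations

* The auto-coder's verb/non-verb judgment is vocabulary-driven: a true
  verb absent from every lexicon entry, the light-verb list and the
  caller-supplied list will be coded not-a-verb.
* CSI's single-verb imputation is a convention; other choices (infinity,
  missing) are defensible and would change CSI-based correlations for
  unanimous nouns.
* The mixed ANOVA treats error-type percentages as the within-subject
  response; these are compositional (they and accuracy sum to 100), so
  effects must be interpreted accordingly.
* The kurtosis-based alternative agreement measure is not implemented.
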