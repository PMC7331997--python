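# Methods

`raredetect` implements a case-detection procedure for extremely rare
diseases in longitudinal patient records. The target use case is a
porphyria-like condition: prevalence on the order of 1 per 100,000, a
nonspecific neurovisceral symptom complex (recurrent unexplained
abdominal pain, nausea, vomiting, constipation, muscle weakness), a
handful of confirmed cases in an institutional corpus, and a large
presumed-negative population in which undiagnosed cases hide.

## The procedure

1. **Corpus assembly.** Patient records are collections of typed
   documents (16 document types: notes, encounter diagnoses, labs,
   medications, problem list, vitals, …). A base corpus can be enriched
   with patients matching case-insensitive trailing-star wildcard
   criteria over diagnosis names, medication names, procedure names and
   note text; merging unions documents per patient and collapses
   content-identical duplicates so each patient is a single sample.

2. **Labeling.** Candidates for the positive class are listed by a
   structured diagnosis code; external adjudication (chart review)
   confirms a subset. Everyone else — including unconfirmed candidates —
   is presumed negative. The undiagnosed cases the method exists to find
   are, by construction, inside the negative class.

3. **Featurization.** Structured fields contribute one feature per whole
   (lowercased) field value; free-text fields are parsed into lowercased
   unigrams and adjacent bigrams that never cross field instances. Every
   feature is provenance-labeled by (document type, field, token), and
   its value is the occurrence count pooled over the entire record. No
   stemming, stop-word removal or concept normalization is applied.

4. **Univariate screening.** Each feature is reduced to
   presence/absence and crossed with the label in a 2×2 table. The
   association statistic is the odds ratio (a·d)/(b·c) — for a single
   binary predictor this is exactly the univariate logistic-regression
   association — with the Haldane–Anscombe 0.5-per-cell correction
   whenever any cell is zero. The p-value is Fisher's two-sided exact
   test on the uncorrected table; with a few dozen positives, Wald
   p-values from an actual logistic fit fail on separated features,
   which here are precisely the interesting ones. The filter keeps
   features with p < 0.01 occurring in ≥ 4 positive patients, then takes
   the top 100 per document type by descending odds ratio (ties: smaller
   p, then lexicographic key). No multiple-testing correction is
   applied; the screen is a recall-oriented funnel feeding a human
   review, not an inference procedure.

5. **Knowledge veto.** Features *caused by* the diagnosis (the disease
   code, disease-specific labs, treatment drugs, the disease name
   itself) would otherwise dominate the model and re-find only the
   already-found. The veto is data, not code: case-insensitive regex
   rules with optional document-type scope and a written reason, applied
   before modeling. After training, a second pass ranks every modeled
   feature by permutation importance (mean decrease in ranking AUC over
   R = 5 seeded shuffles of the feature's column) so an expert can spot
   residual leakage — e.g. a treatment drug given *in response to* the
   diagnosis — and extend the rule set. "Influence > 0" is the review
   trigger; a literal non-zero-weight criterion has no meaning for a
   nonlinear kernel.

6. **Detector.** A support vector machine (default RBF kernel,
   γ = 0.04, C = 1) on count features encoded into [0, 1]. Three
   encodings are available: binary (presence), linear (count / per-
   feature corpus maximum) and log (ln(1+c) / ln(1+max), the default).
   The per-feature maximum is the corpus-wide maximum for that feature;
   whether normalization should be per-feature or global was an open
   choice, and per-feature is this package's documented one. The signed
   decision value (margin distance) is the ranking score; by the
   standard margin convention samples inside the boundary region lie in
   [−1, +1] and no clipping is applied outside it.

7. **Evaluation.** Repeated stratified 2-fold cross-validation (5
   repetitions = 10 fold-evaluations; repetition r is seeded seed + r).
   Folds are stratified because an unstratified 2-fold split of a
   ~30-member class is degenerate. Metrics: AUC, average precision,
   precision@k (k = min(100, fold size); ties broken by patient id) and
   log loss. Margins are not probabilities, so log loss uses a logistic
   (Platt) map — fitted on the training half's margins within each fold,
   and on out-of-fold margins for the final full-data detector.

8. **Apply-back and review cohorts.** The final detector is trained on
   the full labeled corpus and applied back to it. From the ranking,
   excluding known positives, two disjoint top-100 cohorts are drawn:
   cohort A (no disease term in notes, no related code, no
   disease-specific lab — the detection targets) and cohort B (term in
   notes only — a face-validity probe that also catches externally
   worked-up patients). A score-overlap statistic counts negatives
   scoring at or above the minimum positive score. The chart-review
   rubrics are deterministic functions over boolean annotations (the
   human judgments stay inputs): for cohort A, *likely indicated*
   requires all three classic-triad symptom groups (abdominal pain, CNS
   abnormalities, peripheral neuropathy) with no alternative cause and a
   substantial history; *possibly indicated* requires at least one; for
   cohort B the precedence is deceased > diagnosis mentioned > suspicion
   ruled out > suspicion documented > triad-without-cause > unlikely.
   That precedence ordering is this package's choice; the source rubric
   lists categories without one. Expected chance yield is
   n_reviewed × prevalence (200 reviews at 1e-5 → 0.002 cases).

## Synthetic corpus generator

No public corpus of this shape exists, so the generator is first-class,
tested code. Per patient it emulates:

- **Document volume skew**: Poisson document counts per type with means
  from a fixed skew table (notes/diagnoses/labs ≈ 2.5, surgeries 0.1).
- **Background text**: bags of tokens drawn Zipf-like (exponent 1.1)
  over a `vocab_size`-token vocabulary (default 250); structured values
  are drawn similarly from per-family vocabularies of diagnosis, lab,
  medication and procedure names.
- **Planted signal**: each symptom token's per-record count is
  Poisson(base_rate) in negatives and Poisson(base_rate × rate_ratio)
  in positives (defaults 0.4 and 8); symptom tokens are inserted into
  note text so bigram symptoms stay adjacent.
- **Leakage**: diagnosed positives always carry the disease code and,
  with probability `sensitivity` (0.9) each, a problem-list code, the
  disease-specific lab, the treatment medication, and the disease term
  embedded in otherwise ordinary note text. Undiagnosed positives carry
  the symptom signal and *no* leakage. Among negatives, `miscode_rate`
  (6e-4) carry a spurious code (rule-out encounters, charting errors)
  and `boilerplate_rate` (0.01) carry the term in notes only
  (transplant-evaluation documentation, medication precautions) — the
  latter are cohort B's pool by construction.
- **Determinism**: class counts are deterministic rounded expectations,
  not Binomial draws, so extreme-rare classes are testable at small n;
  a fixed seed yields a byte-identical corpus.

Default prevalence is 1e-5 (the motivating disease's diagnosed
prevalence); simulations at desk scale raise it (tests use 0.005–0.02)
for statistical power. What the generator does **not** model: clinical
language beyond token bags, temporal structure, inter-document
correlation beyond per-patient rates, and correlated comorbidity
structure. Passing tests therefore demonstrate the machinery's
correctness and the procedure's behavior under its own assumptions, not
performance on real clinical text.

## Numerical and design notes

- Screening p-values are memoized per unique 2×2 table; at rare-disease
  scale most features share a handful of distinct tables.
- Vocabulary order is sorted by (doc type, field, token), making the
  matrix — and hence screening and the model — invariant to patient and
  document iteration order.
- Odds-ratio ranking ties break by (smaller p, lexicographic key);
  precision@k ties break by patient id; both for determinism.
- A single global pipeline seed fans out to stage seeds by fixed
  offsets.
- Degenerate inputs fail loudly: screening with an empty label class,
  training on one class, score-overlap with zero positives and an
  all-zero 2×2 table are errors, not silent defaults.
- **Selection-leak optimism.** Screening on the full corpus and then
  cross-validating the screened features is optimistically biased: even
  with no planted signal, features chosen for chance label association
  on all the data remain associated in every fold (measured here at
  mean CV AUC ≈ 0.6, single runs to ≈ 0.85, with ~10 positives). The
  pipeline reproduces this design faithfully; consumers should read its
  CV numbers as model-selection scores, not unbiased performance
  estimates. The permutation-null checks therefore evaluate the
  detector on a label-independent, frequency-selected feature set
  (`top_frequency_features`), where the null mean CV AUC is ≈ 0.5 as it
  should be.
- Problem sizes in the test and acceptance suites (n = 2000–5000
  patients, prevalence 0.005–0.01, 200-token vocabulary, 3–20
  replicates) were chosen as the smallest scales at which the rare
  class and its statistics are non-degenerate.

## Known limitations

- The screen's presence/absence reduction discards count information at
  the selection stage (the model sees counts; the filter does not).
- Average precision and precision@100 are highly variable with ≤ 30
  positives; fold-level values should be read with their spread.
- The veto rule language (regex over token text) cannot express
  semantic judgments; it records them.
- Wildcard matching is token-prefix, not substring: "porph*" does not
  match "protoporphyria". This is the documented reading of the
  trailing-star criteria.
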