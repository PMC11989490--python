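# Methods

`afdebut` is a desk-scale re-implementation of a clinical-NLP phenotyping
pipeline for atrial fibrillation (AF): it converts free-text hospital
discharge reports into structured patient-level predictor vectors, detects
*new-onset* AF reports while rejecting prior-AF history, reconciles the
text-derived detections with a (noisy) coded-system export, and quantifies
how label purity of the training corpus affects a downstream AF-onset
report classifier. Because real hospital corpora cannot ship with the
package, every stage is exercised against a bundled synthetic-report
generator with known ground truth; this note records the models,
assumptions and numerical choices.

## Pipeline model

1. **Sectioning.** Reports are segmented into nine standardized sections
   (Header, Reason for Consultation, Personal History, Current Illness,
   General Exploration, Complementary Tests, Diagnosis, Treatment,
   Evolution). The segmenter is a deterministic heading-lexicon matcher:
   a line equal (case-insensitively, accent-folded, optional trailing
   colon) to a known heading surface form opens a section that runs to the
   next recognized heading. Text before the first heading is `Unknown` and
   never searched. Spans are 0-based half-open character offsets,
   non-overlapping, and tile the whole text. A learned sequence model could
   be swapped in behind the same interface; the rule-based segmenter is
   exact on template-structured reports and fully auditable.

2. **Negation.** A NegEx-style trigger/scope algorithm: pre-triggers
   ("no", "sin", "niega" / "no", "denies", "without") negate a mention
   within `scope_window` tokens after them, post-triggers ("descartado",
   "ruled out") within `scope_window` tokens before them; terminator
   tokens (adversative conjunctions, semicolon) break the scope, and scope
   never crosses a sentence boundary (newline, or period + whitespace +
   capital). Default `scope_window` = 5 tokens. Hedging ("possible AF") is
   deliberately not negation. The exact scope semantics are pinned down by
   an exhaustive brute-force enumeration oracle in the test suite.

3. **Extraction.** Each variable carries a regex pattern bank (word roots
   plus synonyms), a value type (boolean, numeric, categorical,
   medication) and a list of *target sections*; patterns only ever run
   inside those sections on accent-folded lower-cased text (folding is
   length-preserving so offsets remain valid). Demographics are read from
   Reason for Consultation / Current Illness, medical history from
   Personal History / Diagnosis, lab numerics only from Complementary
   Tests, medications from Treatment (mapped to WHO ATC codes by
   longest-match lookup), procedures from Evolution / Current Illness.
   Numeric captures are normalized to a canonical unit per variable (e.g.
   creatinine in mg/dL, with µmol/L divided by 88.4). Negated boolean
   mentions yield explicit `False`, never a positive; when a report both
   affirms and negates a variable the affirmation wins (documented
   heuristic). AF itself is excluded from the history bank and handled by
   a dedicated flag detector: prior AF = non-negated AF mention in
   Personal History; new onset = non-negated AF mention in Diagnosis or
   Current Illness that is onset-qualified ("de novo", "primer episodio",
   "debut") or bare with no prior-history mention in the same report.

4. **Temporal overlap.** A patient's report vectors merge into one vector
   anchored on the AF debut date. Windows are per variable class: labs
   180 days before debut to 0 after; echocardiographic parameters 90 days
   either side; history, demographics, medications and procedures
   unbounded before and closed after (all configurable). "6 months" and
   "3 months" are fixed as 180/90 days because calendar-month arithmetic
   is locale-ambiguous. Among eligible candidates the report closest to
   debut wins; ties break toward the earlier report (pre-treatment values
   are preferred on clinical grounds), then the smaller report id. Debut
   resolution takes the earliest report flagged new-onset unless a
   chronologically earlier report asserts prior AF history, in which case
   no debut is assigned rather than guessed; later AF mentions are exposed
   as candidate recurrences but not modelled.

5. **Dataset reconciliation.** The coded export nominates AF-onset
   patients; duplicate coding rows collapse to the earliest event and
   reports within 30 days of the coding date become coded positives. The
   regex side nominates reports flagged new-onset. The *intersection*
   corpus keeps positives found by both sources, the *union* keeps any
   nomination (provenance flags preserve the symmetric-difference
   reading); both share one seed-deterministic negative sample drawn from
   patients with no AF evidence in either source.

6. **Classifier.** tf-idf over unicode word tokens (lower-cased,
   accent-folded), idf(t) = ln((1+N)/(1+df(t))) + 1, L2-normalized rows —
   delegated to scikit-learn's `TfidfVectorizer`; a feedforward network
   (`MLPClassifier`, one hidden layer of 128 ReLU units, Adam,
   learning rate 1e-3, epoch cap 200). Evaluation is stratified k-fold
   (default k = 5) with the vectorizer fitted on training folds only;
   metrics are stored as per-fold confusion matrices from which accuracy,
   precision, recall and F1 are recomputed. Corpus comparisons train both
   models identically and score them on one shared, clean held-out set;
   per-fold F1 vectors are compared with a classic paired t-test
   (hand-implemented so the degenerate contracts are explicit: identical
   vectors → t = 0, p = 1; zero-variance nonzero differences → ±∞, p → 0).
   *Early stopping is off by default*: at the corpus sizes this package
   targets a 10 % validation split is a handful of documents and the
   stopping rule fires at the majority-class plateau before any learning;
   capacity is controlled by the small architecture and the epoch cap
   instead. The flag remains available for larger corpora.

7. **Vector evaluation.** The unit is a (report, variable) cell:
   TP = present in both with matching values (numerics within a relative
   tolerance, default 1 %; booleans/categoricals exact — an explicit
   `False` is a value), FP = extraction asserts what gold lacks or
   contradicts, FN = gold value missed, TN = absent in both. A mismatched
   value counts as FP only by default (a flag also counts the FN);
   undefined ratios are reported as not-applicable and excluded from macro
   averages.

## Synthetic data: what it emulates and what it does not

The generator renders per-patient report timelines from per-language
sentence templates (Spanish, matching the source setting, and English;
both ship as data files so the pattern bank can be stress-tested without
touching code). It emulates the features the pipeline must be robust to:

- the nine-section report structure with heading synonyms;
- variable mentions with synonym variants (`synonym_rate`, default 0.3),
  negated mentions of absent conditions (`negation_rate`, 0.2), and
  distractor sentences that a correct extractor must ignore — lab values
  outside Complementary Tests, unmapped drug names, look-alike diagnoses
  such as atrial flutter (`distractor_rate`, 0.2);
- lab/echo numerics with unit variants, medications mappable to ATC;
- AF-onset phrasing confined to Diagnosis (qualified or bare) versus
  prior-AF phrasing confined to Personal History, with a documentation
  ceiling (`onset_documentation_rate`, default 0.9: some true onsets have
  no report that states the diagnosis, which caps text-based detection at
  about 90 %);
- a coded export with injectable false positives and false negatives
  (defaults 0.23 of coded entries spurious and 0.26 of true onsets
  uncoded, the audit rates the pipeline was built to counter), a ±7-day
  coding-date jitter, and 50 % masking of coded numeric values. Coding
  false positives are drawn preferentially (80 %) from prior-AF patients:
  miscoded "new onset" entries in practice are mostly prior-AF/recurrence
  episodes, and this is what makes union-trained classifiers absorb
  prior-AF vocabulary as a positive signal.

The seed fixes the corpus byte-for-byte. Ground truth (gold) records every
injected mention with its carrying sentence span, value and negated flag,
per-report section spans and AF flags, and per-patient truth vectors, so
every downstream stage has an exact oracle.

What the generator does **not** emulate: realistic clinical prose
(sentences are template-slotted, vocabulary is closed), inter-annotator
ambiguity, OCR/typo noise, cross-report value drift (a patient's lab value
is constant across their timeline), report-length and section-frequency
distributions of real corpora (unknown; defaults are arbitrary and
documented as such), and coding-date distributions. Passing tests
therefore demonstrate *mechanical correctness* of sectioning, scoping,
windowing and reconciliation — not expected field performance of the
pattern bank on real Spanish hospital text, where the original system
reported extraction accuracy ≈ 0.97 and precision ≈ 0.93 against manual
review. On the synthetic corpus the extractor is near-exact by
construction; the noise knobs bound, rather than estimate, real-data
degradation.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale populations chosen to keep the
whole suite in the order of a minute while leaving every statistic
well-resolved: 100–150 patients (≈ 230–370 reports) for extraction and
missingness checks, 1000 patients for coding-rate convergence (binomial
SE ≈ 1.5 points), 250 patients × 10 simulation seeds for the
intersection-vs-union comparison (≈ 180 held-out reports per seed). The
demonstrator schema has 21 variables across the six variable classes; the
schema format scales to a full clinical bank.

Numeric ties and degenerate inputs are pinned down explicitly: empty text
segments to no spans; a mention outside the text raises; unparseable
numeric captures are dropped with a warning rather than crashing;
zero-length corpora and single-class corpora are input errors; the
missingness reduction with a zero coded-missing denominator is reported
as 0.

## Known limitations

- The negation scope model is a deliberate simplification of the original
  system's learned negation module; divergence on real text is expected.
- The union/intersection experiment inherits the generator's assumption
  about *where* coding false positives come from; if spurious codes were
  instead uniform random noise, the union penalty would shrink.
- The bare-AF-mention precedence rule (bare mention counts as onset only
  when the report has no prior-history mention) is one defensible
  resolution of an under-specified case and is isolated in
  `detect_af_flags`.
- Calendar effects (months, leap years) are ignored by design: all windows
  are day counts.
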