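# Methods

## Case definition and integration model

A cohort member is a case if at least one of five sources produces evidence
of a major congenital anomaly. Codes, EUROCAT subgroups and provenance are
set unions over sources; no cross-source adjudication is attempted — the
union is deliberately liberal, trading some false positives for minimal
false negatives, and every case record keeps its source set so downstream
analyses can drop sources. Live-born status always comes from the cohort
registry, never from a source (a death-record case can still be live-born).
Age at first diagnosis is the minimum over contributing candidates.

Within the questionnaire source a consensus rule applies before
integration: a (participant, subgroup) report must occur in ≥2 distinct
instruments to be confirmed. The counting unit is the individual instrument
(any of the 23: delivery abstraction, neonatal admissions, 21 child
questionnaires), at organ/system (subgroup) level; single-instrument
reports are exported as a separate "possible CA" file and never enter the
main case set. Counting instruments rather than the three instrument
families is the stricter and more granular choice; family-level counting
can be recovered by collapsing instrument ids before extraction.

## Coding and classification

- **ICD-10 dialect.** Dot-form codes ("Q21.1") are canonical; dotless input
  is normalised on read. Valid shape: letter + 2 digits + optional 1–2
  digit subdivision.
- **SNOMED → ICD-10.** The cross-map is one-to-many. A unique candidate is
  taken as-is; otherwise the recorded diagnosis text is compared with each
  candidate's ICD-10 rubric by token-set similarity (Sørensen–Dice on
  normalised token sets, range 0–100) and the best scorer wins, ties
  resolved to the lexicographically smallest code. The choice is
  threshold-free because every mapped concept has at least one plausible
  candidate; the ambiguity flag is retained. The packaged map is a compact
  illustrative table (the licensed national cross-map cannot be
  redistributed); it is a plain TSV and fully overridable.
- **Text-only diagnoses** (cardiology, where some events carry no code) are
  assigned the rubric-best-match code only above a minimum similarity of
  60/100: distractor diagnoses (benign murmur, chest pain, family history)
  score near zero against every anomaly rubric and are rejected, while
  genuine anomaly texts are near-verbatim rubric matches.
- **Subgroup classification** is a prefix-interval lookup: a code belongs to
  every range whose interval contains it at the shorter of the two
  precisions, so "Q21.1" inherits membership of Q20–Q26 and a bare "Q79"
  touches any Q79.x range. Listed minor anomalies (e.g. patent ductus
  arteriosus, undescended testicle, hip instability) classify to the empty
  set. The packaged ranges follow the public EUROCAT guideline groupings
  (CHD Q20–Q26, chromosomal Q90–Q99, genetic/teratogenic syndromes Q86–Q87,
  abdominal wall Q79.2–Q79.3/Q79.5, ...); severity and septal/conotruncal
  flags are per-range annotations (severe: e.g. hypoplastic left heart
  Q23.4, transposition Q20.3, tetralogy Q21.3, coarctation Q25.1;
  conotruncal: Q20.0, Q20.1, Q20.3, Q21.3). Registry-specific lists differ
  in detail, so the whole table is an editable TSV and a config override —
  the packaged version is a documented assumption, not a claimed replica of
  any registry's private list.
- **Multiplicity.** CHD-only → isolated; CHD + chromosomal/syndrome →
  syndromic (precedence over other structural anomalies, following
  syndrome-led classification practice); CHD + other structural → CHD with
  other CAs. The three categories are exhaustive and disjoint and sum to
  the CHD total — published tabulations in which the syndromic row overlaps
  the other two are therefore not reproduced cell-for-cell; the explicit
  partition was preferred for internal consistency.

## Text search

Free text is normalised (lower-case, punctuation runs → single space) and
scanned for key phrases on word boundaries; variants found via the
misspelling dictionary are reported under their canonical term. Matching is
exact-substring, not fuzzy: deterministic and auditable, with every hit
traceable to a dictionary entry. The manual read-a-subsample-then-update
loop used when coding such data by hand is mechanised as a fixed-point
expansion: any dictionary variant present in the corpus but absent from the
strategy is added, and the scan repeats until no additions occur
(terminating because the term set grows monotonically within the finite
dictionary). Negation ("no heart problems") is out of scope.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised and validated.

- **Scale.** 14 676 fetuses, live-birth rate 0.958 (≈14 060 live births),
  matching an early-1990s UK regional birth cohort.
- **Ground truth.** Per-subgroup independent Bernoulli anomalies; each
  positive draw assigns one ICD-10-coded anomaly (a random key term of that
  subgroup). Default per-fetus prevalences are calibrated to the reported
  subgroup case totals of such a cohort (CHD 0.0087, limb 0.0134, genital
  0.0044, chromosomal 0.0029, ...), i.e. ~700 true cases per run.
- **Mortality.** Fetal deaths are the non-live-born; live-born cases die in
  childhood with probability 0.04 (non-cases 0.004), exponential age
  (mean 0.8 y). Participants dying before 18 are ineligible for
  primary-care linkage, mirroring the governance rule that blocks record
  extraction for the deceased.
- **Source sensitivities** (probability a true case yields a record):
  primary care 0.80, cardiology 0.24 (CHD cases only), deaths 0.90 (dead
  participants only), child health 0.17; questionnaires report each true
  (case, subgroup) independently per instrument at 0.015, giving ≈29% any-
  instrument capture and ≈84% of captured reports in a single instrument.
  No published per-source sensitivities exist, so these defaults were
  chosen once to reproduce the observed relative contribution of each
  source (primary care dominant; questionnaire reports mostly
  single-instrument) and are not calibrated further.
- **Noise.** Non-case questionnaire false positives at 0.035 per
  participant (one random instrument, one random anomaly phrase);
  misspellings replace a free-text term with a dictionary variant at rate
  0.10 (drawn only from the packaged dictionary, so expansion recall is
  measurable); primary-care non-anomaly codes at 0.05; cardiology
  distractor and diagnosis-free events at 0.012 and 0.02.
- **Age at diagnosis.** Mixture: point mass at birth (p=0.40) + log-normal
  tail (meanlog 1.79 ≈ median 6 y, sdlog 1.0, capped at 25.9 y). Under
  these defaults >50% of heart-defect diagnoses fall after the first year,
  reproducing the continued accrual of diagnoses into the mid-20s that
  motivates multi-decade linkage.
- **Determinism.** Every stream descends from the master seed through
  per-source `SeedSequence` children: identical (seed, config) ⇒
  byte-identical CSVs, and adding a source leaves the others unchanged.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: identity-linkage errors and duplicate
identities, free-text beyond template + dictionary substitution (no
negation, abbreviations or narrative), correlated multi-anomaly syndromes
(subgroups are independent, so the multi-anomaly share is lower than in
real cohorts), secular/geographic coverage differences between sources,
and coding drift. Results on synthetic runs validate the *pipeline logic*
(recall algebra, consensus behaviour, classification, accounting), not
real-world sensitivity values.

## Numerical and reporting choices

- **Rounding** is round-half-up (decimal arithmetic, not banker's), the
  only rule consistent with the published arithmetic this package
  re-derives; prevalence per 10 000 prints one decimal, percentages as
  specified per statistic.
- **Prevalence denominator** is the live-born count (14 791 in the
  reference cohort); numerators are live-born cases. Per-source capture
  denominators are config inputs, not derived, since the true capture
  population of each source is unknowable.
- **Disclosure suppression.** Report cells below 5 render `<5` (zero may
  also be shown as `<5`, so suppressed cells are not invertible); exact
  values remain available on the in-memory objects and via
  `--no-suppress`, mirroring governed-release practice.
- **Age curve bins** at cut-offs 1, 5, 15, 20, 25 years: [0,1), [1,5),
  [5,15), [15,20), [20,∞) — each case binned once at first diagnosis; the
  final bin absorbs slightly older ages from the last extraction sweep.
- **Degenerate inputs.** Zero denominators raise domain errors; empty
  confirmed/possible sets make the validation percentages `None`
  (undefined) rather than raising; unmapped SNOMED codes go to a
  side-channel CSV and never abort extraction; unknown child-health
  categories are hard errors (they indicate schema corruption).

## Test design notes

Stochastic assertions use 3σ binomial bounds at n = 10 000 with fixed
seeds. The perfect-observation oracle (all sensitivities 1, no noise ⇒
output = ground truth exactly) is the strongest end-to-end check; the
union-coverage check verifies 1 − Π(1 − s_k) algebra over the structurally
applicable sources (a living case cannot appear in the deaths file, so the
product runs over the other four). Problem sizes (2 000–14 676 fetuses)
keep the full suite in a few seconds.
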