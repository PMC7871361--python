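# ca-ascertain

Multi-source case ascertainment of congenital anomalies (CAs) in a birth
cohort, as a reusable, tested Python pipeline.

## The problem

Congenital anomalies — structural or functional disorders arising in utero,
coded in ICD-10 chapter Q — affect roughly 2–3% of births. In a longitudinal
birth cohort no single data stream captures all cases: primary-care records
miss participants who died young or were never linked, cardiology registries
only see children who had procedures, death records only the fatal cases,
and parent questionnaires are noisy. This package implements the standard
epidemiological answer: extract candidate cases from **five heterogeneous
sources** and declare a participant a case if *any* source identifies them
(a liberal union that minimises false negatives), with full provenance kept
so analysts can restrict to any source subset.

The five source schemas are:

1. **Primary care** — coded events (Read CTV2 + SNOMED CT), narrowed by a
   Read-code filter list, SNOMED cross-mapped to ICD-10;
2. **Paediatric cardiology** — procedure records with optional ICD-10 codes
   and/or text diagnoses (including non-CA distractors such as benign
   murmur);
3. **Fetal/infant/child deaths** — free-text anomaly descriptions, scanned
   whether or not the anomaly caused the death;
4. **Child health services** — anomaly records with an organ-system category
   and free text;
5. **Questionnaires** — free text from 23 instruments (delivery-record
   abstraction, neonatal admissions, 21 child-based questionnaires), subject
   to a consensus rule: a report must appear in **≥2 distinct instruments**
   (at organ/system level) to be confirmed; single-instrument reports are
   kept as a separate "possible CA" flag.

Cases are classified into EUROCAT organ-system subgroups by prefix-interval
lookup over ICD-10 ranges (congenital heart disease (CHD) = Q20–Q26,
chromosomal = Q90–Q99, ...), minor anomalies excluded. Reported statistics:

- live-birth prevalence per 10 000: `round₁(10⁴ · liveborn_cases / live_births)`,
- the exact Venn partition of cases over the 2⁵−1 source subsets,
- CHD subtype counts (severe, septal, conotruncal; isolated / with other
  CAs / syndromic, syndrome taking precedence),
- cumulative age-at-first-diagnosis curves with `<5` small-cell disclosure
  suppression,
- the questionnaire validation statistic (share of single- vs
  multi-instrument reports confirmed in primary care).

Because real cohort health records are managed-access, the package ships a
**synthetic cohort generator** (`cohort_synth`) that emulates all five
schemas with known ground truth, configurable per-source sensitivities,
dictionary-driven misspellings and questionnaire false positives — every
pipeline stage is testable offline, and recall/precision are measurable
against truth.

## Worked example

```python
from ca_ascertain import cohort_synth as cs, pipeline as pl, epistats as ep

cfg = cs.SynthConfig(seed=7, n_fetuses=5000)
registry, truth = cs.generate_cohort(cfg)
tables = cs.emit_sources(registry, truth, cfg)       # the five source CSVs
result = pl.run_pipeline(registry, tables)           # extract + integrate

live_births = int(registry["live_born"].sum())
records = result.case_records
chd = records[records["any_chd"] == 1]
print(len(truth), len(records), len(chd))
print(ep.prevalence(int(records["live_born"].sum()), live_births))
```

Output (seed 7):

```
cohort: 5000 fetuses, 4802 live births
true cases: 242;  ascertained cases: 215 (34 CHD)
any-CA prevalence: 437.3 per 10,000 live births
CHD prevalence:    66.6 per 10,000 live births
questionnaire validation: possible 23.0% vs confirmed 91.0% found in primary care
first-diagnosis accrual (cut-offs 1/5/15/20/25y): ['116', '51', '31', '7', '10'] cumulative: [116, 167, 198, 205, 215]
```

Reading this: 242 fetuses truly carry an anomaly; the union of the five
imperfect sources recovers 215 of them as confirmed cases. The validation
contrast (23% vs 91%) shows why single-instrument questionnaire reports are
quarantined as "possible": they are far less likely to be corroborated by
primary care than multi-instrument reports. The accrual row shows continued
case accumulation well past infancy — the reason age-capped registries
undercount.

The same run is available from the shell:

```bash
ca-ascertain synth --seed 7 --n-fetuses 5000 --out data/
ca-ascertain run   --data data/ --out results/
ca-ascertain report --cases results/case_records.csv --live-births 4802 --suppress
```

`run` writes `case_records.csv`, the two-column headline extract
(`headline_flags.csv`: `any_ca`, `any_chd`), the `possible_ca.csv`
side-file, unmapped-code side-channel, Venn cells and the report tables.
Counts below 5 are rendered `<5` unless `--no-suppress`.

## Layout

| module | role |
|---|---|
| `ca_ascertain.cohort_synth` | synthetic registry + five source tables with ground truth |
| `ca_ascertain.codes` | ICD-10 handling, SNOMED→ICD-10 cross-map, EUROCAT subgroup/severity tables |
| `ca_ascertain.textscan` | normalised word-boundary text search, misspelling fixed-point expansion |
| `ca_ascertain.ascertain` | the five per-source extractors incl. questionnaire consensus |
| `ca_ascertain.integrate` | participant-level union, CHD subtype + multiplicity classification |
| `ca_ascertain.epistats` | prevalence, Venn partitions, age curves, validation statistic |
| `ca_ascertain.cli` | `ca-ascertain synth / run / report` |

See `docs/methods.md` for the model, parameter defaults and limitations.
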