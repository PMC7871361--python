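"""Synthetic birth cohort with known ground-truth congenital anomalies.

Real multi-source ascertainment data for a birth cohort are managed-access
health records, so every downstream stage of this package is exercised on a
generated cohort that emulates the five source schemas: (1) primary-care
coded events (Read CTV2 + SNOMED CT), (2) paediatric cardiology records,
(3) fetal/infant/child death records with free-text anomaly descriptions,
(4) child-health-service anomaly records, and (5) questionnaire free text
from 23 instruments (delivery-record abstraction, neonatal admissions and
21 child-based questionnaires).

Ground truth is drawn first — per-fetus, per-subgroup independent Bernoulli
anomalies with ICD-10 codes — and each source then observes the truth with
a configurable sensitivity, plus realistic noise: misspelt free-text terms
(drawn only from the packaged misspelling dictionary, so recall is
measurable), questionnaire false positives on non-cases, cardiology
distractor diagnoses (benign murmur, chest pain, family history) and
diagnosis-absent events.

Every random draw descends from one master seed via per-source child
streams, so identical (seed, config) pairs give byte-identical CSV output
and adding a source leaves the others untouched.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import codes as _codes
from . import textscan as _textscan
from .errors import ConfigurationError

__all__ = [
    "SOURCES",
    "INSTRUMENTS",
    "SynthConfig",
    "generate_cohort",
    "emit_sources",
    "write_all",
    "default_search_strategy",
    "default_variant_dictionary",
    "questionnaire_source_sensitivity",
]

SOURCES = ("primary_care", "cardiology", "deaths", "child_health", "alspac_questionnaires")

# questionnaire instruments: delivery-record abstraction, neonatal
# admissions, and 21 child-based questionnaires at these ages (months)
_CQ_MONTHS = (1, 6, 15, 18, 24, 30, 38, 42, 47, 54, 57, 65, 69, 77, 81, 91, 97, 108, 122, 140, 166)
INSTRUMENTS: tuple[tuple[str, float], ...] = (
    ("delivery_abstraction", 0.0),
    ("neonatal_admissions", 28 / 365.25),
) + tuple((f"cq{i + 1:02d}", m / 12) for i, m in enumerate(_CQ_MONTHS))

_TEXT_TEMPLATES = (
    "born with {term}",
    "has {term}",
    "{term} diagnosed at hospital",
    "operation for {term}",
    "{term}",
)
CARDIOLOGY_DISTRACTORS = ("benign murmur", "chest pain", "family history of heart condition")

# defaults reflect the reported subgroup case totals of a ~14,700-fetus
# 1990s UK cohort, expressed as per-fetus probabilities
_DEFAULT_PREVALENCES = {
    "chd": 0.0087,
    "nervous_system": 0.0012,
    "eye": 0.0020,
    "ear_face_neck": 0.0006,
    "respiratory": 0.0004,
    "orofacial_clefts": 0.0011,
    "digestive": 0.0011,
    "abdominal_wall": 0.0004,
    "urinary": 0.0033,
    "genital": 0.0044,
    "limb": 0.0134,
    "other": 0.0041,
    "chromosomal": 0.0029,
    "syndromes": 0.0046,
}

_DEFAULT_SENSITIVITY = {
    "primary_care": 0.80,
    "cardiology": 0.24,  # applies to congenital heart disease cases only
    "deaths": 0.90,  # applies to participants who died
    "child_health": 0.17,
}


def _default_age_mixture() -> dict:
    # point mass at birth + log-normal tail (median ~6 y): under these
    # defaults more than half of heart-defect diagnoses fall after year 1,
    # matching the continued accrual of diagnoses seen up to the mid-20s
    return {"p_birth": 0.40, "meanlog": 1.79, "sdlog": 1.0, "max_age": 25.9}


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort; all probabilities in [0, 1]."""

    n_fetuses: int = 14676
    live_birth_rate: float = 0.958
    subgroup_prevalences: dict = field(default_factory=lambda: dict(_DEFAULT_PREVALENCES))
    source_sensitivity: dict = field(default_factory=lambda: dict(_DEFAULT_SENSITIVITY))
    questionnaire_instrument_sensitivity: float = 0.015
    false_positive_text_rate: float = 0.035
    misspelling_rate: float = 0.10
    age_at_diagnosis: dict = field(default_factory=_default_age_mixture)
    seed: int = 0
    # secondary nuisance rates
    child_death_rate_case: float = 0.04
    child_death_rate_noncase: float = 0.004
    pc_distractor_rate: float = 0.05
    cardiology_distractor_rate: float = 0.012
    cardiology_nodiag_rate: float = 0.02
    cardiology_code_given_rate: float = 0.80
    child_health_text_missing_rate: float = 0.15

    def validate(self) -> None:
        if int(self.n_fetuses) < 1:
            raise ConfigurationError("n_fetuses must be >= 1")
        probs = {
            "live_birth_rate": self.live_birth_rate,
            "questionnaire_instrument_sensitivity": self.questionnaire_instrument_sensitivity,
            "false_positive_text_rate": self.false_positive_text_rate,
            "misspelling_rate": self.misspelling_rate,
            "child_death_rate_case": self.child_death_rate_case,
            "child_death_rate_noncase": self.child_death_rate_noncase,
            "pc_distractor_rate": self.pc_distractor_rate,
            "cardiology_distractor_rate": self.cardiology_distractor_rate,
            "cardiology_nodiag_rate": self.cardiology_nodiag_rate,
            "cardiology_code_given_rate": self.cardiology_code_given_rate,
            "child_health_text_missing_rate": self.child_health_text_missing_rate,
            "age_at_diagnosis.p_birth": self.age_at_diagnosis["p_birth"],
            **{f"subgroup_prevalences[{k}]": v for k, v in self.subgroup_prevalences.items()},
            **{f"source_sensitivity[{k}]": v for k, v in self.source_sensitivity.items()},
        }
        for name, p in probs.items():
            if not (0.0 <= float(p) <= 1.0):
                raise ConfigurationError(f"{name} = {p} is not a probability in [0, 1]")
        unknown = set(self.source_sensitivity) - set(_DEFAULT_SENSITIVITY)
        if unknown:
            raise ConfigurationError(f"unknown source_sensitivity keys: {sorted(unknown)}")
        table = _codes.default_subgroup_table()
        bad = set(self.subgroup_prevalences) - set(table.subgroups)
        if bad:
            raise ConfigurationError(f"unknown subgroups in prevalences: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            cfg = cls(**(yaml.safe_load(fh) or {}))
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def default_search_strategy() -> _textscan.SearchStrategy:
    return _textscan.load_strategy(
        resources.files("ca_ascertain").joinpath("data", "search_terms.tsv")
    )


def default_variant_dictionary() -> dict[str, set[str]]:
    return _textscan.load_variant_dictionary(
        resources.files("ca_ascertain").joinpath("data", "misspellings.tsv")
    )


def questionnaire_source_sensitivity(config: SynthConfig) -> float:
    """Probability a true case is mentioned in >=1 questionnaire instrument."""
    q = config.questionnaire_instrument_sensitivity
    return 1.0 - (1.0 - q) ** len(INSTRUMENTS)


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # one child stream per source, split from the master seed
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), stream)))


def _term_tables():
    strategy = default_search_strategy()
    read = _codes.default_read_table()
    term_read = {r.term: (r.read_code, r.snomed_code) for r in read.itertuples()}
    by_subgroup: dict[str, list[str]] = {}
    for term in sorted(strategy.terms):
        by_subgroup.setdefault(strategy.system_of_term[term], []).append(term)
    return strategy, term_read, by_subgroup


def generate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the cohort registry and the ground-truth anomaly table.

    Returns ``(registry, truth)``. The registry has one row per fetus with
    birth outcome, live-born flag, birth date, death age (if any) and
    primary-care linkage eligibility (participants who died before age 18
    are not linkable). The truth table carries each participant's true
    ICD-10 codes, their subgroup classification under the packaged table,
    and is never read by the ascertainment pipeline.
    """
    config.validate()
    rng = _rng(config, 0)
    n = int(config.n_fetuses)
    strategy, _, by_subgroup = _term_tables()
    table = _codes.default_subgroup_table()

    pids = np.array([f"G1-{i + 1:06d}" for i in range(n)])
    live = rng.random(n) < config.live_birth_rate
    start = _dt.date(1991, 4, 1).toordinal()
    end = _dt.date(1992, 12, 31).toordinal()
    birth_dates = [
        _dt.date.fromordinal(int(o)).isoformat()
        for o in rng.integers(start, end + 1, size=n)
    ]

    # independent per-subgroup anomaly assignment; one coded anomaly (a
    # random key term of that subgroup) per positive draw
    term_of: list[dict[str, str]] = [dict() for _ in range(n)]
    for subgroup in sorted(config.subgroup_prevalences):
        p = config.subgroup_prevalences[subgroup]
        hit = np.flatnonzero(rng.random(n) < p)
        terms = by_subgroup.get(subgroup, [])
        if not terms and len(hit):
            raise ConfigurationError(f"no key terms available for subgroup {subgroup!r}")
        picks = rng.integers(0, len(terms), size=len(hit)) if terms else []
        for i, k in zip(hit, picks):
            term_of[i][subgroup] = terms[k]

    is_case = np.array([bool(t) for t in term_of])

    # child deaths (cases die more often); fetal deaths are the non-live-born
    child_death = live & (
        rng.random(n)
        < np.where(is_case, config.child_death_rate_case, config.child_death_rate_noncase)
    )
    death_age = np.full(n, np.nan)
    death_age[child_death] = np.minimum(rng.exponential(0.8, size=int(child_death.sum())), 10.0)
    death_age[~live] = 0.0

    registry = pd.DataFrame(
        {
            "participant_id": pids,
            "birth_date": birth_dates,
            "birth_outcome": np.where(live, "live_birth", "fetal_death"),
            "live_born": live.astype(int),
            "death_age": [("" if np.isnan(a) else round(float(a), 4)) for a in death_age],
            "pc_eligible": (live & ~child_death).astype(int),
        }
    )

    rows = []
    for i in np.flatnonzero(is_case):
        codes_ = sorted(strategy.icd10_of_term[t] for t in term_of[i].values())
        subgroups = sorted(
            set().union(*(_codes.classify_icd10(c, table) for c in codes_))
        )
        rows.append(
            {
                "participant_id": pids[i],
                "true_icd10_codes": ";".join(codes_),
                "true_subgroups": ";".join(subgroups),
                "true_terms": ";".join(
                    term_of[i][s] for s in sorted(term_of[i])
                ),
                "live_born": int(live[i]),
                "death_age": "" if np.isnan(death_age[i]) else round(float(death_age[i]), 4),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "true_icd10_codes",
            "true_subgroups",
            "true_terms",
            "live_born",
            "death_age",
        ],
    )
    return registry, truth


def _draw_age(rng: np.random.Generator, mix: dict) -> float:
    if rng.random() < mix["p_birth"]:
        return 0.0
    age = float(rng.lognormal(mix["meanlog"], mix["sdlog"]))
    return round(min(age, mix["max_age"]), 4)


def _misspell(
    rng: np.random.Generator, term: str, variants: dict[str, set[str]], rate: float
) -> str:
    vs = sorted(variants.get(term, ()))
    if vs and rng.random() < rate:
        return vs[int(rng.integers(0, len(vs)))]
    return term


def _truth_view(truth: pd.DataFrame, strategy: _textscan.SearchStrategy) -> list[dict]:
    out = []
    for r in truth.itertuples():
        terms = r.true_terms.split(";") if r.true_terms else []
        subgroups = sorted(r.true_subgroups.split(";")) if r.true_subgroups else []
        term_by_sub = {strategy.system_of_term[t]: t for t in terms}
        out.append(
            {
                "pid": r.participant_id,
                "codes": r.true_icd10_codes.split(";") if r.true_icd10_codes else [],
                "subgroups": subgroups,
                "terms": terms,
                "term_by_sub": term_by_sub,
                "live_born": bool(int(r.live_born)),
                "death_age": None if r.death_age == "" else float(r.death_age),
            }
        )
    return out


def emit_sources(
    registry: pd.DataFrame, truth: pd.DataFrame, config: SynthConfig
) -> dict[str, pd.DataFrame]:
    """Observe the ground truth through the five source schemas.

    Each true case yields a record in source *k* with probability
    ``source_sensitivity[k]`` (questionnaires: independently per instrument
    with ``questionnaire_instrument_sensitivity``), subject to structural
    eligibility — cardiology only sees heart-defect cases, the deaths file
    only participants who died, primary care only linkage-eligible
    participants. Non-case noise: primary-care non-anomaly codes,
    cardiology distractor/diagnosis-free events and questionnaire
    false-positive texts.
    """
    config.validate()
    if not registry["participant_id"].is_unique:
        raise ConfigurationError("registry participant_id not unique")
    if not set(truth["participant_id"]).issubset(set(registry["participant_id"])):
        raise ConfigurationError("truth references participants absent from registry")

    strategy, term_read, _ = _term_tables()
    variants = default_variant_dictionary()
    mix = config.age_at_diagnosis
    sens = config.source_sensitivity
    reg = registry.set_index("participant_id")
    cases = _truth_view(truth, strategy)

    # a per-case reference diagnosis age shared across record sources
    rng_base = _rng(config, 6)
    base_age = {c["pid"]: _draw_age(rng_base, mix) for c in cases}

    # --- source 1: primary care -------------------------------------------
    rng = _rng(config, 1)
    pc_rows = []
    for c in cases:
        if not int(reg.at[c["pid"], "pc_eligible"]):
            continue
        if rng.random() >= sens["primary_care"]:
            continue
        for term in c["terms"]:
            read_code, snomed = term_read[term]
            age = base_age[c["pid"]]
            pc_rows.append((c["pid"], round(min(age, 25.9), 4), read_code, snomed, term))
    eligible = registry.loc[registry["pc_eligible"] == 1, "participant_id"].to_numpy()
    distract = eligible[rng.random(len(eligible)) < config.pc_distractor_rate]
    for pid in distract:
        which = int(rng.integers(0, 2))
        read_code, snomed, text = (
            ("H33..", "195967001", "asthma") if which == 0 else ("M11..", "43116000", "eczema")
        )
        pc_rows.append((pid, round(float(rng.uniform(0, 26)), 4), read_code, snomed, text))
    primary_care = pd.DataFrame(
        pc_rows, columns=["participant_id", "event_age", "read_code", "snomed_code", "term_text"]
    ).sort_values(["participant_id", "event_age", "read_code"], kind="mergesort")

    # --- source 2: paediatric cardiology ----------------------------------
    rng = _rng(config, 2)
    card_rows = []
    for c in cases:
        chd_terms = [t for s, t in c["term_by_sub"].items() if s == "chd"]
        if not chd_terms or not c["live_born"]:
            continue
        if rng.random() >= sens["cardiology"]:
            continue
        term = chd_terms[0]
        icd10 = strategy.icd10_of_term[term]
        age = base_age[c["pid"]]
        if c["death_age"] is not None:
            age = min(age, c["death_age"])
        has_code = rng.random() < config.cardiology_code_given_rate
        card_rows.append((c["pid"], round(age, 4), icd10 if has_code else "", term))
    live_pids = registry.loc[registry["live_born"] == 1, "participant_id"].to_numpy()
    for pid in live_pids[rng.random(len(live_pids)) < config.cardiology_distractor_rate]:
        text = CARDIOLOGY_DISTRACTORS[int(rng.integers(0, len(CARDIOLOGY_DISTRACTORS)))]
        card_rows.append((pid, round(float(rng.uniform(0, 18)), 4), "", text))
    for pid in live_pids[rng.random(len(live_pids)) < config.cardiology_nodiag_rate]:
        card_rows.append((pid, round(float(rng.uniform(0, 18)), 4), "", ""))
    cardiology = pd.DataFrame(
        card_rows, columns=["participant_id", "event_age", "icd10_code", "diagnosis_text"]
    ).sort_values(["participant_id", "event_age", "diagnosis_text"], kind="mergesort")

    # --- source 3: fetal and child deaths ---------------------------------
    rng = _rng(config, 3)
    truth_pids = {c["pid"]: c for c in cases}
    death_rows = []
    for r in registry.itertuples():
        died_fetal = r.birth_outcome == "fetal_death"
        died_child = (not died_fetal) and r.death_age != ""
        if not (died_fetal or died_child):
            continue
        c = truth_pids.get(r.participant_id)
        text = ""
        category = "none"
        if c is not None and rng.random() < sens["deaths"]:
            spelt = [
                _misspell(rng, t, variants, config.misspelling_rate) for t in c["terms"]
            ]
            text = "; ".join(spelt)
            category = c["subgroups"][0]
        wigglesworth = (
            "congenital_anomaly"
            if category != "none"
            else ("antepartum" if died_fetal else "other")
        )
        death_rows.append(
            (
                r.participant_id,
                int(died_fetal),
                "" if died_fetal else r.death_age,
                category,
                wigglesworth,
                text,
            )
        )
    deaths = pd.DataFrame(
        death_rows,
        columns=[
            "participant_id",
            "fetal_death",
            "death_age",
            "system_category",
            "wigglesworth_class",
            "anomaly_text",
        ],
    ).sort_values("participant_id", kind="mergesort")

    # --- source 4: child health services ----------------------------------
    rng = _rng(config, 4)
    ch_rows = []
    for c in cases:
        if not c["live_born"]:
            continue
        if rng.random() >= sens["child_health"]:
            continue
        for subgroup in c["subgroups"]:
            term = c["term_by_sub"].get(subgroup)
            if term is None:
                continue
            text = "" if rng.random() < config.child_health_text_missing_rate else term
            age = round(min(base_age[c["pid"]], float(rng.uniform(0, 2.2))), 4)
            ch_rows.append((c["pid"], subgroup, text, age))
    child_health = pd.DataFrame(
        ch_rows, columns=["participant_id", "category", "diagnosis_text", "diagnosis_age"]
    ).sort_values(["participant_id", "category"], kind="mergesort")

    # --- source 5: questionnaires ------------------------------------------
    rng = _rng(config, 5)
    q = config.questionnaire_instrument_sensitivity
    q_rows = []
    for c in cases:
        if c["live_born"]:
            horizon = c["death_age"] if c["death_age"] is not None else np.inf
            available = [(iid, a) for iid, a in INSTRUMENTS if a <= horizon]
        else:
            available = [INSTRUMENTS[0]]  # delivery abstraction only
        for subgroup in c["subgroups"]:
            term = c["term_by_sub"].get(subgroup)
            if term is None:
                continue
            for iid, age in available:
                if rng.random() < q:
                    spelt = _misspell(rng, term, variants, config.misspelling_rate)
                    tmpl = _TEXT_TEMPLATES[int(rng.integers(0, len(_TEXT_TEMPLATES)))]
                    q_rows.append((c["pid"], iid, round(age, 4), tmpl.format(term=spelt)))
    non_case = sorted(set(registry["participant_id"]) - set(truth["participant_id"]))
    all_terms = sorted(strategy.terms)
    for pid in non_case:
        if rng.random() < config.false_positive_text_rate:
            iid, age = INSTRUMENTS[int(rng.integers(0, len(INSTRUMENTS)))]
            term = all_terms[int(rng.integers(0, len(all_terms)))]
            spelt = _misspell(rng, term, variants, config.misspelling_rate)
            tmpl = _TEXT_TEMPLATES[int(rng.integers(0, len(_TEXT_TEMPLATES)))]
            q_rows.append((pid, iid, round(age, 4), tmpl.format(term=spelt)))
    questionnaires = pd.DataFrame(
        q_rows, columns=["participant_id", "instrument_id", "instrument_age", "text"]
    ).sort_values(["participant_id", "instrument_id", "text"], kind="mergesort")

    return {
        "primary_care": primary_care.reset_index(drop=True),
        "cardiology": cardiology.reset_index(drop=True),
        "deaths": deaths.reset_index(drop=True),
        "child_health": child_health.reset_index(drop=True),
        "alspac_questionnaires": questionnaires.reset_index(drop=True),
    }


def write_all(config: SynthConfig, outdir) -> dict[str, Path]:
    """Generate registry, truth and the five sources; write CSVs to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry, truth = generate_cohort(config)
    tables = emit_sources(registry, truth, config)
    paths = {}
    for name, df in {"registry": registry, "ground_truth": truth, **tables}.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, lineterminator="\n")
        paths[name] = p
    config.to_yaml(outdir / "synth_config.yaml")
    return paths
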