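"""Per-source case extraction.

Each of the five heterogeneous source tables is reduced to *candidate
cases*: one row per (participant, source) carrying the ICD-10 codes that
could be assigned, their EUROCAT subgroups, provenance, and the age at
first diagnosis within that source. Questionnaire-derived reports are
additionally split by the consensus rule: a participant's anomaly counts as
*confirmed* only when the same subgroup (organ/system level) is mentioned
in at least two distinct instruments; a single-instrument mention is kept
as a "possible CA" flag but excluded from the main case set, since lone
parent reports are the least reliable evidence stream.

Unmapped SNOMED codes are never fatal: they are routed to a side-channel
table so coding gaps are auditable.
"""

from __future__ import annotations

import pandas as pd

from . import codes as _codes
from . import textscan as _textscan
from .errors import CodeValidationError

__all__ = [
    "CANDIDATE_COLUMNS",
    "extract_primary_care",
    "extract_cardiology",
    "extract_deaths",
    "extract_child_health",
    "extract_questionnaires",
]

CANDIDATE_COLUMNS = [
    "participant_id",
    "source",
    "icd10_codes",  # ";"-joined, sorted
    "subgroups",  # ";"-joined, sorted
    "instruments",  # questionnaire source only, ";"-joined
    "first_diagnosis_age",
    "code_absent",  # 1 when only a subgroup (no ICD-10) could be assigned
    "not_live_born",  # deaths source: fetal-death evidence
]

# minimum token-set similarity for assigning an ICD-10 code from free text
# alone; distractor diagnoses (murmur, chest pain, family history) score
# far below this against any anomaly rubric
TEXT_MATCH_THRESHOLD = 60.0


def _mk_cases(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    return df.sort_values(["participant_id", "source"], kind="mergesort").reset_index(drop=True)


def _finish(per_pid: dict, source: str) -> pd.DataFrame:
    rows = []
    for pid in sorted(per_pid):
        d = per_pid[pid]
        rows.append(
            {
                "participant_id": pid,
                "source": source,
                "icd10_codes": ";".join(sorted(d["codes"])),
                "subgroups": ";".join(sorted(d["subgroups"])),
                "instruments": ";".join(sorted(d.get("instruments", []))),
                "first_diagnosis_age": d.get("age"),
                "code_absent": int(not d["codes"]),
                "not_live_born": int(d.get("not_live_born", False)),
            }
        )
    return _mk_cases(rows)


def _acc(per_pid: dict, pid: str, codes: set[str], subgroups: set[str], age) -> None:
    d = per_pid.setdefault(pid, {"codes": set(), "subgroups": set(), "age": None})
    d["codes"] |= codes
    d["subgroups"] |= subgroups
    if age is not None and not pd.isna(age):
        d["age"] = float(age) if d["age"] is None else min(d["age"], float(age))


def best_text_match(text: str, map_table: _codes.CodeMapTable) -> str | None:
    """Assign an ICD-10 code to a bare text diagnosis.

    The rubric with the highest token-set similarity wins (ties to the
    smallest code); below TEXT_MATCH_THRESHOLD no code is assigned.
    """
    if not _textscan.normalise(text):
        return None
    best_code, best_score = None, TEXT_MATCH_THRESHOLD
    for icd10, rubric in map_table.all_rubrics():
        score = _codes.token_set_ratio(text, rubric)
        if score > best_score:
            best_code, best_score = icd10, score
    return best_code


def extract_primary_care(
    events: pd.DataFrame,
    read_filter: frozenset[str],
    code_map: _codes.CodeMapTable,
    subgroup_table: _codes.SubgroupTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract candidate cases from coded primary-care events.

    Events are first narrowed by the Read-code filter list; surviving SNOMED
    codes are cross-mapped to ICD-10 (text-disambiguated when one-to-many)
    and classified. Participants retaining >=1 anomaly-classified code
    become candidates; ``first_diagnosis_age`` is the earliest anomaly
    event. Returns ``(candidates, unmapped)`` where ``unmapped`` lists
    events whose SNOMED code had no cross-map entry.
    """
    per_pid: dict = {}
    unmapped = []
    for r in events.itertuples():
        if r.read_code not in read_filter:
            continue
        try:
            icd10, _ = _codes.map_snomed_to_icd10(str(r.snomed_code), r.term_text, code_map)
        except _codes.UnmappedCodeError:
            unmapped.append(
                {"participant_id": r.participant_id, "snomed_code": r.snomed_code,
                 "term_text": r.term_text}
            )
            continue
        subgroups = _codes.classify_icd10(icd10, subgroup_table)
        if not subgroups:
            continue
        _acc(per_pid, r.participant_id, {icd10}, subgroups, r.event_age)
    return _finish(per_pid, "primary_care"), pd.DataFrame(
        unmapped, columns=["participant_id", "snomed_code", "term_text"]
    )


def extract_cardiology(
    events: pd.DataFrame,
    code_map: _codes.CodeMapTable,
    subgroup_table: _codes.SubgroupTable,
) -> pd.DataFrame:
    """Extract candidate cases from cardiology/cardiothoracic records.

    Events without any diagnosis are discarded. Coded events use their
    ICD-10 code directly; text-only diagnoses are assigned the
    best-text-match code. Diagnoses that classify into no anomaly subgroup
    (benign murmur, chest pain, family history, ...) yield no case.
    """
    per_pid: dict = {}
    for r in events.itertuples():
        code = str(r.icd10_code).strip() if not pd.isna(r.icd10_code) else ""
        text = str(r.diagnosis_text) if not pd.isna(r.diagnosis_text) else ""
        if not code and not _textscan.normalise(text):
            continue  # tested, nothing found
        icd10 = _codes.normalise_icd10(code) if code else best_text_match(text, code_map)
        if icd10 is None:
            continue
        subgroups = _codes.classify_icd10(icd10, subgroup_table)
        if not subgroups:
            continue
        _acc(per_pid, r.participant_id, {icd10}, subgroups, r.event_age)
    return _finish(per_pid, "cardiology")


def extract_deaths(
    records: pd.DataFrame,
    strategy: _textscan.SearchStrategy,
    code_map: _codes.CodeMapTable,
    subgroup_table: _codes.SubgroupTable,
) -> pd.DataFrame:
    """Extract candidate cases from fetal/infant/child death records.

    The free-text anomaly description is scanned with the search strategy;
    any anomaly mention yields a case regardless of the recorded cause-of-
    death category. Fetal deaths are flagged not-live-born. Age at first
    diagnosis is 0 for fetal deaths, else the recorded death age.
    """
    per_pid: dict = {}
    texts = [
        (r.participant_id, "deaths", r.anomaly_text if not pd.isna(r.anomaly_text) else "")
        for r in records.itertuples()
    ]
    hits = _textscan.search(texts, strategy)
    by_pid: dict[str, list] = {}
    for h in hits:
        by_pid.setdefault(h.participant_id, []).append(h)
    meta = records.set_index("participant_id")
    for pid, pid_hits in by_pid.items():
        codes = set()
        subgroups = set()
        for h in pid_hits:
            icd10 = strategy.icd10_of_term.get(h.term)
            if icd10:
                icd10 = _codes.normalise_icd10(icd10)
                cls = _codes.classify_icd10(icd10, subgroup_table)
                if not cls:
                    continue
                codes.add(icd10)
                subgroups |= cls
            else:
                subgroups.add(h.subgroup)
        if not subgroups:
            continue
        fetal = bool(int(meta.at[pid, "fetal_death"]))
        raw_age = meta.at[pid, "death_age"]
        age = 0.0 if fetal or raw_age == "" or pd.isna(raw_age) else float(raw_age)
        _acc(per_pid, pid, codes, subgroups, age)
        per_pid[pid]["not_live_born"] = fetal
    return _finish(per_pid, "deaths")


def extract_child_health(
    records: pd.DataFrame,
    strategy: _textscan.SearchStrategy,
    code_map: _codes.CodeMapTable,
    subgroup_table: _codes.SubgroupTable,
) -> pd.DataFrame:
    """Extract candidate cases from child-health-service anomaly records.

    Every record is a reported anomaly: an ICD-10 code is assigned from the
    diagnosis text where the search strategy recognises it, otherwise the
    record contributes a subgroup-only (code-absent) case from its category
    column. Unknown categories raise CodeValidationError.
    """
    valid = set(subgroup_table.subgroups)
    per_pid: dict = {}
    for r in records.itertuples():
        if r.category not in valid:
            raise CodeValidationError(f"unknown child-health category: {r.category!r}")
        codes: set[str] = set()
        subgroups: set[str] = set()
        text = r.diagnosis_text if not pd.isna(r.diagnosis_text) else ""
        for h in _textscan.search([(r.participant_id, "child_health", text)], strategy):
            icd10 = strategy.icd10_of_term.get(h.term)
            if icd10:
                icd10 = _codes.normalise_icd10(icd10)
                cls = _codes.classify_icd10(icd10, subgroup_table)
                if cls:
                    codes.add(icd10)
                    subgroups |= cls
        if not subgroups:
            subgroups = {r.category}
        _acc(per_pid, r.participant_id, codes, subgroups, r.diagnosis_age)
    return _finish(per_pid, "child_health")


def extract_questionnaires(
    texts: pd.DataFrame,
    strategy: _textscan.SearchStrategy,
    subgroup_table: _codes.SubgroupTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the text search and the two-instrument consensus rule.

    A (participant, subgroup) pair mentioned in >=2 distinct instruments is
    *confirmed*; mentioned in exactly one it is a *possible CA*. The two
    sets are disjoint per (participant, subgroup) by construction. Returns
    ``(confirmed, possible)`` candidate tables; ``first_diagnosis_age`` is
    the age of the earliest contributing instrument.
    """
    rows = [
        (r.participant_id, r.instrument_id, r.text) for r in texts.itertuples()
    ]
    hits = _textscan.search(rows, strategy)
    age_of = {
        (r.participant_id, r.instrument_id): float(r.instrument_age)
        for r in texts.itertuples()
        if "instrument_age" in texts.columns and not pd.isna(r.instrument_age)
    }
    # (pid, subgroup) -> {instrument -> earliest age}, plus terms seen
    acc: dict[tuple[str, str], dict] = {}
    for h in hits:
        d = acc.setdefault((h.participant_id, h.subgroup), {"instruments": set(), "terms": set()})
        d["instruments"].add(h.instrument_id)
        d["terms"].add(h.term)
    confirmed: dict = {}
    possible: dict = {}
    for (pid, subgroup), d in acc.items():
        target = confirmed if len(d["instruments"]) >= 2 else possible
        codes = {
            _codes.normalise_icd10(strategy.icd10_of_term[t])
            for t in d["terms"]
            if strategy.icd10_of_term.get(t)
        }
        codes = {c for c in codes if _codes.classify_icd10(c, subgroup_table)}
        ages = [age_of[(pid, i)] for i in d["instruments"] if (pid, i) in age_of]
        _acc(target, pid, codes, {subgroup}, min(ages) if ages else None)
        target[pid].setdefault("instruments", set()).update(d["instruments"])
    return (
        _finish(confirmed, "alspac_questionnaires"),
        _finish(possible, "alspac_questionnaires"),
    )
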