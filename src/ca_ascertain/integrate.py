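"""Union of candidate cases across the five sources.

A participant is a case if any source identified them — a deliberately
liberal definition that minimises false negatives at the cost of admitting
some false positives; no adjudication between sources is attempted. Codes,
subgroups and provenance are set unions over the contributing candidates,
the age at first diagnosis is the minimum, and live-born status comes from
the cohort registry (a death-source record does not imply a non-live
birth). Each record is then classified: congenital-heart-disease subtype
flags (severe / septal / conotruncal) and a multiplicity category in which
a co-occurring chromosomal or syndrome diagnosis takes precedence over
other structural anomalies (syndrome-led classification, as in EUROCAT
practice).
"""

from __future__ import annotations

import pandas as pd

from . import codes as _codes
from .errors import IntegrityError

__all__ = ["CASE_COLUMNS", "integrate_cases", "classify_multiplicity", "headline_flags"]

CASE_COLUMNS = [
    "participant_id",
    "icd10_codes",
    "subgroups",
    "sources",
    "live_born",
    "first_diagnosis_age",
    "any_chd",
    "chd_severe",
    "chd_septal",
    "chd_conotruncal",
    "multiplicity",
    "code_absent_only",
]

SYNDROMIC_SUBGROUPS = frozenset({"chromosomal", "syndromes"})


def classify_multiplicity(subgroups: set[str]) -> str:
    """Multiplicity category of a case from its subgroup set.

    CHD alone -> isolated_chd; CHD + chromosomal/syndrome -> chd_with_syndrome
    (precedence over other anomalies); CHD + other structural anomaly ->
    chd_with_other_ca. Non-CHD cases: single_non_chd / multiple_non_chd.
    """
    if not subgroups:
        raise ValueError("classify_multiplicity needs a non-empty subgroup set")
    others = set(subgroups) - {"chd"}
    if "chd" in subgroups:
        if not others:
            return "isolated_chd"
        if others & SYNDROMIC_SUBGROUPS:
            return "chd_with_syndrome"
        return "chd_with_other_ca"
    return "multiple_non_chd" if len(others) > 1 else "single_non_chd"


def integrate_cases(
    candidates: pd.DataFrame,
    registry: pd.DataFrame,
    subgroup_table: _codes.SubgroupTable | None = None,
) -> pd.DataFrame:
    """Merge per-source candidate cases into one record per participant.

    ``candidates`` is the concatenation of the five extractors' outputs
    (questionnaire *confirmed* candidates only; "possible CA" participants
    are excluded upstream and reported separately). A candidate whose
    participant is not in the registry raises IntegrityError.
    """
    table = subgroup_table or _codes.default_subgroup_table()
    reg = registry.set_index("participant_id")
    unknown = set(candidates["participant_id"]) - set(reg.index)
    if unknown:
        raise IntegrityError(f"candidates reference unknown participants: {sorted(unknown)[:5]}")

    rows = []
    for pid, grp in candidates.groupby("participant_id", sort=True):
        codes: set[str] = set()
        subgroups: set[str] = set()
        sources: set[str] = set()
        ages = []
        for r in grp.itertuples():
            codes |= set(filter(None, str(r.icd10_codes).split(";")))
            subgroups |= set(filter(None, str(r.subgroups).split(";")))
            sources.add(r.source)
            if r.first_diagnosis_age is not None and not pd.isna(r.first_diagnosis_age):
                ages.append(float(r.first_diagnosis_age))
        if not sources:
            continue
        # subgroups implied by the pooled codes, plus category-only evidence
        for c in codes:
            subgroups |= _codes.classify_icd10(c, table)
        any_chd = "chd" in subgroups
        if any_chd and any("chd" in _codes.classify_icd10(c, table) for c in codes):
            flags = _codes.chd_subtype(codes, table)
        else:
            flags = _codes.ChdFlags()
        rows.append(
            {
                "participant_id": pid,
                "icd10_codes": ";".join(sorted(codes)),
                "subgroups": ";".join(sorted(subgroups)),
                "sources": ";".join(sorted(sources)),
                "live_born": int(reg.at[pid, "live_born"]),
                "first_diagnosis_age": min(ages) if ages else None,
                "any_chd": int(any_chd),
                "chd_severe": int(flags.severe),
                "chd_septal": int(flags.septal),
                "chd_conotruncal": int(flags.conotruncal),
                "multiplicity": classify_multiplicity(subgroups),
                "code_absent_only": int(not codes),
            }
        )
    return pd.DataFrame(rows, columns=CASE_COLUMNS)


def headline_flags(case_records: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """The two headline variables per cohort member: any_ca and any_chd."""
    cases = case_records.set_index("participant_id")
    out = registry[["participant_id"]].copy()
    out["any_ca"] = out["participant_id"].isin(cases.index).astype(int)
    out["any_chd"] = (
        out["participant_id"].map(cases["any_chd"]).fillna(0).astype(int)
    )
    return out
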