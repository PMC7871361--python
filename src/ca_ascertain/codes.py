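"""Clinical code systems and the EUROCAT subgroup classification.

Three coding layers meet here. UK primary-care events carry Read CTV2 codes
(used only as a pre-filter for potential congenital-anomaly diagnoses) plus
SNOMED CT concept codes; SNOMED concepts cross-map one-to-many onto ICD-10,
and the ambiguity is resolved by matching the recorded diagnosis text
against the candidate ICD-10 rubric texts. Classification into EUROCAT
organ-system subgroups is then a prefix-interval lookup over ICD-10 chapter
Q ranges (e.g. Q20-Q26 for congenital heart disease), with listed minor
anomalies excluded and per-range carve-outs honoured.

The packaged default tables are derived from the public EUROCAT guideline
code ranges and a compact illustrative SNOMED/Read code list; both are
plain TSV and overridable, since registry-specific code lists vary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

from .errors import CodeValidationError, UnmappedCodeError
from .textscan import normalise

__all__ = [
    "CodeMapTable",
    "SubgroupTable",
    "ChdFlags",
    "normalise_icd10",
    "token_set_ratio",
    "map_snomed_to_icd10",
    "classify_icd10",
    "chd_subtype",
    "load_read_code_filter",
    "default_code_map",
    "default_subgroup_table",
    "default_read_table",
    "TABLE2_SUBGROUPS",
]

# the organ-system subgroups reported in EUROCAT-style prevalence tables
TABLE2_SUBGROUPS = (
    "chd",
    "nervous_system",
    "respiratory",
    "orofacial_clefts",
    "eye",
    "ear_face_neck",
    "digestive",
    "abdominal_wall",
    "urinary",
    "genital",
    "limb",
    "chromosomal",
    "other",
    "syndromes",
)

_ICD10_RE = re.compile(r"^([A-Z])(\d{2})(?:\.?(\d{1,2}))?$")


def normalise_icd10(code: str) -> str:
    """Canonicalise an ICD-10 code to dot form ("Q211" -> "Q21.1").

    Raises :class:`CodeValidationError` for anything that is not a letter,
    two digits and an optional 1-2 digit subdivision.
    """
    m = _ICD10_RE.match(str(code).strip().upper())
    if not m:
        raise CodeValidationError(f"malformed ICD-10 code: {code!r}")
    letter, stem, sub = m.groups()
    return f"{letter}{stem}.{sub}" if sub else f"{letter}{stem}"


def _dotless(code: str) -> str:
    return normalise_icd10(code).replace(".", "")


def token_set_ratio(a: str, b: str) -> float:
    """Similarity in [0, 100] between the token *sets* of two strings.

    Soerensen-Dice coefficient on the sets of normalised tokens; word order
    and repetition are ignored, which suits short clinical rubrics.
    """
    ta, tb = set(normalise(a).split()), set(normalise(b).split())
    ta.discard("")
    tb.discard("")
    if not ta and not tb:
        return 100.0
    if not ta or not tb:
        return 0.0
    return 200.0 * len(ta & tb) / (len(ta) + len(tb))


class CodeMapTable:
    """One-to-many SNOMED CT -> ICD-10 cross-map with rubric texts."""

    def __init__(self, rows: Iterable[tuple[str, str, str]]):
        self._map: dict[str, list[tuple[str, str]]] = {}
        for snomed, icd10, text in rows:
            self._map.setdefault(str(snomed), []).append((normalise_icd10(icd10), text))
        # candidate order never matters: sorted for determinism
        for cands in self._map.values():
            cands.sort()

    def __contains__(self, snomed_code: str) -> bool:
        return str(snomed_code) in self._map

    def candidates(self, snomed_code: str) -> list[tuple[str, str]]:
        try:
            return list(self._map[str(snomed_code)])
        except KeyError:
            raise UnmappedCodeError(str(snomed_code)) from None

    def all_rubrics(self) -> list[tuple[str, str]]:
        """Every (icd10, rubric text) pair, deduplicated, sorted."""
        return sorted({pair for cands in self._map.values() for pair in cands})

    @classmethod
    def from_tsv(cls, path) -> "CodeMapTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df[["snomed_code", "icd10", "icd10_text"]].itertuples(index=False))


def map_snomed_to_icd10(
    snomed_code: str, source_text: str, map_table: CodeMapTable
) -> tuple[str, bool]:
    """Resolve a SNOMED code to a single ICD-10 code.

    A unique candidate is returned directly. With several candidates the
    recorded diagnosis text is compared against each candidate's rubric by
    token-set similarity and the best scorer wins (ties: lexicographically
    smallest code). Returns ``(icd10_code, ambiguity_flag)``; the flag marks
    codes chosen among multiple candidates.
    """
    cands = map_table.candidates(snomed_code)
    if len(cands) == 1:
        return cands[0][0], False
    # candidates are code-sorted, and max() keeps the first maximum, so a
    # score tie resolves to the lexicographically smallest code
    best = max(cands, key=lambda c: token_set_ratio(source_text or "", c[1]))
    return best[0], True


@dataclass(frozen=True)
class SubgroupRange:
    subgroup: str
    start: str  # dotless, e.g. "Q20" or "Q212"
    end: str
    exclusions: frozenset[str] = frozenset()
    is_chd: bool = False
    chd_severe: bool = False
    chd_septal: bool = False
    chd_conotruncal: bool = False

    def __post_init__(self):
        if len(self.start) != len(self.end) or self.start > self.end:
            raise CodeValidationError(
                f"degenerate range {self.start}-{self.end} for {self.subgroup}"
            )

    def contains(self, dotless_code: str) -> bool:
        """Prefix-interval membership: compare on the shorter precision."""
        k = min(len(dotless_code), len(self.start))
        if not (self.start[:k] <= dotless_code[:k] <= self.end[:k]):
            return False
        return not any(
            dotless_code.startswith(x) or x.startswith(dotless_code)
            for x in self.exclusions
        )


class ChdFlags(dict):
    """OR-reduced congenital-heart-disease subtype flags."""

    def __init__(self, severe=False, septal=False, conotruncal=False):
        super().__init__(severe=bool(severe), septal=bool(septal), conotruncal=bool(conotruncal))

    severe = property(lambda self: self["severe"])
    septal = property(lambda self: self["septal"])
    conotruncal = property(lambda self: self["conotruncal"])


class SubgroupTable:
    """EUROCAT subgroup ranges plus the minor-anomaly exclusion list."""

    def __init__(self, ranges: Iterable[SubgroupRange], minor_anomaly_codes: Iterable[str] = ()):
        self.ranges = sorted(
            ranges, key=lambda r: (r.subgroup, r.start, r.end)
        )
        self.minor_anomaly_codes = frozenset(_dotless(c) for c in minor_anomaly_codes)
        chd_rows = [r for r in self.ranges if r.is_chd]
        if chd_rows:
            lo = min(r.start for r in chd_rows if r.subgroup == "chd")
            hi = max(r.end[:3] for r in chd_rows if r.subgroup == "chd")
            for r in chd_rows:
                if not (lo <= r.start[:3] and r.end[:3] <= hi):
                    raise CodeValidationError(
                        f"CHD-flagged range {r.start}-{r.end} outside the CHD subgroup"
                    )

    @property
    def subgroups(self) -> frozenset[str]:
        return frozenset(r.subgroup for r in self.ranges)

    def is_minor(self, code: str) -> bool:
        return _minor_match(self, _dotless(code))

    @classmethod
    def from_tsv(cls, path, minor_path=None) -> "SubgroupTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        ranges = [
            SubgroupRange(
                subgroup=r.subgroup,
                start=_dotless(r.start),
                end=_dotless(r.end),
                exclusions=frozenset(
                    _dotless(x) for x in str(r.exclusions).split(";") if x.strip()
                ),
                is_chd=r.is_chd == "1",
                chd_severe=r.chd_severe == "1",
                chd_septal=r.chd_septal == "1",
                chd_conotruncal=r.chd_conotruncal == "1",
            )
            for r in df.itertuples()
        ]
        minors: list[str] = []
        if minor_path is not None:
            minors = pd.read_csv(minor_path, sep="\t", dtype=str)["code"].tolist()
        return cls(ranges, minors)


def _minor_match(table: SubgroupTable, dotless_code: str) -> bool:
    return any(dotless_code.startswith(m) for m in table.minor_anomaly_codes)


def classify_icd10(icd10_code: str, table: SubgroupTable) -> set[str]:
    """EUROCAT subgroups containing ``icd10_code``.

    Empty set iff the code is outside every congenital-anomaly range or is a
    listed minor anomaly. Malformed codes raise CodeValidationError.
    """
    c = _dotless(icd10_code)
    if _minor_match(table, c):
        return set()
    return {r.subgroup for r in table.ranges if r.contains(c)}


def chd_subtype(icd10_codes: Iterable[str], table: SubgroupTable) -> ChdFlags:
    """OR-reduce severity/septal/conotruncal flags over a case's CHD codes.

    Requires at least one code classifying into the CHD subgroup.
    """
    codes = [_dotless(c) for c in icd10_codes]
    if not any("chd" in classify_icd10(c, table) for c in codes):
        raise ValueError("chd_subtype called on a code set with no CHD code")
    severe = septal = conotruncal = False
    for r in table.ranges:
        if not r.is_chd:
            continue
        for c in codes:
            if r.contains(c) and not _minor_match(table, c):
                severe = severe or r.chd_severe
                septal = septal or r.chd_septal
                conotruncal = conotruncal or r.chd_conotruncal
    return ChdFlags(severe=severe, septal=septal, conotruncal=conotruncal)


def _data_path(name: str):
    return resources.files("ca_ascertain").joinpath("data", name)


def default_subgroup_table() -> SubgroupTable:
    return SubgroupTable.from_tsv(
        _data_path("subgroup_table.tsv"), _data_path("minor_anomalies.tsv")
    )


def default_code_map() -> CodeMapTable:
    return CodeMapTable.from_tsv(_data_path("code_map.tsv"))


def default_read_table() -> pd.DataFrame:
    """Read-code list: columns read_code, term, snomed_code."""
    return pd.read_csv(_data_path("read_codes.tsv"), sep="\t", dtype=str)


def load_read_code_filter(path=None) -> frozenset[str]:
    df = default_read_table() if path is None else pd.read_csv(path, sep="\t", dtype=str)
    return frozenset(df["read_code"])
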