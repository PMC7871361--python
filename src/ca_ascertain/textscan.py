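"""Free-text case finding over questionnaire and record text.

Case reports written by parents or abstracted from paper records arrive as
free text ("born with spina biffida"). This module finds mentions of
congenital-anomaly key terms in such text using deterministic, auditable
word-boundary matching, and mechanises the iterative misspelling-expansion
procedure: a supplied dictionary of candidate misspelt variants is folded
into the search strategy until a fixed point is reached, emulating the
manual read-a-subsample-and-update loop used when such datasets are coded
by hand.

Fuzzy (edit-distance) matching is deliberately not used by default: exact
substring matching on normalised text keeps every hit reproducible and
traceable to a dictionary entry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

__all__ = [
    "SearchStrategy",
    "TextHit",
    "normalise",
    "search",
    "expand_strategy",
    "load_strategy",
    "load_variant_dictionary",
]

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalise(text: str) -> str:
    """Lower-case ``text``, collapse punctuation/whitespace runs to single
    spaces and strip the ends.

    Idempotent: ``normalise(normalise(x)) == normalise(x)``.
    """
    return _NON_ALNUM.sub(" ", str(text).lower()).strip()


class TextHit(NamedTuple):
    participant_id: str
    instrument_id: str
    term: str
    subgroup: str


@dataclass(frozen=True)
class SearchStrategy:
    """A set of canonical key phrases with misspelt variants and the
    anomaly subgroup (and ICD-10 code) each phrase points at.

    Invariants enforced at construction: every variant belongs to exactly
    one canonical term; every term has a target subgroup.
    """

    terms: frozenset[str]
    variants: dict[str, frozenset[str]]
    system_of_term: dict[str, str]
    icd10_of_term: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        missing = self.terms - self.system_of_term.keys()
        if missing:
            raise ValueError(f"terms without a target subgroup: {sorted(missing)}")
        owner: dict[str, str] = {}
        for term, vs in self.variants.items():
            if term not in self.terms:
                raise ValueError(f"variants listed for unknown term: {term!r}")
            for v in vs:
                if v in owner and owner[v] != term:
                    raise ValueError(
                        f"variant {v!r} maps to both {owner[v]!r} and {term!r}"
                    )
                owner[v] = term

    def patterns(self) -> list[tuple[str, str]]:
        """All (searchable phrase, canonical term) pairs, deterministic order."""
        out = [(t, t) for t in sorted(self.terms)]
        for term in sorted(self.variants):
            out.extend((v, term) for v in sorted(self.variants[term]))
        return out

    def with_variants(self, extra: dict[str, set[str]]) -> "SearchStrategy":
        merged = {t: set(vs) for t, vs in self.variants.items()}
        for term, vs in extra.items():
            merged.setdefault(term, set()).update(vs)
        return SearchStrategy(
            terms=self.terms,
            variants={t: frozenset(vs) for t, vs in merged.items()},
            system_of_term=dict(self.system_of_term),
            icd10_of_term=dict(self.icd10_of_term),
        )


def _contains_phrase(norm_text: str, phrase: str) -> bool:
    # word-boundary containment on already-normalised text
    return f" {phrase} " in f" {norm_text} "


def search(
    texts: Iterable[tuple[str, str, str]], strategy: SearchStrategy
) -> list[TextHit]:
    """Scan ``(participant_id, instrument_id, text)`` rows for strategy terms.

    One hit per (text row, canonical term): a variant match is reported
    under its canonical term. Output is sorted by
    (participant_id, instrument_id, term) and de-duplicated.
    """
    patterns = strategy.patterns()
    hits: set[TextHit] = set()
    for pid, instrument, text in texts:
        norm = normalise(text)
        if not norm:
            continue
        padded = f" {norm} "
        for phrase, term in patterns:
            if f" {phrase} " in padded:
                hits.add(
                    TextHit(str(pid), str(instrument), term, strategy.system_of_term[term])
                )
    return sorted(hits)


def expand_strategy(
    texts: Iterable[tuple[str, str, str]],
    strategy: SearchStrategy,
    variant_dictionary: dict[str, set[str]],
) -> SearchStrategy:
    """Grow the strategy with dictionary misspellings actually present in
    ``texts`` until a fixed point.

    The term set grows monotonically and is bounded by the dictionary, so
    the loop terminates in at most ``sum(len(v))`` iterations; re-running on
    the output is a no-op.
    """
    norm_texts = [f" {normalise(t)} " for _, _, t in texts]
    current = strategy
    while True:
        known = {v for vs in current.variants.values() for v in vs} | set(current.terms)
        additions: dict[str, set[str]] = {}
        for term, candidates in variant_dictionary.items():
            if term not in current.terms:
                continue
            for cand in candidates:
                c = normalise(cand)
                if c and c not in known and any(f" {c} " in nt for nt in norm_texts):
                    additions.setdefault(term, set()).add(c)
        if not additions:
            return current
        current = current.with_variants(additions)


def load_strategy(path) -> SearchStrategy:
    """Read a strategy TSV with columns: term, subgroup, icd10."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    terms = frozenset(normalise(t) for t in df["term"])
    return SearchStrategy(
        terms=terms,
        variants={},
        system_of_term={normalise(r.term): r.subgroup for r in df.itertuples()},
        icd10_of_term={normalise(r.term): r.icd10 for r in df.itertuples()},
    )


def load_variant_dictionary(path) -> dict[str, set[str]]:
    """Read a misspelling dictionary TSV with columns: term, variant."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(normalise(r.term), set()).add(normalise(r.variant))
    return out
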