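"""Summary statistics for the ascertained case set.

Covers the cohort's reporting surface: live-birth prevalence per 10,000 per
EUROCAT subgroup, the exact Venn partition of cases over the five sources,
cumulative age-at-first-diagnosis curves with small-cell disclosure
suppression, and the questionnaire validation statistic (how often
single-instrument vs multi-instrument questionnaire reports are confirmed
in primary care).

All printed rounding is round-half-up (the convention consistent with the
published arithmetic this package reproduces), implemented with decimal
arithmetic rather than banker's rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from . import codes as _codes
from .errors import DomainError

__all__ = [
    "round_half_up",
    "prevalence",
    "percent",
    "venn",
    "AgeCurve",
    "age_accrual",
    "questionnaire_validation",
    "prevalence_table",
    "chd_subtype_table",
    "eurocat_reference",
]

SUPPRESSION_THRESHOLD = 5
SUPPRESSED = "<5"


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    v = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return v


def prevalence(liveborn_cases: int, live_births: int) -> float:
    """Live-birth prevalence per 10,000, rounded half-up to one decimal."""
    if live_births <= 0:
        raise DomainError("live_births must be positive")
    if not (0 <= liveborn_cases <= live_births):
        raise DomainError("liveborn_cases must lie in [0, live_births]")
    return round_half_up(10_000 * liveborn_cases / live_births, 1)


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise DomainError("denominator must be positive")
    value = round_half_up(100 * numerator / denominator, decimals)
    return value


def _source_sets(case_records: pd.DataFrame) -> list[frozenset[str]]:
    return [
        frozenset(filter(None, str(s).split(";"))) for s in case_records["sources"]
    ]


def venn(
    case_records: pd.DataFrame,
    restrict_to_subgroup: str | None = None,
    sources: Sequence[str] | None = None,
) -> dict[frozenset, int]:
    """Exact-subset partition of cases by provenance.

    Returns a count for every non-empty subset of the source names (so the
    values sum to the number of cases). ``restrict_to_subgroup`` filters the
    case set first (e.g. "chd").
    """
    df = case_records
    if restrict_to_subgroup is not None:
        mask = df["subgroups"].apply(
            lambda s: restrict_to_subgroup in str(s).split(";")
        )
        df = df[mask]
    observed = _source_sets(df)
    if sources is None:
        from .cohort_synth import SOURCES as sources  # default universe

    partition: dict[frozenset, int] = {}
    for k in range(1, len(sources) + 1):
        for combo in combinations(sorted(sources), k):
            partition[frozenset(combo)] = 0
    for s in observed:
        partition[frozenset(s)] = partition.get(frozenset(s), 0) + 1
    return partition


@dataclass
class AgeCurve:
    """Per-bin and cumulative first-diagnosis counts with suppression flags.

    ``cutoffs`` [1, 5, 15, 20, 25] produce bins [0,1), [1,5), [5,15),
    [15,20) and [20, ...]; each case is binned once, at its first diagnosis.
    Counts below the suppression threshold (including, optionally, zero)
    render as "<5" for disclosure control; exact values remain available on
    the object for governed use.
    """

    cutoffs: list[float]
    counts: list[int]
    cumulative: list[int]
    suppressed: list[bool]

    def rendered(self) -> list[str]:
        return [SUPPRESSED if s else str(c) for c, s in zip(self.counts, self.suppressed)]


def age_accrual(
    case_records: pd.DataFrame,
    cutoffs: Sequence[float] = (1, 5, 15, 20, 25),
    suppression_threshold: int = SUPPRESSION_THRESHOLD,
) -> AgeCurve:
    """Bin cases by age at first diagnosis and accumulate.

    Cases with no recorded age are dropped; ages at or beyond the last
    cut-off fall into the final bin (the last extraction sweeps in slightly
    older diagnoses). Negative ages raise DomainError.
    """
    ages = [
        float(a)
        for a in case_records["first_diagnosis_age"]
        if a is not None and not pd.isna(a)
    ]
    if any(a < 0 for a in ages):
        raise DomainError("negative age at first diagnosis")
    cutoffs = list(cutoffs)
    counts = [0] * len(cutoffs)
    for a in ages:
        for i, c in enumerate(cutoffs):
            if a < c or i == len(cutoffs) - 1:
                counts[i] += 1
                break
    cumulative = []
    total = 0
    for c in counts:
        total += c
        cumulative.append(total)
    suppressed = [c < suppression_threshold for c in counts]
    return AgeCurve(cutoffs=cutoffs, counts=counts, cumulative=cumulative, suppressed=suppressed)


def questionnaire_validation(
    confirmed_ids: Iterable[str],
    possible_ids: Iterable[str],
    primary_care_ids: Iterable[str],
) -> tuple[float | None, float | None]:
    """Share of questionnaire reports that are also primary-care cases.

    Returns ``(pct_possible_in_pc, pct_confirmed_in_pc)`` as whole-number
    percentages; a percentage is None (undefined) when its group is empty.
    Multi-instrument (confirmed) reports are expected to validate more
    often than single-instrument (possible) ones.
    """
    pc = set(primary_care_ids)
    confirmed = set(confirmed_ids)
    possible = set(possible_ids)
    pct_possible = percent(len(possible & pc), len(possible), 0) if possible else None
    pct_confirmed = percent(len(confirmed & pc), len(confirmed), 0) if confirmed else None
    return pct_possible, pct_confirmed


def eurocat_reference() -> pd.DataFrame:
    """Static European-registry prevalence column, for report display only."""
    return pd.read_csv(
        resources.files("ca_ascertain").joinpath("data", "eurocat_reference.csv")
    )


def prevalence_table(
    case_records: pd.DataFrame,
    live_births: int,
    suppress: bool = True,
    suppression_threshold: int = SUPPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Per-subgroup totals, live-born counts and prevalence per 10,000.

    One row per reported subgroup plus the any-CA headline row. A child
    with anomalies in several systems contributes to each of those rows,
    once per row. With ``suppress`` the three numeric columns of rows whose
    total is below the threshold are masked "<5"; the EUROCAT reference
    column is joined for display.
    """
    subgroup_sets = [set(filter(None, str(s).split(";"))) for s in case_records["subgroups"]]
    live = case_records["live_born"].astype(int).to_numpy()
    rows = []
    for name in ("any_ca",) + tuple(_codes.TABLE2_SUBGROUPS):
        if name == "any_ca":
            member = [True] * len(subgroup_sets)
        else:
            member = [name in s for s in subgroup_sets]
        total = int(sum(member))
        liveborn = int(sum(l for m, l in zip(member, live) if m))
        rows.append(
            {
                "subgroup": name,
                "total_n": total,
                "liveborn_n": liveborn,
                "prevalence_per_10k": prevalence(liveborn, live_births),
            }
        )
    out = pd.DataFrame(rows).merge(eurocat_reference(), on="subgroup", how="left")
    if suppress:
        mask = out["total_n"] < suppression_threshold
        for col in ("total_n", "liveborn_n", "prevalence_per_10k"):
            out[col] = out[col].astype(object)
            out.loc[mask, col] = SUPPRESSED
    return out


def chd_subtype_table(case_records: pd.DataFrame, suppress: bool = True) -> pd.DataFrame:
    """Congenital-heart-disease subtype counts.

    Severe + non-severe partition the CHD cases, as do the three
    multiplicity categories (isolated / with other anomalies / syndromic,
    syndrome taking precedence).
    """
    chd = case_records[case_records["any_chd"] == 1]
    n = len(chd)
    rows = [
        ("severe_chd", int(chd["chd_severe"].sum())),
        ("non_severe_chd", int(n - chd["chd_severe"].sum())),
        ("any_septal_defect", int(chd["chd_septal"].sum())),
        ("conotruncal", int(chd["chd_conotruncal"].sum())),
        ("isolated_chd", int((chd["multiplicity"] == "isolated_chd").sum())),
        ("chd_with_other_ca", int((chd["multiplicity"] == "chd_with_other_ca").sum())),
        ("chd_with_syndrome", int((chd["multiplicity"] == "chd_with_syndrome").sum())),
        ("any_chd", n),
    ]
    out = pd.DataFrame(rows, columns=["chd_subtype", "n"])
    if suppress:
        out["n"] = out["n"].astype(object)
        out.loc[[isinstance(v, int) and v < SUPPRESSION_THRESHOLD for v in out["n"]], "n"] = SUPPRESSED
    return out


def plot_venn_cells(partition: dict[frozenset, int], path) -> None:
    """Bar chart of the non-empty Venn partition cells, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = sorted(
        ((k, v) for k, v in partition.items() if v > 0),
        key=lambda kv: (-kv[1], sorted(kv[0])),
    )
    labels = ["+".join(sorted(k)) for k, _ in cells]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.3 * len(cells))))
    ax.barh(range(len(cells)), [v for _, v in cells])
    ax.set_yticks(range(len(cells)), labels, fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("cases identified in exactly this source subset")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_age_accrual(curve: AgeCurve, path, suppress: bool = True) -> None:
    """Per-bin bars with the cumulative curve overlaid, saved to ``path``.

    With ``suppress``, bars below the disclosure threshold are drawn at zero
    height and annotated "<5"."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"<{c}" if i == 0 else f"{curve.cutoffs[i - 1]}-{c}" for i, c in enumerate(curve.cutoffs)]
    shown = [0 if (suppress and s) else c for c, s in zip(curve.counts, curve.suppressed)]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(shown)), shown)
    if suppress:
        for i, s in enumerate(curve.suppressed):
            if s:
                ax.annotate(SUPPRESSED, (i, 0), ha="center", va="bottom")
    ax.plot(range(len(shown)), curve.cumulative, "o-", color="black", label="cumulative")
    ax.set_xticks(range(len(shown)), labels)
    ax.set_xlabel("age at first diagnosis (years)")
    ax.set_ylabel("cases")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
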