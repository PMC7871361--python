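"""End-to-end ascertainment: five source tables in, case records out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ascertain as _ascertain
from . import codes as _codes
from . import cohort_synth as _synth
from . import epistats as _epistats
from . import integrate as _integrate
from . import textscan as _textscan

__all__ = ["PipelineResult", "run_pipeline", "load_sources"]


@dataclass
class PipelineResult:
    candidates: pd.DataFrame  # all per-source candidates (questionnaires: confirmed)
    possible: pd.DataFrame  # single-instrument questionnaire reports
    case_records: pd.DataFrame
    unmapped: pd.DataFrame
    strategy: _textscan.SearchStrategy
    per_source: dict = field(default_factory=dict)

    def case_ids(self) -> set[str]:
        return set(self.case_records["participant_id"])


def load_sources(datadir) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Read registry + the five source CSVs from a data directory."""
    datadir = Path(datadir)
    registry = pd.read_csv(datadir / "registry.csv", dtype={"participant_id": str})
    tables = {
        name: pd.read_csv(datadir / f"{name}.csv", dtype={"participant_id": str})
        for name in _synth.SOURCES
    }
    return registry, tables


def run_pipeline(
    registry: pd.DataFrame,
    tables: dict[str, pd.DataFrame],
    subgroup_table: _codes.SubgroupTable | None = None,
    code_map: _codes.CodeMapTable | None = None,
    read_filter: frozenset[str] | None = None,
    strategy: _textscan.SearchStrategy | None = None,
    variant_dictionary: dict[str, set[str]] | None = None,
    expand_misspellings: bool = True,
) -> PipelineResult:
    """Run extraction, misspelling expansion, consensus and integration.

    The search strategy is first expanded to a fixed point against all
    free-text fields using the misspelling dictionary, then applied by the
    text-based extractors (deaths, child health, questionnaires).
    """
    table = subgroup_table or _codes.default_subgroup_table()
    cmap = code_map or _codes.default_code_map()
    rfilter = read_filter or _codes.load_read_code_filter()
    strat = strategy or _synth.default_search_strategy()
    vdict = variant_dictionary if variant_dictionary is not None else _synth.default_variant_dictionary()

    if expand_misspellings and vdict:
        free_texts = [
            ("", "", t)
            for t in list(tables["deaths"].get("anomaly_text", pd.Series(dtype=str)).fillna(""))
            + list(tables["child_health"].get("diagnosis_text", pd.Series(dtype=str)).fillna(""))
            + list(tables["alspac_questionnaires"].get("text", pd.Series(dtype=str)).fillna(""))
        ]
        strat = _textscan.expand_strategy(free_texts, strat, vdict)

    pc, unmapped = _ascertain.extract_primary_care(tables["primary_care"], rfilter, cmap, table)
    card = _ascertain.extract_cardiology(tables["cardiology"], cmap, table)
    deaths = _ascertain.extract_deaths(tables["deaths"], strat, cmap, table)
    ch = _ascertain.extract_child_health(tables["child_health"], strat, cmap, table)
    q_confirmed, q_possible = _ascertain.extract_questionnaires(
        tables["alspac_questionnaires"], strat, table
    )

    per_source = {
        "primary_care": pc,
        "cardiology": card,
        "deaths": deaths,
        "child_health": ch,
        "alspac_questionnaires": q_confirmed,
    }
    nonempty = [df for df in per_source.values() if not df.empty]
    candidates = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=_ascertain.CANDIDATE_COLUMNS)
    )
    case_records = _integrate.integrate_cases(candidates, registry, table)
    return PipelineResult(
        candidates=candidates,
        possible=q_possible,
        case_records=case_records,
        unmapped=unmapped,
        strategy=strat,
        per_source=per_source,
    )


def write_outputs(result: PipelineResult, registry: pd.DataFrame, outdir, live_births: int | None = None, suppress: bool = True) -> dict[str, Path]:
    """Write case records, headline flags, possible-CA file and report tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if live_births is None:
        live_births = int(registry["live_born"].astype(int).sum())
    paths = {}

    def _w(name: str, df: pd.DataFrame):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, lineterminator="\n")
        paths[name] = p

    _w("case_records", result.case_records)
    _w("possible_ca", result.possible)
    _w("candidates", result.candidates)
    _w("unmapped_codes", result.unmapped)
    _w("headline_flags", _integrate.headline_flags(result.case_records, registry))
    _w("prevalence_table", _epistats.prevalence_table(result.case_records, live_births, suppress=suppress))
    _w("chd_subtypes", _epistats.chd_subtype_table(result.case_records, suppress=suppress))
    venn_rows = [
        {"sources": "+".join(sorted(k)), "n": v}
        for k, v in sorted(_epistats.venn(result.case_records).items(), key=lambda kv: sorted(kv[0]))
    ]
    _w("venn_any_ca", pd.DataFrame(venn_rows))
    return paths
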