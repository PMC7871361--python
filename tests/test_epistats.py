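"""Prevalence, percentages, Venn partitions, age curves, validation."""

import itertools
import random

import pandas as pd
import pytest

from ca_ascertain import epistats
from ca_ascertain.cohort_synth import SOURCES
from ca_ascertain.errors import DomainError


class TestRates:
    @pytest.mark.parametrize(
        "liveborn, denom, expected",
        [(119, 14791, 80.5), (196, 14791, 132.5), (0, 14791, 0.0), (44, 14791, 29.7)],
    )
    def test_prevalence_per_10k(self, liveborn, denom, expected):
        assert epistats.prevalence(liveborn, denom) == expected

    def test_prevalence_domain_errors(self):
        with pytest.raises(DomainError):
            epistats.prevalence(1, 0)
        with pytest.raises(DomainError):
            epistats.prevalence(5, 4)

    @pytest.mark.parametrize(
        "num, den, decimals, expected",
        [(151, 590, 1, 25.6), (35, 127, 0, 28), (64, 672, 1, 9.5), (1, 8, 0, 13)],
    )
    def test_percent_rounds_half_up(self, num, den, decimals, expected):
        assert epistats.percent(num, den, decimals) == expected

    def test_percent_zero_denominator(self):
        with pytest.raises(DomainError):
            epistats.percent(1, 0)

    def test_prevalence_monotone_in_cases(self):
        values = [epistats.prevalence(k, 14791) for k in range(0, 600, 25)]
        assert values == sorted(values)


def _records(source_sets, subgroups="chd", ages=None, live=1):
    n = len(source_sets)
    return pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "icd10_codes": "Q21.0",
            "subgroups": subgroups if isinstance(subgroups, list) else [subgroups] * n,
            "sources": [";".join(sorted(s)) for s in source_sets],
            "live_born": live,
            "first_diagnosis_age": ages if ages is not None else [0.0] * n,
            "any_chd": 1,
            "chd_severe": 0,
            "chd_septal": 1,
            "chd_conotruncal": 0,
            "multiplicity": "isolated_chd",
            "code_absent_only": 0,
        }
    )


class TestVenn:
    def test_single_case_single_cell(self):
        part = epistats.venn(_records([{"primary_care"}]))
        assert part[frozenset({"primary_care"})] == 1
        assert sum(part.values()) == 1
        assert len(part) == 2 ** len(SOURCES) - 1

    def test_every_subset_seeded_once(self):
        subsets = [
            set(c)
            for k in range(1, 6)
            for c in itertools.combinations(SOURCES, k)
        ]
        part = epistats.venn(_records(subsets))
        assert all(v == 1 for v in part.values())

    def test_partition_conserves_and_matches_brute_force(self):
        rng = random.Random(17)
        subsets = [
            set(rng.sample(SOURCES, rng.randint(1, 5))) for _ in range(500)
        ]
        records = _records(subsets)
        part = epistats.venn(records)
        assert sum(part.values()) == len(records)
        for combo, count in part.items():
            assert count == sum(1 for s in subsets if frozenset(s) == combo)

    def test_subgroup_restriction(self):
        records = _records([{"primary_care"}, {"deaths"}], subgroups=["chd", "limb"])
        part = epistats.venn(records, restrict_to_subgroup="chd")
        assert sum(part.values()) == 1 and part[frozenset({"primary_care"})] == 1


class TestAgeCurve:
    def test_first_diagnosis_binned_once(self):
        # integrated records already carry the minimum age (3y here, not 7y)
        curve = epistats.age_accrual(_records([{"primary_care"}], ages=[3.0]))
        assert curve.counts == [0, 1, 0, 0, 0]
        assert curve.cumulative[-1] == 1

    def test_counts_below_threshold_render_suppressed(self):
        ages = [0.5] * 3 + [2.0] * 6
        curve = epistats.age_accrual(_records([{"primary_care"}] * 9, ages=ages))
        assert curve.counts == [3, 6, 0, 0, 0]
        assert curve.rendered() == ["<5", "6", "<5", "<5", "<5"]

    def test_cumulative_reaches_total(self, default_run):
        _, _, _, _, result = default_run
        with_age = result.case_records.dropna(subset=["first_diagnosis_age"])
        curve = epistats.age_accrual(result.case_records)
        assert curve.cumulative[-1] == len(with_age)
        assert curve.cumulative == sorted(curve.cumulative)

    def test_negative_age_rejected(self):
        with pytest.raises(DomainError):
            epistats.age_accrual(_records([{"deaths"}], ages=[-0.1]))

    def test_age_beyond_last_cutoff_in_final_bin(self):
        curve = epistats.age_accrual(_records([{"primary_care"}], ages=[25.7]))
        assert curve.counts[-1] == 1


class TestValidation:
    def test_half_in_primary_care(self):
        pct_possible, _ = epistats.questionnaire_validation(
            confirmed_ids=[], possible_ids=["A", "B"], primary_care_ids=["A"]
        )
        assert pct_possible == 50

    def test_empty_group_signals_undefined(self):
        pct_possible, pct_confirmed = epistats.questionnaire_validation(
            confirmed_ids=[], possible_ids=["A"], primary_care_ids=[]
        )
        assert pct_confirmed is None and pct_possible == 0


class TestReportTables:
    def test_prevalence_table_identities(self, default_run):
        _, registry, _, _, result = default_run
        live_births = int(registry["live_born"].sum())
        tab = epistats.prevalence_table(result.case_records, live_births, suppress=False)
        any_ca = tab[tab["subgroup"] == "any_ca"].iloc[0]
        assert any_ca["total_n"] == len(result.case_records)
        for r in tab.itertuples():
            assert r.liveborn_n <= r.total_n
            assert r.total_n <= any_ca["total_n"]
            assert r.prevalence_per_10k == epistats.prevalence(r.liveborn_n, live_births)

    def test_small_cells_masked_when_suppressing(self):
        records = _records([{"primary_care"}] * 3)  # 3 CHD cases only
        tab = epistats.prevalence_table(records, 1000, suppress=True)
        chd = tab[tab["subgroup"] == "chd"].iloc[0]
        assert chd["total_n"] == "<5" and chd["prevalence_per_10k"] == "<5"

    def test_chd_subtype_partition(self, default_run):
        _, _, _, _, result = default_run
        tab = epistats.chd_subtype_table(result.case_records, suppress=False).set_index("chd_subtype")["n"]
        assert tab["severe_chd"] + tab["non_severe_chd"] == tab["any_chd"]
        assert (
            tab["isolated_chd"] + tab["chd_with_other_ca"] + tab["chd_with_syndrome"]
            == tab["any_chd"]
        )


def test_plots_render_to_svg(tmp_path, default_run):
    _, _, _, _, result = default_run
    epistats.plot_venn_cells(epistats.venn(result.case_records), tmp_path / "venn.svg")
    epistats.plot_age_accrual(epistats.age_accrual(result.case_records), tmp_path / "age.svg")
    assert (tmp_path / "venn.svg").stat().st_size > 0
    assert (tmp_path / "age.svg").stat().st_size > 0
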