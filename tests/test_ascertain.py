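"""Per-source extraction rules on constructed fixtures."""

import pandas as pd
import pytest

from ca_ascertain import ascertain, codes
from ca_ascertain.errors import CodeValidationError


@pytest.fixture(scope="module")
def read_filter():
    return codes.load_read_code_filter()


def _pc_events(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "event_age", "read_code", "snomed_code", "term_text"]
    )


class TestPrimaryCare:
    def test_single_ca_event_yields_candidate(self, read_filter, code_map, subgroup_table):
        events = _pc_events([("p1", 2.5, "P540.", "30288003", "ventricular septal defect")])
        cases, unmapped = ascertain.extract_primary_care(events, read_filter, code_map, subgroup_table)
        assert len(cases) == 1 and unmapped.empty
        row = cases.iloc[0]
        assert row.source == "primary_care"
        assert row.icd10_codes == "Q21.0" and row.subgroups == "chd"
        assert row.first_diagnosis_age == 2.5

    def test_non_filter_codes_yield_nothing(self, read_filter, code_map, subgroup_table):
        events = _pc_events([("p1", 1.0, "H33..", "195967001", "asthma")])
        cases, _ = ascertain.extract_primary_care(events, read_filter, code_map, subgroup_table)
        assert cases.empty

    def test_first_diagnosis_age_is_minimum(self, read_filter, code_map, subgroup_table):
        events = _pc_events(
            [
                ("p1", 7.0, "P540.", "30288003", "ventricular septal defect"),
                ("p1", 3.0, "P10..", "67531005", "spina bifida"),
            ]
        )
        cases, _ = ascertain.extract_primary_care(events, read_filter, code_map, subgroup_table)
        assert len(cases) == 1
        assert cases.iloc[0].first_diagnosis_age == 3.0
        assert cases.iloc[0].subgroups == "chd;nervous_system"

    def test_unmapped_snomed_goes_to_side_channel(self, read_filter, code_map, subgroup_table):
        events = _pc_events([("p1", 1.0, "P540.", "999999999", "mystery")])
        cases, unmapped = ascertain.extract_primary_care(events, read_filter, code_map, subgroup_table)
        assert cases.empty
        assert list(unmapped["snomed_code"]) == ["999999999"]


def _card_events(rows):
    return pd.DataFrame(rows, columns=["participant_id", "event_age", "icd10_code", "diagnosis_text"])


class TestCardiology:
    def test_coded_chd_event(self, code_map, subgroup_table):
        cases = ascertain.extract_cardiology(
            _card_events([("p1", 0.5, "Q21.0", "")]), code_map, subgroup_table
        )
        assert len(cases) == 1 and cases.iloc[0].subgroups == "chd"

    @pytest.mark.parametrize(
        "text", ["benign murmur", "chest pain", "family history of heart condition"]
    )
    def test_distractor_diagnoses_rejected(self, code_map, subgroup_table, text):
        cases = ascertain.extract_cardiology(
            _card_events([("p1", 1.0, "", text)]), code_map, subgroup_table
        )
        assert cases.empty

    def test_diagnosis_absent_event_discarded(self, code_map, subgroup_table):
        cases = ascertain.extract_cardiology(
            _card_events([("p1", 1.0, "", "")]), code_map, subgroup_table
        )
        assert cases.empty

    def test_text_only_diagnosis_best_matched(self, code_map, subgroup_table):
        cases = ascertain.extract_cardiology(
            _card_events([("p1", 1.0, "", "tetralogy of fallot")]), code_map, subgroup_table
        )
        assert len(cases) == 1 and cases.iloc[0].icd10_codes == "Q21.3"


def _death_records(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "fetal_death",
            "death_age",
            "system_category",
            "wigglesworth_class",
            "anomaly_text",
        ],
    )


class TestDeaths:
    def test_fetal_anomaly_text_yields_not_live_born_case(self, strategy, code_map, subgroup_table):
        recs = _death_records([("p1", 1, "", "nervous_system", "antepartum", "anencephaly")])
        cases = ascertain.extract_deaths(recs, strategy, code_map, subgroup_table)
        assert len(cases) == 1
        row = cases.iloc[0]
        assert row.subgroups == "nervous_system"
        assert row.not_live_born == 1 and row.first_diagnosis_age == 0.0

    def test_death_without_anomaly_text_is_not_a_case(self, strategy, code_map, subgroup_table):
        recs = _death_records([("p1", 0, 0.3, "none", "other", "")])
        assert ascertain.extract_deaths(recs, strategy, code_map, subgroup_table).empty

    def test_anomaly_counts_even_if_not_cause_of_death(self, strategy, code_map, subgroup_table):
        # cause category says preterm; anomaly text still makes the case
        recs = _death_records([("p1", 0, 0.1, "none", "preterm", "born with cleft palate")])
        cases = ascertain.extract_deaths(recs, strategy, code_map, subgroup_table)
        assert len(cases) == 1 and cases.iloc[0].subgroups == "orofacial_clefts"
        assert cases.iloc[0].first_diagnosis_age == pytest.approx(0.1)


def _ch_records(rows):
    return pd.DataFrame(rows, columns=["participant_id", "category", "diagnosis_text", "diagnosis_age"])


class TestChildHealth:
    def test_text_assigns_code(self, strategy, code_map, subgroup_table):
        recs = _ch_records([("p1", "limb", "club foot", 0.5)])
        cases = ascertain.extract_child_health(recs, strategy, code_map, subgroup_table)
        assert cases.iloc[0].icd10_codes == "Q66.0" and cases.iloc[0].code_absent == 0

    def test_textless_record_is_code_absent_subgroup_case(self, strategy, code_map, subgroup_table):
        recs = _ch_records([("p1", "urinary", "", 1.0)])
        cases = ascertain.extract_child_health(recs, strategy, code_map, subgroup_table)
        row = cases.iloc[0]
        assert row.code_absent == 1 and row.subgroups == "urinary" and row.icd10_codes == ""

    def test_unknown_category_raises(self, strategy, code_map, subgroup_table):
        recs = _ch_records([("p1", "teeth", "", 1.0)])
        with pytest.raises(CodeValidationError, match="teeth"):
            ascertain.extract_child_health(recs, strategy, code_map, subgroup_table)


def _q_texts(rows):
    return pd.DataFrame(rows, columns=["participant_id", "instrument_id", "instrument_age", "text"])


class TestQuestionnaireConsensus:
    def test_two_instruments_same_subgroup_confirmed(self, strategy, subgroup_table):
        texts = _q_texts(
            [
                ("p1", "delivery_abstraction", 0.0, "born with a heart defect"),
                ("p1", "cq03", 1.25, "hole in the heart diagnosed at hospital"),
            ]
        )
        confirmed, possible = ascertain.extract_questionnaires(texts, strategy, subgroup_table)
        assert list(confirmed["participant_id"]) == ["p1"] and possible.empty
        assert confirmed.iloc[0].subgroups == "chd"
        assert confirmed.iloc[0].first_diagnosis_age == 0.0
        assert set(confirmed.iloc[0].instruments.split(";")) == {"delivery_abstraction", "cq03"}

    def test_single_instrument_is_possible_only(self, strategy, subgroup_table):
        texts = _q_texts([("p1", "cq05", 2.0, "has a heart defect")])
        confirmed, possible = ascertain.extract_questionnaires(texts, strategy, subgroup_table)
        assert confirmed.empty and list(possible["participant_id"]) == ["p1"]

    def test_cross_subgroup_mentions_do_not_confirm(self, strategy, subgroup_table):
        # consensus is at organ/system level: one CHD + one limb mention
        texts = _q_texts(
            [
                ("p1", "cq01", 0.1, "heart defect"),
                ("p1", "cq02", 0.5, "club foot"),
            ]
        )
        confirmed, possible = ascertain.extract_questionnaires(texts, strategy, subgroup_table)
        assert confirmed.empty
        assert len(possible) == 1  # one participant, two possible subgroups
        assert set(possible.iloc[0].subgroups.split(";")) == {"chd", "limb"}

    def test_same_instrument_twice_does_not_confirm(self, strategy, subgroup_table):
        texts = _q_texts(
            [
                ("p1", "cq01", 0.1, "heart defect"),
                ("p1", "cq01", 0.1, "hole in the heart"),
            ]
        )
        confirmed, possible = ascertain.extract_questionnaires(texts, strategy, subgroup_table)
        assert confirmed.empty and len(possible) == 1

    def test_confirmed_and_possible_disjoint_per_subgroup(self, default_run):
        _, _, _, _, result = default_run
        confirmed = result.per_source["alspac_questionnaires"]
        pairs_c = {
            (r.participant_id, s)
            for r in confirmed.itertuples()
            for s in r.subgroups.split(";")
        }
        pairs_p = {
            (r.participant_id, s)
            for r in result.possible.itertuples()
            for s in r.subgroups.split(";")
        }
        assert pairs_c.isdisjoint(pairs_p)


def test_perfect_observation_recovers_ground_truth_small():
    """All sensitivities 1, no noise: pipeline output equals ground truth."""
    from ca_ascertain import cohort_synth as cs, pipeline as pl

    cfg = cs.SynthConfig(
        seed=2,
        n_fetuses=2000,
        source_sensitivity={k: 1.0 for k in cs._DEFAULT_SENSITIVITY},
        questionnaire_instrument_sensitivity=1.0,
        false_positive_text_rate=0.0,
        misspelling_rate=0.0,
    )
    registry, truth = cs.generate_cohort(cfg)
    result = pl.run_pipeline(registry, cs.emit_sources(registry, truth, cfg))
    assert result.case_ids() == set(truth["participant_id"])
    expected = dict(zip(truth["participant_id"], truth["true_subgroups"]))
    for r in result.case_records.itertuples():
        assert r.subgroups == expected[r.participant_id]
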