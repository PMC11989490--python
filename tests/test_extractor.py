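"""Extraction: section targeting, negation handling, units, AF flags, ATC."""

import logging

import pytest

from afdebut.extractor import detect_af_flags, extract, load_schema, map_medication
from afdebut.sectioner import segment
from afdebut.types import SectionLabel


def run_extract(text, es_schema, es_lexicon, es_rules):
    sectioned = segment(text, es_lexicon, "r1")
    return extract(sectioned, text, es_schema, es_rules)


def run_flags(text, es_schema, es_lexicon, es_rules):
    sectioned = segment(text, es_lexicon, "r1")
    return detect_af_flags(sectioned, text, es_schema.af, es_rules)


def test_lab_value_in_complementary_tests(es_schema, es_lexicon, es_rules):
    text = "PRUEBAS COMPLEMENTARIAS\nCreatinina 1.2 mg/dl."
    rv = run_extract(text, es_schema, es_lexicon, es_rules)
    assert rv.values["creatinine"] == pytest.approx(1.2)


def test_lab_value_outside_target_section_is_missing(es_schema, es_lexicon, es_rules):
    text = "ANTECEDENTES PERSONALES\nCreatinina 1.2 mg/dl."
    rv = run_extract(text, es_schema, es_lexicon, es_rules)
    assert "creatinine" not in rv.values


def test_unit_conversion_to_canonical(es_schema, es_lexicon, es_rules):
    text = "PRUEBAS COMPLEMENTARIAS\nCreatinina 106 umol/l."
    rv = run_extract(text, es_schema, es_lexicon, es_rules)
    assert rv.values["creatinine"] == pytest.approx(1.2, rel=0.01)


def test_negated_disease_is_explicit_false(es_schema, es_lexicon, es_rules):
    text = "DIAGNOSTICO\nno diabetes."
    rv = run_extract(text, es_schema, es_lexicon, es_rules)
    assert rv.values["diabetes"] is False


def test_affirmed_beats_negated_in_same_report(es_schema, es_lexicon, es_rules):
    text = "ANTECEDENTES PERSONALES\nNiega diabetes.\nDiabetes mellitus tipo 2."
    rv = run_extract(text, es_schema, es_lexicon, es_rules)
    assert rv.values["diabetes"] is True


def test_accent_folding_in_patterns(es_schema, es_lexicon, es_rules):
    text = "ANTECEDENTES PERSONALES\nHipertensión arterial en tratamiento."
    rv = run_extract(text, es_schema, es_lexicon, es_rules)
    assert rv.values["hypertension"] is True


@pytest.mark.parametrize("text,expected", [
    ("ANTECEDENTES PERSONALES\nFibrilación auricular conocida.", (False, True)),
    ("DIAGNOSTICO\nfibrilación auricular de novo.", (True, False)),
    ("DIAGNOSTICO\nno fibrilación auricular.", (False, False)),
    # bare AF in Diagnosis + prior history in the same report: not new onset
    ("ANTECEDENTES PERSONALES\nFA conocida.\nDIAGNOSTICO\nFibrilación auricular.",
     (False, True)),
    # bare AF in Diagnosis, no prior mention anywhere: counts as onset
    ("DIAGNOSTICO\nFibrilación auricular.", (True, False)),
    # onset-qualified mention wins even with prior history present
    ("ANTECEDENTES PERSONALES\nFA conocida.\nDIAGNOSTICO\nDebut de fibrilación auricular.",
     (True, True)),
    # AF on the ECG line lives outside the flag sections
    ("PRUEBAS COMPLEMENTARIAS\nECG: fibrilación auricular.", (False, False)),
])
def test_af_flag_assignment(es_schema, es_lexicon, es_rules, text, expected):
    assert run_flags(text, es_schema, es_lexicon, es_rules) == expected


def test_medication_mapping_direct_and_folded(es_schema):
    atc = es_schema.spec("anticoagulant").atc_map
    assert map_medication("apixaban", atc) == "B01AF02"
    assert map_medication("Apixabán 5 mg", atc) == "B01AF02"


def test_medication_longest_match():
    atc = {"warfarina": "B01AA03", "warfa": "XXX"}
    assert map_medication("warfarina 5 mg", atc) == "B01AA03"


def test_unmapped_medication_warns_and_returns_missing(es_schema, caplog):
    atc = es_schema.spec("anticoagulant").atc_map
    with caplog.at_level(logging.WARNING):
        assert map_medication("drugX", atc) is None
    assert "unmapped" in caplog.text
    with pytest.raises(ValueError):
        map_medication("apixaban", {})


def test_unparseable_numeric_dropped_with_warning(es_lexicon, es_rules, caplog):
    schema = load_schema({
        "af": {"patterns": ["fibrilacion auricular"], "onset_qualifiers": ["de novo"]},
        "variables": [{
            "variable_id": "creatinine", "value_type": "numeric",
            "variable_class": "lab", "target_sections": ["ComplementaryTests"],
            "unit_factors": {"mg/dl": 1.0},
            "patterns": [r"creatinina\s*(?P<value>\S+)"],
        }],
    })
    text = "PRUEBAS COMPLEMENTARIAS\nCreatinina pendiente."
    with caplog.at_level(logging.WARNING):
        rv = extract(segment(text, es_lexicon, "r"), text, schema, es_rules)
    assert "creatinine" not in rv.values
    assert "unparseable" in caplog.text


def test_invalid_schema_rejected():
    base = {"af": {"patterns": ["x"], "onset_qualifiers": ["y"]}}
    with pytest.raises(ValueError):
        load_schema(base | {"variables": [{
            "variable_id": "v", "value_type": "numeric", "variable_class": "lab",
            "target_sections": ["ComplementaryTests"], "patterns": ["no value group"],
        }]})
    with pytest.raises(ValueError):
        load_schema(base | {"variables": [{
            "variable_id": "v", "value_type": "medication", "variable_class": "medication",
            "target_sections": ["Treatment"], "patterns": ["drug"],
        }]})


def test_mentions_confined_to_target_sections(noisy_corpus, noisy_vectors,
                                              es_schema, es_lexicon):
    _, reports, _, _ = noisy_corpus
    by_id = {r.report_id: r for r in reports}
    for rv in noisy_vectors:
        sectioned = segment(by_id[rv.report_id].text, es_lexicon, rv.report_id)
        for m in rv.mentions:
            spec = es_schema.spec(m.variable_id)
            assert m.section in spec.target_sections
            assert any(s.label is m.section and s.start <= m.start and m.end <= s.end
                       for s in sectioned.spans)


def test_negated_gold_mentions_never_extracted_positive(noisy_corpus, noisy_vectors):
    """Negation soundness on a corpus with negation noise."""
    _, _, _, gold = noisy_corpus
    extracted = {rv.report_id: rv for rv in noisy_vectors}
    negated_cells = 0
    for rid, g in gold.reports.items():
        for m in g.mentions:
            if m.negated:
                negated_cells += 1
                assert extracted[rid].values.get(m.variable_id) is not True
    assert negated_cells > 20  # the corpus actually exercises negation


def test_zero_noise_round_trip_is_exact(zero_noise_corpus, zero_noise_vectors):
    _, reports, _, gold = zero_noise_corpus
    for rv in zero_noise_vectors:
        g = gold.reports[rv.report_id]
        assert rv.values == g.values
        assert rv.af_new_onset == g.af_new_onset
        assert rv.af_prior_history == g.af_prior_history
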