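import json
import re

import pytest

from evallr import (
    CoARecord,
    EvalConfig,
    EvidenceCondition,
    Finding,
    ReferenceSummary,
    ValidationError,
    check_disclosure,
    evaluate,
    generate_fixture_coa,
    read_coa,
    render_report,
)
from evallr.reporting import POSTERIOR_DENYLIST

# ---------------------------------------------------------------------------
# CoA reading


def test_read_coa_parses_the_diastase_row(diastase_csv):
    records, issues = read_coa(diastase_csv)
    assert issues == []
    (rec,) = records
    assert rec.finding.parameter == "diastase activity"
    assert rec.finding.value == 4.4
    assert rec.finding.units == "DN"
    assert rec.finding.condition.direction == "le"
    assert rec.finding.condition.threshold == 8.0
    assert rec.finding.condition_met
    assert rec.reference == ReferenceSummary(
        n=20000, k=1600, population="bee-keeper", source="Bogdanov et al. 1999"
    )


def test_read_coa_empty_file_warns_and_returns_nothing(tmp_path, caplog):
    path = tmp_path / "empty.csv"
    path.write_text("")
    with caplog.at_level("WARNING", logger="evallr"):
        records, issues = read_coa(path)
    assert records == [] and issues == []
    assert any("empty" in r.message for r in caplog.records)


def test_read_coa_collects_bad_rows_with_line_numbers(tmp_path):
    header = (
        "parameter,mode,value,units,lod,loq,mu,condition_direction,"
        "condition_threshold,ref_n,ref_k,ref_population,ref_source\n"
    )
    rows = (
        "good,quantitative,4.4,DN,,,,le,8,100,10,pop,src\n"
        "bad lod,quantitative,4.4,DN,9,5,,le,8,,,,\n"       # LoD > LoQ
        "bad count,quantitative,4.4,DN,,,,le,8,10,20,,\n"   # k > n
    )
    path = tmp_path / "coa.csv"
    path.write_text(header + rows)
    records, issues = read_coa(path)
    assert len(records) == 1
    assert [i.row for i in issues] == [3, 4]
    assert "LoD" in issues[0].message


def test_read_coa_missing_column_is_fatal(tmp_path):
    path = tmp_path / "coa.csv"
    path.write_text("parameter,mode\nx,quantitative\n")
    with pytest.raises(ValidationError, match="missing required columns"):
        read_coa(path)


def test_read_coa_json_round_trip(tmp_path, diastase_record):
    path = tmp_path / "coa.json"
    path.write_text(json.dumps({"records": [diastase_record.to_dict()]}))
    records, issues = read_coa(path, format="json")
    assert issues == []
    assert records == [diastase_record]


# ---------------------------------------------------------------------------
# disclosure audit


def qualitative_caramel(loq=None):
    return CoARecord(finding=Finding(
        parameter="caramel E150c/d", mode="qualitative",
        condition=EvidenceCondition(direction="detected"),
        detected=True, loq=loq,
    ))


def test_detected_without_loq_fails_disclosure():
    checklist = check_disclosure([qualitative_caramel(loq=None)])
    flags = checklist.per_finding["caramel E150c/d"]
    assert flags["lod_or_loq_reported"] is False
    assert not checklist.complete


def test_fully_disclosed_finding_passes(diastase_record):
    checklist = check_disclosure([diastase_record], strength_assessed={"diastase activity": True})
    flags = checklist.per_finding["diastase activity"]
    assert flags == {
        "quantitative_value_reported": True,
        "lod_or_loq_reported": True,
        "mu_reported": True,
        "reference_dataset_cited": True,
        "strength_assessed": True,
    }


def test_uncited_reference_fails_citation_flag(diastase_record):
    rec = CoARecord(
        finding=diastase_record.finding,
        reference=ReferenceSummary(n=20000, k=1600, population="bee-keeper", source=""),
    )
    checklist = check_disclosure([rec])
    assert checklist.per_finding["diastase activity"]["reference_dataset_cited"] is False


def test_method_acceptability_defaults_to_explicit_false(diastase_record):
    checklist = check_disclosure([diastase_record])
    assert checklist.method_acceptability == {
        "tested": False, "peer_reviewed": False,
        "error_rate_known": False, "generally_accepted": False,
    }


# ---------------------------------------------------------------------------
# evaluation pipeline


def test_diastase_evaluation_reproduces_the_worked_example(diastase_record):
    report = evaluate([diastase_record])
    (ev,) = report.findings
    assert ev.lr.value == 12.5
    assert ev.probability.p == 0.08
    assert ev.downgraded is True
    assert ev.label == "Slight or limited support"  # one band below moderate
    assert ev.supported == "Hp"
    assert report.badge == "evaluative"


def test_three_asserted_independent_findings_combine_to_125():
    records = [
        CoARecord(finding=Finding(
            parameter=f"marker_{i}", mode="qualitative",
            condition=EvidenceCondition(direction="detected"),
            detected=True, loq=5.0,
        ))
        for i in range(3)
    ]
    config = EvalConfig(
        scale="literature",
        asserted={f"marker_{i}": {"p": 0.2, "justification": "panel experience"} for i in range(3)},
    )
    report = evaluate(records, config)
    assert all(ev.lr.value == 5.0 for ev in report.findings)
    assert report.combined.value == 125
    assert report.combined.independence_assumed
    # 125 sits just above the 100 demarcation: conservatively one band lower
    assert report.combined_downgraded is True
    assert report.combined_label == "Moderate support"


def test_unmet_condition_is_inconclusive():
    rec = CoARecord(
        finding=Finding(
            parameter="diastase activity", mode="quantitative",
            condition=EvidenceCondition(direction="le", threshold=8.0, units="DN"),
            value=12.0, units="DN",
        ),
        reference=ReferenceSummary(n=20000, k=1600, source="x"),
    )
    report = evaluate([rec])
    (ev,) = report.findings
    assert ev.condition_met is False
    assert ev.lr.value == 1.0
    assert ev.label == "Null"
    assert report.combined.value == 1.0


def test_finding_without_probability_forces_intelligence_badge(diastase_record):
    orphan = CoARecord(finding=Finding(
        parameter="psicose", mode="qualitative",
        condition=EvidenceCondition(direction="detected"), detected=True,
    ))
    report = evaluate([diastase_record, orphan])
    assert report.badge == "intelligence_investigative_technical"
    psicose = next(e for e in report.findings if e.parameter == "psicose")
    assert not psicose.evaluated
    assert psicose.lr is None
    # the evaluated finding still carries its strength
    assert next(e for e in report.findings if e.parameter == "diastase activity").lr.value == 12.5


def test_no_findings_yields_intelligence_badge():
    report = evaluate([])
    assert report.badge == "intelligence_investigative_technical"
    assert report.combined is None


def test_correlation_groups_flow_from_config():
    records = [
        CoARecord(finding=Finding(
            parameter=p, mode="qualitative",
            condition=EvidenceCondition(direction="detected"), detected=True, loq=1.0,
        ))
        for p in ("a", "b")
    ]
    config = EvalConfig(
        groups=[["a", "b"]],
        asserted={
            "a": {"p": 1 / 7, "justification": "x"},
            "b": {"p": 1 / 3, "justification": "x"},
        },
    )
    report = evaluate(records, config)
    assert report.combined.value == pytest.approx(7.0)
    assert not report.combined.independence_assumed


# ---------------------------------------------------------------------------
# rendering


def test_render_is_deterministic_and_uses_conditional_phrasing(diastase_record):
    report = evaluate([diastase_record])
    text1 = render_report(report, format="markdown")
    text2 = render_report(report, format="markdown")
    assert text1 == text2  # byte-identical
    assert "12.5 times more likely if [" in text1
    assert "] than if [" in text1
    assert "ENFSI" in text1


def test_rendered_text_never_matches_posterior_denylist(diastase_record):
    report = evaluate([diastase_record])
    for fmt in ("markdown", "json"):
        text = render_report(report, format=fmt)
        for pattern in POSTERIOR_DENYLIST:
            assert not re.search(pattern, text, flags=re.IGNORECASE)


def test_json_rendering_is_schema_stable(diastase_record):
    report = evaluate([diastase_record])
    doc = json.loads(render_report(report, format="json"))
    assert set(doc) == {
        "findings", "combined", "combined_label", "combined_downgraded",
        "checklist", "badge", "scale_name", "conservative_margin",
        "sig_figs", "narrative",
    }
    assert doc["findings"][0]["lr"]["value"] == 12.5


def test_empty_report_renders_minimally():
    text = render_report(evaluate([]), format="markdown")
    assert "No findings could be combined" in text
    assert "intelligence / investigative / technical" in text


def test_verbal_label_always_cited_with_lr_and_scale(diastase_record):
    text = render_report(evaluate([diastase_record]))
    assert "Slight or limited support (likelihood ratio 12.5, ENFSI scale)" in text


# ---------------------------------------------------------------------------
# fixture generation


def test_fixture_is_deterministic(tmp_path):
    p1, t1 = generate_fixture_coa(1, directory=tmp_path / "a")
    p2, t2 = generate_fixture_coa(1, directory=tmp_path / "b")
    assert p1.read_bytes() == p2.read_bytes()
    assert t1 == t2


def test_single_adulterated_marker_yields_lr_10(tmp_path):
    path, truth = generate_fixture_coa(
        1, n_parameters=1, adulterated=True, prevalence_range=(0.1, 0.1), directory=tmp_path
    )
    records, issues = read_coa(path)
    assert issues == []
    report = evaluate(records)
    (ev,) = report.findings
    assert ev.lr.value == 10.0
    assert truth["parameters"][0]["prevalence"] == 0.1


def test_adulterated_fixture_meets_all_conditions(tmp_path):
    _, truth = generate_fixture_coa(5, n_parameters=4, adulterated=True, directory=tmp_path)
    assert all(p["condition_met"] for p in truth["parameters"])


def test_genuine_fixtures_are_mostly_inconclusive(tmp_path):
    """Over many seeds, genuine CoAs evaluate to combined LR 1 at about the
    closed-form rate prod(1 - prevalence) ~ 0.9^3, and the combined LR always
    matches the ground-truth record."""
    null_count = 0
    for seed in range(100):
        path, truth = generate_fixture_coa(seed, directory=tmp_path / str(seed))
        records, issues = read_coa(path)
        assert issues == []
        report = evaluate(records)
        assert report.combined.value == pytest.approx(truth["expected_combined_lr"], rel=1e-9)
        if report.combined.value == 1.0:
            null_count += 1
    expected = 0.9 ** 3  # mean prevalence 0.1 per marker, three markers
    assert abs(null_count / 100 - expected) <= 3 * (expected * (1 - expected) / 100) ** 0.5


def test_end_to_end_pipeline_is_deterministic(tmp_path):
    path, _ = generate_fixture_coa(3, adulterated=True, directory=tmp_path)
    outputs = set()
    for _ in range(2):
        records, _issues = read_coa(path)
        outputs.add(render_report(evaluate(records), format="markdown"))
        outputs.add(render_report(evaluate(records), format="json"))
    assert len(outputs) == 2  # one markdown and one json, each byte-stable


def test_badge_rule_on_generated_fixtures(tmp_path):
    """Every fixture evaluates fully (references always attached), so the
    report is evaluative; dropping a reference flips the badge."""
    for seed in (0, 1, 2):
        path, _ = generate_fixture_coa(seed, directory=tmp_path / str(seed))
        records, _ = read_coa(path)
        assert evaluate(records).badge == "evaluative"
        # strip the reference from one met finding, if any is met
        stripped = [CoARecord(finding=r.finding, reference=None) for r in records]
        report = evaluate(stripped)
        if any(r.finding.condition_met for r in records):
            assert report.badge == "intelligence_investigative_technical"
        else:
            assert report.badge == "evaluative"
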