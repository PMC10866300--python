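"""Process compatibility, role mapping, factors and estimation modes."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emitra import (
    Basis,
    CatalystClass,
    EmissionRecord,
    EstimationMode,
    FactorRule,
    Medium,
    Participant,
    ProcessRecord,
    PropertyName,
    ReadAcrossFactor,
    Role,
    audit_estimate,
    check_process_compatibility,
    compute_factors,
    estimate_average,
    estimate_closest,
    estimate_conservative,
    estimate_pooled,
    estimate_trend,
    map_species_roles,
    overall_factor,
)
from emitra.datasets import SeriesSpec, TrendLaw, generate_series

from conftest import chem


def proc(pid, product, reactants=(), catalyst=CatalystClass.SOLID_ACID, **kw):
    participants = [Participant(chemical_id=r, role=Role.REACTANT) for r in reactants]
    participants.append(Participant(chemical_id=product, role=Role.PRODUCT))
    return ProcessRecord(
        process_id=pid, product_id=product, participants=participants,
        catalyst_class=catalyst, **kw,
    )


# ------------------------------------------------------------ compatibility

def test_catalyst_class_mismatch_is_incompatible():
    a = proc("a", "x", catalyst=CatalystClass.SOLID_ACID)
    b = proc("b", "y", catalyst=CatalystClass.LIQUID_ACID)
    report = check_process_compatibility(a, b)
    assert not report.compatible
    assert any("catalyst class mismatch" in r for r in report.reasons)


def test_identical_processes_compatible_without_warnings():
    a = proc("a", "x", temperature_C=120.0, time_h=2.0)
    report = check_process_compatibility(a, a)
    assert report.compatible and not report.warnings


def test_large_temperature_gap_warns_but_stays_compatible():
    a = proc("a", "x", temperature_C=50.0)
    b = proc("b", "y", temperature_C=150.0)
    report = check_process_compatibility(a, b)
    assert report.compatible
    assert any("temperature" in w for w in report.warnings)


def test_control_set_difference_warns():
    a = proc("a", "x", controls=["scrubber"])
    b = proc("b", "y")
    assert any("control" in w for w in check_process_compatibility(a, b).warnings)


# ------------------------------------------------------------- role mapping

def case_chemicals(fx):
    return {c.id: c for c in fx.chemicals}


def test_case_study_role_mapping(case_study):
    source = case_study.process("cumene_process")
    target = case_study.process("p-cymene_process")
    mapping = map_species_roles(target, source, case_chemicals(case_study))
    assert dict(mapping.pairs) == {
        "cumene": "p-cymene",
        "benzene": "toluene",
        "propylene": "propylene",
    }
    assert not mapping.unmatched_source


def test_identity_mapping_for_identical_processes(case_study):
    p = case_study.process("cumene_process")
    mapping = map_species_roles(p, p, case_chemicals(case_study))
    assert all(s == t for s, t in mapping.pairs)


def test_unmatched_solvent_reported_and_rows_dropped(case_study):
    source = ProcessRecord(
        process_id="src",
        product_id="cumene",
        participants=[
            Participant(chemical_id="benzene", role=Role.SOLVENT),
            Participant(chemical_id="cumene", role=Role.PRODUCT),
        ],
        catalyst_class=CatalystClass.SOLID_ACID,
    )
    target = proc("tgt", "p-cymene")
    mapping = map_species_roles(target, source, case_chemicals(case_study))
    assert "benzene" in mapping.unmatched_source
    rows = [
        EmissionRecord(process_id="src", species_id="benzene", medium=Medium.AIR,
                       value=1e-6, basis=Basis.MEASURED),
        EmissionRecord(process_id="src", species_id="cumene", medium=Medium.AIR,
                       value=2e-6, basis=Basis.MEASURED),
    ]
    estimates = estimate_closest(target, source, mapping, rows)
    assert [e.record.species_id for e in estimates] == ["p-cymene"]


# ------------------------------------------------------------------ factors

def test_mw_and_vp_factors_from_property_table(case_study):
    target = case_study.chemical("p-cymene")
    source = case_study.chemical("cumene")
    factors = {
        f.property: f
        for f in compute_factors(target, source, [PropertyName.MW, PropertyName.VP])
    }
    assert factors[PropertyName.MW].factor == pytest.approx(134.2 / 120.2, rel=1e-12)
    assert factors[PropertyName.MW].factor == pytest.approx(1.1165, abs=5e-5)
    assert factors[PropertyName.VP].factor == pytest.approx(1.55 / 4.6, rel=1e-12)
    assert factors[PropertyName.VP].factor == pytest.approx(0.3370, abs=5e-5)


def test_identical_chemicals_give_unit_factors(case_study):
    c = case_study.chemical("cumene")
    for f in compute_factors(c, c, [PropertyName.MW, PropertyName.VP, PropertyName.BP]):
        assert f.factor == 1.0


def test_missing_property_error_names_it(case_study):
    target = case_study.chemical("1,4-diisopropylbenzene")  # lacks logkow
    source = case_study.chemical("cumene")
    with pytest.raises(ValueError, match="logkow"):
        compute_factors(target, source, [PropertyName.LOGKOW])


def rf(prop, t, s):
    return ReadAcrossFactor(property=prop, target_value=t, source_value=s, factor=t / s)


def test_overall_factor_rules():
    factors = [rf(PropertyName.MW, 2.0, 1.0), rf(PropertyName.VP, 1.0, 2.0)]
    assert overall_factor(factors, FactorRule.GEOMEAN) == pytest.approx(1.0)
    assert overall_factor(factors, FactorRule.PRODUCT) == pytest.approx(1.0)
    assert overall_factor(factors, FactorRule.UNITY) == 1.0
    ones = [rf(PropertyName.MW, 1.0, 1.0)] * 2
    assert overall_factor(ones, FactorRule.GEOMEAN) == 1.0


def test_geomean_rejects_negative_factor():
    with pytest.raises(ValueError, match="positive"):
        overall_factor([rf(PropertyName.LOGKOW, -1.0, 1.0)], FactorRule.GEOMEAN)


# -------------------------------------------------------------------- modes

def test_closest_scales_source_values(case_study):
    source = case_study.process("cumene_process")
    target = case_study.process("p-cymene_process")
    mapping = map_species_roles(target, source, case_chemicals(case_study))
    estimates = estimate_closest(
        target, source, mapping, case_study.emissions, factor=0.5
    )
    by_species = {e.record.species_id: e.record.value for e in estimates}
    assert by_species["p-cymene"] == pytest.approx(0.5 * 1.9e-5, rel=1e-12)
    assert by_species["toluene"] == pytest.approx(0.5 * 5.9e-6, rel=1e-12)


def test_closest_with_unit_factor_and_identical_process_is_identity(case_study):
    p = case_study.process("cumene_process")
    mapping = map_species_roles(p, p, case_chemicals(case_study))
    estimates = estimate_closest(p, p, mapping, case_study.emissions, factor=1.0)
    measured = {e.species_id: e.value for e in case_study.emissions}
    for est in estimates:
        assert est.record.value == measured[est.record.species_id]
        assert est.record.basis is Basis.READ_ACROSS


def test_closest_without_emission_data_advises_fallback(case_study):
    target = case_study.process("p-cymene_process")
    mapping = map_species_roles(target, target, case_chemicals(case_study))
    with pytest.raises(ValueError, match="fallback"):
        estimate_closest(target, target, mapping, case_study.emissions)


def test_average_and_conservative():
    assert estimate_average([2e-6, 4e-6]) == pytest.approx(3e-6)
    assert estimate_conservative([2e-6, 4e-6]) == 4e-6
    assert estimate_average([5.0, 5.0]) == 5.0
    assert estimate_conservative([5.0, 5.0]) == 5.0
    with pytest.raises(ValueError):
        estimate_average([1.0])
    with pytest.raises(ValueError):
        estimate_conservative([1.0])


@settings(deadline=None, max_examples=100)
@given(values=st.lists(st.floats(min_value=0, max_value=1e3), min_size=2, max_size=10))
def test_conservative_dominates_average(values):
    assert min(values) <= estimate_average(values) <= estimate_conservative(values)


def _series(noise=0.0, carbons=(7, 8, 9, 11, 12), seed=0):
    return generate_series(
        SeriesSpec(
            carbon_counts=tuple(carbons),
            emission_laws={Role.PRODUCT: TrendLaw(intercept=-4.0, slope=-0.1)},
            noise_sd=noise,
            seed=seed,
        )
    )


def test_trend_recovers_withheld_member_exactly():
    # log10(E) = -4 - 0.1*n; withhold n=10 -> E = 1e-5
    data = _series()
    target = chem("t10", "C" * 4 + "c1ccccc1")
    target_proc = proc("tp", "t10")
    members = [c for c in data.chemicals if c.id != "propylene"]
    procs = {p.product_id: p for p in data.processes}
    estimates = estimate_trend(members, procs, data.emissions, target, target_proc)
    assert len(estimates) == 1
    assert estimates[0].record.value == pytest.approx(1e-5, rel=1e-9)
    assert not estimates[0].extrapolated


def test_trend_flat_series_returns_constant():
    data = generate_series(
        SeriesSpec(
            carbon_counts=(7, 8, 9),
            emission_laws={Role.PRODUCT: TrendLaw(intercept=-5.0, slope=0.0)},
            seed=0,
        )
    )
    target = chem("t10", "CCCCc1ccccc1")
    members = [c for c in data.chemicals if c.id != "propylene"]
    procs = {p.product_id: p for p in data.processes}
    estimates = estimate_trend(members, procs, data.emissions, target, proc("tp", "t10"))
    assert estimates[0].record.value == pytest.approx(1e-5, rel=1e-9)


def test_trend_outside_range_is_flagged_extrapolated():
    data = _series(carbons=(7, 8, 9))
    target = chem("t20", "C" * 14 + "c1ccccc1")
    members = [c for c in data.chemicals if c.id != "propylene"]
    procs = {p.product_id: p for p in data.processes}
    estimates = estimate_trend(members, procs, data.emissions, target, proc("tp", "t20"))
    assert estimates[0].extrapolated


def test_trend_requires_two_members():
    data = _series(carbons=(7, 8, 9))
    members = [c for c in data.chemicals if c.id == "alkylbenzene_C7"]
    procs = {p.product_id: p for p in data.processes}
    with pytest.raises(ValueError, match=">= 2"):
        estimate_trend(
            members, procs, data.emissions, chem("t", "CCCCc1ccccc1"), proc("tp", "t")
        )


# ------------------------------------------------------------- invariants

def test_self_read_across_identity_all_pool_modes(case_study):
    p = case_study.process("cumene_process")
    mapping = map_species_roles(p, p, case_chemicals(case_study))
    measured = {e.species_id: e.value for e in case_study.emissions}
    for mode in (EstimationMode.AVERAGE, EstimationMode.CONSERVATIVE):
        estimates = estimate_pooled(
            mode, p, [p, p], [mapping, mapping], case_study.emissions
        )
        for est in estimates:
            assert est.record.value == measured[est.record.species_id]


@settings(deadline=None, max_examples=25)
@given(k=st.floats(min_value=1e-3, max_value=1e3))
def test_scaling_equivariance(k):
    from emitra import load_case_study

    case_study = load_case_study()
    source = case_study.process("cumene_process")
    target = case_study.process("p-cymene_process")
    mapping = map_species_roles(target, source, case_chemicals(case_study))
    scaled = [
        EmissionRecord(
            process_id=e.process_id, species_id=e.species_id, medium=e.medium,
            value=e.value * k, basis=e.basis,
        )
        for e in case_study.emissions
    ]
    base = estimate_closest(target, source, mapping, case_study.emissions)
    after = estimate_closest(target, source, mapping, scaled)
    for b, a in zip(base, after):
        assert a.record.value == pytest.approx(b.record.value * k, rel=1e-12)


def test_audit_rederives_every_mode(case_study):
    source = case_study.process("cumene_process")
    target = case_study.process("p-cymene_process")
    mapping = map_species_roles(target, source, case_chemicals(case_study))
    for est in estimate_closest(target, source, mapping, case_study.emissions, factor=0.337):
        assert audit_estimate(est)
    for mode in (EstimationMode.AVERAGE, EstimationMode.CONSERVATIVE):
        for est in estimate_pooled(
            mode, target, [source, source], [mapping, mapping], case_study.emissions
        ):
            assert audit_estimate(est)
    data = _series(noise=0.2, seed=7)
    members = [c for c in data.chemicals if c.id != "propylene"]
    procs = {p.product_id: p for p in data.processes}
    for est in estimate_trend(
        members, procs, data.emissions, chem("t10", "CCCCc1ccccc1"), proc("tp", "t10")
    ):
        assert audit_estimate(est)


def test_audit_detects_tampering(case_study):
    source = case_study.process("cumene_process")
    target = case_study.process("p-cymene_process")
    mapping = map_species_roles(target, source, case_chemicals(case_study))
    est = estimate_closest(target, source, mapping, case_study.emissions)[0]
    tampered = est.model_copy(
        update={"record": est.record.model_copy(update={"value": est.record.value * 1.01})}
    )
    assert not audit_estimate(tampered)
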