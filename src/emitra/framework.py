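"""End-to-end read-across workflow.

``run_framework`` executes the seven-step procedure in order — identify
the target and its process, characterize it, select structural
analogues, analyse and optionally fill property gaps, compare the
processes, estimate the emissions, and check whether a second
iteration is warranted — then grades the uncertainty of the result.
Every step's decision and the provenance of every number it consumed
are recorded in the returned report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import analogs, engine, uncertainty
from .chem import FingerprintParams
from .records import (
    AnalogueMatch,
    Basis,
    Category,
    ChemicalRecord,
    EmissionEstimate,
    EmissionRecord,
    EstimationMode,
    FactorRule,
    Medium,
    ProcessRecord,
    PropertyName,
    UncertaintyGrade,
)

log = logging.getLogger("emitra.framework")


@dataclass
class FrameworkConfig:
    """Inputs and knobs for one framework run."""

    target_id: str
    chemicals: list[ChemicalRecord]
    processes: list[ProcessRecord]
    emissions: list[EmissionRecord]
    mode: EstimationMode = EstimationMode.CLOSEST
    factor_rule: FactorRule = FactorRule.GEOMEAN
    # Volatility drives air releases, so the vapor-pressure ratio is the
    # default property behind the overall factor for the air medium.
    factor_properties: tuple[PropertyName, ...] = (PropertyName.VP,)
    fingerprint: FingerprintParams = field(default_factory=FingerprintParams)
    cutoff: Optional[float] = None
    medium: Medium = Medium.AIR
    descriptor: str = "carbon_count"
    fill_gaps: bool = True
    max_iterations: int = 2


@dataclass
class StepResult:
    step: int
    name: str
    status: str  # "ok" | "halted"
    details: dict = field(default_factory=dict)


@dataclass
class FrameworkReport:
    steps: list[StepResult] = field(default_factory=list)
    matches: list[AnalogueMatch] = field(default_factory=list)
    category: Optional[Category] = None
    estimates: list[EmissionEstimate] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    uncertainty: Optional[UncertaintyGrade] = None
    iterations: int = 1
    halted_at: Optional[int] = None

    @property
    def ok(self) -> bool:
        return self.halted_at is None

    def halt(self, step: int, name: str, reason: str) -> "FrameworkReport":
        log.info("framework halted at step %d (%s): %s", step, name, reason)
        self.steps.append(
            StepResult(step=step, name=name, status="halted", details={"reason": reason})
        )
        self.halted_at = step
        return self


def _process_of(product_id: str, processes: Sequence[ProcessRecord]) -> Optional[ProcessRecord]:
    for proc in processes:
        if proc.product_id == product_id:
            return proc
    return None


def run_framework(config: FrameworkConfig) -> FrameworkReport:
    """Run the full read-across workflow for one target chemical.

    Steps are executed in order; an unrecoverable failure marks the
    step in the report and halts. When property gaps were filled, a
    second iteration recomputes the factors and estimates with the
    filled values, and the uncertainty grade records that trend-filled
    data entered the result.
    """
    report = FrameworkReport()
    chemicals = {c.id: c for c in config.chemicals}

    # Step 1 — problem identification: target chemical and its process.
    target = chemicals.get(config.target_id)
    if target is None:
        return report.halt(1, "identify", f"unknown target chemical {config.target_id!r}")
    target_proc = _process_of(target.id, config.processes)
    if target_proc is None:
        return report.halt(1, "identify", f"no process with product {target.id!r}")
    report.steps.append(
        StepResult(1, "identify", "ok", {"target": target.id, "process": target_proc.process_id})
    )

    # Step 2 — characterization of the target process.
    report.steps.append(
        StepResult(
            2,
            "characterize",
            "ok",
            {
                "participants": {
                    p.chemical_id: p.role.value for p in target_proc.participants
                },
                "catalyst_class": target_proc.catalyst_class.value,
                "properties": {
                    p.value: pv.provenance.value
                    for p, pv in target.properties.items()
                },
            },
        )
    )

    # Step 3 — analogue selection among chemicals that are products of a
    # known process; analogues with measured emissions rank first in use.
    measured_process_ids = {
        e.process_id for e in config.emissions if e.basis is Basis.MEASURED
    }
    measured_ids = frozenset(
        proc.product_id
        for proc in config.processes
        if proc.process_id in measured_process_ids
    )
    candidates = [
        c
        for c in config.chemicals
        if c.id != target.id and _process_of(c.id, config.processes) is not None
    ]
    if not candidates:
        return report.halt(3, "analogue_selection", "no candidate source chemicals with processes")
    matches = analogs.find_analogues(
        target,
        candidates,
        cutoff=config.cutoff,
        params=config.fingerprint,
        measured_ids=measured_ids,
    )
    report.matches = matches
    usable = [m for m in matches if m.has_measured_emissions]
    if not usable:
        return report.halt(
            3, "analogue_selection", "no analogue above the cutoff has measured emissions"
        )
    best = usable[0]
    grouping = analogs.select_mode(1, len(usable)).value
    report.steps.append(
        StepResult(
            3,
            "analogue_selection",
            "ok",
            {
                "closest": best.source_id,
                "similarity": best.similarity,
                "n_usable": len(usable),
                "grouping": grouping,
            },
        )
    )

    # Category validation over target + usable sources, for trend mode
    # and gap filling.
    category_members = [target] + [chemicals[m.source_id] for m in usable]
    category: Optional[Category] = None
    if len(category_members) >= 2:
        category = analogs.validate_category(category_members)
        report.category = category

    # Step 4 — gap analysis over the factor properties, with trend filling.
    from . import properties as props_mod

    needed = set(config.factor_properties)
    involved = [target] + [chemicals[m.source_id] for m in usable]
    gap_report = props_mod.gap_analysis(involved, needed)
    filled: list[tuple[str, PropertyName]] = []
    if config.fill_gaps and gap_report.n_missing:
        for chem_id, prop in gap_report.missing:
            rec = chemicals[chem_id]
            donors = [m for m in category_members if m.has(prop)]
            if len(donors) >= 2:
                pv = props_mod.fill_by_trend(donors, prop, rec, config.descriptor)
                rec.properties = {**rec.properties, prop: pv}
                filled.append((chem_id, prop))
                log.info("filled %s for %s by category trend: %g", prop.value, chem_id, pv.value)
    report.steps.append(
        StepResult(
            4,
            "gap_analysis",
            "ok",
            {
                "missing": [(cid, p.value) for cid, p in gap_report.missing],
                "filled": [(cid, p.value) for cid, p in filled],
            },
        )
    )

    # Step 5 — process comparison.
    source = chemicals[best.source_id]
    source_proc = _process_of(source.id, config.processes)
    assert source_proc is not None
    compat = engine.check_process_compatibility(target_proc, source_proc)
    report.warnings.extend(compat.warnings)
    if not compat.compatible:
        return report.halt(5, "process_comparison", "; ".join(compat.reasons))
    report.steps.append(
        StepResult(
            5,
            "process_comparison",
            "ok",
            {"reasons": list(compat.reasons), "warnings": list(compat.warnings)},
        )
    )

    # Steps 6–7 — estimation, iterated once more when gaps were filled.
    def _estimate() -> list[EmissionEstimate]:
        usable_props = [
            p
            for p in config.factor_properties
            if target.has(p) and source.has(p)
        ]
        if config.factor_rule is FactorRule.UNITY or not usable_props:
            breakdown = []
            factor = 1.0
        else:
            breakdown = engine.compute_factors(target, source, usable_props)
            factor = engine.overall_factor(breakdown, config.factor_rule)
        if config.mode is EstimationMode.CLOSEST:
            mapping = engine.map_species_roles(
                target_proc, source_proc, chemicals, config.fingerprint
            )
            if mapping.unmatched_source:
                report.warnings.append(
                    f"unmatched source species dropped: {sorted(mapping.unmatched_source)}"
                )
            return engine.estimate_closest(
                target_proc,
                source_proc,
                mapping,
                config.emissions,
                factor,
                breakdown,
                config.medium,
            )
        if config.mode is EstimationMode.TREND:
            member_procs = {
                m.source_id: _process_of(m.source_id, config.processes)
                for m in usable
            }
            return engine.estimate_trend(
                [chemicals[m.source_id] for m in usable],
                {k: v for k, v in member_procs.items() if v is not None},
                config.emissions,
                target,
                target_proc,
                config.descriptor,
                config.medium,
            )
        # average / conservative pool over all usable analogues
        procs, mappings = [], []
        for m in usable:
            proc = _process_of(m.source_id, config.processes)
            if proc is None:
                continue
            procs.append(proc)
            mappings.append(
                engine.map_species_roles(target_proc, proc, chemicals, config.fingerprint)
            )
        return engine.estimate_pooled(
            config.mode, target_proc, procs, mappings, config.emissions,
            factor, breakdown, config.medium,
        )

    estimates = _estimate()
    report.steps.append(
        StepResult(6, "estimation", "ok", {"mode": config.mode.value, "n": len(estimates)})
    )

    iterate = bool(filled) and config.max_iterations > 1
    if iterate:
        estimates = _estimate()
        report.iterations = 2
    report.steps.append(
        StepResult(
            7,
            "iteration_check",
            "ok",
            {"second_iteration": iterate, "reason": "gaps filled" if iterate else "none"},
        )
    )

    # Uncertainty assessment.
    source_bases = {
        e.basis
        for e in config.emissions
        if e.process_id == source_proc.process_id
    } or {Basis.READ_ACROSS}
    worst_basis = max(
        source_bases,
        key=lambda b: [Basis.MEASURED, Basis.ESTIMATED, Basis.READ_ACROSS].index(b),
    )
    any_trend_filled = bool(filled)
    any_extrapolated = any(e.extrapolated for e in estimates)
    grade = uncertainty.grade(
        similarity=best.similarity,
        process_compatible=compat.compatible,
        process_warnings=len(compat.warnings),
        source_basis=worst_basis,
        any_trend_filled_properties=any_trend_filled,
        extrapolated=any_extrapolated,
        thresholds=uncertainty.GradingThresholds.for_scheme(config.fingerprint),
    )
    report.uncertainty = grade
    report.estimates = [
        e.model_copy(update={"uncertainty": grade}) for e in estimates
    ]

    for est in report.estimates:
        if not engine.audit_estimate(est):  # pragma: no cover - defensive
            report.warnings.append(
                f"audit failed for estimate of {est.record.species_id}"
            )
    return report
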