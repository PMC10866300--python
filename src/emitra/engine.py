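"""The read-across estimation engine.

Given a target manufacturing process with no emission data and one or
more structurally analogous source processes with measured emissions,
this module checks that the processes are comparable (same catalyst
class, similar conditions), maps each source species onto its target
counterpart by role and structural similarity, scales the source
emission values by an overall read-across factor derived from
physicochemical property ratios, and produces fully audited estimates
under one of four quantitative modes:

``closest``
    carry over the closest analogue's values;
``trend``
    regress log10(emission) on a structural descriptor across a
    validated category and evaluate at the target;
``average``
    arithmetic mean over two or more analogues;
``conservative``
    worst case (highest emission) over two or more analogues.

Every estimate records its source chain, factors and mode, and
``audit_estimate`` re-derives the value from that record bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import FingerprintParams, fingerprint, parse_structure, tanimoto
from .records import (
    Basis,
    ChemicalRecord,
    EmissionEstimate,
    EmissionRecord,
    EstimationMode,
    FactorRule,
    Medium,
    ProcessRecord,
    PropertyName,
    ReadAcrossFactor,
    Role,
    SourceLink,
    TrendFit,
)

log = logging.getLogger("emitra.engine")

# Process-condition warning thresholds: differences beyond these are
# flagged but do not block estimation (a catalyst-class mismatch does).
TEMPERATURE_WARN_C = 50.0
TIME_WARN_RATIO = 2.0


@dataclass(frozen=True)
class CompatibilityReport:
    compatible: bool
    reasons: tuple[str, ...]
    warnings: tuple[str, ...] = ()


def check_process_compatibility(
    target: ProcessRecord,
    source: ProcessRecord,
    temperature_warn_c: float = TEMPERATURE_WARN_C,
    time_warn_ratio: float = TIME_WARN_RATIO,
) -> CompatibilityReport:
    """Decide whether emissions can be read across two processes.

    A catalyst-class mismatch (e.g. solid acid vs liquid acid) makes
    the processes incompatible. Large temperature or reaction-time
    differences, or differing pollution-control sets, produce warnings
    but not incompatibility; unknown conditions produce neither.
    """
    reasons: list[str] = []
    warnings: list[str] = []

    if target.catalyst_class != source.catalyst_class:
        reasons.append(
            f"catalyst class mismatch: target {target.catalyst_class.value} "
            f"vs source {source.catalyst_class.value}"
        )
    else:
        reasons.append(f"catalyst class matches ({target.catalyst_class.value})")

    if target.temperature_C is not None and source.temperature_C is not None:
        dt = abs(target.temperature_C - source.temperature_C)
        if dt > temperature_warn_c:
            warnings.append(
                f"temperature difference {dt:g} degC exceeds {temperature_warn_c:g}"
            )
    if target.time_h is not None and source.time_h is not None:
        lo, hi = sorted([target.time_h, source.time_h])
        if lo > 0 and hi / lo > time_warn_ratio:
            warnings.append(
                f"reaction time ratio {hi / lo:g} exceeds {time_warn_ratio:g}"
            )
    if set(target.controls) != set(source.controls):
        warnings.append(
            f"pollution control sets differ: {sorted(set(target.controls))} "
            f"vs {sorted(set(source.controls))}"
        )

    return CompatibilityReport(
        compatible=not [r for r in reasons if "mismatch" in r],
        reasons=tuple(reasons),
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class RoleMapping:
    """Source-to-target species correspondence within one role each."""

    pairs: tuple[tuple[str, str], ...]  # (source_id, target_id)
    unmatched_source: tuple[str, ...]
    unmatched_target: tuple[str, ...]

    def target_for(self, source_id: str) -> Optional[str]:
        for s, t in self.pairs:
            if s == source_id:
                return t
        return None


def map_species_roles(
    target: ProcessRecord,
    source: ProcessRecord,
    chemicals: dict[str, ChemicalRecord],
    params: FingerprintParams | None = None,
) -> RoleMapping:
    """Match each source species to a target species of the same role.

    The product always maps to the product. Other participants are
    matched greedily within equal role by highest Tanimoto similarity
    (tie-break: lexicographic id pair); source species with no target
    counterpart in their role are reported unmatched so their emission
    rows can be dropped with a warning.
    """
    params = params or FingerprintParams()
    pairs: list[tuple[str, str]] = [(source.product_id, target.product_id)]
    unmatched_source: list[str] = []
    unmatched_target: list[str] = []

    fps: dict[str, object] = {}

    def fp_of(chem_id: str):
        if chem_id not in fps:
            rec = chemicals.get(chem_id)
            if rec is None:
                raise KeyError(f"no chemical record for participant {chem_id!r}")
            fps[chem_id] = fingerprint(parse_structure(rec.smiles), params)
        return fps[chem_id]

    for role in (Role.REACTANT, Role.SOLVENT, Role.CATALYST, Role.AUXILIARY):
        src_ids = [p.chemical_id for p in source.participants_with_role(role)]
        tgt_ids = [p.chemical_id for p in target.participants_with_role(role)]
        candidates = sorted(
            (
                (-tanimoto(fp_of(s), fp_of(t)).value, s, t)
                for s in src_ids
                for t in tgt_ids
            ),
        )
        used_s: set[str] = set()
        used_t: set[str] = set()
        for neg_sim, s, t in candidates:
            if s in used_s or t in used_t:
                continue
            used_s.add(s)
            used_t.add(t)
            pairs.append((s, t))
            log.info(
                "role map [%s]: %s -> %s (similarity %.3f)", role.value, s, t, -neg_sim
            )
        unmatched_source.extend(s for s in src_ids if s not in used_s)
        unmatched_target.extend(t for t in tgt_ids if t not in used_t)

    return RoleMapping(
        pairs=tuple(pairs),
        unmatched_source=tuple(unmatched_source),
        unmatched_target=tuple(unmatched_target),
    )


def compute_factors(
    target: ChemicalRecord,
    source: ChemicalRecord,
    properties: Sequence[PropertyName],
) -> list[ReadAcrossFactor]:
    """One read-across factor per property: target value / source value."""
    factors: list[ReadAcrossFactor] = []
    for prop in properties:
        t_pv, s_pv = target.get(prop), source.get(prop)
        if t_pv is None:
            raise ValueError(f"target {target.id!r} lacks property {prop.value}")
        if s_pv is None:
            raise ValueError(f"source {source.id!r} lacks property {prop.value}")
        if s_pv.value == 0:
            raise ValueError(f"source {source.id!r} has zero {prop.value}")
        factors.append(
            ReadAcrossFactor(
                property=prop,
                target_value=t_pv.value,
                source_value=s_pv.value,
                factor=t_pv.value / s_pv.value,
            )
        )
    return factors


def overall_factor(
    factors: Sequence[ReadAcrossFactor],
    rule: FactorRule = FactorRule.GEOMEAN,
) -> float:
    """Combine per-property factors into one overall read-across factor.

    ``geomean`` (default) takes the geometric mean; ``product``
    multiplies them; ``unity`` returns 1 regardless — the choice when
    target and source properties are so similar that the source values
    are carried over unchanged.
    """
    if rule is FactorRule.UNITY:
        return 1.0
    if not factors:
        raise ValueError("factors must be non-empty")
    values = [f.factor for f in factors]
    if rule is FactorRule.PRODUCT:
        return float(np.prod(values))
    if any(v <= 0 for v in values):
        raise ValueError("geometric mean requires positive factors")
    return float(np.exp(np.mean(np.log(values))))


def _emissions_of(
    process_id: str, emissions: Sequence[EmissionRecord], medium: Medium | None
) -> list[EmissionRecord]:
    return [
        e
        for e in emissions
        if e.process_id == process_id and (medium is None or e.medium == medium)
    ]


def estimate_closest(
    target_proc: ProcessRecord,
    source_proc: ProcessRecord,
    mapping: RoleMapping,
    emissions: Sequence[EmissionRecord],
    factor: float = 1.0,
    factor_breakdown: Sequence[ReadAcrossFactor] = (),
    medium: Medium | None = Medium.AIR,
) -> list[EmissionEstimate]:
    """Carry each mapped source emission over to the target process.

    Each source row becomes a target estimate: value x overall factor,
    species relabelled through the role mapping. Source rows whose
    species has no target counterpart are dropped with a warning.
    """
    rows = _emissions_of(source_proc.process_id, emissions, medium)
    if not rows:
        raise ValueError(
            f"closest analogue process {source_proc.process_id!r} has no "
            "emission data; use a trend/average/conservative fallback"
        )
    estimates: list[EmissionEstimate] = []
    for row in rows:
        target_species = mapping.target_for(row.species_id)
        if target_species is None:
            log.warning(
                "dropping emission row for %s: no counterpart in target process",
                row.species_id,
            )
            continue
        estimates.append(
            EmissionEstimate(
                record=EmissionRecord(
                    process_id=target_proc.process_id,
                    species_id=target_species,
                    medium=row.medium,
                    value=row.value * factor,
                    basis=Basis.READ_ACROSS,
                ),
                mode=EstimationMode.CLOSEST,
                overall_factor=factor,
                factor_breakdown=tuple(factor_breakdown),
                source_chain=(
                    SourceLink(
                        process_id=row.process_id,
                        species_id=row.species_id,
                        value=row.value,
                    ),
                ),
            )
        )
    return estimates


def _fit_log_trend(xs: Sequence[float], values: Sequence[float]) -> tuple[float, float]:
    slope, intercept = np.polyfit(np.asarray(xs, float), np.log10(values), 1)
    return float(intercept), float(slope)


def estimate_trend(
    members: Sequence[ChemicalRecord],
    member_processes: dict[str, ProcessRecord],
    emissions: Sequence[EmissionRecord],
    target: ChemicalRecord,
    target_proc: ProcessRecord,
    descriptor: str = "carbon_count",
    medium: Medium | None = Medium.AIR,
    roles: Sequence[Role] = (Role.PRODUCT,),
) -> list[EmissionEstimate]:
    """Estimate target emissions from a category-wide log-linear trend.

    For each requested role, the emission of the species holding that
    role in each member's process is regressed (log10) against the
    member product's structural descriptor, and the line is evaluated
    at the target's descriptor. Requires measured data for at least two
    members per role; the estimate is flagged extrapolated when the
    target descriptor lies outside the members' range.
    """
    from .properties import _descriptor_value

    estimates: list[EmissionEstimate] = []
    for role in roles:
        xs: list[float] = []
        values: list[float] = []
        chain: list[SourceLink] = []
        for m in members:
            if m.id == target.id or m.id not in member_processes:
                continue
            proc = member_processes[m.id]
            species = [p.chemical_id for p in proc.participants_with_role(role)]
            rows = [
                r
                for r in _emissions_of(proc.process_id, emissions, medium)
                if r.species_id in species
            ]
            for row in rows:
                xs.append(_descriptor_value(m, descriptor))
                values.append(row.value)
                chain.append(
                    SourceLink(
                        process_id=row.process_id,
                        species_id=row.species_id,
                        value=row.value,
                    )
                )
        if len(xs) < 2:
            raise ValueError(
                f"trend estimation for role {role.value!r} requires >= 2 "
                f"members with emission data, found {len(xs)}"
            )
        target_participants = target_proc.participants_with_role(role)
        if not target_participants:
            continue
        x_t = _descriptor_value(target, descriptor)
        intercept, slope = _fit_log_trend(xs, values)
        value = float(10.0 ** (intercept + slope * x_t))
        estimates.append(
            EmissionEstimate(
                record=EmissionRecord(
                    process_id=target_proc.process_id,
                    species_id=target_participants[0].chemical_id,
                    medium=medium or Medium.AIR,
                    value=value,
                    basis=Basis.READ_ACROSS,
                ),
                mode=EstimationMode.TREND,
                overall_factor=1.0,
                source_chain=tuple(chain),
                extrapolated=not (min(xs) <= x_t <= max(xs)),
                trend_fit=TrendFit(
                    descriptor=descriptor,
                    xs=tuple(xs),
                    x_target=x_t,
                    intercept=intercept,
                    slope=slope,
                ),
            )
        )
    return estimates


def estimate_average(values: Sequence[float]) -> float:
    """Arithmetic mean of two or more source endpoint values."""
    if len(values) < 2:
        raise ValueError("averaging requires >= 2 source values")
    return float(sum(values) / len(values))


def estimate_conservative(values: Sequence[float]) -> float:
    """Worst case over two or more source values — the highest emission."""
    if len(values) < 2:
        raise ValueError("a conservative estimate requires >= 2 source values")
    return float(max(values))


def estimate_pooled(
    mode: EstimationMode,
    target_proc: ProcessRecord,
    source_procs: Sequence[ProcessRecord],
    mappings: Sequence[RoleMapping],
    emissions: Sequence[EmissionRecord],
    factor: float = 1.0,
    factor_breakdown: Sequence[ReadAcrossFactor] = (),
    medium: Medium | None = Medium.AIR,
) -> list[EmissionEstimate]:
    """Average or conservative estimates pooled over several analogues.

    Each source's emission rows are mapped onto target species; for
    every target species with contributions from at least two sources
    the rows are combined by the mode's formula, then scaled.
    """
    if mode not in (EstimationMode.AVERAGE, EstimationMode.CONSERVATIVE):
        raise ValueError(f"pooled estimation does not support mode {mode.value}")
    pooled: dict[tuple[str, Medium], list[SourceLink]] = {}
    for proc, mapping in zip(source_procs, mappings):
        for row in _emissions_of(proc.process_id, emissions, medium):
            tgt = mapping.target_for(row.species_id)
            if tgt is None:
                continue
            pooled.setdefault((tgt, row.medium), []).append(
                SourceLink(
                    process_id=row.process_id,
                    species_id=row.species_id,
                    value=row.value,
                )
            )
    combine = estimate_average if mode is EstimationMode.AVERAGE else estimate_conservative
    estimates = []
    for (species, med), chain in sorted(pooled.items()):
        values = [link.value for link in chain]
        estimates.append(
            EmissionEstimate(
                record=EmissionRecord(
                    process_id=target_proc.process_id,
                    species_id=species,
                    medium=med,
                    value=combine(values) * factor,
                    basis=Basis.READ_ACROSS,
                ),
                mode=mode,
                overall_factor=factor,
                factor_breakdown=tuple(factor_breakdown),
                source_chain=tuple(chain),
            )
        )
    return estimates


def audit_estimate(estimate: EmissionEstimate) -> bool:
    """Re-derive an estimate's value from its own provenance record.

    Applies the estimate's mode formula to its source chain (and trend
    fit, for trend mode), multiplies by the overall factor, and checks
    bit-for-bit equality with the stored value.
    """
    values = [link.value for link in estimate.source_chain]
    if estimate.mode is EstimationMode.CLOSEST:
        derived = values[0] * estimate.overall_factor
    elif estimate.mode is EstimationMode.AVERAGE:
        derived = estimate_average(values) * estimate.overall_factor
    elif estimate.mode is EstimationMode.CONSERVATIVE:
        derived = estimate_conservative(values) * estimate.overall_factor
    elif estimate.mode is EstimationMode.TREND:
        fit = estimate.trend_fit
        if fit is None:
            return False
        intercept, slope = _fit_log_trend(fit.xs, values)
        derived = 10.0 ** (intercept + slope * fit.x_target) * estimate.overall_factor
    else:  # pragma: no cover
        return False
    return derived == estimate.record.value or (
        math.isnan(derived) and math.isnan(estimate.record.value)
    )
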