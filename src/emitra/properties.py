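"""Property gap analysis and within-category trend filling.

Homologous series show regular property trends with chain length:
linear for molecular weight, boiling point and logKow, log-linear for
vapor pressure and water solubility (which span decades). A missing
property for one member can therefore be filled by least-squares
regression of the property against a structural descriptor (carbon
count by default) over the members that do have data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chem import parse_structure
from .records import ChemicalRecord, PropertyName, PropertyValue, Provenance


@dataclass(frozen=True)
class GapReport:
    """Presence/absence matrix for a requested property set."""

    required: tuple[PropertyName, ...]
    presence: dict[str, dict[PropertyName, bool]]

    @property
    def missing(self) -> list[tuple[str, PropertyName]]:
        return [
            (chem_id, prop)
            for chem_id, row in self.presence.items()
            for prop, present in row.items()
            if not present
        ]

    @property
    def n_missing(self) -> int:
        return len(self.missing)

    @property
    def n_present(self) -> int:
        return sum(
            present for row in self.presence.values() for present in row.values()
        )


def gap_analysis(
    records: list[ChemicalRecord], required: set[PropertyName]
) -> GapReport:
    """Tabulate which chemicals lack which of the required properties."""
    if not records:
        raise ValueError("records must be non-empty")
    ordered = tuple(sorted(required, key=lambda p: p.value))
    presence = {
        rec.id: {prop: rec.has(prop) for prop in ordered} for rec in records
    }
    return GapReport(required=ordered, presence=presence)


def _descriptor_value(rec: ChemicalRecord, descriptor: str) -> float:
    if descriptor == "carbon_count":
        return float(parse_structure(rec.smiles).carbon_count)
    if descriptor == "heavy_atom_count":
        return float(parse_structure(rec.smiles).heavy_atom_count)
    raise ValueError(f"unknown descriptor {descriptor!r}")


def trend_line(
    members: list[ChemicalRecord],
    prop: PropertyName,
    descriptor: str = "carbon_count",
) -> tuple[float, float, tuple[float, float]]:
    """Least-squares line of a property against a descriptor.

    Returns ``(intercept, slope, (x_min, x_max))`` where the fit is on
    log10 of the property when the property is log-domain. Members
    lacking the property are ignored.
    """
    xs, ys = [], []
    for m in members:
        pv = m.get(prop)
        if pv is None:
            continue
        xs.append(_descriptor_value(m, descriptor))
        y = pv.value
        if prop.log_domain:
            if y <= 0:
                raise ValueError(
                    f"{prop.value} of {m.id!r} must be positive for a "
                    "log-domain trend"
                )
            y = np.log10(y)
        ys.append(y)
    if len(xs) < 2:
        raise ValueError("trend requires >= 2 members with the property")
    if len(set(xs)) == 1:
        raise ValueError("trend requires >= 2 distinct descriptor values")
    slope, intercept = np.polyfit(np.asarray(xs), np.asarray(ys), 1)
    return float(intercept), float(slope), (min(xs), max(xs))


def fill_by_trend(
    members: list[ChemicalRecord],
    prop: PropertyName,
    target: ChemicalRecord,
    descriptor: str = "carbon_count",
) -> PropertyValue:
    """Fill the target's missing property from the category trend.

    The trend is evaluated at the target's descriptor value; the result
    carries ``trend_filled`` provenance and is flagged as extrapolated
    when the target lies outside the members' descriptor range. Values
    with measured or database provenance are never overwritten.

    Raises
    ------
    ValueError
        If fewer than 2 members carry the property, or the target
        already has it with measured/database provenance.
    """
    existing = target.get(prop)
    if existing is not None and existing.provenance in (
        Provenance.MEASURED,
        Provenance.DATABASE,
    ):
        raise ValueError(
            f"{target.id!r} already has {prop.value} with "
            f"{existing.provenance.value} provenance; refusing to overwrite"
        )
    donors = [m for m in members if m.id != target.id]
    intercept, slope, (x_min, x_max) = trend_line(donors, prop, descriptor)
    x_t = _descriptor_value(target, descriptor)
    y = intercept + slope * x_t
    value = float(10.0 ** y) if prop.log_domain else float(y)
    return PropertyValue(
        name=prop,
        value=value,
        provenance=Provenance.TREND_FILLED,
        extrapolated=not (x_min <= x_t <= x_max),
    )


def slope_standard_error(
    xs: np.ndarray, ys: np.ndarray
) -> tuple[float, float, float]:
    """OLS slope, intercept and slope standard error for a 1-D trend."""
    res = stats.linregress(xs, ys)
    return float(res.slope), float(res.intercept), float(res.stderr)
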