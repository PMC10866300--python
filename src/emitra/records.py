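"""Validated record types shared across the read-across pipeline.

Every quantity that flows through an estimate carries provenance:
chemical properties record where each value came from, emission records
record whether they were measured or inferred, and estimates carry the
full chain of source values and factors from which they can be
re-derived.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class PropertyName(str, enum.Enum):
    """Physicochemical properties with their fixed units."""

    MW = "mw"                    # molecular weight, amu
    BP = "bp_c"                  # boiling point, degC
    VP = "vp_mmhg_25c"           # vapor pressure, mmHg at 25 degC
    WSOL = "wsol_mg_l"           # water solubility, mg/L
    LOGKOW = "logkow"            # log octanol-water partition coefficient

    @property
    def log_domain(self) -> bool:
        """Whether within-category trends are fitted on log10 of the value.

        Vapor pressure and water solubility span decades across a
        homologous series, so their trends are log-linear; the others
        are fitted in the linear domain.
        """
        return self in (PropertyName.VP, PropertyName.WSOL)


class Provenance(str, enum.Enum):
    MEASURED = "measured"
    DATABASE = "database"
    ESTIMATED = "estimated"
    TREND_FILLED = "trend_filled"


class Role(str, enum.Enum):
    REACTANT = "reactant"
    SOLVENT = "solvent"
    CATALYST = "catalyst"
    AUXILIARY = "auxiliary"
    PRODUCT = "product"


class CatalystClass(str, enum.Enum):
    SOLID_ACID = "solid_acid"
    LIQUID_ACID = "liquid_acid"
    BASE = "base"
    METAL = "metal"
    ENZYME = "enzyme"
    NONE = "none"
    OTHER = "other"


class Medium(str, enum.Enum):
    AIR = "air"
    WATER = "water"
    LAND = "land"


class Basis(str, enum.Enum):
    MEASURED = "measured"
    ESTIMATED = "estimated"
    READ_ACROSS = "read_across"


class Grade(str, enum.Enum):
    """Qualitative uncertainty levels, ordered by severity."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"

    @property
    def severity(self) -> int:
        return {"low": 0, "moderate": 1, "high": 2}[self.value]


class PropertyValue(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: PropertyName
    value: float
    provenance: Provenance
    extrapolated: bool = False

    @model_validator(mode="after")
    def _non_negative_where_physical(self) -> "PropertyValue":
        if self.name in (PropertyName.VP, PropertyName.WSOL) and self.value < 0:
            raise ValueError(f"{self.name.value} must be >= 0, got {self.value}")
        if not math.isfinite(self.value):
            raise ValueError(f"{self.name.value} must be finite")
        return self


class ChemicalRecord(BaseModel):
    """A chemical's identity plus its property map with provenance."""

    model_config = ConfigDict(validate_assignment=True)

    id: str
    name: str
    smiles: str
    properties: dict[PropertyName, PropertyValue] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _property_keys_match(self) -> "ChemicalRecord":
        for key, pv in self.properties.items():
            if key != pv.name:
                raise ValueError(f"property map key {key} != value name {pv.name}")
        return self

    def get(self, prop: PropertyName) -> Optional[PropertyValue]:
        return self.properties.get(prop)

    def has(self, prop: PropertyName) -> bool:
        return prop in self.properties


class Participant(BaseModel):
    model_config = ConfigDict(frozen=True)

    chemical_id: str
    role: Role


class ProcessRecord(BaseModel):
    """A manufacturing process: role-annotated participants and conditions."""

    process_id: str
    product_id: str
    participants: list[Participant]
    catalyst_class: CatalystClass = CatalystClass.NONE
    temperature_C: Optional[float] = None
    time_h: Optional[float] = None
    controls: list[str] = Field(default_factory=list)
    production_volume: Optional[float] = None

    @model_validator(mode="after")
    def _exactly_one_product(self) -> "ProcessRecord":
        ids = [p.chemical_id for p in self.participants]
        if len(ids) != len(set(ids)):
            raise ValueError("participant chemical ids must be unique")
        products = [p for p in self.participants if p.role is Role.PRODUCT]
        if len(products) != 1:
            raise ValueError(
                f"process {self.process_id!r} must have exactly one product "
                f"role, found {len(products)}"
            )
        if products[0].chemical_id != self.product_id:
            raise ValueError("product_id must match the product participant")
        return self

    def participants_with_role(self, role: Role) -> list[Participant]:
        return [p for p in self.participants if p.role is role]

    def role_of(self, chemical_id: str) -> Optional[Role]:
        for p in self.participants:
            if p.chemical_id == chemical_id:
                return p.role
        return None


class EmissionRecord(BaseModel):
    """An emitted mass per unit mass of product (kg/kg)."""

    model_config = ConfigDict(frozen=True)

    process_id: str
    species_id: str
    medium: Medium
    value: float = Field(ge=0, description="kg emitted per kg product")
    basis: Basis

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("emission value must be finite")
        return v


class AnalogueMatch(BaseModel):
    model_config = ConfigDict(frozen=True)

    target_id: str
    source_id: str
    similarity: float = Field(ge=0, le=1)
    rank: int = Field(ge=1)
    has_measured_emissions: bool = False


class PairCheck(BaseModel):
    """Validation outcome for one adjacent pair of category members."""

    model_config = ConfigDict(frozen=True)

    first_id: str
    second_id: str
    passed: bool
    reasons: tuple[str, ...] = ()


class Category(BaseModel):
    """A structural category: members ordered by carbon count, validated."""

    member_ids: list[str]
    shared_feature: str
    validation: list[PairCheck]

    @property
    def is_valid(self) -> bool:
        return all(check.passed for check in self.validation)


class GroupingMode(str, enum.Enum):
    """How many analogues inform how many targets."""

    ONE_TO_ONE = "one_to_one"
    ONE_TO_MANY = "one_to_many"
    MANY_TO_ONE = "many_to_one"
    MANY_TO_MANY = "many_to_many"


class EstimationMode(str, enum.Enum):
    CLOSEST = "closest"
    TREND = "trend"
    AVERAGE = "average"
    CONSERVATIVE = "conservative"


class FactorRule(str, enum.Enum):
    GEOMEAN = "geomean"
    PRODUCT = "product"
    UNITY = "unity"


class ReadAcrossFactor(BaseModel):
    model_config = ConfigDict(frozen=True)

    property: PropertyName
    target_value: float
    source_value: float
    factor: float

    @model_validator(mode="after")
    def _consistent(self) -> "ReadAcrossFactor":
        if self.source_value == 0:
            raise ValueError("source property value must be nonzero")
        expected = self.target_value / self.source_value
        if not math.isclose(self.factor, expected, rel_tol=1e-12):
            raise ValueError("factor must equal target_value / source_value")
        return self


class SourceLink(BaseModel):
    model_config = ConfigDict(frozen=True)

    process_id: str
    species_id: str
    value: float


class Driver(BaseModel):
    model_config = ConfigDict(frozen=True)

    criterion: str
    level: Grade


class UncertaintyGrade(BaseModel):
    model_config = ConfigDict(frozen=True)

    grade: Grade
    drivers: tuple[Driver, ...]

    @model_validator(mode="after")
    def _grade_is_worst_driver(self) -> "UncertaintyGrade":
        if not self.drivers:
            raise ValueError("drivers must be non-empty")
        worst = max(d.level.severity for d in self.drivers)
        if self.grade.severity != worst:
            raise ValueError("grade must equal the worst driver level")
        return self


class TrendFit(BaseModel):
    """The fitted log-linear trend behind a trend-mode estimate.

    ``xs`` are the structural-descriptor values aligned one-to-one with
    the estimate's source chain, so the regression can be re-derived
    from the estimate alone.
    """

    model_config = ConfigDict(frozen=True)

    descriptor: str
    xs: tuple[float, ...]
    x_target: float
    intercept: float
    slope: float


class EmissionEstimate(BaseModel):
    """An estimated emission with its full derivation chain.

    The estimate is re-derivable: applying ``mode``'s formula to the
    ``source_chain`` values and multiplying by ``overall_factor`` must
    reproduce ``record.value`` bit-for-bit (see ``engine.audit_estimate``).
    """

    record: EmissionRecord
    mode: EstimationMode
    overall_factor: float
    factor_breakdown: tuple[ReadAcrossFactor, ...] = ()
    source_chain: tuple[SourceLink, ...]
    uncertainty: Optional[UncertaintyGrade] = None
    extrapolated: bool = False
    trend_fit: Optional[TrendFit] = None

    @model_validator(mode="after")
    def _chain_non_empty(self) -> "EmissionEstimate":
        if not self.source_chain:
            raise ValueError("source_chain must be non-empty")
        if self.record.basis is not Basis.READ_ACROSS:
            raise ValueError("estimate basis must be read_across")
        return self
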