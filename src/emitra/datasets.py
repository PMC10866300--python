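"""Embedded case-study fixture and synthetic homologous-series generator.

The case study is the alkylation pair: cumene (isopropylbenzene,
manufactured from benzene + propylene over a solid acid catalyst) as
the measured source process, and p-cymene (4-isopropyltoluene, from
toluene + propylene over a solid acid catalyst) as the target whose
emissions are to be estimated. Physicochemical properties for the four
alkylbenzene analogues and the measured air-emission factors of the
cumene process are embedded verbatim.

The generator builds n-alkylbenzene homologous series whose properties
and emissions follow stated (log-)linear laws in carbon count, with
optional seeded log-normal noise, so trend estimation can be validated
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import (
    Basis,
    CatalystClass,
    ChemicalRecord,
    EmissionRecord,
    Medium,
    Participant,
    ProcessRecord,
    PropertyName,
    PropertyValue,
    Provenance,
    Role,
)

CUMENE = "cumene"
P_CYMENE = "p-cymene"
DIPB = "1,4-diisopropylbenzene"
TIPB = "1,3,5-triisopropylbenzene"

# (id, name, SMILES, {property: value}); water solubility is absent for
# the di- and tri-isopropyl homologues (reported only as insoluble) and
# logKow is unreported for them.
_CHEMICALS: list[tuple[str, str, str, dict[PropertyName, float]]] = [
    (
        P_CYMENE,
        "p-cymene",
        "CC(C)c1ccc(C)cc1",
        {
            PropertyName.MW: 134.2,
            PropertyName.BP: 176.8,
            PropertyName.VP: 1.55,
            PropertyName.WSOL: 23.4,
            PropertyName.LOGKOW: 4.10,
        },
    ),
    (
        CUMENE,
        "cumene",
        "CC(C)c1ccccc1",
        {
            PropertyName.MW: 120.2,
            PropertyName.BP: 152.4,
            PropertyName.VP: 4.6,
            PropertyName.WSOL: 50.0,
            PropertyName.LOGKOW: 3.66,
        },
    ),
    (
        DIPB,
        "1,4-diisopropylbenzene",
        "CC(C)c1ccc(C(C)C)cc1",
        {
            PropertyName.MW: 162.27,
            PropertyName.BP: 210.3,
            PropertyName.VP: 0.24,
        },
    ),
    (
        TIPB,
        "1,3,5-triisopropylbenzene",
        "CC(C)c1cc(C(C)C)cc(C(C)C)c1",
        {
            PropertyName.MW: 204.35,
            PropertyName.BP: 232.0,
            PropertyName.VP: 0.02,
        },
    ),
    ("benzene", "benzene", "c1ccccc1", {}),
    ("toluene", "toluene", "Cc1ccccc1", {}),
    ("propylene", "propylene", "C=CC", {}),
]

# Measured air emission factors of the cumene process, kg emitted per
# kg cumene produced.
_CUMENE_EMISSIONS: list[tuple[str, float]] = [
    ("benzene", 5.9e-06),
    ("propylene", 7.8e-06),
    (CUMENE, 1.9e-05),
]


@dataclass(frozen=True)
class CaseStudyFixture:
    chemicals: tuple[ChemicalRecord, ...]
    processes: tuple[ProcessRecord, ...]
    emissions: tuple[EmissionRecord, ...]

    def chemical(self, chem_id: str) -> ChemicalRecord:
        for c in self.chemicals:
            if c.id == chem_id:
                return c
        raise KeyError(chem_id)

    def process(self, process_id: str) -> ProcessRecord:
        for p in self.processes:
            if p.process_id == process_id:
                return p
        raise KeyError(process_id)


def load_case_study() -> CaseStudyFixture:
    """Build the embedded cumene -> p-cymene case-study fixture.

    A fresh object graph is returned on every call, so callers (such
    as gap filling) may annotate their copy without affecting others.
    """
    chemicals = tuple(
        ChemicalRecord(
            id=cid,
            name=name,
            smiles=smiles,
            properties={
                prop: PropertyValue(
                    name=prop, value=value, provenance=Provenance.DATABASE
                )
                for prop, value in props.items()
            },
        )
        for cid, name, smiles, props in _CHEMICALS
    )
    processes = (
        ProcessRecord(
            process_id="cumene_process",
            product_id=CUMENE,
            participants=[
                Participant(chemical_id="benzene", role=Role.REACTANT),
                Participant(chemical_id="propylene", role=Role.REACTANT),
                Participant(chemical_id=CUMENE, role=Role.PRODUCT),
            ],
            catalyst_class=CatalystClass.SOLID_ACID,
        ),
        ProcessRecord(
            process_id="p-cymene_process",
            product_id=P_CYMENE,
            participants=[
                Participant(chemical_id="toluene", role=Role.REACTANT),
                Participant(chemical_id="propylene", role=Role.REACTANT),
                Participant(chemical_id=P_CYMENE, role=Role.PRODUCT),
            ],
            catalyst_class=CatalystClass.SOLID_ACID,
        ),
    )
    emissions = tuple(
        EmissionRecord(
            process_id="cumene_process",
            species_id=species,
            medium=Medium.AIR,
            value=value,
            basis=Basis.MEASURED,
        )
        for species, value in _CUMENE_EMISSIONS
    )
    return CaseStudyFixture(chemicals=chemicals, processes=processes, emissions=emissions)


@dataclass(frozen=True)
class TrendLaw:
    """A linear law ``y = intercept + slope * n_carbons``.

    For log-domain quantities (vapor pressure, water solubility,
    emissions) the law applies to log10 of the value.
    """

    intercept: float
    slope: float

    def value_at(self, n_carbons: int, log_domain: bool) -> float:
        y = self.intercept + self.slope * n_carbons
        return float(10.0 ** y) if log_domain else float(y)


@dataclass(frozen=True)
class SeriesSpec:
    """Specification of a synthetic n-alkylbenzene homologous series.

    ``carbon_counts`` are total carbon numbers (>= 7: six ring carbons
    plus at least one chain carbon). ``emission_laws`` give log10
    emission (kg/kg product) per role; ``noise_sd`` is the standard
    deviation of additive Gaussian noise on log10(emission), i.e.
    multiplicative log-normal noise on the emission itself. The seed is
    mandatory so generation is reproducible.
    """

    carbon_counts: tuple[int, ...]
    property_laws: dict[PropertyName, TrendLaw] = field(default_factory=dict)
    emission_laws: dict[Role, TrendLaw] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    catalyst_class: CatalystClass = CatalystClass.SOLID_ACID

    def __post_init__(self) -> None:
        if len(self.carbon_counts) < 3:
            raise ValueError("a homologous series needs >= 3 members")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SeriesData:
    chemicals: tuple[ChemicalRecord, ...]
    processes: tuple[ProcessRecord, ...]
    emissions: tuple[EmissionRecord, ...]
    # Exact (noise-free) emission values per (member id, role), for
    # recovery tests against the generating laws.
    truth: dict[tuple[str, Role], float]
    spec: SeriesSpec


def _alkylbenzene_smiles(n_carbons: int) -> str:
    if n_carbons < 7:
        raise ValueError(
            f"n-alkylbenzene template requires >= 7 carbons, got {n_carbons}"
        )
    return "C" * (n_carbons - 6) + "c1ccccc1"


def generate_series(spec: SeriesSpec) -> SeriesData:
    """Generate a homologous series with known property/emission laws."""
    rng = np.random.default_rng(spec.seed)
    chemicals: list[ChemicalRecord] = [
        ChemicalRecord(id="propylene", name="propylene", smiles="C=CC")
    ]
    processes: list[ProcessRecord] = []
    emissions: list[EmissionRecord] = []
    truth: dict[tuple[str, Role], float] = {}

    for n in spec.carbon_counts:
        cid = f"alkylbenzene_C{n}"
        chemicals.append(
            ChemicalRecord(
                id=cid,
                name=f"n-alkylbenzene with {n} carbons",
                smiles=_alkylbenzene_smiles(n),
                properties={
                    prop: PropertyValue(
                        name=prop,
                        value=law.value_at(n, prop.log_domain),
                        provenance=Provenance.DATABASE,
                    )
                    for prop, law in spec.property_laws.items()
                },
            )
        )
        proc_id = f"process_C{n}"
        processes.append(
            ProcessRecord(
                process_id=proc_id,
                product_id=cid,
                participants=[
                    Participant(chemical_id="propylene", role=Role.REACTANT),
                    Participant(chemical_id=cid, role=Role.PRODUCT),
                ],
                catalyst_class=spec.catalyst_class,
            )
        )
        for role, law in spec.emission_laws.items():
            participants = [
                p for p in processes[-1].participants if p.role is role
            ]
            if not participants:
                continue
            exact = law.value_at(n, log_domain=True)
            truth[(cid, role)] = exact
            noisy = exact * float(10.0 ** rng.normal(0.0, spec.noise_sd)) \
                if spec.noise_sd > 0 else exact
            emissions.append(
                EmissionRecord(
                    process_id=proc_id,
                    species_id=participants[0].chemical_id,
                    medium=Medium.AIR,
                    value=noisy,
                    basis=Basis.MEASURED,
                )
            )

    return SeriesData(
        chemicals=tuple(chemicals),
        processes=tuple(processes),
        emissions=tuple(emissions),
        truth=truth,
        spec=spec,
    )
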