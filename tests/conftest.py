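import pytest

from emitra import (
    ChemicalRecord,
    PropertyName,
    PropertyValue,
    Provenance,
    load_case_study,
)

CUMENE_SMILES = "CC(C)c1ccccc1"
P_CYMENE_SMILES = "CC(C)c1ccc(C)cc1"
DIPB_SMILES = "CC(C)c1ccc(C(C)C)cc1"
TIPB_SMILES = "CC(C)c1cc(C(C)C)cc(C(C)C)c1"


@pytest.fixture()
def case_study():
    return load_case_study()


@pytest.fixture()
def alkylbenzene_library():
    """Four-member analogue library for the p-cymene target."""
    return [
        ChemicalRecord(id="cumene", name="cumene", smiles=CUMENE_SMILES),
        ChemicalRecord(
            id="1,4-diisopropylbenzene",
            name="1,4-diisopropylbenzene",
            smiles=DIPB_SMILES,
        ),
        ChemicalRecord(
            id="1,3,5-triisopropylbenzene",
            name="1,3,5-triisopropylbenzene",
            smiles=TIPB_SMILES,
        ),
        ChemicalRecord(id="methane", name="methane", smiles="C"),
    ]


@pytest.fixture()
def p_cymene_record():
    return ChemicalRecord(id="p-cymene", name="p-cymene", smiles=P_CYMENE_SMILES)


def chem(chem_id: str, smiles: str, **props) -> ChemicalRecord:
    """Shorthand ChemicalRecord builder with database-provenance properties."""
    properties = {
        PropertyName(k): PropertyValue(
            name=PropertyName(k), value=v, provenance=Provenance.DATABASE
        )
        for k, v in props.items()
    }
    return ChemicalRecord(id=chem_id, name=chem_id, smiles=smiles, properties=properties)
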