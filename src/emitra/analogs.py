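"""Analogue ranking and structural-category validation.

Source-chemical selection works in two ways. The analogue route ranks a
library of candidates by fingerprint Tanimoto similarity to the target
and picks the closest. The category route groups the target with two or
more structurally related source chemicals and validates the group
against the standard structural rules: every member shares the same
functional groups, and consecutive members (ordered by carbon count)
differ by at most two carbon atoms — the homologous-series condition
under which properties are expected to follow a regular trend.
"""

from __future__ import annotations

from rdkit import Chem

from .chem import (
    FingerprintParams,
    fingerprint,
    molecular_weight,
    parse_structure,
    tanimoto,
)
from .records import (
    AnalogueMatch,
    Category,
    ChemicalRecord,
    GroupingMode,
    PairCheck,
)

# Default analogue cutoffs per fingerprint kind. Similarity values are
# not comparable across schemes: atom-pair scores for accepted analogues
# run much lower than circular-fingerprint scores for the same pairs, so
# each built-in scheme carries its own calibrated cutoff.
DEFAULT_CUTOFFS: dict[str, float] = {
    "atompair": 0.3,
    "morgan": 0.7,
    "rdkit": 0.7,
}

MAX_ADJACENT_CARBON_DIFF = 2

# Substructure patterns for functional-group detection. The group
# multiset (pattern name -> match count) is what category validation
# compares between members.
FUNCTIONAL_GROUP_SMARTS: dict[str, str] = {
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "ester": "[CX3](=O)[OX2H0][#6]",
    "aldehyde": "[CX3H1](=O)[#6]",
    "ketone": "[#6][CX3](=O)[#6]",
    "alcohol": "[OX2H][CX4]",
    "ether": "[OD2]([CX4])[CX4]",
    "amine": "[NX3;H2,H1;!$(NC=O)]",
    "amide": "[NX3][CX3](=O)",
    "nitrile": "[NX1]#[CX2]",
    "alkyl_halide": "[CX4][F,Cl,Br,I]",
    "aromatic_ring": "[cR1]1[cR1][cR1][cR1][cR1][cR1]1",
    "alkene": "[CX3]=[CX3]",
    "alkyne": "[CX2]#[CX2]",
}

_COMPILED = {name: Chem.MolFromSmarts(s) for name, s in FUNCTIONAL_GROUP_SMARTS.items()}


def default_cutoff(params: FingerprintParams | None = None) -> float:
    params = params or FingerprintParams()
    return DEFAULT_CUTOFFS.get(params.kind, 0.7)


def functional_groups(smiles: str) -> dict[str, int]:
    """Count occurrences of each known functional group in a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    counts: dict[str, int] = {}
    for name, patt in _COMPILED.items():
        n = len(mol.GetSubstructMatches(patt, uniquify=True))
        if n:
            counts[name] = n
    return counts


def find_analogues(
    target: ChemicalRecord,
    library: list[ChemicalRecord],
    cutoff: float | None = None,
    params: FingerprintParams | None = None,
    measured_ids: frozenset[str] = frozenset(),
) -> list[AnalogueMatch]:
    """Rank library chemicals by Tanimoto similarity to the target.

    Returns matches with similarity >= ``cutoff`` (scheme-calibrated
    default), sorted by descending similarity. Ties are broken by
    smaller molecular-weight difference to the target, then by id, so
    the ranking is invariant under library permutation. The target
    itself (same id) is excluded.

    Parameters
    ----------
    measured_ids:
        Ids of chemicals with measured emission data; flagged on the
        matches so the caller can prefer data-rich analogues.
    """
    if not library:
        raise ValueError("analogue library must be non-empty")
    params = params or FingerprintParams()
    if cutoff is None:
        cutoff = default_cutoff(params)
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")

    t_struct = parse_structure(target.smiles)
    t_fp = fingerprint(t_struct, params)
    t_mw = molecular_weight(t_struct)

    scored: list[tuple[float, float, str, ChemicalRecord]] = []
    for rec in library:
        if rec.id == target.id:
            continue
        struct = parse_structure(rec.smiles)
        sim = tanimoto(t_fp, fingerprint(struct, params)).value
        if sim >= cutoff:
            scored.append((sim, abs(molecular_weight(struct) - t_mw), rec.id, rec))

    scored.sort(key=lambda item: (-item[0], item[1], item[2]))
    return [
        AnalogueMatch(
            target_id=target.id,
            source_id=rec.id,
            similarity=sim,
            rank=i + 1,
            has_measured_emissions=rec.id in measured_ids,
        )
        for i, (sim, _dmw, _id, rec) in enumerate(scored)
    ]


def validate_category(members: list[ChemicalRecord]) -> Category:
    """Validate a candidate structural category.

    Members are ordered by carbon count (id as tie-break); every
    consecutive pair is checked for an identical functional-group
    multiset and a carbon-count difference of at most
    ``MAX_ADJACENT_CARBON_DIFF``. Failures are recorded per pair with
    reasons, never raised — an invalid category is a reportable result.
    """
    if len(members) < 2:
        raise ValueError("a category requires at least 2 members")

    parsed = {m.id: parse_structure(m.smiles) for m in members}
    groups = {m.id: functional_groups(m.smiles) for m in members}
    ordered = sorted(members, key=lambda m: (parsed[m.id].carbon_count, m.id))

    common = set(groups[ordered[0].id])
    for m in ordered[1:]:
        common &= set(groups[m.id])
    shared_feature = ", ".join(sorted(common)) if common else "none"

    checks: list[PairCheck] = []
    for a, b in zip(ordered, ordered[1:]):
        reasons: list[str] = []
        if groups[a.id] != groups[b.id]:
            only_a = set(groups[a.id].items()) - set(groups[b.id].items())
            only_b = set(groups[b.id].items()) - set(groups[a.id].items())
            reasons.append(
                "functional group mismatch: "
                f"{sorted(k for k, _ in only_a)} vs {sorted(k for k, _ in only_b)}"
            )
        diff = abs(parsed[a.id].carbon_count - parsed[b.id].carbon_count)
        if diff > MAX_ADJACENT_CARBON_DIFF:
            reasons.append(
                f"chain length difference > {MAX_ADJACENT_CARBON_DIFF} "
                f"({diff} carbon atoms)"
            )
        checks.append(
            PairCheck(
                first_id=a.id, second_id=b.id, passed=not reasons,
                reasons=tuple(reasons),
            )
        )

    return Category(
        member_ids=[m.id for m in ordered],
        shared_feature=shared_feature,
        validation=checks,
    )


def select_mode(n_targets: int, n_sources: int) -> GroupingMode:
    """Classify the read-across grouping by analogue and target counts.

    One analogue for one target is one-to-one; one analogue reused for
    several targets is one-to-many; several analogues pooled for a
    single target is many-to-one; and several for several is
    many-to-many.
    """
    if n_targets < 1 or n_sources < 1:
        raise ValueError("target and source counts must be >= 1")
    if n_sources == 1:
        return GroupingMode.ONE_TO_ONE if n_targets == 1 else GroupingMode.ONE_TO_MANY
    return GroupingMode.MANY_TO_ONE if n_targets == 1 else GroupingMode.MANY_TO_MANY
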