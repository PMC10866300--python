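"""Qualitative uncertainty grading of read-across estimates.

Each estimate is graded low / moderate / high from four drivers:
structural similarity of target and source, similarity of the two
manufacturing processes, the quality basis of the source emission data,
and whether trend-filled properties or extrapolation entered the
derivation. The overall grade is the worst driver — high data quality
together with very similar chemicals and processes yields low
uncertainty, and degrading any one driver can only worsen the grade.

The driver set and numeric thresholds are this package's
reconstruction of the qualitative rule; no published numeric criteria
exist for it. Thresholds are configuration keys, and because Tanimoto
values are not comparable across fingerprint schemes the similarity
thresholds default per scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import FingerprintParams
from .records import Basis, Driver, Grade, UncertaintyGrade

# (low, moderate) similarity thresholds per fingerprint kind: similarity
# >= low grades low, >= moderate grades moderate, below grades high.
# Atom-pair similarities for accepted analogue pairs run far lower than
# circular-fingerprint similarities for the same pairs, hence the
# scheme-specific calibration.
SIMILARITY_THRESHOLDS: dict[str, tuple[float, float]] = {
    "atompair": (0.5, 0.25),
    "morgan": (0.9, 0.7),
    "rdkit": (0.9, 0.7),
}


@dataclass(frozen=True)
class GradingThresholds:
    similarity_low: float = 0.9
    similarity_moderate: float = 0.7

    @classmethod
    def for_scheme(cls, params: FingerprintParams | None = None) -> "GradingThresholds":
        params = params or FingerprintParams()
        low, moderate = SIMILARITY_THRESHOLDS.get(params.kind, (0.9, 0.7))
        return cls(similarity_low=low, similarity_moderate=moderate)


def grade(
    similarity: float,
    process_compatible: bool,
    process_warnings: int,
    source_basis: Basis,
    any_trend_filled_properties: bool = False,
    extrapolated: bool = False,
    thresholds: GradingThresholds | None = None,
) -> UncertaintyGrade:
    """Grade an estimate's uncertainty from its drivers.

    Parameters
    ----------
    similarity:
        Tanimoto similarity of target and source under the scheme the
        ``thresholds`` were calibrated for.
    process_compatible, process_warnings:
        Outcome of the process-compatibility check. Incompatible
        processes grade high (estimation should have been blocked
        upstream); warnings grade moderate.
    source_basis:
        Basis of the source emission data: measured grades low,
        estimated moderate; a source that is itself a read-across
        result grades high, since confidence then rests on the
        reliability of that earlier estimate.
    any_trend_filled_properties, extrapolated:
        Either forces at least moderate uncertainty.
    """
    th = thresholds or GradingThresholds()

    if similarity >= th.similarity_low:
        sim_level = Grade.LOW
    elif similarity >= th.similarity_moderate:
        sim_level = Grade.MODERATE
    else:
        sim_level = Grade.HIGH

    if not process_compatible:
        proc_level = Grade.HIGH
    elif process_warnings > 0:
        proc_level = Grade.MODERATE
    else:
        proc_level = Grade.LOW

    basis_level = {
        Basis.MEASURED: Grade.LOW,
        Basis.ESTIMATED: Grade.MODERATE,
        Basis.READ_ACROSS: Grade.HIGH,
    }[source_basis]

    drivers = [
        Driver(criterion="structural_similarity", level=sim_level),
        Driver(criterion="process_similarity", level=proc_level),
        Driver(criterion="source_data_basis", level=basis_level),
        Driver(
            criterion="trend_filled_properties",
            level=Grade.MODERATE if any_trend_filled_properties else Grade.LOW,
        ),
        Driver(
            criterion="extrapolation",
            level=Grade.MODERATE if extrapolated else Grade.LOW,
        ),
    ]
    overall = max((d.level for d in drivers), key=lambda g: g.severity)
    return UncertaintyGrade(grade=overall, drivers=tuple(drivers))
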