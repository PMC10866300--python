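"""Readers and writers for the on-disk interchange formats.

Chemicals with their property tables travel as CSV (one ``*_src``
provenance column per property column, ``NA`` for missing), process
metadata as JSON, emissions as CSV, and run configuration as strict
YAML. Schema violations are reported with row/column coordinates;
write followed by read is the identity on every record type.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .records import (
    Basis,
    CatalystClass,
    ChemicalRecord,
    EmissionRecord,
    EstimationMode,
    FactorRule,
    Medium,
    Participant,
    ProcessRecord,
    PropertyName,
    PropertyValue,
    Provenance,
    Role,
)

NA = "NA"

_PROPERTY_COLUMNS = [p.value for p in PropertyName]


class SchemaError(ValueError):
    """A malformed table cell, reported with its coordinates."""


# ---------------------------------------------------------------- chemicals

def write_chemicals_csv(chemicals: list[ChemicalRecord], path: str | Path) -> None:
    rows = []
    for chem in chemicals:
        row: dict[str, Any] = {"id": chem.id, "name": chem.name, "smiles": chem.smiles}
        for prop in PropertyName:
            pv = chem.get(prop)
            row[prop.value] = pv.value if pv else NA
            row[f"{prop.value}_src"] = pv.provenance.value if pv else NA
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_chemicals_csv(path: str | Path) -> list[ChemicalRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("id", "name", "smiles"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    chemicals = []
    for i, row in df.iterrows():
        properties: dict[PropertyName, PropertyValue] = {}
        for prop in PropertyName:
            raw = row.get(prop.value, NA)
            if raw in (NA, ""):
                continue
            try:
                value = float(raw)
            except ValueError as exc:
                raise SchemaError(
                    f"{path}: row {i + 2}, column {prop.value}: "
                    f"not a number: {raw!r}"
                ) from exc
            src = row.get(f"{prop.value}_src", Provenance.DATABASE.value)
            if src in (NA, ""):
                src = Provenance.DATABASE.value
            try:
                properties[prop] = PropertyValue(
                    name=prop, value=value, provenance=Provenance(src)
                )
            except (ValueError, ValidationError) as exc:
                raise SchemaError(
                    f"{path}: row {i + 2}, column {prop.value}: {exc}"
                ) from exc
        chemicals.append(
            ChemicalRecord(
                id=row["id"], name=row["name"], smiles=row["smiles"],
                properties=properties,
            )
        )
    return chemicals


# ---------------------------------------------------------------- processes

def write_processes_json(processes: list[ProcessRecord], path: str | Path) -> None:
    payload = [proc.model_dump(mode="json") for proc in processes]
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_processes_json(path: str | Path) -> list[ProcessRecord]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    processes = []
    for i, entry in enumerate(payload):
        try:
            processes.append(ProcessRecord.model_validate(entry))
        except ValidationError as exc:
            raise SchemaError(f"{path}: process record {i}: {exc}") from exc
    return processes


# ---------------------------------------------------------------- emissions

_EMISSION_COLUMNS = ["process_id", "species_id", "medium", "kg_per_kg_product", "basis"]


def write_emissions_csv(emissions: list[EmissionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "process_id": e.process_id,
                "species_id": e.species_id,
                "medium": e.medium.value,
                # repr round-trips float64 exactly
                "kg_per_kg_product": repr(e.value),
                "basis": e.basis.value,
            }
            for e in emissions
        ],
        columns=_EMISSION_COLUMNS,
    ).to_csv(path, index=False)


def read_emissions_csv(path: str | Path) -> list[EmissionRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _EMISSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    emissions = []
    for i, row in df.iterrows():
        coords = f"{path}: row {i + 2}"
        try:
            value = float(row["kg_per_kg_product"])
        except ValueError as exc:
            raise SchemaError(
                f"{coords}, column kg_per_kg_product: not a number: "
                f"{row['kg_per_kg_product']!r}"
            ) from exc
        if value < 0:
            raise SchemaError(
                f"{coords}, column kg_per_kg_product: value must be >= 0"
            )
        try:
            emissions.append(
                EmissionRecord(
                    process_id=row["process_id"],
                    species_id=row["species_id"],
                    medium=Medium(row["medium"]),
                    value=value,
                    basis=Basis(row["basis"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise SchemaError(f"{coords}: {exc}") from exc
    return emissions


# ------------------------------------------------------------------ config

class RunConfig(BaseModel):
    """A full run configuration, loadable from strict YAML.

    Unknown keys are rejected so typos cannot silently change a run.
    """

    model_config = ConfigDict(extra="forbid")

    target_id: str
    chemicals_csv: Optional[str] = None
    processes_json: Optional[str] = None
    emissions_csv: Optional[str] = None
    use_case_study: bool = False
    mode: EstimationMode = EstimationMode.CLOSEST
    factor_rule: FactorRule = FactorRule.GEOMEAN
    factor_properties: list[PropertyName] = [PropertyName.VP]
    fingerprint_kind: str = "atompair"
    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048
    cutoff: Optional[float] = None
    medium: Medium = Medium.AIR
    descriptor: str = "carbon_count"
    fill_gaps: bool = True
    seed: int = 0
    output_dir: Optional[str] = None


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    try:
        config = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    base = Path(path).parent
    for attr in ("chemicals_csv", "processes_json", "emissions_csv"):
        rel = getattr(config, attr)
        if rel is not None:
            resolved = (base / rel) if not Path(rel).is_absolute() else Path(rel)
            if not resolved.exists():
                raise SchemaError(f"{path}: {attr} path does not exist: {rel}")
            setattr(config, attr, str(resolved))
    return config


# ------------------------------------------------------------------ report

def report_to_dict(report) -> dict:
    """Convert a FrameworkReport into a JSON-serializable dictionary."""

    def convert(obj):
        if isinstance(obj, BaseModel):
            return obj.model_dump(mode="json")
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                f.name: convert(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            }
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return convert(report)


def write_report(report, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a framework report as JSON plus a TSV of estimated rows."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    json_path.write_text(
        json.dumps(report_to_dict(report), indent=2), encoding="utf-8"
    )
    tsv_path = out / "estimates.tsv"
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write(
            "process_id\tspecies_id\tmedium\tkg_per_kg_product\tmode\t"
            "overall_factor\tuncertainty\n"
        )
        for est in report.estimates:
            unc = est.uncertainty.grade.value if est.uncertainty else NA
            fh.write(
                f"{est.record.process_id}\t{est.record.species_id}\t"
                f"{est.record.medium.value}\t{est.record.value:.6g}\t"
                f"{est.mode.value}\t{est.overall_factor:.6g}\t{unc}\n"
            )
    return json_path, tsv_path
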