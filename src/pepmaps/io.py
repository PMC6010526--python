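"""Table readers/writers, bundled reference tables, and run manifests.

The primary dialect is TSV: tab-separated, UTF-8, ``.`` decimal, header
row mandatory.  Peptides are stored as bare one-letter strings; dash
separated three-letter names are accepted on input and converted.
"""

from __future__ import annotations

import hashlib
import importlib.metadata
import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import parse_peptide
from .kinetics import DoseResponseCurve, KineticsDataset
from .qsar import ActivityRecord


def _fixture_path(name: str) -> str:
    return str(importlib.resources.files("pepmaps.data").joinpath(name))


def read_activity_table(path: str | Path | None = None) -> list[ActivityRecord]:
    """Read a ``peptide  ic50_uM`` TSV into validated activity records.

    Defaults to the bundled 33-peptide reference panel.  Rows with
    non-positive IC50, unknown residues or duplicate sequences raise with
    the offending (1-based, header-exclusive) row number.
    """
    if path is None:
        path = _fixture_path("table1_activity.tsv")
    table = pd.read_csv(path, sep="\t", comment="#")
    if not {"peptide", "ic50_uM"}.issubset(table.columns):
        raise ValueError("activity table needs 'peptide' and 'ic50_uM' columns")
    records = []
    seen: dict[str, int] = {}
    for row_no, row in enumerate(table.itertuples(index=False), start=1):
        try:
            record = ActivityRecord(str(row.peptide), float(row.ic50_uM))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {row_no}: {exc}") from exc
        if record.peptide in seen:
            raise ValueError(
                f"row {row_no}: duplicate peptide {record.peptide!r} "
                f"(first seen at row {seen[record.peptide]})"
            )
        seen[record.peptide] = row_no
        records.append(record)
    return records


def write_activity_table(records: list[ActivityRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"peptide": [r.peptide for r in records], "ic50_uM": [r.ic50 for r in records]}
    ).to_csv(path, sep="\t", index=False)


def load_analog_table() -> pd.DataFrame:
    """The bundled analog panel: design/validation tripeptides with their
    printed per-position normalized v3 values, measured IC50 (where
    determined), inhibition mode and protease-stability flag."""
    table = pd.read_csv(_fixture_path("table2_analogs.tsv"), sep="\t")
    table["peptide"] = table["peptide"].map(parse_peptide)
    return table


def read_design_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    if not {"x", "y", "z"}.issubset(table.columns):
        raise ValueError("design table needs 'x', 'y', 'z' columns")
    return table


def read_dose_response(path: str | Path) -> DoseResponseCurve:
    """Read ``conc_uM  rep1  rep2 ...`` TSV into a dose-response curve."""
    table = pd.read_csv(path, sep="\t", comment="#")
    if "conc_uM" not in table.columns:
        raise ValueError("dose-response table needs a 'conc_uM' column")
    reps = [c for c in table.columns if c.startswith("rep")]
    if not reps:
        raise ValueError("dose-response table needs rep1..repN columns")
    return DoseResponseCurve(
        concentrations=table["conc_uM"].to_numpy(dtype=float),
        inhibition=table[reps].to_numpy(dtype=float),
    )


def write_dose_response(curve: DoseResponseCurve, path: str | Path) -> None:
    out = pd.DataFrame(
        curve.inhibition,
        columns=[f"rep{j + 1}" for j in range(curve.inhibition.shape[1])],
    )
    out.insert(0, "conc_uM", curve.concentrations)
    out.to_csv(path, sep="\t", index=False)


def read_kinetics_table(path: str | Path) -> KineticsDataset:
    return KineticsDataset(pd.read_csv(path, sep="\t", comment="#"))


def write_kinetics_table(data: KineticsDataset, path: str | Path) -> None:
    data.table.to_csv(path, sep="\t", index=False)


def write_manifest(
    path: str | Path,
    command: str,
    params: dict,
    inputs: list[str | Path] = (),
) -> None:
    """Record everything needed to re-run a stage bit-identically."""
    try:
        version = importlib.metadata.version("pepmaps")
    except importlib.metadata.PackageNotFoundError:
        version = "unknown"
    digests = {}
    for p in inputs:
        p = Path(p)
        if p.exists():
            digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "package": "pepmaps",
        "version": version,
        "command": command,
        "params": {k: _jsonable(v) for k, v in params.items()},
        "input_sha256": digests,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _jsonable(value):
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, Path):
        return str(value)
    return value
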