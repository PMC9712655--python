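"""Chemical library records and plain-text I/O.

A library is a list of :class:`ChemicalRecord`: one entry per chemical with
its identifiers, the raw structure string as received (SMILES), and a
per-endpoint activity label.  Labels take one of three states: ``active``,
``inactive`` or ``excluded`` — the last one holds chemicals whose activity is
too uncertain to use on either side of a binary model (e.g. borderline
actives, single-dose-only responders).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InputError

LABEL_STATES = ("active", "inactive", "excluded")


@dataclass
class ChemicalRecord:
    """One library entry.

    Parameters
    ----------
    id:
        Unique identifier within the library.
    smiles_raw:
        Structure string as received (uncurated SMILES).
    casrn, name:
        Optional registry number and chemical name.
    labels:
        Mapping endpoint name -> one of ``active``/``inactive``/``excluded``.
    """

    id: str
    smiles_raw: str
    casrn: str = ""
    name: str = ""
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for endpoint, state in self.labels.items():
            if state not in LABEL_STATES:
                raise InputError(
                    f"label for endpoint {endpoint!r} on chemical {self.id!r} "
                    f"must be one of {LABEL_STATES}, got {state!r}"
                )


def check_unique_ids(records: Iterable[ChemicalRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise InputError(f"duplicate chemical id {rec.id!r}")
        seen.add(rec.id)


def write_library_csv(records: Iterable[ChemicalRecord], path: str | Path) -> None:
    """Write a library as CSV with columns id, casrn, name, smiles."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["id", "casrn", "name", "smiles"])
        for rec in records:
            writer.writerow([rec.id, rec.casrn, rec.name, rec.smiles_raw])


def write_labels_csv(records: Iterable[ChemicalRecord], path: str | Path) -> None:
    """Write activity labels as long-format CSV (id, endpoint, active)."""
    code = {"active": 1, "inactive": 0, "excluded": ""}
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["id", "endpoint", "active"])
        for rec in records:
            for endpoint in sorted(rec.labels):
                writer.writerow([rec.id, endpoint, code[rec.labels[endpoint]]])


def read_library_csv(path: str | Path) -> list[ChemicalRecord]:
    """Read a library CSV (id, casrn, name, smiles); extra columns ignored."""
    records = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or "id" not in reader.fieldnames or "smiles" not in reader.fieldnames:
            raise InputError(f"{path}: expected header with at least 'id' and 'smiles' columns")
        for row in reader:
            records.append(
                ChemicalRecord(
                    id=row["id"],
                    smiles_raw=row["smiles"],
                    casrn=row.get("casrn", "") or "",
                    name=row.get("name", "") or "",
                )
            )
    check_unique_ids(records)
    return records


def attach_labels(
    records: list[ChemicalRecord], labels: Mapping[str, Mapping[str, str]]
) -> list[ChemicalRecord]:
    """Attach per-endpoint labels (endpoint -> id -> state) to records in place."""
    for rec in records:
        for endpoint, mapping in labels.items():
            if rec.id in mapping:
                state = mapping[rec.id]
                if state not in LABEL_STATES:
                    raise InputError(
                        f"label {state!r} for {rec.id!r} not in {LABEL_STATES}"
                    )
                rec.labels[endpoint] = state
    return records
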