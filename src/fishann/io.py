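"""File I/O: the per-fish record CSV dialect and fitted-model JSON documents.

Record CSV dialect: UTF-8, "." decimal, header
``species,concentration_uL_per_L,IT_s,RT_s,WBC,RBC,HGB,HCT``.
Floats are written with ``repr`` so a write/read round trip is lossless.
"""

from __future__ import annotations

import csv
import json
import os
from pathlib import Path

import numpy as np

from .activations import ActivationKind
from .network import NetworkParams
from .pipeline import FittedEndpointModel, NormalizationParams
from .records import CSV_HEADER, Endpoint, FishRecord, Species

__all__ = [
    "RecordParseError",
    "read_records",
    "write_records",
    "save_fitted_model",
    "load_fitted_model",
    "atomic_write_text",
]


class RecordParseError(ValueError):
    """A record CSV violates the dialect; names the column (and row)."""


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write via a temporary file and rename, so readers never see a
    half-written artifact."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def write_records(records: list[FishRecord], path: str | os.PathLike) -> None:
    """Write records in the package CSV dialect (atomically)."""
    lines = [",".join(CSV_HEADER)]
    for r in records:
        lines.append(
            ",".join(
                [r.species.value]
                + [repr(v) for v in (r.concentration, r.IT, r.RT, r.WBC, r.RBC, r.HGB, r.HCT)]
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_records(path: str | os.PathLike) -> list[FishRecord]:
    """Read a record CSV, enforcing the unit-bearing header.

    Raises :class:`RecordParseError` naming the missing column, or the
    row/column of a non-numeric cell.  Row order is preserved.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RecordParseError("empty file") from None
        for col in CSV_HEADER:
            if col not in header:
                raise RecordParseError(f"missing column {col}")
        pos = {col: header.index(col) for col in CSV_HEADER}
        out: list[FishRecord] = []
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            values = {}
            for col in CSV_HEADER[1:]:
                cell = row[pos[col]]
                try:
                    values[col] = float(cell)
                except ValueError:
                    raise RecordParseError(
                        f"non-numeric cell at row {rownum}, column {col}: {cell!r}"
                    ) from None
            try:
                species = Species(row[pos["species"]])
            except ValueError:
                raise RecordParseError(
                    f"unknown species at row {rownum}: {row[pos['species']]!r}"
                ) from None
            out.append(
                FishRecord(
                    species=species,
                    concentration=values["concentration_uL_per_L"],
                    IT=values["IT_s"],
                    RT=values["RT_s"],
                    WBC=values["WBC"],
                    RBC=values["RBC"],
                    HGB=values["HGB"],
                    HCT=values["HCT"],
                )
            )
    return out


def save_fitted_model(model: FittedEndpointModel, path: str | os.PathLike) -> None:
    """Serialize a fitted endpoint model (network + normalization) as JSON."""
    doc = {
        "species": model.species.value,
        "endpoint": model.endpoint.value,
        "trainer": model.trainer,
        "final_mse": model.final_mse,
        "hidden_activation": model.net.hidden_activation.value,
        "output_activation": model.net.output_activation.value,
        "input_weights": model.net.input_weights.tolist(),
        "hidden_biases": model.net.hidden_biases.tolist(),
        "output_weights": model.net.output_weights.tolist(),
        "output_bias": model.net.output_bias,
        "x_norm": {"min": model.x_norm.min, "max": model.x_norm.max},
        "y_norm": {"min": model.y_norm.min, "max": model.y_norm.max},
    }
    atomic_write_text(path, json.dumps(doc, indent=1))


def load_fitted_model(path: str | os.PathLike) -> FittedEndpointModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    net = NetworkParams(
        input_weights=np.asarray(doc["input_weights"], dtype=float),
        hidden_biases=np.asarray(doc["hidden_biases"], dtype=float),
        output_weights=np.asarray(doc["output_weights"], dtype=float),
        output_bias=float(doc["output_bias"]),
        hidden_activation=ActivationKind(doc["hidden_activation"]),
        output_activation=ActivationKind(doc["output_activation"]),
    )
    return FittedEndpointModel(
        species=Species(doc["species"]),
        endpoint=Endpoint(doc["endpoint"]),
        net=net,
        x_norm=NormalizationParams(**doc["x_norm"]),
        y_norm=NormalizationParams(**doc["y_norm"]),
        trainer=str(doc["trainer"]),
        final_mse=float(doc["final_mse"]),
    )
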