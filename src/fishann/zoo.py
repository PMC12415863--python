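"""Packaged transcription of the 18 published trained networks.

Three species x six endpoints, each a fully parameterized 1-H-1 network
transcribed verbatim from the printed weight tables, with the activation,
trainer and architecture metadata the accompanying narrative states.  The
transcription is deliberately uncorrected: printed anomalies (a mislabeled
or unlabeled weight block, a missing neuron row, a row-count/architecture
mismatch) are packaged as printed and surfaced as caveats, never repaired.

Two unresolvable ambiguities are surfaced rather than assumed:

* **Input scale.**  The narrative states inputs were scaled to [0, 1], but
  several printed bias magnitudes (124.454, -2718.79) are implausible for
  normalized inputs.  Every entry therefore carries
  ``input_scale="unverified"``; predictions default to feeding the raw
  concentration in uL/L and tag their output with the scale used.
* **logsig dialect.**  The printed logsig formula is 2/(1+e^-x) (twice the
  canonical logistic).  Entries tagged logsig default to this
  ``LOGSIG_SCALED`` dialect; pass ``logsig_dialect=ActivationKind.LOGSIG``
  to evaluate with the canonical one instead.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .activations import ActivationKind
from .network import NetworkParams, forward
from .records import Endpoint, Species

__all__ = [
    "ZooEntry",
    "ZooPrediction",
    "ValidationCheck",
    "ValidationReport",
    "ZooIntegrityError",
    "DoseRangeError",
    "ModelCardError",
    "load_zoo",
    "get_entry",
    "validate_entry",
    "zoo_predict",
    "export_model_card",
    "import_model_card",
    "load_transcription",
    "dose_range",
]

INPUT_SCALES = ("raw_uL_per_L", "normalized01", "unverified")

_ACTIVATION_TAGS = {"purelin", "tansig", "logsig"}


class ZooIntegrityError(RuntimeError):
    """Packaged transcription data are corrupted or inconsistent."""


class DoseRangeError(ValueError):
    """Concentration outside the species' tested range without override."""


class ModelCardError(ValueError):
    """A model-card document violates the schema."""

    def __init__(self, path: str, message: str):
        super().__init__(f"{path}: {message}")
        self.path = path


@dataclass
class ZooEntry:
    """One transcribed network plus its printed metadata.

    ``architecture`` is the architecture the narrative text states (e.g.
    "1-7-1"); ``params.hidden_size`` may disagree where the printed table
    does, in which case a caveat records the conflict.
    """

    species: Species
    endpoint: Endpoint
    architecture: str
    hidden_activation_tag: str  # purelin | tansig | logsig, as printed
    trainer_name: str
    params: NetworkParams
    neuron_indices: tuple[int, ...]  # printed row indices i
    input_scale: str = "unverified"
    caveats: list[str] = field(default_factory=list)

    @property
    def stated_hidden_size(self) -> int:
        return int(self.architecture.split("-")[1])


@dataclass(frozen=True)
class ZooPrediction:
    """A zoo forward-pass result with its provenance tags."""

    value: float
    species: Species
    endpoint: Endpoint
    concentration: float
    scale_used: str
    input_scale: str
    caveats: tuple[str, ...]


@dataclass(frozen=True)
class ValidationCheck:
    name: str
    passed: bool
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    species: Species
    endpoint: Endpoint
    checks: tuple[ValidationCheck, ...]
    caveats: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)


def _data_text(name: str) -> str:
    return resources.files("fishann.data").joinpath(name).read_text(encoding="utf-8")


def load_transcription() -> list[dict[str, str]]:
    """The packaged weight transcription as rows of *strings*, exactly as
    stored (one row per species, endpoint, printed neuron index)."""
    rows = list(csv.DictReader(_data_text("zoo_weights.csv").splitlines()))
    if not rows:
        raise ZooIntegrityError("zoo_weights.csv is empty")
    return rows


def _hidden_kind(tag: str, logsig_dialect: ActivationKind) -> ActivationKind:
    if tag == "purelin":
        return ActivationKind.PURELIN
    if tag == "tansig":
        return ActivationKind.TANSIG
    if tag == "logsig":
        return ActivationKind(logsig_dialect)
    raise ZooIntegrityError(f"unknown activation tag {tag!r}")


def load_zoo(
    logsig_dialect: ActivationKind = ActivationKind.LOGSIG_SCALED,
) -> list[ZooEntry]:
    """Load all 18 transcribed networks.

    Parameters
    ----------
    logsig_dialect
        Dialect used for entries whose printed activation is logsig;
        defaults to the printed 2/(1+e^-x) form.
    """
    if logsig_dialect not in (ActivationKind.LOGSIG, ActivationKind.LOGSIG_SCALED):
        raise ValueError("logsig_dialect must be a logsig variant")
    meta = json.loads(_data_text("zoo_meta.json"))
    rows = load_transcription()
    by_key: dict[tuple[str, str], list[dict[str, str]]] = {}
    for r in rows:
        by_key.setdefault((r["species"], r["endpoint"]), []).append(r)

    entries: list[ZooEntry] = []
    for m in meta["entries"]:
        key = (m["species"], m["endpoint"])
        block = by_key.pop(key, None)
        if not block:
            raise ZooIntegrityError(f"no weight rows for {key}")
        idx = [int(r["i"]) for r in block]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ZooIntegrityError(f"neuron indices corrupt for {key}")
        if m["hidden_activation"] not in _ACTIVATION_TAGS:
            raise ZooIntegrityError(f"bad activation for {key}")
        try:
            params = NetworkParams(
                input_weights=np.array([float(r["W1"]) for r in block]),
                hidden_biases=np.array([float(r["theta_i"]) for r in block]),
                output_weights=np.array([float(r["Lw"]) for r in block]),
                output_bias=float(m["output_bias"]),
                hidden_activation=_hidden_kind(m["hidden_activation"], logsig_dialect),
                output_activation=ActivationKind.PURELIN,
            )
        except ValueError as exc:  # noqa: PERF203 - integrity boundary
            raise ZooIntegrityError(f"invalid parameters for {key}: {exc}") from exc
        entries.append(
            ZooEntry(
                species=Species(m["species"]),
                endpoint=Endpoint(m["endpoint"]),
                architecture=m["architecture"],
                hidden_activation_tag=m["hidden_activation"],
                trainer_name=m["trainer"],
                params=params,
                neuron_indices=tuple(idx),
                input_scale="unverified",
                caveats=list(m["caveats"]),
            )
        )
    if by_key:
        raise ZooIntegrityError(f"orphan weight rows: {sorted(by_key)}")
    if len(entries) != 18:
        raise ZooIntegrityError(f"expected 18 entries, found {len(entries)}")
    if len({(e.species, e.endpoint) for e in entries}) != 18:
        raise ZooIntegrityError("duplicate (species, endpoint) pairs")
    return entries


def get_entry(
    species: Species,
    endpoint: Endpoint,
    logsig_dialect: ActivationKind = ActivationKind.LOGSIG_SCALED,
) -> ZooEntry:
    """The zoo entry for one (species, endpoint) pair."""
    species, endpoint = Species(species), Endpoint(endpoint)
    for e in load_zoo(logsig_dialect):
        if e.species is species and e.endpoint is endpoint:
            return e
    raise KeyError(f"no zoo entry for ({species}, {endpoint})")  # pragma: no cover


def validate_entry(entry: ZooEntry) -> ValidationReport:
    """Audit one entry: shape vs stated architecture, finiteness, metadata.

    Reports, never repairs; printed inconsistencies fail their check and the
    packaged caveat explains them.
    """
    checks = []
    H = entry.params.hidden_size
    stated = entry.stated_hidden_size
    if H == stated and entry.neuron_indices == tuple(range(1, H + 1)):
        checks.append(
            ValidationCheck("architecture_agreement", True,
                            f"{H} rows match stated {entry.architecture}")
        )
    else:
        missing = sorted(set(range(1, stated + 1)) - set(entry.neuron_indices))
        detail = f"text says 1-{stated}-1, table block has {H} rows"
        if missing:
            gaps = ", ".join(f"i={i}" for i in missing)
            detail = (
                f"row {gaps} absent from printed table; "
                f"{H} rows vs. stated 1-{stated}-1"
            )
        checks.append(ValidationCheck("architecture_agreement", False, detail))
    finite = all(
        np.all(np.isfinite(v))
        for v in (
            entry.params.input_weights,
            entry.params.hidden_biases,
            entry.params.output_weights,
            [entry.params.output_bias],
        )
    )
    checks.append(ValidationCheck("finite_parameters", finite, ""))
    checks.append(
        ValidationCheck(
            "output_activation_purelin",
            entry.params.output_activation is ActivationKind.PURELIN,
            "",
        )
    )
    checks.append(
        ValidationCheck(
            "caveats_cover_anomalies",
            all(c.passed for c in checks) or bool(entry.caveats),
            "; ".join(entry.caveats),
        )
    )
    return ValidationReport(
        species=entry.species,
        endpoint=entry.endpoint,
        checks=tuple(checks),
        caveats=tuple(entry.caveats),
    )


def dose_range(species: Species) -> tuple[float, float]:
    """Tested concentration range (uL/L) for one species."""
    meta = json.loads(_data_text("zoo_meta.json"))
    lo, hi = meta["dose_ranges_uL_per_L"][Species(species).value]
    return float(lo), float(hi)


def zoo_predict(
    species: Species,
    endpoint: Endpoint,
    c: float,
    scale: str | None = None,
    *,
    allow_extrapolation: bool = False,
    logsig_dialect: ActivationKind = ActivationKind.LOGSIG_SCALED,
) -> ZooPrediction:
    """Forward pass of a transcribed network at concentration *c* (uL/L).

    ``scale`` selects how *c* is presented to the network:
    ``"raw_uL_per_L"`` (default) feeds it unchanged; ``"normalized01"``
    min-max scales it over the species' tested range.  The true scale of
    the printed weights is unverified, so the result always carries both
    the entry's ``input_scale`` tag and the scale actually used.
    """
    entry = get_entry(species, endpoint, logsig_dialect)
    lo, hi = dose_range(entry.species)
    if not (lo <= c <= hi) and not allow_extrapolation:
        raise DoseRangeError(
            f"{c} uL/L outside tested range [{lo}, {hi}] for {entry.species}; "
            "pass allow_extrapolation=True to override"
        )
    scale = scale or "raw_uL_per_L"
    if scale == "raw_uL_per_L":
        x = float(c)
    elif scale == "normalized01":
        x = (float(c) - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return ZooPrediction(
        value=forward(entry.params, x),
        species=entry.species,
        endpoint=entry.endpoint,
        concentration=float(c),
        scale_used=scale,
        input_scale=entry.input_scale,
        caveats=tuple(entry.caveats),
    )


# ---------------------------------------------------------------------------
# model cards

_CARD_FIELDS = (
    "species",
    "endpoint",
    "architecture",
    "hidden_activation",
    "output_activation",
    "trainer",
    "input_weights",
    "hidden_biases",
    "output_weights",
    "output_bias",
    "neuron_indices",
    "input_scale",
    "caveats",
)


def export_model_card(entry: ZooEntry) -> dict:
    """A JSON-serializable document capturing every field at full precision."""
    p = entry.params
    return {
        "species": entry.species.value,
        "endpoint": entry.endpoint.value,
        "architecture": entry.architecture,
        "hidden_activation": p.hidden_activation.value,
        "output_activation": p.output_activation.value,
        "trainer": entry.trainer_name,
        "input_weights": [float(v) for v in p.input_weights],
        "hidden_biases": [float(v) for v in p.hidden_biases],
        "output_weights": [float(v) for v in p.output_weights],
        "output_bias": float(p.output_bias),
        "neuron_indices": list(entry.neuron_indices),
        "input_scale": entry.input_scale,
        "caveats": list(entry.caveats),
    }


def import_model_card(document: dict) -> ZooEntry:
    """Rebuild a :class:`ZooEntry` from a model-card document.

    Raises :class:`ModelCardError` naming the offending field on any schema
    violation.
    """
    if not isinstance(document, dict):
        raise ModelCardError("$", "model card must be a mapping")
    for name in _CARD_FIELDS:
        if name not in document:
            raise ModelCardError(name, "missing required field")
    try:
        species = Species(document["species"])
        endpoint = Endpoint(document["endpoint"])
    except ValueError as exc:
        raise ModelCardError("species/endpoint", str(exc)) from exc
    if document["input_scale"] not in INPUT_SCALES:
        raise ModelCardError("input_scale", f"must be one of {INPUT_SCALES}")
    try:
        params = NetworkParams(
            input_weights=np.asarray(document["input_weights"], dtype=float),
            hidden_biases=np.asarray(document["hidden_biases"], dtype=float),
            output_weights=np.asarray(document["output_weights"], dtype=float),
            output_bias=float(document["output_bias"]),
            hidden_activation=ActivationKind(document["hidden_activation"]),
            output_activation=ActivationKind(document["output_activation"]),
        )
    except (TypeError, ValueError) as exc:
        raise ModelCardError("parameters", str(exc)) from exc
    tag = document["hidden_activation"]
    if tag == ActivationKind.LOGSIG_SCALED.value:
        tag = "logsig"
    return ZooEntry(
        species=species,
        endpoint=endpoint,
        architecture=str(document["architecture"]),
        hidden_activation_tag=tag,
        trainer_name=str(document["trainer"]),
        params=params,
        neuron_indices=tuple(int(i) for i in document["neuron_indices"]),
        input_scale=str(document["input_scale"]),
        caveats=list(document["caveats"]),
    )
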