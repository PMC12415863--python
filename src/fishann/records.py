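"""Shared domain vocabulary: species, response endpoints, per-fish records.

Endpoints and their units:

====  =========================  ===========
code  meaning                    unit
====  =========================  ===========
IT    induction time             s
RT    recovery time              s
WBC   white blood cell count     10^3 / uL
RBC   red blood cell count       10^6 / uL
HGB   hemoglobin concentration   g/dL
HCT   hematocrit                 %
====  =========================  ===========
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = ["Species", "Endpoint", "FishRecord", "ENDPOINT_UNITS", "CSV_HEADER"]


class Species(str, enum.Enum):
    COMMON_CARP = "common_carp"
    DANUBE_STURGEON = "danube_sturgeon"
    RAINBOW_TROUT = "rainbow_trout"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Endpoint(str, enum.Enum):
    IT = "IT"
    RT = "RT"
    WBC = "WBC"
    RBC = "RBC"
    HGB = "HGB"
    HCT = "HCT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ENDPOINT_UNITS: dict[Endpoint, str] = {
    Endpoint.IT: "s",
    Endpoint.RT: "s",
    Endpoint.WBC: "10^3/uL",
    Endpoint.RBC: "10^6/uL",
    Endpoint.HGB: "g/dL",
    Endpoint.HCT: "%",
}

#: Column order of the package's record CSV dialect.
CSV_HEADER = [
    "species",
    "concentration_uL_per_L",
    "IT_s",
    "RT_s",
    "WBC",
    "RBC",
    "HGB",
    "HCT",
]


@dataclass(frozen=True)
class FishRecord:
    """One animal: anesthetic concentration and its six response endpoints."""

    species: Species
    concentration: float  # uL/L
    IT: float  # s
    RT: float  # s
    WBC: float  # 10^3/uL
    RBC: float  # 10^6/uL
    HGB: float  # g/dL
    HCT: float  # %

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", Species(self.species))
        for name in ("concentration", "IT", "RT", "WBC", "RBC", "HGB", "HCT"):
            v = float(getattr(self, name))
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
            object.__setattr__(self, name, v)

    def response(self, endpoint: Endpoint) -> float:
        """The value of one endpoint."""
        return getattr(self, Endpoint(endpoint).value)
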