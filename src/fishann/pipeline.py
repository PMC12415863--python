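"""End-to-end analysis: min-max normalization, stratified 18/12 split,
per-endpoint architecture search, performance reporting, and dose
recommendation.

The study design this reproduces: 30 fish per species (10 at each of 3
concentrations), 18 used for training and 12 for testing; one network per
endpoint with concentration as the only input; architectures chosen by
trial and error over hidden-layer size, hidden activation and trainer,
selecting the highest test-set R^2 (conventional) with the smallest
train/test R^2 gap as tie-break.  Normalization parameters are computed on
the training split only and reused for the test split, so no information
leaks from test data into training.

Seeding: every stage derives its own stream from the single run seed via
``numpy.random.SeedSequence(seed, spawn_key=...)``; one integer reproduces
a whole analysis bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .activations import ActivationKind
from .metrics import EvalMetrics, evaluate
from .network import NetworkParams, predict_batch
from .records import Endpoint, FishRecord, Species
from .training import DivergenceError, TrainerConfig, init_network, train

__all__ = [
    "NormalizationParams",
    "FittedEndpointModel",
    "FitReportRow",
    "DoseRecommendation",
    "SearchGrid",
    "CellResult",
    "SearchResult",
    "SearchFailureError",
    "ModelSpec",
    "minmax_normalize",
    "normalize_with",
    "denormalize",
    "split_dataset",
    "architecture_search",
    "fit_endpoint",
    "analyze_species",
    "performance_report",
    "render_report",
    "recommend_dose",
]

# stage tags for seed derivation
_STAGE_SPLIT = 0
_STAGE_INIT = 1


def _derive_seed(seed: int, *key: int) -> int:
    """Deterministic per-stage sub-seed (< 2^31) from the run seed."""
    state = np.random.SeedSequence(int(seed), spawn_key=tuple(key)).generate_state(1)
    return int(state[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# normalization

@dataclass(frozen=True)
class NormalizationParams:
    """Min-max scaling parameters; max must exceed min."""

    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.max > self.min:
            raise ValueError("degenerate range: max must exceed min")


def minmax_normalize(values) -> tuple[np.ndarray, NormalizationParams]:
    """Scale to [0, 1]; both endpoints are attained.

    Raises for constant input (degenerate range).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to normalize")
    params = NormalizationParams(float(v.min()), float(v.max()))
    return normalize_with(v, params), params


def normalize_with(values, params: NormalizationParams) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return (v - params.min) / (params.max - params.min)


def denormalize(scaled, params: NormalizationParams) -> np.ndarray:
    v = np.asarray(scaled, dtype=float)
    out = v * (params.max - params.min) + params.min
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# split

def split_dataset(
    records: list[FishRecord], seed: int
) -> tuple[list[FishRecord], list[FishRecord]]:
    """Stratified 18/12 split: 6 train + 4 test fish at each concentration.

    Stratification keeps every dose level represented in both phases (with
    one input variable, an unstratified split could drop a dose from
    training entirely).  The shuffle within each stratum is seeded.
    """
    if len(records) != 30:
        raise ValueError(f"expected 30 records, got {len(records)}")
    by_dose: dict[float, list[FishRecord]] = {}
    for r in records:
        by_dose.setdefault(r.concentration, []).append(r)
    if len(by_dose) != 3 or any(len(v) != 10 for v in by_dose.values()):
        raise ValueError("expected 10 records at each of 3 concentrations")
    rng = np.random.default_rng(_derive_seed(seed, _STAGE_SPLIT))
    train: list[FishRecord] = []
    test: list[FishRecord] = []
    for dose in sorted(by_dose):
        idx = rng.permutation(10)
        stratum = by_dose[dose]
        train.extend(stratum[i] for i in idx[:6])
        test.extend(stratum[i] for i in idx[6:])
    return train, test


# ---------------------------------------------------------------------------
# fitted models

@dataclass
class FittedEndpointModel:
    """A trained network plus the normalization needed to use it on raw
    concentrations (uL/L) and report predictions in native endpoint units."""

    species: Species
    endpoint: Endpoint
    net: NetworkParams
    x_norm: NormalizationParams
    y_norm: NormalizationParams
    trainer: str
    final_mse: float  # on normalized targets

    @property
    def architecture(self) -> str:
        return self.net.architecture

    def predict(self, cs) -> np.ndarray:
        """Predict endpoint values (native units) at raw concentrations."""
        x = normalize_with(np.atleast_1d(np.asarray(cs, dtype=float)), self.x_norm)
        return denormalize(predict_batch(self.net, x), self.y_norm)


@dataclass(frozen=True)
class ModelSpec:
    """One architecture-search cell: hidden size, activation, trainer."""

    hidden_size: int
    hidden_activation: ActivationKind
    trainer: TrainerConfig


@dataclass(frozen=True)
class FitReportRow:
    species: Species
    endpoint: Endpoint
    architecture: str
    hidden_activation: ActivationKind
    trainer: str
    phase: str  # "training" | "testing"
    metrics: EvalMetrics


@dataclass(frozen=True)
class DoseRecommendation:
    species: Species
    concentration: float  # uL/L
    predicted_IT: float  # s
    predicted_RT: float  # s
    constraints_met: bool


# ---------------------------------------------------------------------------
# architecture search

@dataclass(frozen=True)
class SearchGrid:
    """The trial-and-error grid: H in 4..10, three hidden activations,
    three trainers."""

    hidden_sizes: tuple[int, ...] = tuple(range(4, 11))
    activations: tuple[ActivationKind, ...] = (
        ActivationKind.PURELIN,
        ActivationKind.TANSIG,
        ActivationKind.LOGSIG,
    )
    trainers: tuple[str, ...] = ("gda", "rp", "seq")

    def cells(self, defaults: TrainerConfig | None = None):
        base = defaults or TrainerConfig()
        order = 0
        for H in self.hidden_sizes:
            for act in self.activations:
                for alg in self.trainers:
                    yield order, ModelSpec(
                        H, ActivationKind(act), replace(base, algorithm=alg)
                    )
                    order += 1


@dataclass
class CellResult:
    """One trained grid cell with its train/test metrics (or its failure)."""

    spec: ModelSpec
    order: int
    model: FittedEndpointModel | None
    train_metrics: EvalMetrics | None
    test_metrics: EvalMetrics | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None

    @property
    def r2_gap(self) -> float:
        return abs(self.train_metrics.r2_conventional - self.test_metrics.r2_conventional)


@dataclass
class SearchResult:
    best: CellResult
    leaderboard: list[CellResult]  # every cell, selection order


class SearchFailureError(RuntimeError):
    """Every grid cell failed; carries per-cell diagnostics."""

    def __init__(self, diagnostics: list[str]):
        super().__init__("all architecture-search cells failed")
        self.diagnostics = diagnostics


def _xy(records: list[FishRecord], endpoint: Endpoint):
    cs = np.array([r.concentration for r in records])
    ys = np.array([r.response(endpoint) for r in records])
    return cs, ys


def _fit_cell(
    train_recs, endpoint, spec: ModelSpec, seed: int, species: Species
) -> FittedEndpointModel:
    cs, ys = _xy(train_recs, endpoint)
    xs, x_norm = minmax_normalize(cs)
    yn, y_norm = minmax_normalize(ys)
    net0 = init_network(spec.hidden_size, spec.hidden_activation, seed)
    result = train(net0, xs, yn, spec.trainer)
    return FittedEndpointModel(
        species=species,
        endpoint=endpoint,
        net=result.net,
        x_norm=x_norm,
        y_norm=y_norm,
        trainer=spec.trainer.algorithm,
        final_mse=result.final_mse,
    )


def _cell_metrics(model: FittedEndpointModel, recs, endpoint) -> EvalMetrics:
    cs, ys = _xy(recs, endpoint)
    return evaluate(ys, model.predict(cs))


def architecture_search(
    train_recs: list[FishRecord],
    test_recs: list[FishRecord],
    endpoint: Endpoint,
    grid: SearchGrid | None = None,
    seed: int = 0,
    trainer_defaults: TrainerConfig | None = None,
) -> SearchResult:
    """Train every grid cell and select the best by test-set R^2.

    Selection: maximum conventional R^2 on the test split; ties broken by
    the smaller |train - test| R^2 gap (least overfitting), then smaller
    hidden layer, then grid order.  Cells that diverge are kept on the
    leaderboard with their error; if every cell fails a
    :class:`SearchFailureError` carries the diagnostics.
    """
    endpoint = Endpoint(endpoint)
    grid = grid or SearchGrid()
    if not (grid.hidden_sizes and grid.activations and grid.trainers):
        raise ValueError("empty search grid")
    if {id(r) for r in train_recs} & {id(r) for r in test_recs}:
        raise ValueError("train and test records overlap")
    species = train_recs[0].species
    results: list[CellResult] = []
    for order, spec in grid.cells(trainer_defaults):
        cell_seed = _derive_seed(seed, _STAGE_INIT, _endpoint_tag(endpoint), order)
        try:
            model = _fit_cell(train_recs, endpoint, spec, cell_seed, species)
            tr = _cell_metrics(model, train_recs, endpoint)
            te = _cell_metrics(model, test_recs, endpoint)
            results.append(CellResult(spec, order, model, tr, te))
        except (DivergenceError, ValueError) as exc:
            results.append(
                CellResult(spec, order, None, None, None, error=str(exc))
            )
    ok = [r for r in results if r.ok]
    if not ok:
        raise SearchFailureError(
            [f"cell {r.order} ({r.spec}): {r.error}" for r in results]
        )
    ranked = sorted(
        ok,
        key=lambda r: (
            -r.test_metrics.r2_conventional,
            r.r2_gap,
            r.spec.hidden_size,
            r.order,
        ),
    )
    leaderboard = ranked + [r for r in results if not r.ok]
    return SearchResult(best=ranked[0], leaderboard=leaderboard)


def _endpoint_tag(endpoint: Endpoint) -> int:
    return list(Endpoint).index(Endpoint(endpoint))


# ---------------------------------------------------------------------------
# fitting and reporting

def fit_endpoint(
    records: list[FishRecord],
    endpoint: Endpoint,
    spec: ModelSpec,
    seed: int,
) -> tuple[tuple[FitReportRow, FitReportRow], FittedEndpointModel, NormalizationParams]:
    """Split, train one configuration, and report both phases.

    Metrics are computed on denormalized predictions in native endpoint
    units; the testing row always covers exactly the 12 held-out fish.
    """
    endpoint = Endpoint(endpoint)
    train_recs, test_recs = split_dataset(records, seed)
    cell_seed = _derive_seed(seed, _STAGE_INIT, _endpoint_tag(endpoint), 0)
    model = _fit_cell(train_recs, endpoint, spec, cell_seed, records[0].species)
    rows = tuple(
        FitReportRow(
            species=model.species,
            endpoint=endpoint,
            architecture=model.architecture,
            hidden_activation=spec.hidden_activation,
            trainer=spec.trainer.algorithm,
            phase=phase,
            metrics=_cell_metrics(model, recs, endpoint),
        )
        for phase, recs in (("training", train_recs), ("testing", test_recs))
    )
    return rows, model, model.y_norm


@dataclass
class SpeciesAnalysis:
    """All six endpoint fits for one species."""

    species: Species
    models: dict[Endpoint, FittedEndpointModel]
    rows: list[FitReportRow]  # 6 endpoints x 2 phases
    leaderboards: dict[Endpoint, list[CellResult]]


def analyze_species(
    records: list[FishRecord],
    seed: int,
    grid: SearchGrid | None = None,
    trainer_defaults: TrainerConfig | None = None,
    endpoints: tuple[Endpoint, ...] = tuple(Endpoint),
) -> SpeciesAnalysis:
    """Split once, then run the architecture search for each endpoint."""
    train_recs, test_recs = split_dataset(records, seed)
    species = records[0].species
    models: dict[Endpoint, FittedEndpointModel] = {}
    rows: list[FitReportRow] = []
    boards: dict[Endpoint, list[CellResult]] = {}
    for ep in endpoints:
        ep = Endpoint(ep)
        res = architecture_search(
            train_recs, test_recs, ep, grid=grid, seed=seed,
            trainer_defaults=trainer_defaults,
        )
        best = res.best
        models[ep] = best.model
        boards[ep] = res.leaderboard
        for phase, metrics in (
            ("training", best.train_metrics),
            ("testing", best.test_metrics),
        ):
            rows.append(
                FitReportRow(
                    species=species,
                    endpoint=ep,
                    architecture=best.model.architecture,
                    hidden_activation=best.spec.hidden_activation,
                    trainer=best.spec.trainer.algorithm,
                    phase=phase,
                    metrics=metrics,
                )
            )
    return SpeciesAnalysis(species=species, models=models, rows=rows, leaderboards=boards)


_REPORT_COLUMNS = [
    "species",
    "endpoint",
    "architecture",
    "hidden_activation",
    "trainer",
    "phase",
    "rmse",
    "mape",
    "mape_band",
    "r2_conventional",
    "r2_prednorm",
    "n",
]


def performance_report(rows: list[FitReportRow]) -> pd.DataFrame:
    """Tabulate fit rows as a species x endpoint x phase performance grid."""
    if not rows:
        raise ValueError("no report rows")
    keys = [(r.species, r.endpoint, r.phase) for r in rows]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (species, endpoint, phase) rows")
    data = [
        {
            "species": r.species.value,
            "endpoint": r.endpoint.value,
            "architecture": r.architecture,
            "hidden_activation": r.hidden_activation.value,
            "trainer": r.trainer,
            "phase": r.phase,
            "rmse": r.metrics.rmse,
            "mape": r.metrics.mape,
            "mape_band": r.metrics.mape_band.value,
            "r2_conventional": r.metrics.r2_conventional,
            "r2_prednorm": r.metrics.r2_prednorm,
            "n": r.metrics.n,
        }
        for r in rows
    ]
    df = pd.DataFrame(data, columns=_REPORT_COLUMNS)
    order_sp = [s.value for s in Species]
    order_ep = [e.value for e in Endpoint]
    df["__s"] = df["species"].map(order_sp.index)
    df["__e"] = df["endpoint"].map(order_ep.index)
    df["__p"] = (df["phase"] == "testing").astype(int)
    df = df.sort_values(["__s", "__e", "__p"]).drop(columns=["__s", "__e", "__p"])
    return df.reset_index(drop=True)


def render_report(df: pd.DataFrame) -> str:
    """Aligned-text rendering of a performance report."""
    show = df.copy()
    for col in ("rmse", "mape", "r2_conventional", "r2_prednorm"):
        show[col] = show[col].map(lambda v: f"{v:.4f}")
    return show.to_string(index=False)


# ---------------------------------------------------------------------------
# dose recommendation

def recommend_dose(
    it_model: FittedEndpointModel,
    rt_model: FittedEndpointModel,
    dose_range: tuple[float, float],
    step: float = 1.0,
    it_max_s: float = 180.0,
    rt_max_s: float = 300.0,
) -> DoseRecommendation:
    """Lowest concentration meeting the acceptability criteria.

    Scans the range at the given step and returns the lowest dose whose
    predicted induction time is at most ``it_max_s`` (default 180 s) and
    predicted recovery time at most ``rt_max_s`` (default 300 s).  If no
    dose qualifies, returns the induction-time-minimizing dose with
    ``constraints_met=False``.
    """
    if it_model.species is not rt_model.species:
        raise ValueError("IT and RT models are for different species")
    if it_model.endpoint is not Endpoint.IT or rt_model.endpoint is not Endpoint.RT:
        raise ValueError("models must be an (IT, RT) pair")
    lo, hi = float(dose_range[0]), float(dose_range[1])
    if not hi >= lo or step <= 0:
        raise ValueError("empty or invalid dose range")
    doses = np.arange(lo, hi + step / 2, step)
    its = it_model.predict(doses)
    rts = rt_model.predict(doses)
    ok = (its <= it_max_s) & (rts <= rt_max_s)
    if np.any(ok):
        i = int(np.argmax(ok))  # first qualifying (lowest) dose
        met = True
    else:
        i = int(np.argmin(its))
        met = False
    return DoseRecommendation(
        species=it_model.species,
        concentration=float(doses[i]),
        predicted_IT=float(its[i]),
        predicted_RT=float(rts[i]),
        constraints_met=met,
    )
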