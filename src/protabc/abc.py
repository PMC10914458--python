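"""ABC model choice: rejection, multinomial logistic regression, and a
small neural-network ensemble, plus cross-validation and goodness of fit.

Distances are Euclidean on MAD-standardized summary statistics; the
retained fraction is the tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .summary import STAT_NAMES, SummaryVector

MIN_RETAIN_FACTOR = 10  # regression/NN need >= 10 x n_models retained rows


class ConvergenceError(RuntimeError):
    """Too few retained simulations for regression/NN estimation."""


@dataclass
class SimulationTable:
    """Labelled simulation rows: model, theta draw, 7 summary statistics."""

    labels: np.ndarray
    thetas: np.ndarray
    stats: np.ndarray
    allow_unbalanced: bool = False  # leave-one-out subtables only

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.stats = np.asarray(self.stats, dtype=float)
        if self.stats.ndim != 2 or self.stats.shape[1] != len(STAT_NAMES):
            raise ValueError("stats must be (rows, 7)")
        if not (len(self.labels) == len(self.thetas) == len(self.stats)):
            raise ValueError("column length mismatch")
        if not np.isfinite(self.stats).all():
            raise ValueError("non-finite summary statistics")
        models, counts = np.unique(self.labels, return_counts=True)
        if len(models) < 2:
            raise ValueError("need at least 2 distinct model labels")
        if len(set(counts)) != 1 and not self.allow_unbalanced:
            raise ValueError(
                "each model needs the same number of simulations; got "
                + ", ".join(f"{m}:{c}" for m, c in zip(models, counts))
            )

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    @property
    def models(self) -> list[str]:
        return sorted(set(self.labels))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stats, columns=list(STAT_NAMES))
        df.insert(0, "theta", self.thetas)
        df.insert(0, "model", self.labels)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SimulationTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            labels=df["model"].to_numpy(),
            thetas=df["theta"].to_numpy(),
            stats=df[list(STAT_NAMES)].to_numpy(),
        )

    @classmethod
    def from_rows(cls, rows) -> "SimulationTable":
        labels, thetas, stats = [], [], []
        for label, theta, vec in rows:
            labels.append(label)
            thetas.append(theta)
            stats.append(
                vec.as_array() if isinstance(vec, SummaryVector) else np.asarray(vec)
            )
        return cls(labels=np.array(labels, dtype=object),
                   thetas=np.array(thetas), stats=np.array(stats))


@dataclass
class ABCConfig:
    method: str = "rejection"  # rejection | mnlogistic | neuralnet
    tolerance: float = 0.005
    n_sims_per_model: int = 10_000
    seed: int = 0
    n_nets: int = 10
    hidden_units: int = 5

    def __post_init__(self) -> None:
        if self.method not in ("rejection", "mnlogistic", "neuralnet"):
            raise ValueError(f"unknown ABC method {self.method!r}")
        if not (0 < self.tolerance <= 1):
            raise ValueError("tolerance must lie in (0, 1]")


@dataclass
class PosteriorResult:
    probabilities: dict[str, float]
    retained_indices: np.ndarray
    distances: np.ndarray
    method: str = "rejection"

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")

    @property
    def best_model(self) -> str:
        best = max(self.probabilities.values())
        return sorted(m for m, p in self.probabilities.items() if p == best)[0]


def _as_vector(observed) -> np.ndarray:
    if isinstance(observed, SummaryVector):
        return observed.as_array()
    return np.asarray(observed, dtype=float)


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def standardize(
    table: SimulationTable, observed
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Divide each statistic by its MAD over all simulations.

    Degenerate statistics (MAD = 0) are dropped with a warning.  Returns
    (standardized stats, standardized observed, kept column indices).
    """
    obs = _as_vector(observed)
    mads = np.array([_mad(table.stats[:, j]) for j in range(table.stats.shape[1])])
    keep = np.flatnonzero(mads > 0)
    if keep.size == 0:
        raise ValueError("all summary statistics are degenerate")
    if keep.size < mads.size:
        dropped = [STAT_NAMES[j] for j in np.flatnonzero(mads == 0)]
        warnings.warn(f"dropping degenerate statistics: {', '.join(dropped)}")
    return table.stats[:, keep] / mads[keep], obs[keep] / mads[keep], keep


def _distances(std_stats: np.ndarray, std_obs: np.ndarray) -> np.ndarray:
    return np.sqrt(((std_stats - std_obs[None, :]) ** 2).sum(axis=1))


def _retained(table: SimulationTable, observed, tolerance: float):
    std_stats, std_obs, _ = standardize(table, observed)
    d = _distances(std_stats, std_obs)
    k = math.ceil(tolerance * table.n_rows)
    order = np.argsort(d, kind="stable")  # ties broken by row index
    idx = order[:k]
    return idx, d, std_stats, std_obs


def abc_rejection(observed, table: SimulationTable, config: ABCConfig) -> PosteriorResult:
    """Posterior model probabilities as label frequencies among the
    retained (closest) simulations."""
    idx, d, _, _ = _retained(table, observed, config.tolerance)
    labels = table.labels[idx]
    probs = {m: float(np.mean(labels == m)) for m in table.models}
    return PosteriorResult(
        probabilities=probs, retained_indices=idx, distances=d[idx],
        method="rejection",
    )


def _epanechnikov(d: np.ndarray) -> np.ndarray:
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    w = 1.0 - (d / dmax) ** 2
    if w.sum() == 0:  # all retained rows at d == dmax
        return np.ones_like(d)
    return w


def _check_regression_ok(table: SimulationTable, config: ABCConfig, k: int) -> None:
    need = MIN_RETAIN_FACTOR * len(table.models)
    if k < need:
        raise ConvergenceError(
            f"{config.method} needs >= {need} retained simulations "
            f"({MIN_RETAIN_FACTOR} x {len(table.models)} models) but tolerance "
            f"{config.tolerance} retains only {k}; increase the tolerance"
        )


def _finish_probs(raw: dict[str, float], models, idx, d, method) -> PosteriorResult:
    probs = {m: min(max(raw.get(m, 0.0), 1e-12), 1.0) for m in models}
    total = sum(probs.values())
    probs = {m: p / total for m, p in probs.items()}
    return PosteriorResult(
        probabilities=probs, retained_indices=idx, distances=d[idx], method=method
    )


def abc_mnlogistic(observed, table: SimulationTable, config: ABCConfig) -> PosteriorResult:
    """Weighted multinomial logistic regression on the retained set."""
    from sklearn.linear_model import LogisticRegression

    idx, d, std_stats, std_obs = _retained(table, observed, config.tolerance)
    _check_regression_ok(table, config, idx.size)
    labels = table.labels[idx]
    X, y = std_stats[idx], labels.astype(str)
    if len(set(y)) == 1:
        return _finish_probs({y[0]: 1.0}, table.models, idx, d, "mnlogistic")
    w = _epanechnikov(d[idx])
    clf = LogisticRegression(max_iter=5000, C=1e6)
    try:
        clf.fit(X, y, sample_weight=w)
    except Exception as exc:  # pragma: no cover - sklearn internal failures
        raise ConvergenceError(
            f"multinomial logistic regression failed ({exc}); increase tolerance"
        ) from exc
    p = clf.predict_proba(std_obs[None, :])[0]
    raw = dict(zip(clf.classes_, p))
    return _finish_probs(raw, table.models, idx, d, "mnlogistic")


def abc_neuralnet(observed, table: SimulationTable, config: ABCConfig) -> PosteriorResult:
    """Ensemble of small MLP classifiers, weight-resampled, averaged."""
    from sklearn.neural_network import MLPClassifier

    idx, d, std_stats, std_obs = _retained(table, observed, config.tolerance)
    _check_regression_ok(table, config, idx.size)
    labels = table.labels[idx].astype(str)
    if len(set(labels)) == 1:
        return _finish_probs({labels[0]: 1.0}, table.models, idx, d, "neuralnet")
    w = _epanechnikov(d[idx])
    p_w = w / w.sum()
    rng = np.random.default_rng(config.seed)
    X = std_stats[idx]
    classes = np.array(sorted(set(labels)))
    acc = np.zeros(classes.size)
    done = 0
    for member in range(config.n_nets):
        # MLPClassifier has no sample_weight; weighted bootstrap instead
        take = rng.choice(idx.size, size=idx.size, replace=True, p=p_w)
        Xi, yi = X[take], labels[take]
        if len(set(yi)) < 2:
            continue
        net = MLPClassifier(
            hidden_layer_sizes=(config.hidden_units,),
            max_iter=2000,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net.fit(Xi, yi)
        p = net.predict_proba(std_obs[None, :])[0]
        for cls, prob in zip(net.classes_, p):
            acc[np.searchsorted(classes, cls)] += prob
        done += 1
    if done == 0:
        raise ConvergenceError("no neural-network ensemble member converged")
    raw = dict(zip(classes, acc / done))
    return _finish_probs(raw, table.models, idx, d, "neuralnet")


_METHODS = {
    "rejection": abc_rejection,
    "mnlogistic": abc_mnlogistic,
    "neuralnet": abc_neuralnet,
}


def estimate_posterior(observed, table: SimulationTable, config: ABCConfig) -> PosteriorResult:
    return _METHODS[config.method](observed, table, config)


# ---------------------------------------------------------------------------
# Cross-validation and goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    models: list[str]
    counts: np.ndarray  # counts[true][selected]
    mean_true_posterior: dict[str, float]

    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.models, columns=self.models)


def cross_validate(
    table: SimulationTable,
    config: ABCConfig,
    n_eval: int = 100,
    seed: int | None = None,
) -> ConfusionMatrix:
    """Leave-one-out model selection on pseudo-observed table rows."""
    models = table.models
    per_model = table.n_rows // len(models)
    if n_eval > per_model:
        raise ValueError(f"n_eval {n_eval} exceeds per-model count {per_model}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    counts = np.zeros((len(models), len(models)), dtype=int)
    post_sum = {m: 0.0 for m in models}
    for mi, m in enumerate(models):
        rows = np.flatnonzero(table.labels == m)
        picked = rng.choice(rows, size=n_eval, replace=False)
        for r in picked:
            mask = np.ones(table.n_rows, dtype=bool)
            mask[r] = False
            sub = SimulationTable(
                labels=table.labels[mask],
                thetas=table.thetas[mask],
                stats=table.stats[mask],
                allow_unbalanced=True,
            )
            res = estimate_posterior(table.stats[r], sub, config)
            counts[mi, models.index(res.best_model)] += 1
            post_sum[m] += res.probabilities[m]
    return ConfusionMatrix(
        models=models,
        counts=counts,
        mean_true_posterior={m: post_sum[m] / n_eval for m in models},
    )


@dataclass
class GoodnessOfFit:
    models: list[str]
    distances: dict[str, np.ndarray]  # per model: retained distances
    envelope: dict[str, dict[str, bool]]  # model -> stat name -> inside?

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            d = self.distances[m]
            row = {
                "model": m,
                "min_distance": d.min(),
                "median_distance": float(np.median(d)),
                "max_distance": d.max(),
            }
            row.update({f"in_envelope_{s}": self.envelope[m][s] for s in STAT_NAMES})
            rows.append(row)
        return pd.DataFrame(rows)


def goodness_of_fit(
    observed, table: SimulationTable, config: ABCConfig
) -> GoodnessOfFit:
    """Per-model retained-distance distributions and [1%, 99%] quantile
    envelope checks of the observed statistics."""
    obs = _as_vector(observed)
    std_stats, std_obs, _ = standardize(table, observed)
    d_all = _distances(std_stats, std_obs)
    distances: dict[str, np.ndarray] = {}
    envelope: dict[str, dict[str, bool]] = {}
    for m in table.models:
        rows = np.flatnonzero(table.labels == m)
        k = math.ceil(config.tolerance * rows.size)
        order = rows[np.argsort(d_all[rows], kind="stable")][:k]
        distances[m] = d_all[order]
        env = {}
        for j, name in enumerate(STAT_NAMES):
            vals = table.stats[order, j]
            lo, hi = np.quantile(vals, [0.01, 0.99])
            env[name] = bool(lo <= obs[j] <= hi)
        envelope[m] = env
    return GoodnessOfFit(models=table.models, distances=distances, envelope=envelope)
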