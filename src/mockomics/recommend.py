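"""Probabilistic surrogate model and next-cycle design recommendation.

The surrogate maps categorical designs (KO/NoMod/UP vectors) to predicted
production.  It is a bootstrap ensemble mixing two member families, each fit
on a resampled copy of the training set: stochastic gradient-boosted trees on
the raw categories (which capture the strong interactions that categorical
flux designs produce, e.g. a knockout that only pays off together with an
upregulation) and ridge regressions on one-hot indicators (which extrapolate
additive structure to unseen corners of the space).  The ensemble mean is the
point prediction and the ensemble spread is the predictive uncertainty.  This
reproduces the decision-relevant interface of a Bayesian ensemble recommender
— probabilistic predictions and a mean ranking over the enumerable design
space — without its posterior machinery; the ensemble is deterministic given
a seed, and invariant to training-row order (rows are canonicalized before
fitting).

Recommendation is exhaustive: every unseen category vector is scored and the
top-k by predicted mean are returned (ties broken by smaller predicted
standard deviation, then lexicographic category order).  An
expected-improvement acquisition is available behind a config switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .designs import CATEGORIES, Design, design_space_size, enumerate_design_space

N_CATEGORIES = len(CATEGORIES)


@dataclass
class TrainingSet:
    """Design category matrix plus production responses.

    ``X`` is ``n × d`` with entries in {0,1,2}; ``y`` is production in mM.
    """

    X: np.ndarray
    y: np.ndarray
    reactions: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y shapes disagree")
        if self.X.shape[1] != len(self.reactions):
            raise ValueError("X width does not match the target-reaction list")
        if not np.isin(self.X, CATEGORIES).all():
            raise ValueError("categories must be in {0, 1, 2}")
        if (self.y < 0).any():
            raise ValueError("production responses must be non-negative")
        keys = {tuple(row) for row in self.X}
        if len(keys) != len(self.X):
            raise ValueError("duplicate design rows in training set")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def keys(self) -> set[tuple[int, ...]]:
        return {tuple(row) for row in self.X}

    @classmethod
    def from_map(
        cls, truth: dict[tuple[int, ...], float], reactions: list[str]
    ) -> "TrainingSet":
        keys = sorted(truth)
        return cls(
            X=np.array(keys), y=np.array([truth[k] for k in keys]), reactions=reactions
        )


def one_hot(X: np.ndarray) -> np.ndarray:
    """Encode an ``n × d`` category matrix as ``n × 3d`` indicators."""
    X = np.asarray(X, dtype=int)
    n, d = X.shape
    out = np.zeros((n, d * N_CATEGORIES))
    for j in range(d):
        for c in CATEGORIES:
            out[:, j * N_CATEGORIES + c] = X[:, j] == c
    return out


@dataclass
class SurrogateConfig:
    """Ensemble composition and acquisition settings.

    ``n_boosted`` members are stochastic gradient-boosted trees; the
    remaining ``ensemble_size − n_boosted`` are one-hot ridge regressions.
    """

    ensemble_size: int = 100
    n_boosted: int = 30
    ridge_alpha: float = 1e-2
    boost_params: dict = field(
        default_factory=lambda: {
            "n_estimators": 50,
            "max_depth": 3,
            "subsample": 0.8,
        }
    )
    min_instances_over_d: int = 2  # require n >= d + this
    acquisition: str = "mean"  # "mean" | "expected_improvement"

    def validate(self) -> None:
        if not 0 <= self.n_boosted <= self.ensemble_size:
            raise ValueError("n_boosted must be within the ensemble size")
        if self.ensemble_size < 2:
            raise ValueError("ensemble needs at least two members")


@dataclass
class PredictiveDistribution:
    """Per-design prediction: mean, spread, and the ensemble samples."""

    mean: float
    sd: float
    samples: np.ndarray

    def quantile(self, q) -> float | np.ndarray:
        return np.quantile(self.samples, q)


@dataclass
class SurrogateModel:
    """Fitted bootstrap ensemble: boosted-tree and ridge members."""

    reactions: list[str]
    boosted_members: list  # GradientBoostingRegressor, on raw categories
    ridge_coef: np.ndarray  # (3d, B_ridge) coefficients on one-hot
    ridge_intercept: np.ndarray  # (B_ridge,)
    training_keys: set = field(default_factory=set)
    training_best: float = 0.0

    @property
    def ensemble_size(self) -> int:
        return len(self.boosted_members) + self.ridge_coef.shape[1]

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        """Per-member predictions, shape ``(n, B)``."""
        X = np.asarray(X, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be n x d")
        cols = [m.predict(X) for m in self.boosted_members]
        ridge = one_hot(X) @ self.ridge_coef + self.ridge_intercept
        if cols:
            return np.column_stack([np.column_stack(cols), ridge])
        return ridge

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        samples = self.member_predictions(X)
        return samples.mean(axis=1), samples.std(axis=1)

    def predictive_distribution(self, x: np.ndarray) -> PredictiveDistribution:
        samples = self.member_predictions(np.asarray(x).reshape(1, -1))[0]
        return PredictiveDistribution(
            mean=float(samples.mean()), sd=float(samples.std()), samples=samples
        )


def fit_surrogate(
    training: TrainingSet,
    config: SurrogateConfig | None = None,
    rng_seed: int = 0,
) -> SurrogateModel:
    """Fit the bootstrap ridge ensemble on a training set.

    Rows are sorted into a canonical (lexicographic) order before the
    bootstrap draws, so fitting is invariant to the order in which the
    training instances were collected.
    """
    config = config or SurrogateConfig()
    config.validate()
    minimum = training.d + config.min_instances_over_d
    if training.n < minimum:
        raise ValueError(
            f"need at least {minimum} training instances for d={training.d}, "
            f"got {training.n}"
        )
    order = np.lexsort(training.X.T[::-1])
    X, y = training.X[order], training.y[order]
    H = one_hot(X)
    rng = np.random.default_rng(rng_seed)

    boosted = []
    for _ in range(config.n_boosted):
        idx = rng.integers(0, len(y), size=len(y))
        member = GradientBoostingRegressor(
            random_state=int(rng.integers(2**31)), **config.boost_params
        ).fit(X[idx], y[idx])
        boosted.append(member)

    n_ridge = config.ensemble_size - config.n_boosted
    coef = np.empty((H.shape[1], n_ridge))
    intercept = np.empty(n_ridge)
    for b in range(n_ridge):
        idx = rng.integers(0, len(y), size=len(y))
        member = Ridge(alpha=config.ridge_alpha).fit(H[idx], y[idx])
        coef[:, b] = member.coef_
        intercept[b] = member.intercept_

    return SurrogateModel(
        reactions=list(training.reactions),
        boosted_members=boosted,
        ridge_coef=coef,
        ridge_intercept=intercept,
        training_keys=training.keys(),
        training_best=float(y.max()) if len(y) else 0.0,
    )


def crossval_predictions(
    training: TrainingSet,
    folds: int = 10,
    rng_seed: int = 0,
    config: SurrogateConfig | None = None,
) -> list[tuple[float, float, float]]:
    """k-fold cross-validated (observed, predicted mean, predicted sd) triples.

    Each instance is predicted exactly once, by an ensemble fit without it;
    triples are returned in the original training-row order.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > training.n:
        raise ValueError(f"folds={folds} exceeds n={training.n}")
    config = config or SurrogateConfig()
    out: list[tuple[float, float, float] | None] = [None] * training.n
    kf = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    for f, (train_idx, test_idx) in enumerate(kf.split(training.X)):
        sub = TrainingSet(
            training.X[train_idx], training.y[train_idx], training.reactions
        )
        model = fit_surrogate(sub, config, rng_seed=rng_seed + 1 + f)
        mean, sd = model.predict(training.X[test_idx])
        for i, idx in enumerate(test_idx):
            out[idx] = (float(training.y[idx]), float(mean[i]), float(sd[i]))
    assert all(t is not None for t in out)
    return out  # type: ignore[return-value]


@dataclass
class RecommendationSet:
    """Ranked (design, predictive distribution) pairs, best first."""

    items: list[tuple[Design, PredictiveDistribution]]

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def keys(self) -> list[tuple[int, ...]]:
        return [design.key() for design, _ in self.items]


def recommend(
    model: SurrogateModel,
    k: int = 10,
    space: list[tuple[int, ...]] | None = None,
    exclude: TrainingSet | None = None,
    config: SurrogateConfig | None = None,
) -> RecommendationSet:
    """Top-k unseen designs by exhaustive scoring of the category space.

    ``space`` defaults to all ``3^d`` category vectors (refused above 10^6).
    Designs in ``exclude`` (defaulting to the surrogate's own training set)
    are never recommended.
    """
    config = config or SurrogateConfig()
    d = len(model.reactions)
    if space is None:
        if design_space_size(d) > 10**6:
            raise ValueError("design space too large to enumerate")
        space = list(enumerate_design_space(model.reactions))
    excluded = exclude.keys() if exclude is not None else set(model.training_keys)
    candidates = [key for key in space if tuple(key) not in excluded]
    if not candidates:
        raise ValueError("no unseen designs left to recommend")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} unseen designs")

    X = np.array(candidates)
    samples = model.member_predictions(X)
    mean = samples.mean(axis=1)
    sd = samples.std(axis=1)
    if config.acquisition == "expected_improvement":
        best = model.training_best
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (mean - best) / sd, 0.0)
        score = np.where(
            sd > 0,
            (mean - best) * norm.cdf(z) + sd * norm.pdf(z),
            np.maximum(mean - best, 0.0),
        )
    elif config.acquisition == "mean":
        score = mean
    else:
        raise ValueError(f"unknown acquisition {config.acquisition!r}")

    order = sorted(
        range(len(candidates)), key=lambda i: (-score[i], sd[i], candidates[i])
    )
    items = []
    for rank, i in enumerate(order[:k], start=1):
        design = Design(
            dict(zip(model.reactions, candidates[i])), label=f"REC{rank}"
        )
        items.append(
            (design, PredictiveDistribution(float(mean[i]), float(sd[i]), samples[i]))
        )
    return RecommendationSet(items)
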