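"""Binary WOA wrapper feature selection.

Whales move in a continuous space of dimension C_total (one coordinate per
feature).  An S-shaped transfer function maps each coordinate to the
probability that the corresponding feature is selected; a stochastic
threshold then yields a binary inclusion mask.  Each candidate mask is
scored by training a naive-Bayes classifier on the selected columns of the
training part and measuring its error on the held-out part, combined with a
subset-size penalty:

    F = α · E_R(D) + (1 − α) · R / C      (minimized)

where E_R(D) is the classification error of the R-feature subset, C the
total feature count, and α ∈ [0, 1] weights accuracy against parsimony
(β = 1 − α).  The equivalent maximization form is
F' = α·γ_R(D) + (1 − α)·(C − R)/C with γ_R the accuracy; F' = 1 − F
whenever γ_R = 1 − E_R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import expit

from . import naive_bayes, woa
from .exceptions import SplitError

if TYPE_CHECKING:  # pragma: no cover
    from .data import Dataset

__all__ = [
    "FeatureMask",
    "FitnessConfig",
    "FSResult",
    "transfer",
    "binarize",
    "fitness_min",
    "fitness_max",
    "evaluate_mask",
    "select_features",
]


@dataclass
class FeatureMask:
    """Binary inclusion vector over features; 1 = feature selected."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=int)
        if self.bits.ndim != 1 or not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be a 1-D 0/1 vector")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def as_string(self) -> str:
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_string(cls, s: str) -> "FeatureMask":
        return cls(np.array([int(ch) for ch in s]))


@dataclass
class FitnessConfig:
    """Weights and direction of the wrapper fitness.

    ``alpha`` (default 0.99) weights the classification term; ``beta`` is
    always 1 − alpha.  ``mode`` selects the minimized-error form (default)
    or the maximized-accuracy complement.
    """

    alpha: float = 0.99
    mode: str = "minimize-error"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.mode not in ("minimize-error", "maximize-accuracy"):
            raise ValueError(f"unknown fitness mode {self.mode!r}")

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


@dataclass
class FSResult:
    """Outcome of one feature-selection run."""

    mask: FeatureMask
    fitness: float
    accuracy: float
    error_rate: float
    history: list[float]
    seed: int
    split_seed: int
    selected_names: list[str] = field(default_factory=list)


def transfer(v: float) -> float:
    """S-shaped transfer function: sigmoid 1 / (1 + e^{−v}).

    Strictly increasing, range (0, 1); maps a whale coordinate to the
    probability of selecting the corresponding feature.
    """
    return float(expit(v))


def binarize(position: np.ndarray, rng: np.random.Generator) -> FeatureMask:
    """Stochastically threshold a continuous position into a mask.

    Bit d is 1 iff a fresh uniform draw falls below transfer(position_d).
    An all-zero outcome is repaired by setting one uniformly chosen bit —
    an empty feature subset is never a valid candidate.
    """
    position = np.asarray(position, dtype=float)
    probs = expit(position)
    bits = (rng.random(position.shape[0]) < probs).astype(int)
    if bits.sum() == 0:
        bits[int(rng.integers(position.shape[0]))] = 1
    return FeatureMask(bits)


def _check_fitness_args(rate: float, R: int, C_total: int, alpha: float) -> None:
    if C_total < 1:
        raise ValueError("C_total must be at least 1")
    if not 0 <= R <= C_total:
        raise ValueError(f"R={R} outside [0, {C_total}]")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")


def fitness_min(error_rate: float, R: int, C_total: int, alpha: float = 0.99) -> float:
    """Minimization fitness α·error + (1 − α)·R/C; lies in [0, 1]."""
    _check_fitness_args(error_rate, R, C_total, alpha)
    return alpha * error_rate + (1.0 - alpha) * (R / C_total)


def fitness_max(accuracy: float, R: int, C_total: int, alpha: float = 0.99) -> float:
    """Maximization fitness α·accuracy + (1 − α)·(C − R)/C.

    Exact complement of :func:`fitness_min` when accuracy = 1 − error.
    """
    _check_fitness_args(accuracy, R, C_total, alpha)
    return alpha * accuracy + (1.0 - alpha) * ((C_total - R) / C_total)


def evaluate_mask(
    mask: FeatureMask,
    train: "Dataset",
    eval: "Dataset",
    smoothing: float = 1.0,
) -> tuple[float, float]:
    """Train NB on the masked columns of ``train``, score on ``eval``.

    Returns ``(error_rate, accuracy)`` with accuracy the plain fraction of
    correct predictions (0/1 loss over all classes).
    """
    if mask.n_selected < 1:
        raise ValueError("mask selects no features")
    if eval.n == 0:
        raise ValueError("evaluation split is empty")
    model = naive_bayes.fit_dataset(train.select_features(mask), smoothing=smoothing)
    pred = naive_bayes.predict_batch(model, eval.select_features(mask).X)
    acc = float(np.mean(pred == eval.y))
    return 1.0 - acc, acc


def select_features(
    dataset: "Dataset",
    woa_config: woa.WOAConfig | None = None,
    fitness_config: FitnessConfig | None = None,
    split_seed: int = 0,
    smoothing: float = 1.0,
    holdout: str = "test",
    train_fraction: float = 0.70,
    memoize: bool = True,
) -> FSResult:
    """Run the full wrapper: split, optimize masks with WOA, return the best.

    The dataset is split 70/30 stratified (seeded by ``split_seed``).  With
    ``holdout="test"`` (default) candidate masks are fitted on the training
    part and scored on the test part; ``holdout="internal"`` instead carves
    a 70/30 validation fold out of the training part so the test part never
    steers the search.  Each whale's objective is
    ``fitness_min(evaluate_mask(binarize(position)))``; ties between
    equal-fitness masks prefer fewer selected features, then the
    earlier-found mask.  Fully reproducible from the seeds and configs.
    """
    from .data import SplitSpec, train_test_split  # runtime import avoids a cycle

    if dataset.n_classes < 2:
        raise ValueError("dataset must have at least 2 classes")
    if dataset.n_features < 1:
        raise ValueError("dataset must have at least 1 feature")
    if holdout not in ("test", "internal"):
        raise ValueError(f"unknown holdout policy {holdout!r}")
    woa_config = woa_config or woa.WOAConfig()
    fitness_config = fitness_config or FitnessConfig()

    train, test = train_test_split(
        dataset, SplitSpec(train_fraction=train_fraction, stratified=True, seed=split_seed)
    )
    for part, label in ((train, "train"), (test, "test")):
        if len(set(part.y.tolist())) < dataset.n_classes:
            raise SplitError(f"a class is absent from the {label} split")
    if holdout == "internal":
        fit_part, val_part = train_test_split(
            train, SplitSpec(train_fraction=train_fraction, stratified=True,
                             seed=split_seed + 1)
        )
    else:
        fit_part, val_part = train, test

    C_total = dataset.n_features
    alpha = fitness_config.alpha
    bin_rng = np.random.default_rng(np.random.SeedSequence([woa_config.seed, 0x6D61736B]))
    cache: dict[bytes, tuple[float, float]] = {}
    # incumbent under the tie rules: better fitness, else fewer features,
    # else first found
    best: dict = {"fitness": np.inf, "R": C_total + 1, "mask": None,
                  "error": None, "acc": None}

    def objective(position: np.ndarray) -> float:
        mask = binarize(position, bin_rng)
        key = mask.bits.tobytes()
        if memoize and key in cache:
            error, acc = cache[key]
        else:
            error, acc = evaluate_mask(mask, fit_part, val_part, smoothing=smoothing)
            if memoize:
                cache[key] = (error, acc)
        if fitness_config.mode == "maximize-accuracy":
            f = 1.0 - fitness_max(acc, mask.n_selected, C_total, alpha)
        else:
            f = fitness_min(error, mask.n_selected, C_total, alpha)
        if f < best["fitness"] or (
            f == best["fitness"] and mask.n_selected < best["R"]
        ):
            best.update(fitness=f, R=mask.n_selected, mask=mask, error=error, acc=acc)
        return f

    _, history = woa.optimize(objective, C_total, woa_config)
    mask = best["mask"]
    names = [n for n, b in zip(dataset.feature_names, mask.bits) if b]
    return FSResult(
        mask=mask,
        fitness=float(best["fitness"]),
        accuracy=float(best["acc"]),
        error_rate=float(best["error"]),
        history=history,
        seed=woa_config.seed,
        split_seed=split_seed,
        selected_names=names,
    )
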