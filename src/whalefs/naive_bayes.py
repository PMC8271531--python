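"""Naïve Bayes classifier with Gaussian and smoothed-categorical likelihoods.

Bayes' rule with class-conditional feature independence:

    P(c | x) ∝ P(c) · Π_f P(x_f | c)

Class priors come from training frequencies.  Continuous features get
per-class Gaussian likelihoods (sample mean, floored sample variance);
categorical features get frequency tables with additive (Laplace) smoothing:

    P(v | c) = (count(v, c) + s) / (count(c) + s·|vocabulary|)

With smoothing ``s = 0`` a category unseen in training makes every
posterior zero and prediction impossible; the model raises
:class:`ZeroProbabilityError` in that case rather than guessing.  All
probabilities are carried in log space so that hundreds of tiny
per-feature likelihoods cannot underflow a posterior to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any

import numpy as np

from .exceptions import DegenerateVarianceError, ZeroProbabilityError

__all__ = ["NBModel", "fit", "predict_log_posterior", "predict", "predict_proba"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class _GaussianFeature:
    kind = "continuous"
    mean: np.ndarray   # (n_classes,)
    var: np.ndarray    # (n_classes,), strictly positive after flooring


@dataclass
class _CategoricalFeature:
    kind = "categorical"
    categories: list          # training vocabulary, sorted
    log_prob: np.ndarray      # (n_classes, vocab) smoothed log P(v|c)
    log_unseen: np.ndarray    # (n_classes,) log P(unseen v|c); -inf if s=0


@dataclass
class NBModel:
    """A fitted naive-Bayes model.

    ``classes`` fixes the order of every per-class vector the model
    returns; ties in :func:`predict` break toward the earliest class.
    """

    classes: np.ndarray
    log_priors: np.ndarray
    feature_models: list
    feature_names: list[str]
    feature_kinds: list[str]
    smoothing: float

    def to_json(self) -> str:
        """Serialize to a JSON document (lossless for reuse)."""
        doc: dict[str, Any] = {
            "classes": self.classes.tolist(),
            "log_priors": self.log_priors.tolist(),
            "feature_names": list(self.feature_names),
            "feature_kinds": list(self.feature_kinds),
            "smoothing": self.smoothing,
            "features": [],
        }
        for fm in self.feature_models:
            if fm.kind == "continuous":
                doc["features"].append(
                    {"kind": "continuous", "mean": fm.mean.tolist(), "var": fm.var.tolist()}
                )
            else:
                doc["features"].append(
                    {
                        "kind": "categorical",
                        "categories": list(fm.categories),
                        "log_prob": fm.log_prob.tolist(),
                        "log_unseen": fm.log_unseen.tolist(),
                    }
                )
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NBModel":
        doc = json.loads(text)
        feature_models: list = []
        for f in doc["features"]:
            if f["kind"] == "continuous":
                feature_models.append(
                    _GaussianFeature(np.array(f["mean"]), np.array(f["var"]))
                )
            else:
                feature_models.append(
                    _CategoricalFeature(
                        list(f["categories"]),
                        np.array(f["log_prob"]),
                        np.array(f["log_unseen"]),
                    )
                )
        return cls(
            classes=np.array(doc["classes"]),
            log_priors=np.array(doc["log_priors"]),
            feature_models=feature_models,
            feature_names=list(doc["feature_names"]),
            feature_kinds=list(doc["feature_kinds"]),
            smoothing=float(doc["smoothing"]),
        )


def fit(
    X: np.ndarray,
    y: np.ndarray,
    feature_kinds: list[str],
    smoothing: float = 1.0,
    feature_names: list[str] | None = None,
    variance_floor: bool = True,
) -> NBModel:
    """Fit priors and per-class per-feature likelihood models.

    Parameters
    ----------
    X, y:
        Training matrix (n × F; float or object dtype) and label vector.
        Missing values (NaN) are rejected.
    feature_kinds:
        Per column, ``"continuous"`` or ``"categorical"``.
    smoothing:
        Additive smoothing constant ``s ≥ 0`` for categorical tables.
        ``s = 0`` keeps raw frequencies and restores the zero-probability
        failure mode as an explicit error at predict time.
    variance_floor:
        Floor each per-class variance at ``1e-9 · (global variance +
        1e-12)``.  Disabling it makes a feature that is constant within
        every class a :class:`DegenerateVarianceError`.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of instances")
    if X.shape[1] != len(feature_kinds):
        raise ValueError("feature_kinds length must match the number of columns")
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    for j, kind in enumerate(feature_kinds):
        if kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown feature kind {kind!r} for column {j}")
        if kind == "continuous":
            col = X[:, j].astype(float)
            if np.isnan(col).any():
                raise ValueError(f"missing values in continuous column {j}")

    classes, y_idx = np.unique(y, return_inverse=True)
    n = len(y)
    counts = np.bincount(y_idx, minlength=len(classes)).astype(float)
    log_priors = np.log(counts / n)

    feature_models: list = []
    for j, kind in enumerate(feature_kinds):
        col = X[:, j]
        if kind == "continuous":
            col = col.astype(float)
            means = np.empty(len(classes))
            var = np.empty(len(classes))
            for k in range(len(classes)):
                vals = col[y_idx == k]
                means[k] = vals.mean()
                var[k] = vals.var()
            if variance_floor:
                floor = 1e-9 * (col.var() + 1e-12)
                var = np.maximum(var, floor)
            elif (var <= 0).any():
                raise DegenerateVarianceError(
                    f"column {j} is constant within a class and the variance "
                    "floor is disabled"
                )
            feature_models.append(_GaussianFeature(means, var))
        else:
            cats = sorted(set(col.tolist()))
            vocab = len(cats)
            cat_index = {v: i for i, v in enumerate(cats)}
            table = np.zeros((len(classes), vocab))
            for value, k in zip(col, y_idx):
                table[k, cat_index[value]] += 1.0
            denom = counts + smoothing * vocab
            with np.errstate(divide="ignore"):
                log_prob = np.log((table + smoothing)) - np.log(denom)[:, None]
                log_unseen = (
                    np.log(smoothing) - np.log(denom)
                    if smoothing > 0
                    else np.full(len(classes), -np.inf)
                )
            feature_models.append(_CategoricalFeature(cats, log_prob, log_unseen))

    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    return NBModel(
        classes=classes,
        log_priors=log_priors,
        feature_models=feature_models,
        feature_names=list(feature_names),
        feature_kinds=list(feature_kinds),
        smoothing=float(smoothing),
    )


def fit_dataset(dataset, smoothing: float = 1.0, **kwargs) -> NBModel:
    """Fit from a :class:`whalefs.data.Dataset` (duck-typed)."""
    return fit(
        dataset.X,
        dataset.y,
        dataset.feature_kinds,
        smoothing=smoothing,
        feature_names=dataset.feature_names,
        **kwargs,
    )


def _log_likelihood_matrix(model: NBModel, X: np.ndarray) -> np.ndarray:
    """Unnormalized log posteriors for a batch: (n, n_classes)."""
    X = np.asarray(X)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != len(model.feature_models):
        raise ValueError(
            f"record has {X.shape[1]} features; model expects "
            f"{len(model.feature_models)}"
        )
    n = X.shape[0]
    scores = np.tile(model.log_priors, (n, 1))
    for j, fm in enumerate(model.feature_models):
        col = X[:, j]
        if fm.kind == "continuous":
            col = col.astype(float)[:, None]  # (n, 1)
            scores += -0.5 * (
                _LOG2PI + np.log(fm.var)[None, :]
                + (col - fm.mean[None, :]) ** 2 / fm.var[None, :]
            )
        else:
            cat_index = {v: i for i, v in enumerate(fm.categories)}
            for i, value in enumerate(col.tolist()):
                idx = cat_index.get(value)
                if idx is None:
                    if model.smoothing == 0:
                        raise ZeroProbabilityError(
                            f"category {value!r} of feature "
                            f"{model.feature_names[j]!r} was never seen in "
                            "training and smoothing is 0"
                        )
                    scores[i] += fm.log_unseen
                else:
                    scores[i] += fm.log_prob[:, idx]
    return scores


def predict_log_posterior(model: NBModel, x: np.ndarray) -> np.ndarray:
    """Per-class unnormalized log posteriors log P(c) + Σ_f log P(x_f|c).

    The evidence term P(x) is constant across classes and omitted.
    """
    return _log_likelihood_matrix(model, np.asarray(x).reshape(1, -1))[0]


def predict(model: NBModel, x: np.ndarray) -> Any:
    """The class with the highest posterior; ties break toward the class
    earliest in ``model.classes``."""
    scores = predict_log_posterior(model, x)
    return model.classes[int(np.argmax(scores))]


def predict_batch(model: NBModel, X: np.ndarray) -> np.ndarray:
    """Vectorized :func:`predict` over the rows of a matrix."""
    scores = _log_likelihood_matrix(model, X)
    return model.classes[np.argmax(scores, axis=1)]


def predict_proba(model: NBModel, x: np.ndarray) -> np.ndarray:
    """Normalized posterior probabilities, in ``model.classes`` order.

    Softmax of the log scores — this supplies the division by P(x).
    """
    return predict_proba_batch(model, np.asarray(x).reshape(1, -1))[0]


def predict_proba_batch(model: NBModel, X: np.ndarray) -> np.ndarray:
    scores = _log_likelihood_matrix(model, X)
    scores = scores - scores.max(axis=1, keepdims=True)
    p = np.exp(scores)
    return p / p.sum(axis=1, keepdims=True)
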