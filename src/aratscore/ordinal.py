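"""Ordinal classification of ARAT task scores.

The classifier follows the cumulative binary decomposition of Frank &
Hall: for ordered classes c_0 < ... < c_{K-1}, K-1 independent
L2-regularised logistic regressions each estimate P(y > c_k); class
probabilities are recovered by differencing adjacent cumulative
probabilities, clipping negatives and renormalising.  Features are
standardised with statistics learned from the training rows only, and the
training set is rebalanced with SMOTE — synthetic minority samples
interpolated between a minority row and one of its k nearest same-class
neighbours — before fitting.  Test data never passes through SMOTE.

``FrankHallOrdinalClassifier`` is a scikit-learn estimator and composes
with sklearn pipelines and model selection.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

logger = logging.getLogger(__name__)

#: the four ARAT domains a model set must cover
from .registry import DOMAINS  # noqa: E402


@dataclass(frozen=True)
class SmoteProvenance:
    """Where one synthetic sample came from: x_new = x[source] + u * (x[neighbor] - x[source])."""

    class_label: int
    source_index: int
    neighbor_index: int
    u: float


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, list[SmoteProvenance]]:
    """Upsample every minority class to the majority count by SMOTE.

    Each synthetic row is ``x + u * (x' - x)`` with ``u ~ Uniform(0, 1)``,
    ``x`` a random minority row and ``x'`` one of its k nearest same-class
    neighbours (Euclidean).  Original rows are preserved and come first in
    the output; the provenance of every synthetic row (indices into the
    input ``X`` and the interpolation coefficient) is returned alongside.

    A class with a single row falls back to duplication with tiny Gaussian
    jitter (sd 1e-6) since it has no neighbours to interpolate toward.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    classes, counts = np.unique(y, return_counts=True)
    majority = int(counts.max())
    X_out = [X]
    y_out = [y]
    provenance: list[SmoteProvenance] = []
    for cls, count in zip(classes, counts):
        need = majority - int(count)
        if need == 0:
            continue
        idx = np.flatnonzero(y == cls)
        if len(idx) == 1:
            warnings.warn(
                f"class {cls} has a single row; duplicating with jitter instead of SMOTE",
                stacklevel=2,
            )
            src = idx[0]
            X_new = X[src] + rng.normal(0.0, 1e-6, size=(need, X.shape[1]))
            provenance.extend(
                SmoteProvenance(int(cls), int(src), int(src), 0.0) for _ in range(need)
            )
        else:
            k = min(k_neighbors, len(idx) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(X[idx])
            # first neighbour is the point itself
            neigh = nn.kneighbors(X[idx], return_distance=False)[:, 1:]
            pick = rng.integers(0, len(idx), size=need)
            which = rng.integers(0, k, size=need)
            u = rng.uniform(0.0, 1.0, size=need)
            src = idx[pick]
            nbr = idx[neigh[pick, which]]
            X_new = X[src] + u[:, None] * (X[nbr] - X[src])
            provenance.extend(
                SmoteProvenance(int(cls), int(s), int(nb), float(uu))
                for s, nb, uu in zip(src, nbr, u)
            )
        X_out.append(X_new)
        y_out.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(X_out), np.concatenate(y_out), provenance


def compose_cumulative(cumulative: np.ndarray) -> np.ndarray:
    """Frank-Hall composition: cumulative P(y > c_k), k = 0..K-2, to class
    probabilities over K classes; negatives clipped, rows renormalised."""
    cum = np.atleast_2d(np.asarray(cumulative, dtype=float))
    n, km1 = cum.shape
    probs = np.empty((n, km1 + 1))
    probs[:, 0] = 1.0 - cum[:, 0]
    if km1 > 1:
        probs[:, 1:-1] = cum[:, :-1] - cum[:, 1:]
    probs[:, -1] = cum[:, -1]
    probs = np.clip(probs, 0.0, None)
    totals = probs.sum(axis=1, keepdims=True)
    # all-zero rows (pathological cumulative inputs) fall back to uniform
    uniform = np.full_like(probs, 1.0 / probs.shape[1])
    return np.where(totals > 0, probs / np.where(totals > 0, totals, 1.0), uniform)


class FrankHallOrdinalClassifier(BaseEstimator, ClassifierMixin):
    """Ordinal logistic classifier via cumulative binary decomposition.

    Parameters
    ----------
    C : float
        Inverse L2 regularisation strength of each binary logistic model.
    use_smote : bool
        Rebalance the training set with SMOTE before fitting (on the
        standardised features, so neighbourhoods are scale-free).
    k_neighbors : int
        SMOTE neighbourhood size.
    random_state : int
        Seed for the SMOTE draws.
    max_iter : int
        Solver iteration cap of each binary logistic model.

    Attributes
    ----------
    classes_ : ndarray
        Ordered class labels seen in training (a subset of {0,1,2,3} for
        ARAT scores; e.g. the gross domain may lack score 0 entirely).
    estimators_ : list of LogisticRegression
        K-1 binary models, model k estimating P(y > classes_[k]).
    scaler_ : StandardScaler
        Per-feature standardisation learned from the training rows only.
    smote_provenance_ : list of SmoteProvenance
        Source row, neighbour row and interpolation coefficient of every
        synthetic training sample.
    """

    def __init__(
        self,
        C: float = 1.0,
        use_smote: bool = True,
        k_neighbors: int = 5,
        random_state: int = 0,
        max_iter: int = 2000,
    ):
        self.C = C
        self.use_smote = use_smote
        self.k_neighbors = k_neighbors
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = y.astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("ordinal classifier needs at least 2 classes")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.smote_provenance_: list[SmoteProvenance] = []
        if self.use_smote:
            Xs, y, self.smote_provenance_ = smote_balance(
                Xs, y, k_neighbors=self.k_neighbors,
                rng=np.random.default_rng(self.random_state),
            )
        self.estimators_ = []
        for ck in self.classes_[:-1]:
            target = (y > ck).astype(int)
            # LogisticRegression penalises with L2 by default
            est = LogisticRegression(
                C=self.C, max_iter=self.max_iter, solver="lbfgs"
            ).fit(Xs, target)
            self.estimators_.append(est)
        self.n_features_in_ = X.shape[1]
        return self

    def cumulative_proba(self, X) -> np.ndarray:
        """(n, K-1) matrix of P(y > classes_[k])."""
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        Xs = self.scaler_.transform(X)
        cols = [est.predict_proba(Xs)[:, 1] for est in self.estimators_]
        return np.column_stack(cols)

    def predict_proba(self, X) -> np.ndarray:
        return compose_cumulative(self.cumulative_proba(X))

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        # argmax takes the first maximum: ties break toward the lowest class
        return self.classes_[np.argmax(probs, axis=1)]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "estimators_")
        return {
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "coefs": [e.coef_[0].tolist() for e in self.estimators_],
            "intercepts": [float(e.intercept_[0]) for e in self.estimators_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrankHallOrdinalClassifier":
        model = cls(**d["params"])
        model.classes_ = np.asarray(d["classes"], dtype=int)
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(d["scaler_mean"], dtype=float)
        scaler.scale_ = np.asarray(d["scaler_scale"], dtype=float)
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = len(scaler.mean_)
        model.scaler_ = scaler
        model.estimators_ = []
        for coef, b in zip(d["coefs"], d["intercepts"]):
            est = LogisticRegression()
            est.coef_ = np.asarray([coef], dtype=float)
            est.intercept_ = np.asarray([b], dtype=float)
            est.classes_ = np.array([0, 1])
            model.estimators_.append(est)
        model.n_features_in_ = len(d["scaler_mean"])
        model.smote_provenance_ = []
        return model


def fit_domain_models(
    table,
    feature_columns: list[str],
    C: float = 1.0,
    k_neighbors: int = 5,
    seed: int = 0,
) -> dict[str, FrankHallOrdinalClassifier]:
    """Fit one ordinal classifier per ARAT domain from a feature table.

    A domain whose rows all carry a single class is skipped with a
    warning (it cannot be trained); classes absent from a domain are
    simply absent from that domain's label set.
    """
    models: dict[str, FrankHallOrdinalClassifier] = {}
    for i, domain in enumerate(DOMAINS):
        rows = table[table["domain"] == domain]
        if rows.empty:
            logger.warning("domain %s has no rows; skipped", domain)
            continue
        y = rows["score"].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            logger.warning("domain %s has a single class; skipped", domain)
            continue
        X = rows[feature_columns].to_numpy(dtype=float)
        models[domain] = FrankHallOrdinalClassifier(
            C=C, k_neighbors=k_neighbors, random_state=seed + i
        ).fit(X, y)
    return models


def save_models(models: dict[str, FrankHallOrdinalClassifier], path: str | Path) -> None:
    payload = {dom: m.to_dict() for dom, m in models.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_models(path: str | Path) -> dict[str, FrankHallOrdinalClassifier]:
    payload = json.loads(Path(path).read_text())
    return {dom: FrankHallOrdinalClassifier.from_dict(d) for dom, d in payload.items()}
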