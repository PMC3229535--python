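"""The eight classifier configurations behind a uniform fit/predict contract.

Families and fixed settings:

* ``DT_Gini`` / ``DT_Information`` -- CART decision trees (gini / entropy
  splitting), pruned to the subtree with the lowest internal 10-fold
  cross-validated error along the cost-complexity path;
* ``NN_OneLayer`` -- single-hidden-layer network with logistic units, weight
  decay 1e-3, initial weights uniform in +/-0.1, at most 100 optimizer
  iterations; hidden size tuned over {2, 3, 4, 5} by inner CV;
* ``NN_NoLayer`` -- the same framework with no hidden layer (direct
  input-output connections, i.e. penalized logistic regression);
* ``SVM_Linear`` / ``SVM_Poly2`` / ``SVM_Poly3`` / ``SVM_Rb`` -- nu-SVC with
  nu = 0.2 and unscaled inputs; the polynomial kernels use
  (x.y + 1)**degree; the radial-basis inverse kernel width sigma is tuned
  over a power-of-two grid on [2**-14, 2**14] by inner CV.

Only ``NN_OneLayer`` and ``SVM_Rb`` have a tuned parameter; all tuning uses
the training data exclusively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.svm import NuSVC
from sklearn.tree import DecisionTreeClassifier

from .gene_selection import GENE_COUNT_GRID

__all__ = ["CLASSIFIER_NAMES", "ClassifierSpec", "SPECS", "applicable",
           "fit", "FittedModel", "SIGMA_GRID", "NN_SIZES"]

CLASSIFIER_NAMES = ("DT_Gini", "DT_Information", "NN_OneLayer", "NN_NoLayer",
                    "SVM_Linear", "SVM_Poly2", "SVM_Poly3", "SVM_Rb")

#: power-of-two grid over the stated sigma interval, step 2**2
SIGMA_GRID = tuple(float(2.0 ** e) for e in range(-14, 15, 2))
NN_SIZES = (2, 3, 4, 5)


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    fixed_params: dict = field(default_factory=dict)
    tuned_params: dict = field(default_factory=dict)


SPECS: dict[str, ClassifierSpec] = {
    "DT_Gini": ClassifierSpec("DT_Gini", {"criterion": "gini"}),
    "DT_Information": ClassifierSpec("DT_Information", {"criterion": "entropy"}),
    "NN_OneLayer": ClassifierSpec(
        "NN_OneLayer", {"decay": 1e-3, "rang": 0.1, "maxit": 100},
        {"size": NN_SIZES}),
    "NN_NoLayer": ClassifierSpec(
        "NN_NoLayer", {"decay": 1e-3, "rang": 0.1, "maxit": 100, "size": 0}),
    "SVM_Linear": ClassifierSpec("SVM_Linear", {"kernel": "linear", "nu": 0.2}),
    "SVM_Poly2": ClassifierSpec("SVM_Poly2", {"kernel": "poly", "degree": 2, "nu": 0.2}),
    "SVM_Poly3": ClassifierSpec("SVM_Poly3", {"kernel": "poly", "degree": 3, "nu": 0.2}),
    "SVM_Rb": ClassifierSpec("SVM_Rb", {"kernel": "rbf", "nu": 0.2},
                             {"sigma": SIGMA_GRID}),
}


def applicable(name: str, n_genes: int) -> bool:
    """Whether a classifier runs at a given gene count.

    SVMs are not run with only two genes; the one-hidden-layer network is
    capped at 150 genes and the no-hidden-layer network at 900.
    """
    if name not in SPECS:
        raise ValueError(f"unknown classifier {name!r}")
    if n_genes not in GENE_COUNT_GRID:
        raise ValueError(f"n_genes={n_genes} is not on the gene-count grid")
    if name.startswith("SVM") and n_genes == 2:
        return False
    if name == "NN_OneLayer" and n_genes > 150:
        return False
    if name == "NN_NoLayer" and n_genes > 900:
        return False
    return True


# ---------------------------------------------------------------------------
# small nnet-style neural network (logistic units, weight decay, BFGS-family
# optimizer, uniform +/-rang initial weights)
# ---------------------------------------------------------------------------

class _NNet:
    """Binary classifier: 0 or 1 hidden layer of logistic units.

    With ``size == 0`` the model is a penalized logistic regression
    (direct input-output connections only).  The objective is the mean
    cross-entropy plus ``decay`` times the squared norm of all weights.
    """

    def __init__(self, size: int, decay: float = 1e-3, rang: float = 0.1,
                 maxit: int = 100, seed: int = 0):
        self.size = int(size)
        self.decay = decay
        self.rang = rang
        self.maxit = maxit
        self.seed = seed

    def _unpack(self, w, p):
        h = self.size
        if h == 0:
            return None, None, w[:p], w[p]
        i = 0
        W1 = w[i:i + h * p].reshape(h, p); i += h * p
        b1 = w[i:i + h]; i += h
        w2 = w[i:i + h]; i += h
        b2 = w[i]
        return W1, b1, w2, b2

    def _objective(self, w, X, y):
        n, p = X.shape
        W1, b1, w2, b2 = self._unpack(w, p)
        if self.size == 0:
            z = X @ w2 + b2
            prob = expit(z)
            eps = 1e-12
            J = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
            J += self.decay * np.sum(w ** 2)
            dz = (prob - y) / n
            g_w2 = X.T @ dz + 2 * self.decay * w2
            g_b2 = np.sum(dz) + 2 * self.decay * b2
            grad = np.concatenate([g_w2, [g_b2]])
            return J, grad
        A1 = X @ W1.T + b1
        H = expit(A1)
        z = H @ w2 + b2
        prob = expit(z)
        eps = 1e-12
        J = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        J += self.decay * np.sum(w ** 2)
        dz = (prob - y) / n
        g_w2 = H.T @ dz + 2 * self.decay * w2
        g_b2 = np.sum(dz) + 2 * self.decay * b2
        dH = np.outer(dz, w2)
        dA1 = dH * H * (1 - H)
        g_W1 = dA1.T @ X + 2 * self.decay * W1
        g_b1 = dA1.sum(axis=0) + 2 * self.decay * b1
        grad = np.concatenate([g_W1.ravel(), g_b1, g_w2, [g_b2]])
        return J, grad

    def fit(self, X: np.ndarray, y01: np.ndarray) -> "_NNet":
        X = np.asarray(X, dtype=float)
        y01 = np.asarray(y01, dtype=float)
        n, p = X.shape
        n_par = p + 1 if self.size == 0 else self.size * (p + 2) + 1
        rng = np.random.default_rng(self.seed)
        w0 = rng.uniform(-self.rang, self.rang, size=n_par)
        res = minimize(self._objective, w0, args=(X, y01), jac=True,
                       method="L-BFGS-B", options={"maxiter": self.maxit})
        self._w = res.x
        self._p = p
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        W1, b1, w2, b2 = self._unpack(self._w, self._p)
        if self.size == 0:
            z = X @ w2 + b2
        else:
            z = expit(X @ W1.T + b1) @ w2 + b2
        return (z > 0).astype(int)


# ---------------------------------------------------------------------------
# fitting, tuning, prediction
# ---------------------------------------------------------------------------

def _stratified_folds(y01: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified k-fold assignment (fold index per sample)."""
    rng = np.random.default_rng(seed)
    counts = np.bincount(y01, minlength=2)
    k = int(min(k, counts[counts > 0].min()))
    if k < 2:
        return []
    fold = np.empty(len(y01), dtype=int)
    for c in (0, 1):
        idx = np.where(y01 == c)[0]
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return [np.where(fold == f)[0] for f in range(k)]


def _cv_error(make_model, X, y01, folds) -> float:
    errs = []
    for test_idx in folds:
        train = np.ones(len(y01), dtype=bool)
        train[test_idx] = False
        if len(np.unique(y01[train])) < 2:
            errs.append(0.5)
            continue
        try:
            model = make_model().fit(X[train], y01[train])
            pred = model.predict(X[test_idx])
        except ValueError:
            errs.append(1.0)
            continue
        errs.append(float(np.mean(pred != y01[test_idx])))
    return float(np.mean(errs))


def _make_svm(name: str, sigma: float | None = None) -> NuSVC:
    if name == "SVM_Linear":
        return NuSVC(nu=0.2, kernel="linear")
    if name == "SVM_Poly2":
        return NuSVC(nu=0.2, kernel="poly", degree=2, gamma=1.0, coef0=1.0)
    if name == "SVM_Poly3":
        return NuSVC(nu=0.2, kernel="poly", degree=3, gamma=1.0, coef0=1.0)
    if name == "SVM_Rb":
        return NuSVC(nu=0.2, kernel="rbf", gamma=sigma)
    raise ValueError(name)


@dataclass
class FittedModel:
    """A fitted binary classifier with name-based column alignment."""

    spec: ClassifierSpec
    backend: Any
    classes: np.ndarray              # two original label values, sorted
    feature_names: list | None
    tuned: dict = field(default_factory=dict)

    def _align(self, X):
        if isinstance(X, pd.DataFrame):
            if self.feature_names is not None:
                missing = [f for f in self.feature_names if f not in X.columns]
                if missing:
                    raise ValueError(f"input lacks fitted features: {missing[:5]}")
                X = X[self.feature_names]
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        n_fit = len(self.feature_names) if self.feature_names is not None else None
        if n_fit is not None and X.shape[1] != n_fit:
            raise ValueError("column count differs from the fitted gene set")
        return X

    def predict(self, X) -> np.ndarray:
        X = self._align(X)
        raw = self.backend.predict(X)
        return self.classes[np.asarray(raw, dtype=int)]


def fit(spec: str | ClassifierSpec, X, y, inner_folds: int = 10,
        seed: int = 0) -> FittedModel:
    """Fit one of the eight configurations on (samples x genes, labels).

    Tuned parameters (hidden size, sigma) are chosen by stratified
    ``inner_folds``-fold CV on the training data; everything is seeded and
    reproducible.
    """
    if isinstance(spec, str):
        if spec not in SPECS:
            raise ValueError(f"unknown classifier {spec!r}")
        spec = SPECS[spec]
    name = spec.name

    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else \
        np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("training labels must contain exactly two classes")
    y01 = (y == classes[1]).astype(int)

    folds = _stratified_folds(y01, inner_folds, seed)
    tuned: dict[str, Any] = {}

    if name in ("DT_Gini", "DT_Information"):
        criterion = spec.fixed_params["criterion"]
        full = DecisionTreeClassifier(criterion=criterion, random_state=seed)
        path = full.fit(Xa, y01).cost_complexity_pruning_path(Xa, y01)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
        if len(alphas) > 1 and folds:
            scores = [
                _cv_error(lambda a=a: DecisionTreeClassifier(
                    criterion=criterion, random_state=seed, ccp_alpha=a),
                    Xa, y01, folds)
                for a in alphas
            ]
            best = np.min(scores)
            # ties -> largest alpha = simplest tree
            alpha = float(alphas[np.where(np.isclose(scores, best))[0][-1]])
        else:
            alpha = 0.0
        tuned["ccp_alpha"] = alpha
        backend = DecisionTreeClassifier(criterion=criterion, random_state=seed,
                                         ccp_alpha=alpha).fit(Xa, y01)

    elif name == "NN_OneLayer":
        sizes = spec.tuned_params.get("size", NN_SIZES) if spec.tuned_params \
            else NN_SIZES
        if folds:
            scores = [
                _cv_error(lambda s=s: _NNet(size=s, seed=seed), Xa, y01, folds)
                for s in sizes
            ]
            size = int(sizes[int(np.argmin(scores))])
        else:
            size = int(sizes[0])
        tuned["size"] = size
        backend = _NNet(size=size, seed=seed).fit(Xa, y01)

    elif name == "NN_NoLayer":
        backend = _NNet(size=0, seed=seed).fit(Xa, y01)

    elif name == "SVM_Rb":
        if folds:
            scores = [
                _cv_error(lambda s=s: _make_svm(name, sigma=s), Xa, y01, folds)
                for s in SIGMA_GRID
            ]
            sigma = float(SIGMA_GRID[int(np.argmin(scores))])
        else:
            sigma = float(SIGMA_GRID[len(SIGMA_GRID) // 2])
        tuned["sigma"] = sigma
        backend = _make_svm(name, sigma=sigma).fit(Xa, y01)

    elif name.startswith("SVM"):
        backend = _make_svm(name).fit(Xa, y01)

    else:  # pragma: no cover
        raise ValueError(name)

    return FittedModel(spec=spec, backend=backend, classes=classes,
                       feature_names=feature_names, tuned=tuned)
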