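"""Weighted sparse representation classifier (WSRC).

A test vector is expressed as a sparse linear combination of the
training vectors by weighted stable l1-minimization, where the penalty
on each training atom grows with its Gaussian distance from the test
vector (locality weighting: near neighbours are cheap atoms, far ones
expensive).  The class whose atoms alone reconstruct the test vector
with minimum residual wins.  The classifier is instance-based: fitting
only stores the column-normalized training matrix.

Defaults follow standard practice for this classifier on protein pair
features: Gaussian kernel width ``sigma = 1.5`` and reconstruction
tolerance ``epsilon = 0.00005``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import PairFeature
from .l1 import SparseSolution, solve_weighted_l1

DEFAULT_SIGMA = 1.5
DEFAULT_EPSILON = 0.00005

#: Supported locality-weight modes.  "reciprocal" (the default) sets the
#: l1 penalty of atom i to 1 / similarity(y, x_i), so near atoms are
#: preferred; "similarity" uses the raw Gaussian similarity as the
#: penalty, which inverts the locality preference and is provided only
#: for comparison.
WEIGHT_MODES = ("reciprocal", "similarity")

FORMAT_VERSION = 1


@dataclass
class WSRCModel:
    """Column-normalized training matrix with labels and hyperparameters."""

    train_matrix: np.ndarray  # m x n, unit l2-norm columns
    labels: np.ndarray  # n integer class labels
    classes: np.ndarray  # sorted unique labels, length K >= 2
    sigma: float = DEFAULT_SIGMA
    epsilon: float = DEFAULT_EPSILON
    weight_mode: str = "reciprocal"
    pair_ids: list[tuple[str, str]] = field(default_factory=list)
    feature_meta: dict = field(default_factory=dict)
    _pinv: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_samples(self) -> int:
        return self.train_matrix.shape[1]

    @property
    def n_features(self) -> int:
        return self.train_matrix.shape[0]

    def class_mask(self, cls) -> np.ndarray:
        return self.labels == cls

    def least_squares(self, y: np.ndarray) -> np.ndarray:
        """Least-norm least-squares solve against the training matrix.

        The pseudoinverse is computed once per model and cached, since
        prediction solves many right-hand sides against the same matrix.
        """
        if self._pinv is None:
            self._pinv = np.linalg.pinv(self.train_matrix)
        return self._pinv @ y

    def save(self, path) -> None:
        """Persist the model as a single ``.npz`` archive."""
        np.savez_compressed(
            path,
            format_version=FORMAT_VERSION,
            train_matrix=self.train_matrix,
            labels=self.labels,
            sigma=self.sigma,
            epsilon=self.epsilon,
            weight_mode=self.weight_mode,
            pair_ids=np.array([f"{a}\t{b}" for a, b in self.pair_ids]),
            feature_meta=json.dumps(self.feature_meta, sort_keys=True),
        )

    @classmethod
    def load(cls, path) -> "WSRCModel":
        with np.load(path, allow_pickle=False) as npz:
            version = int(npz["format_version"])
            if version > FORMAT_VERSION:
                raise ValueError(f"unsupported model format version {version}")
            labels = np.asarray(npz["labels"])
            return cls(
                train_matrix=np.asarray(npz["train_matrix"]),
                labels=labels,
                classes=np.unique(labels),
                sigma=float(npz["sigma"]),
                epsilon=float(npz["epsilon"]),
                weight_mode=str(npz["weight_mode"]),
                pair_ids=[tuple(s.split("\t")) for s in npz["pair_ids"].tolist()],
                feature_meta=json.loads(str(npz["feature_meta"])),
            )


@dataclass(frozen=True)
class Prediction:
    """Predicted class with per-class reconstruction residuals.

    ``score`` (binary problems only) is the residual margin
    ``r_negative - r_positive``: positive values favour the interacting
    class, and thresholding at 0 recovers the hard decision (ties go to
    the smaller class label).
    """

    predicted_class: int
    classes: np.ndarray
    residuals: np.ndarray
    score: float | None
    solution: SparseSolution


def fit(
    features: Sequence[PairFeature],
    sigma: float = DEFAULT_SIGMA,
    epsilon: float = DEFAULT_EPSILON,
    weight_mode: str = "reciprocal",
    feature_meta: dict | None = None,
) -> WSRCModel:
    """Stack labelled pair features into a WSRC model.

    Feature vectors become the columns of the training matrix and are
    l2-normalized.  At least two classes are required, and every vector
    must be nonzero (a zero vector cannot be normalized).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
    if not features:
        raise ValueError("no training features given")
    if any(f.label is None for f in features):
        raise ValueError("all training features must be labelled")
    lengths = {f.vector.size for f in features}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent feature lengths: {sorted(lengths)}")

    X = np.column_stack([f.vector for f in features]).astype(float)
    norms = np.linalg.norm(X, axis=0)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        bad = features[zero[0]].pair_id
        raise ValueError(f"training feature for pair {bad} is the zero vector")
    X /= norms

    labels = np.array([f.label for f in features], dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training data contains a single class; need at least two")
    return WSRCModel(
        train_matrix=X,
        labels=labels,
        classes=classes,
        sigma=float(sigma),
        epsilon=float(epsilon),
        weight_mode=weight_mode,
        pair_ids=[f.pair_id for f in features],
        feature_meta=dict(feature_meta or {}),
    )


def gaussian_distance(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian similarity exp(-||x - y||^2 / (2 sigma^2)), in (0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sq = float(np.sum((x - y) ** 2))
    return float(np.exp(-sq / (2.0 * sigma * sigma)))


def locality_weights(model: WSRCModel, y: np.ndarray) -> np.ndarray:
    """Per-atom l1 penalties from Gaussian similarity to the test vector.

    In the default "reciprocal" mode the penalty of atom i is
    ``1 / similarity``, so it is 1 for an atom identical to y and grows
    as atoms move away — the locality structure of the data enters the
    sparse code.  As ``sigma`` grows all weights tend to 1 and the
    classifier degenerates to unweighted sparse representation.
    """
    y = np.asarray(y, dtype=float).ravel()
    diff = model.train_matrix - y[:, None]
    sq = np.einsum("ij,ij->j", diff, diff)
    sim = np.exp(-sq / (2.0 * model.sigma**2))
    if model.weight_mode == "similarity":
        return sim
    return 1.0 / sim


def predict(model: WSRCModel, y: np.ndarray, refit: bool = True) -> Prediction:
    """Classify one vector by minimum class-restricted residual.

    The test vector is l2-normalized, locality weights are computed, the
    weighted stable l1 problem is solved, and for each class c the
    residual ``r_c = ||y - X alpha_c||`` is evaluated with the solved
    coefficients restricted to class-c atoms.  With ``refit`` (default)
    the coefficients are first polished by a least-squares fit on their
    support, removing the epsilon-sized bias the inequality constraint
    leaves on the solution.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != model.n_features:
        raise ValueError(f"expected a vector of length {model.n_features}, got {y.size}")
    norm = np.linalg.norm(y)
    if norm == 0:
        raise ValueError("cannot classify the zero vector")
    y = y / norm

    weights = locality_weights(model, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # infeasible eps is routine here
        solution = solve_weighted_l1(
            model.train_matrix,
            y,
            weights,
            model.epsilon,
            least_squares=model.least_squares,
        )

    alpha = solution.alpha
    if refit and solution.converged:
        support = np.flatnonzero(np.abs(alpha) > 1e-12)
        if support.size:
            sub = model.train_matrix[:, support]
            coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
            polished = np.zeros_like(alpha)
            polished[support] = coef
            # keep the polish only if it does not worsen the fit
            if np.linalg.norm(y - sub @ coef) <= solution.residual_norm + 1e-12:
                alpha = polished

    residuals = np.empty(model.classes.size)
    for idx, cls in enumerate(model.classes):
        masked = np.where(model.class_mask(cls), alpha, 0.0)
        residuals[idx] = np.linalg.norm(y - model.train_matrix @ masked)

    best = int(np.argmin(residuals))  # ties -> smallest class index
    score = None
    if model.classes.size == 2:
        score = float(residuals[0] - residuals[1])
    return Prediction(
        predicted_class=int(model.classes[best]),
        classes=model.classes,
        residuals=residuals,
        score=score,
        solution=solution,
    )
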