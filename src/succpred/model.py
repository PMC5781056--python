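"""RBF-kernel support vector machine for succinylation-site discrimination.

The classifier predicts the label of an unseen lysine descriptor x' as

    y' = sign( sum_i alpha_i * y_i * K(x_i, x') + beta ),
    K(u, v) = exp(-gamma * ||u - v||^2)

where the sum runs over the support vectors x_i with dual weights
0 <= alpha_i <= C and bias beta.  Default hyperparameters are C = 1,
gamma = 0.01, solver tolerance = 0.001 and a round-off epsilon of 1e-12
(the epsilon belongs to SMO implementations that carry an explicit
round-off threshold; here it is recorded in the parameter set and the
solver's own tolerance governs convergence).

Features are z-scored on the training data before the kernel is applied:
the descriptor mixes square Angstroms, degrees and probabilities, and a
fixed gamma of 0.01 is only meaningful on a common scale.  Standardization
can be disabled.

The module follows the model/results idiom: :class:`SuccinylationSVM` is
constructed from data and ``fit()`` returns an :class:`SVMResults` carrying
the support vectors, dual weights, bias, training diagnostics, a
``summary()`` table and JSON (de)serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .balance import LabeledDataset

MODEL_FORMAT_VERSION = 1


class ModelError(ValueError):
    pass


@dataclass
class SVMParams:
    """Hyperparameters of the soft-margin RBF SVM."""

    C: float = 1.0
    gamma: float = 0.01
    tolerance: float = 0.001
    epsilon: float = 1e-12  # SMO round-off threshold; informational here
    standardize: bool = True

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "gamma": self.gamma,
            "tolerance": self.tolerance,
            "epsilon": self.epsilon,
            "standardize": self.standardize,
        }


class SuccinylationSVM:
    """Soft-margin RBF-kernel SVM built from a labeled lysine dataset.

    Parameters
    ----------
    data : LabeledDataset or None
        Training data with labels in {+1, -1}.  Alternatively pass ``X``
        and ``y`` directly.
    params : SVMParams
        Hyperparameters; defaults C=1, gamma=0.01, tolerance=0.001.
    """

    def __init__(
        self,
        data: LabeledDataset | None = None,
        X: np.ndarray | None = None,
        y: np.ndarray | None = None,
        params: SVMParams | None = None,
    ) -> None:
        if data is not None:
            X, y = data.X, data.y
        if X is None or y is None:
            raise ModelError("provide a LabeledDataset or X and y")
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ModelError("X must be 2-D with one label per row")
        if np.any(~np.isfinite(self.X)):
            raise ModelError("feature matrix contains NaN or infinite values")
        classes = set(np.unique(self.y))
        if not classes <= {-1, 1}:
            raise ModelError("labels must lie in {+1, -1}")
        if classes != {-1, 1}:
            raise ModelError("training data must contain both classes")
        self.params = params or SVMParams()

    @classmethod
    def from_dataset(
        cls, data: LabeledDataset, params: SVMParams | None = None
    ) -> "SuccinylationSVM":
        return cls(data=data, params=params)

    def fit(self) -> "SVMResults":
        """Solve the soft-margin dual and return a results object."""
        p = self.params
        if p.standardize:
            mean = self.X.mean(axis=0)
            sd = self.X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mean = np.zeros(self.X.shape[1])
            sd = np.ones(self.X.shape[1])
        Xs = (self.X - mean) / sd

        svc = SVC(C=p.C, kernel="rbf", gamma=p.gamma, tol=p.tolerance, cache_size=200)
        svc.fit(Xs, self.y)
        # sklearn orders classes ascending, so decision > 0 <=> class +1 and
        # dual_coef_ already carries alpha_i * y_i.
        results = SVMResults(
            params=p,
            scaler_mean=mean,
            scaler_scale=sd,
            support_vectors=svc.support_vectors_.copy(),
            dual_coef=svc.dual_coef_.ravel().copy(),
            intercept=float(svc.intercept_[0]),
            support_labels=self.y[svc.support_].copy(),
            n_features=self.X.shape[1],
            n_train=self.X.shape[0],
        )
        results._svc = svc
        results._train_accuracy = float(
            np.mean(results.predict(self.X) == self.y)
        )
        return results


@dataclass
class SVMResults:
    """Fitted SVM: support-vector expansion plus the training-data scaler.

    ``support_vectors`` live in the standardized feature space;
    ``dual_coef`` holds ``alpha_i * y_i`` so the decision value of a raw
    input x is ``sum_i dual_coef_i * K(sv_i, scale(x)) + intercept``.
    """

    params: SVMParams
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    support_labels: np.ndarray
    n_features: int
    n_train: int
    _train_accuracy: float | None = field(default=None, repr=False)
    _svc: object | None = field(default=None, repr=False, compare=False)

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]

    @property
    def alpha(self) -> np.ndarray:
        """Dual weights alpha_i (all in [0, C])."""
        return self.dual_coef * self.support_labels

    @property
    def train_accuracy(self) -> float | None:
        return self._train_accuracy

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ModelError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        return (X - self.scaler_mean) / self.scaler_scale

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Real-valued margin of each row.

        Uses the underlying solver when the results came straight from
        ``fit()``; after deserialization it falls back to the explicit
        support-vector expansion (:meth:`dual_expansion`), which agrees to
        solver round-off.
        """
        if self._svc is not None:
            return np.asarray(self._svc.decision_function(self._scale(X)))
        return self.dual_expansion(X)

    def dual_expansion(self, X: np.ndarray) -> np.ndarray:
        """Explicit decision value sum_i alpha_i y_i K(x_i, x) + beta."""
        Xs = self._scale(X)
        d2 = (
            np.sum(Xs**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * Xs @ self.support_vectors.T
        )
        K = np.exp(-self.params.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted labels; the tie sign(0) resolves to +1."""
        d = self.decision_function(X)
        return np.where(d >= 0.0, 1, -1)

    def summary(self) -> str:
        """Human-readable fit summary."""
        p = self.params
        lines = [
            "RBF-SVM succinylation classifier",
            "=" * 40,
            f"training samples      {self.n_train}",
            f"features              {self.n_features}",
            f"support vectors       {self.n_support}",
            f"C                     {p.C:g}",
            f"gamma                 {p.gamma:g}",
            f"solver tolerance      {p.tolerance:g}",
            f"standardized inputs   {p.standardize}",
            f"bias (beta)           {self.intercept:.6f}",
        ]
        if self._train_accuracy is not None:
            lines.append(f"training accuracy     {self._train_accuracy:.4f}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "params": self.params.to_dict(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "support_labels": self.support_labels.tolist(),
            "intercept": self.intercept,
            "n_features": self.n_features,
            "n_train": self.n_train,
            "train_accuracy": self._train_accuracy,
        }
        return json.dumps(payload)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "SVMResults":
        payload = json.loads(text)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ModelError(
                f"unsupported model format version {payload.get('format_version')!r}"
            )
        return cls(
            params=SVMParams(**payload["params"]),
            scaler_mean=np.asarray(payload["scaler_mean"]),
            scaler_scale=np.asarray(payload["scaler_scale"]),
            support_vectors=np.asarray(payload["support_vectors"]),
            dual_coef=np.asarray(payload["dual_coef"]),
            support_labels=np.asarray(payload["support_labels"], dtype=int),
            intercept=float(payload["intercept"]),
            n_features=int(payload["n_features"]),
            n_train=int(payload["n_train"]),
            _train_accuracy=payload.get("train_accuracy"),
        )

    @classmethod
    def load(cls, path) -> "SVMResults":
        with open(path) as fh:
            return cls.from_json(fh.read())


def train(data: LabeledDataset, params: SVMParams | None = None) -> SVMResults:
    """Convenience wrapper: fit :class:`SuccinylationSVM` on a dataset."""
    return SuccinylationSVM(data=data, params=params).fit()
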