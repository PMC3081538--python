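"""Soft-margin kernel SVM with the study protocol's hyperparameters.

The evaluation protocol trains an RBF-kernel SVM with ``C = 10``,
``gamma = 0.1``, a loose termination tolerance of ``1.0`` and, notably, an
*unbiased* hyperplane (svm_light's ``-b 0``): the decision function is
``f(x) = sum_i alpha_i y_i K(x, x_i)`` with no intercept.  Without a bias
term the dual problem loses its equality constraint and becomes a
box-constrained QP,

    max_alpha  sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K_ij
    s.t.       0 <= alpha_i <= C,

which this module solves by cyclic coordinate ascent with closed-form
single-variable updates (numba-compiled), stopping when the largest KKT
violation drops below the termination tolerance.  scikit-learn's SVC cannot
drop the intercept for kernel machines, so the unbiased solver is native
here; ``biased=True`` delegates to :class:`sklearn.svm.SVC`.

Overfitting gate: a trained model whose support-vector count reaches 10% of
the training set is flagged as overfit (support vectors tailored to the
training sample generalize poorly at that density).

Conventions: a decision score of exactly 0 maps to the negative class;
larger ``C`` means a larger penalty on margin violations (less tolerance to
training error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .feature_table import FeatureTable

_SUPPORTED_KERNELS = ("rbf",)


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameters; the defaults are the study protocol's flags."""

    c: float = 10.0
    kernel: str = "rbf"
    gamma: float = 0.1
    epsilon: float = 1.0          # KKT-violation termination tolerance
    biased: bool = False
    sv_fraction_limit: float = 0.1
    max_passes: int = 2000

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.kernel not in _SUPPORTED_KERNELS:
            raise ValueError(f"unsupported kernel {self.kernel!r}; supported: {_SUPPORTED_KERNELS}")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if not 0 < self.sv_fraction_limit <= 1:
            raise ValueError("sv_fraction_limit must lie in (0, 1]")


def rbf_kernel_matrix(a: np.ndarray, b: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(a, b, metric="sqeuclidean"))


@njit(cache=True)
def _coordinate_ascent(K, y, c, eps, max_passes):  # pragma: no cover - compiled
    n = K.shape[0]
    alpha = np.zeros(n)
    f = np.zeros(n)  # f[i] = sum_j alpha_j y_j K[i, j]
    for _ in range(max_passes):
        max_viol = 0.0
        for i in range(n):
            g = 1.0 - y[i] * f[i]  # dual gradient wrt alpha_i
            a = alpha[i]
            if a <= 0.0:
                viol = g if g > 0.0 else 0.0
            elif a >= c:
                viol = -g if g < 0.0 else 0.0
            else:
                viol = abs(g)
            if viol > max_viol:
                max_viol = viol
            if viol > 0.0:
                new = a + g / K[i, i]
                if new < 0.0:
                    new = 0.0
                elif new > c:
                    new = c
                delta = new - a
                if delta != 0.0:
                    alpha[i] = new
                    yi = y[i]
                    for j in range(n):
                        f[j] += delta * yi * K[j, i]
        if max_viol < eps:
            break
    return alpha


@dataclass
class TrainedModel:
    """A fitted SVM restricted to one tool subset.

    Holds only the support vectors; ``decision_function`` maps feature rows
    (same columns, same order as training) to real scores, and prediction is
    positive iff the score is strictly greater than 0.
    """

    tool_names: list[str]
    support_vectors: np.ndarray   # (n_sv, n_tools)
    dual_coef: np.ndarray         # alpha_i * y_i at the support vectors
    intercept: float
    sv_count: int
    train_size: int
    config: SVMConfig

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        k = rbf_kernel_matrix(x, self.support_vectors, self.config.gamma)
        return k @ self.dual_coef + self.intercept


def train(table: FeatureTable, config: SVMConfig = SVMConfig()) -> TrainedModel:
    """Fit the SVM on an imputed feature table (labels taken from the table).

    Raises if the table still has missing cells, contains a single class, or
    holds non-finite features.
    """
    if table.has_missing:
        raise ValueError("training data contains missing cells; impute first")
    x = np.ascontiguousarray(table.values, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature value in training data")
    y01 = table.labels
    if table.n_positive == 0 or table.n_negative == 0:
        raise ValueError("training data must contain both classes")
    y = np.where(y01 == 1, 1.0, -1.0)

    if config.biased:
        from sklearn.svm import SVC

        clf = SVC(C=config.c, kernel="rbf", gamma=config.gamma, tol=min(config.epsilon, 1e-3))
        clf.fit(x, y)
        sv = clf.support_vectors_
        coef = clf.dual_coef_.ravel()
        intercept = float(clf.intercept_[0])
    else:
        K = rbf_kernel_matrix(x, x, config.gamma)
        alpha = _coordinate_ascent(K, y, float(config.c), float(config.epsilon), config.max_passes)
        sv_idx = np.nonzero(alpha > 0.0)[0]
        sv = x[sv_idx]
        coef = alpha[sv_idx] * y[sv_idx]
        intercept = 0.0

    return TrainedModel(
        tool_names=list(table.tool_names),
        support_vectors=sv,
        dual_coef=coef,
        intercept=intercept,
        sv_count=int(sv.shape[0]),
        train_size=table.n_proteins,
        config=config,
    )


def labels_from_scores(scores: np.ndarray) -> np.ndarray:
    """Positive class iff score > 0; an exact 0 is negative (documented tie-break)."""
    return (np.asarray(scores) > 0).astype(np.int8)


def predict(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Predict {0, 1} labels for every row of a table with the model's columns."""
    if list(table.tool_names) != model.tool_names:
        raise ValueError(
            f"feature columns {table.tool_names} do not match the model's "
            f"training columns {model.tool_names} (name and order must agree)"
        )
    if table.has_missing:
        raise ValueError("prediction data contains missing cells; impute first")
    return labels_from_scores(model.decision_function(table.values))


def sv_gate(model: TrainedModel, limit: float | None = None) -> bool:
    """True iff the support-vector fraction stays below the overfitting limit."""
    if limit is None:
        limit = model.config.sv_fraction_limit
    if not 0 < limit <= 1:
        raise ValueError("limit must lie in (0, 1]")
    # at the degenerate upper bound the gate admits everything, even an
    # all-support-vector model (fraction exactly 1)
    return limit == 1.0 or model.sv_count / model.train_size < limit
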