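"""Independent reference solver for the unbiased soft-margin SVM dual.

Solves  min_a 0.5 a'Qa - sum(a)  s.t. 0 <= a <= C,  Q = (y y') * K,
with scipy's L-BFGS-B — a completely different optimization route from the
package's coordinate-ascent engine, used only as a test oracle.
"""

import numpy as np
from scipy.optimize import minimize

from mitosweep.svm import rbf_kernel_matrix


def qp_scores(x_train, y01, x_eval, c=10.0, gamma=0.1):
    y = np.where(np.asarray(y01) == 1, 1.0, -1.0)
    k = rbf_kernel_matrix(x_train, x_train, gamma)
    q = (y[:, None] * y[None, :]) * k
    res = minimize(
        lambda a: 0.5 * a @ q @ a - a.sum(),
        np.zeros(len(y)),
        jac=lambda a: q @ a - 1.0,
        method="L-BFGS-B",
        bounds=[(0.0, c)] * len(y),
        options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return rbf_kernel_matrix(np.asarray(x_eval, float), x_train, gamma) @ (res.x * y)


def random_instance(seed, max_n=200):
    """A small seeded two-class instance with unit-interval features."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(40, max_n))
    d = int(rng.integers(1, 5))
    n_pos = max(2, n // 5)
    y01 = np.concatenate([np.ones(n_pos, np.int8), np.zeros(n - n_pos, np.int8)])
    x = np.clip(
        rng.random((n, d)) * 0.3 + 0.5 * y01[:, None] + 0.1 * rng.standard_normal((n, d)),
        0.0, 1.0,
    )
    return x, y01
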