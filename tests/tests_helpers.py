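"""Independent oracles shared by tests."""

import numpy as np
import scipy.optimize


def qp_oracle_objective(A, b):
    """Brute-force bound-constrained QP solution of min 0.5||Ax-b||^2, x >= 0.

    Deliberately independent of the active-set path: dense L-BFGS-B from
    several starts, keeping the best objective found.
    """
    def f(x):
        r = A @ x - b
        return 0.5 * r @ r

    def g(x):
        return A.T @ (A @ x - b)

    n = A.shape[1]
    best = np.inf
    for x0 in (np.zeros(n), np.full(n, 0.5), np.linalg.lstsq(A, b, rcond=None)[0].clip(0)):
        res = scipy.optimize.minimize(f, x0, jac=g, method="L-BFGS-B",
                                      bounds=[(0, None)] * n,
                                      options={"ftol": 1e-14, "gtol": 1e-12})
        best = min(best, res.fun)
    return best
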