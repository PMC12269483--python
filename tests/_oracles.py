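"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package's solver: the lasso
oracle is plain cyclic coordinate descent on the Gram form, and the
derivative oracle is central finite differences.
"""

import numpy as np


def cd_lasso(A, b, lam, mask, max_sweeps=20000, tol=1e-13):
    """Cyclic coordinate descent for min 1/2 x'Ax - b'x + lam*||x[mask]||_1."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    p = b.shape[0]
    x = np.zeros(p)
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            r = b[j] - A[j] @ x + A[j, j] * x[j]
            if mask[j]:
                new = np.sign(r) * max(abs(r) - lam, 0.0) / A[j, j]
            else:
                new = r / A[j, j]
            delta = max(delta, abs(new - x[j]))
            x[j] = new
        if delta < tol:
            break
    return x


def wls_quadratic(X, w, y):
    """Gram form (A, b) of the weighted least-squares mean loss."""
    n = X.shape[0]
    A = 2.0 * (X * (w / n)[:, None]).T @ X
    b = 2.0 * X.T @ (w * y / n)
    return A, b


def fd_gradient(f, x, h=1e-6):
    """Central finite-difference gradient of a scalar function."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for j in range(x.shape[0]):
        e = np.zeros_like(x)
        e[j] = h
        g[j] = (f(x + e) - f(x - e)) / (2.0 * h)
    return g


def fd_hessian_from_gradient(grad, x, h=1e-6):
    """Central finite-difference Jacobian of a gradient function."""
    x = np.asarray(x, dtype=float)
    p = x.shape[0]
    H = np.empty((p, p))
    for j in range(p):
        e = np.zeros_like(x)
        e[j] = h
        H[:, j] = (grad(x + e) - grad(x - e)) / (2.0 * h)
    return 0.5 * (H + H.T)
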