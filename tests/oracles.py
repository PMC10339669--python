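"""Independent numerical oracles used by the tests.

Deliberately avoids the code paths under test: eigenvalues come from the
characteristic polynomial (Faddeev-LeVerrier coefficients + bisection on
Gershgorin intervals), not from a matrix eigensolver.
"""

import numpy as np


def charpoly_coefficients(H: np.ndarray) -> np.ndarray:
    """Coefficients of det(lambda I - H) by Faddeev-LeVerrier."""
    n = H.shape[0]
    coeffs = np.zeros(n + 1)
    coeffs[0] = 1.0
    M = np.zeros_like(H)
    for k in range(1, n + 1):
        M = H @ M + coeffs[k - 1] * np.eye(n)
        coeffs[k] = -np.trace(H @ M) / k
    return coeffs


def charpoly_eigenvalues(H: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Real symmetric eigenvalues via sign changes of the charpoly."""
    n = H.shape[0]
    c = charpoly_coefficients(H)

    def p(x):
        out = 0.0
        for ck in c:
            out = out * x + ck
        return out

    # Gershgorin bound for the search interval
    radius = np.abs(H).sum(axis=1)
    lo = float((np.diag(H) - radius).min()) - 1.0
    hi = float((np.diag(H) + radius).max()) + 1.0
    grid = np.linspace(lo, hi, 20000)
    vals = np.array([p(x) for x in grid])
    roots = []
    for i in range(len(grid) - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0:
            roots.append(a)
            continue
        if fa * fb < 0:
            while b - a > tol:
                m = 0.5 * (a + b)
                fm = p(m)
                if fa * fm <= 0:
                    b = m
                else:
                    a, fa = m, fm
            roots.append(0.5 * (a + b))
    return np.sort(np.array(roots))
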