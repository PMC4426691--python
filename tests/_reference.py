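"""Independent reference trilinear solver for oracle tests.

Deliberately different from the package implementation: unconstrained ALS
with direct ``numpy.linalg.lstsq`` solves on full Khatri-Rao design
matrices, no normal equations, no non-negativity, no missing-data handling.
"""

import numpy as np


def khatri_rao(u, v):
    n_u, f = u.shape
    n_v = v.shape[0]
    out = np.empty((n_u * n_v, f))
    for col in range(f):
        out[:, col] = np.outer(u[:, col], v[:, col]).ravel()
    return out


def reference_als(x, n_components, seed=0, max_iter=2000, tol=1e-12):
    """Plain ALS on a (n, J, K) tensor; returns (a, b, c, sse)."""
    rng = np.random.default_rng(seed)
    n, nj, nk = x.shape
    b = rng.random((nj, n_components))
    c = rng.random((nk, n_components))
    a = rng.random((n, n_components))
    prev = np.inf
    for _ in range(max_iter):
        a = np.linalg.lstsq(khatri_rao(b, c), x.reshape(n, -1).T, rcond=None)[0].T
        b = np.linalg.lstsq(
            khatri_rao(a, c), x.transpose(1, 0, 2).reshape(nj, -1).T, rcond=None
        )[0].T
        c = np.linalg.lstsq(
            khatri_rao(a, b), x.transpose(2, 0, 1).reshape(nk, -1).T, rcond=None
        )[0].T
        model = np.einsum("if,jf,kf->ijk", a, b, c)
        sse = float(np.sum((x - model) ** 2))
        if prev - sse < tol * max(prev, 1.0):
            break
        prev = sse
    return a, b, c, sse


def cosine(x, y):
    """Brute-force cosine, written out elementwise as the congruence oracle."""
    num = 0.0
    sx = 0.0
    sy = 0.0
    for xi, yi in zip(x, y):
        num += xi * yi
        sx += xi * xi
        sy += yi * yi
    return num / (sx**0.5 * sy**0.5)
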