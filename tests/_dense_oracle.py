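"""Dense closed-form mixed-model computations used as independent oracles.

Everything here works on explicit N x N matrices (V = ZGZ' + R) and the
textbook GLS/BLUP formulas, deliberately avoiding the package's sparse
MME path, so small instances can cross-check it.
"""

import numpy as np
import scipy.sparse as sp

from clonesel.lmm import assemble_covariance

LOG2PI = float(np.log(2.0 * np.pi))


def dense_parts(design, est):
    """(X, Z_full, G_full, R) as dense arrays in MME term order."""
    G_s, G_c, G_b, R = assemble_covariance(est, design)
    blocks = {"family": G_s, "clone": G_c, "block": G_b}
    Zs, Gs = [], []
    for term in design.terms:
        Zs.append(design.Z[term].toarray())
        Gs.append(blocks[term].toarray())
    Z = np.hstack(Zs)
    G = sp.block_diag([sp.csc_matrix(g) for g in Gs]).toarray()
    return design.X, Z, G, R.toarray()


def dense_reml_loglik(design, est):
    X, Z, G, R = dense_parts(design, est)
    y = design.y
    V = Z @ G @ Z.T + R
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtVX)
    n, o = X.shape
    return -0.5 * ((n - o) * LOG2PI + ldV + ldX + quad)


def dense_blup(design, est):
    """(beta, u, pev_diag, pev_full) from the closed formulas."""
    X, Z, G, R = dense_parts(design, est)
    y = design.y
    V = Z @ G @ Z.T + R
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    u = G @ Z.T @ Vi @ (y - X @ beta)
    P = Vi - Vi @ X @ np.linalg.solve(XtVX, X.T @ Vi)
    pev = G - G @ Z.T @ P @ Z @ G  # var(u_hat - u)
    return beta, u, np.diag(pev), pev
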