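"""Restricted-maximum-likelihood engines for the growth mixed models.

Two estimators share this module:

``fit_lmm``
    Gaussian linear mixed model with independent subjects,
    ``y_i = X_i beta + Z_i b_i + e_i``, ``b_i ~ N(0, G)`` unstructured,
    ``e_i ~ N(0, sigma2 I)``.  Fitted by the exact REML EM algorithm
    (Laird-Ware style, with the fixed-effect trace correction), which keeps
    G positive semi-definite by construction and increases the restricted
    log-likelihood at every iteration — the recorded trace is monotone.
    Subjects are padded to a common length so each iteration is a handful
    of batched linear-algebra calls.

``fit_shared_spline``
    The penalized-spline mixed model: on top of the subject random effects
    there is a population-level vector u of truncated-line coefficients
    shared by all rows (the spline ridge penalty in mixed-model form),
    ``y = X beta + T u + Z b + e`` with ``u ~ N(0, sigma_u2 I)``.  The
    shared u couples all subjects, so here the profiled REML criterion
    (sigma2 and beta profiled out, Woodbury correction for the K shared
    columns) is minimised directly over the few variance ratios by
    Nelder-Mead; the recorded trace is the best objective so far, which is
    non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .basis import DegenerateDesignError

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class REMLResult:
    beta: np.ndarray          # fixed effects
    G: np.ndarray             # subject random-effect covariance (q x q, PSD)
    sigma2: float             # residual variance
    loglik: float             # restricted log-likelihood at the optimum
    trace: list[float]        # per-iteration restricted log-likelihood
    converged: bool
    n_iter: int
    message: str = ""
    # penalized-spline extras
    u_blup: np.ndarray | None = None    # BLUP of the shared spline coefficients
    sigma_u2: float | None = None       # their variance component


def _pack(X, Z, y, groups):
    """Sort rows by subject and pad to a common length.

    Returns (Xp, Zp, yp, counts) with shapes (N, nmax, p), (N, nmax, q),
    (N, nmax); padded rows are all-zero, which makes the padded part of
    each V_i equal sigma2*I and lets every sum run over the full padded
    arrays with exactly cancelling corrections.
    """
    groups = np.asarray(groups)
    _, inv = np.unique(groups, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    inv_s = inv[order]
    counts = np.bincount(inv_s)
    N, nmax = len(counts), counts.max()
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    slot = np.arange(len(inv_s)) - starts[inv_s]
    Xp = np.zeros((N, nmax, X.shape[1]))
    Zp = np.zeros((N, nmax, Z.shape[1]))
    yp = np.zeros((N, nmax))
    Xp[inv_s, slot] = X[order]
    Zp[inv_s, slot] = Z[order]
    yp[inv_s, slot] = y[order]
    return Xp, Zp, yp, counts


def fit_lmm(X, Z, y, groups, *, max_iter=3000, tol=1e-8,
            sigma2_floor=None) -> REMLResult:
    """REML fit of the subject-level Gaussian LMM by the EM algorithm.

    Parameters
    ----------
    X, Z : fixed and random design matrices (rows = observations).
    y : response vector.
    groups : subject label per row (any hashable dtype).
    tol : relative restricted-log-likelihood change declaring convergence.
    sigma2_floor : lower clamp for the residual variance; defaults to
        ``1e-9 * var(y)``, which keeps V invertible in double precision on
        noiseless data (condition number ~1e9) while staying far below any
        real measurement-error variance.
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    n, p = X.shape
    q = Z.shape[1]
    if len(np.unique(groups)) < 2:
        raise DegenerateDesignError("need at least 2 subjects")
    if n <= p:
        raise DegenerateDesignError("more fixed effects than observations")

    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < p:
        raise DegenerateDesignError("singular fixed-effect design")
    beta = np.linalg.solve(XtX, X.T @ y)
    resid_var = float(np.var(y - X @ beta))
    if resid_var == 0.0:
        resid_var = max(float(np.var(y)), 1.0)
    if sigma2_floor is None:
        sigma2_floor = 1e-9 * max(float(np.var(y)), 1e-30)

    sigma2 = max(0.5 * resid_var, sigma2_floor)
    G = 0.5 * resid_var * np.eye(q)

    Xp, Zp, yp, counts = _pack(X, Z, y, groups)
    N, nmax = yp.shape
    pad = nmax - counts                       # padded slots per subject
    eye = np.eye(nmax)
    beta_out = beta

    def em_step(G, sigma2):
        """One REML EM update; returns the restricted log-likelihood AT the
        input parameters together with the updated (beta, G, sigma2)."""
        nonlocal beta_out
        ZG = Zp @ G
        V = ZG @ Zp.transpose(0, 2, 1) + sigma2 * eye[None]
        W = np.linalg.inv(V)
        _, ld = np.linalg.slogdet(V)
        logdetV = float(ld.sum() - pad.sum() * np.log(sigma2))
        WX = W @ Xp
        XtWX = np.einsum("nij,nik->jk", Xp, WX)
        XtWy = np.einsum("nij,ni->j", WX, yp)
        try:
            S = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError as e:
            raise DegenerateDesignError(f"singular GLS system: {e}") from e
        beta = S @ XtWy
        beta_out = beta
        r = (yp - Xp @ beta)
        # padded rows of X and Z are zero, so V (hence W) is block-diagonal
        # between real and padded slots; zeroing padded residuals suffices
        r[np.arange(nmax)[None, :] >= counts[:, None]] = 0.0
        Wr = np.einsum("nij,nj->ni", W, r)
        quad = float((r * Wr).sum())
        _, ldS = np.linalg.slogdet(XtWX)
        loglik = -0.5 * (logdetV + ldS + quad + (n - p) * _LOG2PI)
        # E-step quantities under REML (P = V^-1 - V^-1 X S X' V^-1)
        P = W - WX @ S @ WX.transpose(0, 2, 1)
        bhat = np.einsum("pq,niq,ni->np", G, Zp, Wr)
        ZtPZ = np.einsum("nip,nij,njq->npq", Zp, P, Zp)
        Ebb = bhat[:, :, None] * bhat[:, None, :] + G[None] - G @ ZtPZ @ G
        G_new = Ebb.mean(axis=0)
        G_new = _psd(0.5 * (G_new + G_new.T))
        trP = float(np.einsum("nii->", P))
        Eee = sigma2**2 * float((Wr * Wr).sum()) + sigma2 * (N * nmax) \
            - sigma2**2 * trP
        s2_new = max(Eee / n, sigma2_floor)
        return loglik, G_new, s2_new

    def _psd(M):
        ev, U = np.linalg.eigh(M)
        if ev[0] < 0:
            M = (U * np.clip(ev, 0.0, None)) @ U.T
        return M

    def to_vec(G, s2):
        return np.concatenate([G.ravel(), [np.log(max(s2, sigma2_floor))]])

    def from_vec(v):
        Gm = _psd(0.5 * (v[:-1].reshape(q, q) + v[:-1].reshape(q, q).T))
        return Gm, max(float(np.exp(v[-1])), sigma2_floor)

    # EM with SQUAREM-style extrapolation: each cycle takes two plain EM
    # steps, extrapolates along the parameter change, and keeps the
    # extrapolated point only if it does not lower the restricted
    # log-likelihood -- so the recorded trace stays monotone.
    trace: list[float] = []
    converged = False
    n_em = 0
    best_ll = -np.inf
    stalled = 0
    while n_em < max_iter and not converged:
        ll0, G1, s1 = em_step(G, sigma2)
        ll1, G2, s2 = em_step(G1, s1)
        n_em += 2
        trace.extend([ll0, ll1])
        if abs(ll1 - ll0) <= tol * (1.0 + abs(ll0)):
            G, sigma2 = G1, s1
            converged = True
            break
        # near a variance boundary the likelihood can stop improving while
        # round-off keeps the per-step change above tol: treat a long run
        # of cycles without improvement as converged (flat to precision)
        if ll1 > best_ll + tol * (1.0 + abs(ll1)):
            best_ll = max(best_ll, ll1)
            stalled = 0
        else:
            stalled += 1
            if stalled >= 8:
                G, sigma2 = G1, s1
                converged = True
                break
        t0 = to_vec(G, sigma2)
        rvec = to_vec(G1, s1) - t0
        vvec = (to_vec(G2, s2) - to_vec(G1, s1)) - rvec
        nv = np.linalg.norm(vvec)
        if nv > 0:
            alpha = min(-np.linalg.norm(rvec) / nv, -1.0)
            Ge, se = from_vec(t0 - 2.0 * alpha * rvec + alpha**2 * vvec)
            try:
                lle, G3, s3 = em_step(Ge, se)
                n_em += 1
            except (DegenerateDesignError, np.linalg.LinAlgError):
                lle = -np.inf
            if np.isfinite(lle) and lle >= ll1:
                trace.append(lle)
                if abs(lle - ll1) <= tol * (1.0 + abs(ll1)):
                    G, sigma2 = Ge, se
                    converged = True
                    break
                G, sigma2 = G3, s3
                continue
        G, sigma2 = G2, s2

    loglik = trace[-1] if trace else -np.inf
    return REMLResult(beta=beta_out, G=G, sigma2=float(sigma2),
                      loglik=float(loglik), trace=trace, converged=converged,
                      n_iter=n_em,
                      message="EM converged" if converged else
                      "EM iteration budget exhausted")


def _gamma_from_theta(theta, q_sub):
    """Subject covariance ratio Gamma = blockdiag(LL', r_nu I) from the
    unconstrained parameter vector (log-Cholesky 2x2 + log ratios)."""
    a11, a21, a22, log_rnu, log_ru = theta
    L = np.array([[np.exp(a11), 0.0], [a21, np.exp(a22)]])
    A = L @ L.T
    Gam = np.zeros((q_sub, q_sub))
    Gam[:2, :2] = A
    if q_sub > 2:
        Gam[2:, 2:] = np.exp(log_rnu) * np.eye(q_sub - 2)
    return Gam, np.exp(log_ru)


def fit_shared_spline(X, T, Z, y, groups, *, max_iter=2000,
                      tol=1e-8) -> REMLResult:
    """Profiled REML for the penalized-spline mixed model.

    X: fixed [1, t] columns; T: shared population truncated-line columns
    (ridge-penalized); Z: subject random design ([1, t] + subject truncated
    lines); groups: subject per row.
    """
    X = np.asarray(X, float)
    T = np.asarray(T, float)
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    n, p = X.shape
    K = T.shape[1]
    q = Z.shape[1]
    if len(np.unique(groups)) < 2:
        raise DegenerateDesignError("need at least 2 subjects")
    if n <= p:
        raise DegenerateDesignError("more fixed effects than observations")

    C = np.column_stack([X, T])
    Cp, Zp, yp, counts = _pack(C, Z, y, groups)
    Xp = Cp[:, :, :p]
    N, nmax = yp.shape
    eye = np.eye(nmax)
    # floor on the profiled residual variance: keeps the criterion bounded
    # on noiseless data (otherwise it decreases without limit as every
    # variance ratio grows) and the conditioning sane in double precision
    s2_floor = 1e-9 * max(float(np.var(y)), 1e-30)

    def criterion(theta, want=False):
        theta = np.asarray(theta, float)
        # reject proposals beyond any physically meaningful variance ratio
        # before they overflow the exponentials
        if not np.all(np.isfinite(theta)) or np.any(np.abs(theta) > 60.0):
            return (np.inf, None) if want else np.inf
        Gam, rho_u = _gamma_from_theta(theta, q)
        B = Zp @ Gam @ Zp.transpose(0, 2, 1) + eye[None]
        try:
            Binv = np.linalg.inv(B)
        except np.linalg.LinAlgError:
            return (np.inf, None) if want else np.inf
        _, ldB = np.linalg.slogdet(B)
        logdetB = float(ldB.sum())          # padded slots contribute log 1 = 0
        BC = Binv @ Cp
        A0 = np.einsum("nij,nik->jk", Cp, BC)
        c0 = np.einsum("nij,ni->j", BC, yp)
        yBy = float(np.einsum("ni,nij,nj->", yp, Binv, yp))
        Axx, Axu, Auu = A0[:p, :p], A0[:p, p:], A0[p:, p:]
        M = np.eye(K) / rho_u + Auu
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            return (np.inf, None) if want else np.inf
        XtVX = Axx - Axu @ Minv @ Axu.T
        XtVy = c0[:p] - Axu @ Minv @ c0[p:]
        yVy = yBy - c0[p:] @ Minv @ c0[p:]
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return (np.inf, None) if want else np.inf
        quad = yVy - beta @ XtVy
        s2 = max(quad / (n - p), s2_floor)
        sM, ldM = np.linalg.slogdet(M)
        sV, ldXtVX = np.linalg.slogdet(XtVX)
        if sM <= 0 or sV <= 0:
            return (np.inf, None) if want else np.inf
        obj = (n - p) * np.log(s2) + logdetB + K * np.log(rho_u) + ldM + ldXtVX
        if not want:
            return obj
        g = c0[p:] - Axu.T @ beta           # T' B^-1 (y - X beta)
        u_blup = Minv @ g
        return obj, dict(beta=beta, sigma2=s2, Gam=Gam, rho_u=rho_u,
                         u_blup=u_blup)

    best = [np.inf]
    trace: list[float] = []

    def cb(xk):
        f = criterion(xk)
        best[0] = min(best[0], f)
        trace.append(best[0])

    # multi-start: the 5-parameter REML surface has local optima (the
    # population-spline ratio trades off against the subject smooth), and
    # a single simplex start is not reliable across basis sizes
    base = np.array([np.log(0.3), 0.0, np.log(0.3),
                     np.log(0.1), np.log(1.0)])
    res = None
    for shift in (0.0, 2.5, -2.5):
        cand = minimize(criterion, base + shift, method="Nelder-Mead",
                        options=dict(maxiter=max_iter, xatol=1e-6, fatol=tol,
                                     adaptive=True), callback=cb)
        if res is None or criterion(cand.x) < criterion(res.x):
            res = cand
    theta, obj = res.x, criterion(res.x)
    _, ex0 = criterion(theta, want=True)
    # a fit pinned at the residual-variance floor is a boundary optimum
    # (noiseless data), not a failure to converge
    converged = bool(res.success) or (ex0 is not None
                                      and ex0["sigma2"] <= 1.0001 * s2_floor)

    # (near-)noiseless data drive every variance RATIO to infinity (the
    # profiled sigma^2 goes to zero); Nelder-Mead crawls along that valley,
    # so walk it directly: scale the whole subject/population covariance
    # up while the criterion keeps improving
    def scaled(th, c):
        out = np.array(th, float)
        out[0] += c
        out[2] += c
        out[1] *= np.exp(c)
        out[3] += 2.0 * c
        out[4] += 2.0 * c
        return out

    moved = False
    for _ in range(40):
        cand = scaled(theta, 1.0)
        cobj = criterion(cand)
        if np.isfinite(cobj) and cobj < obj - tol * (1.0 + abs(obj)):
            theta, obj = cand, cobj
            trace.append(min(best[0], obj))
            best[0] = min(best[0], obj)
            moved = True
        else:
            if moved:
                converged = True   # boundary optimum reached
            break
    if moved:
        res2 = minimize(criterion, theta, method="Nelder-Mead",
                        options=dict(maxiter=300, xatol=1e-6, fatol=tol,
                                     adaptive=True), callback=cb)
        if criterion(res2.x) < obj:
            theta = res2.x

    obj, extras = criterion(theta, want=True)
    if extras is None:
        raise DegenerateDesignError("penalized-spline REML criterion degenerate")
    s2 = float(extras["sigma2"])
    loglik = -0.5 * (obj + (n - p) * (1.0 + _LOG2PI))
    return REMLResult(
        beta=extras["beta"], G=s2 * extras["Gam"], sigma2=s2,
        loglik=float(loglik), trace=trace, converged=converged,
        n_iter=int(res.nit), message=str(res.message),
        u_blup=extras["u_blup"], sigma_u2=float(s2 * extras["rho_u"]))
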