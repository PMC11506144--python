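"""Average-information REML for single-trait and bivariate GBLUP.

Both models have covariance that is a linear combination of the observed
GRM block and the identity, which makes the eigenbasis of the observed
GRM a canonical transformation: with G_oo = U diag(d) U',

* single trait:  V = sigma_a^2 G_oo + sigma_e^2 I  becomes diagonal with
  entries sigma_a^2 d_i + sigma_e^2;
* bivariate:     V = M (x) G_oo + R (x) I  becomes block-diagonal with
  2x2 blocks V_i = d_i M + R.

After one symmetric eigendecomposition every REML quantity (restricted
log-likelihood, analytic gradient, average-information matrix, EM update)
costs O(n) per iteration, which is algebraically identical to dense
AI-REML on the original data.  Fixed effects are one overall mean per
trait.  Accepted iterations never decrease the restricted log-likelihood:
an AI step that leaves the parameter space or lowers the likelihood is
step-halved and finally replaced by an EM step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EigenGRM",
    "ConvergenceLog",
    "reml_single",
    "reml_bivariate",
    "restricted_loglik",
    "pack_bivariate",
    "unpack_bivariate",
    "bend",
]

_LL_TOL = 1e-6  # absolute log-likelihood change at convergence
_MAX_HALVINGS = 30


@dataclass
class EigenGRM:
    """Eigendecomposition of the phenotyped (observed) GRM block."""

    d: np.ndarray  # eigenvalues
    u: np.ndarray  # eigenvectors, columns

    @classmethod
    def from_matrix(cls, g_oo: np.ndarray) -> "EigenGRM":
        d, u = np.linalg.eigh(g_oo)
        if d.min() <= 0:
            raise np.linalg.LinAlgError(
                "observed GRM block is not positive definite; "
                "increase the diagonal stabilization epsilon"
            )
        return cls(d=d, u=u)

    def rotate(self, v: np.ndarray) -> np.ndarray:
        return self.u.T @ v


@dataclass
class ConvergenceLog:
    """Per-iteration REML trace: log-likelihood, parameters, step type."""

    records: list[dict] = field(default_factory=list)
    status: str = "running"

    def append(self, it: int, loglik: float, params: np.ndarray, step: str) -> None:
        self.records.append(
            {"iter": it, "loglik": float(loglik), "params": params.copy(), "step": step}
        )

    @property
    def n_iter(self) -> int:
        return len(self.records)

    @property
    def converged(self) -> bool:
        return self.status == "converged"


def bend(a: np.ndarray, floor_frac: float = 1e-6) -> np.ndarray:
    """Floor the eigenvalues of a symmetric matrix at floor_frac * trace."""
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    floor = floor_frac * max(np.trace(a), np.finfo(float).tiny)
    if w.min() >= floor:
        return a
    w = np.maximum(w, floor)
    return (v * w) @ v.T


# ---------------------------------------------------------------------------
# single trait
# ---------------------------------------------------------------------------


def _single_quantities(theta: np.ndarray, d: np.ndarray, xt: np.ndarray, yt: np.ndarray):
    """Log-likelihood, gradient, AI matrix and rotated Py for one parameter point."""
    sa, se = theta
    v = sa * d + se
    if v.min() <= 0:
        return None
    vi = 1.0 / v
    cxx = float(np.sum(xt * xt * vi))
    cxy = float(np.sum(xt * yt * vi))
    beta = cxy / cxx
    e = yt - beta * xt
    py = e * vi
    quad = float(np.sum(e * py))
    ll = -0.5 * (float(np.sum(np.log(v))) + np.log(cxx) + quad)

    grad = np.empty(2)
    ai = np.empty((2, 2))
    bases = (d, np.ones_like(d))
    pw = []
    for b in bases:
        w = b * py
        xvw = float(np.sum(xt * w * vi))
        pw.append(w * vi - xt * vi * (xvw / cxx))
    for k, bk in enumerate(bases):
        tr_pv = float(np.sum(bk * vi)) - float(np.sum(xt * xt * bk * vi * vi)) / cxx
        ypvpy = float(np.sum(bk * py * py))
        grad[k] = -0.5 * (tr_pv - ypvpy)
        for l in range(2):
            ai[k, l] = 0.5 * float(np.sum(bases[k] * py * pw[l]))
    ai = (ai + ai.T) / 2.0
    return ll, grad, ai, py, beta


def reml_single(
    y: np.ndarray,
    eig: EigenGRM,
    start: tuple[float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, ConvergenceLog, dict]:
    """AI-REML for y = 1*mu + g + e with g ~ N(0, G sigma_a^2).

    Returns the parameter vector (sigma_a^2, sigma_e^2), the iteration
    log, and auxiliary quantities for BLUP (rotated Py, mean, AI matrix).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    yt = eig.rotate(y)
    xt = eig.rotate(np.ones(n))
    vy = float(y.var())
    log = ConvergenceLog()
    if vy <= np.finfo(float).eps * max(1.0, abs(y).max()) ** 2:
        log.status = "degenerate"
        theta = np.array([np.finfo(float).tiny, np.finfo(float).tiny])
        return theta, log, {"py": np.zeros(n), "mu": float(y.mean()), "ai": np.eye(2)}
    floor = 1e-8 * vy
    theta = np.array(start, dtype=float) if start is not None else np.array([0.5 * vy, 0.5 * vy])
    theta = np.maximum(theta, floor)

    q = _single_quantities(theta, eig.d, xt, yt)
    if q is None:
        raise ValueError("starting values outside the parameter space")
    ll, grad, ai, py, beta = q
    log.append(0, ll, theta, "start")

    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(ai, grad)
            step_name = "AI"
        except np.linalg.LinAlgError:
            delta = grad / (np.abs(np.diag(ai)) + 1e-12)
            step_name = "diag"
        accepted = False
        for h in range(_MAX_HALVINGS):
            cand = np.maximum(theta + delta, floor)
            qc = _single_quantities(cand, eig.d, xt, yt)
            if qc is not None and qc[0] >= ll - 1e-10:
                accepted = True
                name = step_name if h == 0 else f"{step_name}/2^{h}"
                break
            delta = delta / 2.0
        if not accepted:
            # EM step: theta_k += theta_k^2 (y'P V_k P y - tr(P V_k)) / n
            em = theta + theta**2 * (2.0 * grad) / n
            cand = np.maximum(em, floor)
            qc = _single_quantities(cand, eig.d, xt, yt)
            name = "EM"
            if qc is None or qc[0] < ll - 1e-10:
                log.status = "stalled"
                break
        dll = qc[0] - ll
        rel = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), floor))
        theta, (ll, grad, ai, py, beta) = cand, qc
        log.append(it, ll, theta, name)
        if rel < tol and abs(dll) < _LL_TOL:
            log.status = "converged"
            break
    else:
        log.status = "max_iter"
    if log.status == "running":
        log.status = "max_iter"
    return theta, log, {"py": py, "mu": beta, "ai": ai}


# ---------------------------------------------------------------------------
# bivariate
# ---------------------------------------------------------------------------

# symmetric 2x2 basis in packing order (11, 12, 22)
_E = (
    np.array([[1.0, 0.0], [0.0, 0.0]]),
    np.array([[0.0, 1.0], [1.0, 0.0]]),
    np.array([[0.0, 0.0], [0.0, 1.0]]),
)


def pack_bivariate(m_cov: np.ndarray, r_cov: np.ndarray) -> np.ndarray:
    """(M, R) -> 6-vector (m11, m12, m22, r11, r12, r22)."""
    return np.array(
        [m_cov[0, 0], m_cov[0, 1], m_cov[1, 1], r_cov[0, 0], r_cov[0, 1], r_cov[1, 1]]
    )


def unpack_bivariate(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m11, m12, m22, r11, r12, r22 = theta
    return np.array([[m11, m12], [m12, m22]]), np.array([[r11, r12], [r12, r22]])


def _bi_quantities(theta: np.ndarray, d: np.ndarray, xt: np.ndarray, yt: np.ndarray):
    """Bivariate analogue of :func:`_single_quantities`.

    yt has shape (n, 2): both traits rotated into the GRM eigenbasis.
    """
    m_cov, r_cov = unpack_bivariate(theta)
    n = d.shape[0]
    v11 = d * m_cov[0, 0] + r_cov[0, 0]
    v12 = d * m_cov[0, 1] + r_cov[0, 1]
    v22 = d * m_cov[1, 1] + r_cov[1, 1]
    det = v11 * v22 - v12 * v12
    if v11.min() <= 0 or det.min() <= 0:
        return None
    i11, i12, i22 = v22 / det, -v12 / det, v11 / det

    x2 = xt * xt
    c = np.array(
        [
            [np.sum(x2 * i11), np.sum(x2 * i12)],
            [np.sum(x2 * i12), np.sum(x2 * i22)],
        ]
    )
    viy = np.stack([i11 * yt[:, 0] + i12 * yt[:, 1], i12 * yt[:, 0] + i22 * yt[:, 1]], axis=1)
    xvy = xt @ viy
    beta = np.linalg.solve(c, xvy)
    e = yt - xt[:, None] * beta
    q = np.stack([i11 * e[:, 0] + i12 * e[:, 1], i12 * e[:, 0] + i22 * e[:, 1]], axis=1)
    quad = float(np.sum(e * q))
    sign, logdet_c = np.linalg.slogdet(c)
    if sign <= 0:
        return None
    ll = -0.5 * (float(np.sum(np.log(det))) + logdet_c + quad)

    cinv = np.linalg.inv(c)
    scale = (d, np.ones(n))  # M params scale by d_i, R params by 1
    grad = np.empty(6)
    w_list = []
    # gradient: -(1/2)(tr(P V_k) - q' B_k q) with B_k = c_i E_k
    for blk in range(2):
        ci = scale[blk]
        # per-index traces of Vinv E_k and Vinv E_k Vinv (2x2 in i11,i12,i22)
        tr_vb = (ci * i11, 2.0 * ci * i12, ci * i22)
        vbv = (
            (ci * i11 * i11, ci * i11 * i12, ci * i12 * i12),
            (2.0 * ci * i11 * i12, ci * (i11 * i22 + i12 * i12), 2.0 * ci * i12 * i22),
            (ci * i12 * i12, ci * i12 * i22, ci * i22 * i22),
        )
        ypv = (
            ci * q[:, 0] * q[:, 0],
            2.0 * ci * q[:, 0] * q[:, 1],
            ci * q[:, 1] * q[:, 1],
        )
        for k in range(3):
            s11, s12, s22 = (np.sum(x2 * t) for t in vbv[k])
            s_mat = np.array([[s11, s12], [s12, s22]])
            tr_pv = float(np.sum(tr_vb[k])) - float(np.trace(cinv @ s_mat))
            grad[3 * blk + k] = -0.5 * (tr_pv - float(np.sum(ypv[k])))
            # w_k = B_k q, needed for the AI matrix
            e_k = _E[k]
            wk = np.stack(
                [
                    ci * (e_k[0, 0] * q[:, 0] + e_k[0, 1] * q[:, 1]),
                    ci * (e_k[1, 0] * q[:, 0] + e_k[1, 1] * q[:, 1]),
                ],
                axis=1,
            )
            w_list.append(wk)

    ai = np.empty((6, 6))
    pw_list = []
    for wk in w_list:
        viw = np.stack(
            [i11 * wk[:, 0] + i12 * wk[:, 1], i12 * wk[:, 0] + i22 * wk[:, 1]], axis=1
        )
        t = xt @ viw
        u = cinv @ t
        corr = np.stack([i11 * u[0] + i12 * u[1], i12 * u[0] + i22 * u[1]], axis=1)
        pw_list.append(viw - xt[:, None] * corr)
    for k in range(6):
        for l in range(k + 1):
            ai[k, l] = ai[l, k] = 0.5 * float(np.sum(w_list[k] * pw_list[l]))
    return ll, grad, ai, q, beta


def _em_bivariate(theta: np.ndarray, d: np.ndarray, xt: np.ndarray, q: np.ndarray, cinv, i_blocks, n):
    """Matrix EM update M += M S_M M / n, R += R S_R R / n.

    S is the per-block sum of q_i q_i' minus the (i,i) block of P; it
    reduces to the scalar EM-REML update in one dimension.
    """
    i11, i12, i22 = i_blocks
    x2 = xt * xt
    m_cov, r_cov = unpack_bivariate(theta)
    out = []
    for blk, cov in ((0, m_cov), (1, r_cov)):
        ci = d if blk == 0 else np.ones_like(d)
        s = np.empty((2, 2))
        # Sum c_i q_i q_i'
        s[0, 0] = np.sum(ci * q[:, 0] * q[:, 0])
        s[0, 1] = s[1, 0] = np.sum(ci * q[:, 0] * q[:, 1])
        s[1, 1] = np.sum(ci * q[:, 1] * q[:, 1])
        # minus Sum c_i P_ii with P_ii = Vinv_i - x_i^2 Vinv_i Cinv Vinv_i
        p11 = np.sum(ci * i11)
        p12 = np.sum(ci * i12)
        p22 = np.sum(ci * i22)
        a11 = np.sum(x2 * ci * (i11 * (cinv[0, 0] * i11 + cinv[0, 1] * i12) + i12 * (cinv[1, 0] * i11 + cinv[1, 1] * i12)))
        a12 = np.sum(x2 * ci * (i11 * (cinv[0, 0] * i12 + cinv[0, 1] * i22) + i12 * (cinv[1, 0] * i12 + cinv[1, 1] * i22)))
        a22 = np.sum(x2 * ci * (i12 * (cinv[0, 0] * i12 + cinv[0, 1] * i22) + i22 * (cinv[1, 0] * i12 + cinv[1, 1] * i22)))
        s[0, 0] -= p11 - a11
        s[0, 1] -= p12 - a12
        s[1, 0] = s[0, 1]
        s[1, 1] -= p22 - a22
        out.append(cov + cov @ s @ cov / n)
    return pack_bivariate(bend(out[0]), bend(out[1]))


def reml_bivariate(
    y: np.ndarray,
    eig: EigenGRM,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, ConvergenceLog, dict]:
    """AI-REML for the stacked two-trait model with V = M (x) G + R (x) I.

    y has shape (n, 2); both traits must be observed on the same
    individuals.  Returns the packed 6-parameter vector, the iteration
    log and auxiliary quantities for BLUP.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must have shape (n, 2)")
    n = y.shape[0]
    yt = eig.u.T @ y
    xt = eig.rotate(np.ones(n))
    log = ConvergenceLog()
    cov_y = np.cov(y.T)
    if min(cov_y[0, 0], cov_y[1, 1]) <= np.finfo(float).eps * max(1.0, np.abs(y).max()) ** 2:
        log.status = "degenerate"
        theta = pack_bivariate(np.eye(2) * np.finfo(float).tiny, np.eye(2) * np.finfo(float).tiny)
        return theta, log, {"py": np.zeros((n, 2)), "mu": y.mean(axis=0), "ai": np.eye(6)}
    if start is None:
        half = bend(0.5 * cov_y)
        theta = pack_bivariate(half, half)
    else:
        theta = np.asarray(start, dtype=float).copy()

    qq = _bi_quantities(theta, eig.d, xt, yt)
    if qq is None:
        raise ValueError("starting values outside the parameter space")
    ll, grad, ai, q, beta = qq
    log.append(0, ll, theta, "start")

    scale = float(np.trace(cov_y))
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(ai + 1e-12 * scale * np.eye(6), grad)
            step_name = "AI"
        except np.linalg.LinAlgError:
            delta = grad / (np.abs(np.diag(ai)) + 1e-12)
            step_name = "diag"
        accepted = False
        for h in range(_MAX_HALVINGS):
            m_c, r_c = unpack_bivariate(theta + delta)
            cand = pack_bivariate(bend(m_c), bend(r_c))
            qc = _bi_quantities(cand, eig.d, xt, yt)
            if qc is not None and qc[0] >= ll - 1e-10:
                accepted = True
                name = step_name if h == 0 else f"{step_name}/2^{h}"
                break
            delta = delta / 2.0
        if not accepted:
            m_cov, r_cov = unpack_bivariate(theta)
            v11 = eig.d * m_cov[0, 0] + r_cov[0, 0]
            v12 = eig.d * m_cov[0, 1] + r_cov[0, 1]
            v22 = eig.d * m_cov[1, 1] + r_cov[1, 1]
            det = v11 * v22 - v12 * v12
            i_blocks = (v22 / det, -v12 / det, v11 / det)
            x2 = xt * xt
            c = np.array(
                [
                    [np.sum(x2 * i_blocks[0]), np.sum(x2 * i_blocks[1])],
                    [np.sum(x2 * i_blocks[1]), np.sum(x2 * i_blocks[2])],
                ]
            )
            cand = _em_bivariate(theta, eig.d, xt, q, np.linalg.inv(c), i_blocks, n)
            qc = _bi_quantities(cand, eig.d, xt, yt)
            name = "EM"
            if qc is None or qc[0] < ll - 1e-10:
                log.status = "stalled"
                break
        dll = qc[0] - ll
        rel = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), 1e-8 * scale))
        theta, (ll, grad, ai, q, beta) = cand, qc
        log.append(it, ll, theta, name)
        if rel < tol and abs(dll) < _LL_TOL:
            log.status = "converged"
            break
    else:
        log.status = "max_iter"
    if log.status == "running":
        log.status = "max_iter"
    return theta, log, {"py": q, "mu": beta, "ai": ai}


# ---------------------------------------------------------------------------
# public restricted log-likelihood (with analytic gradient)
# ---------------------------------------------------------------------------


def restricted_loglik(
    params: np.ndarray, y: np.ndarray, grm_obs: np.ndarray
) -> tuple[float, np.ndarray]:
    """Restricted log-likelihood (up to its constant) and analytic gradient.

    ``params`` is (sigma_a^2, sigma_e^2) when ``y`` is a vector, or the
    packed (m11, m12, m22, r11, r12, r22) when ``y`` has shape (n, 2).
    """
    y = np.asarray(y, dtype=float)
    eig = EigenGRM.from_matrix(np.asarray(grm_obs, dtype=float))
    params = np.asarray(params, dtype=float)
    if y.ndim == 1:
        out = _single_quantities(params, eig.d, eig.rotate(np.ones(y.shape[0])), eig.rotate(y))
    else:
        out = _bi_quantities(params, eig.d, eig.rotate(np.ones(y.shape[0])), eig.u.T @ y)
    if out is None:
        raise ValueError("covariance parameters outside the positive-definite region")
    return out[0], out[1]
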