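"""REML estimation of variance components and genetic correlations.

Fits the longevity mixed model by restricted maximum likelihood on
pedigree relationships (matrix A), with average-information updates by
default and EM steps as a guaranteed-ascent fallback.  The restricted
log-likelihood is always evaluated exactly through the MME factorisation
(log-determinant identity); the trace terms of the score, the AI matrix
and the EM updates use

* exact dense algebra when the equation system is small, and
* seeded Hutchinson (Rademacher-probe) Monte-Carlo estimates with
  batched sparse-LU solves when it is large - the strategy large-scale
  REML programs use.  The probes are drawn once per fit, so the
  estimated score is a smooth deterministic function of the parameters
  and the optimiser converges to within Monte-Carlo precision.

Non-convergence is a first-class outcome: the last iterate, its history
and ``converged=False`` are returned, never a silent estimate.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import ConfigurationError
from .mixed_model import (
    ModelSpec,
    splu_symmetric,
    VarianceComponents,
    assemble_mme,
    build_design_matrices,
    split_solution,
)

log = logging.getLogger(__name__)

VARIANCE_FLOOR_FRACTION = 1e-8


# ---------------------------------------------------------------------------
# parameter vector layout


class _ParamLayout:
    """theta = [vech(G0) row-wise lower triangle, sigma_v2 per slot, sigma_e2 per slot]."""

    def __init__(self, t: int, has_litter: bool):
        self.t = t
        self.has_litter = has_litter
        self.g_pairs = [(i, j) for i in range(t) for j in range(i + 1)]
        self.n_g = len(self.g_pairs)
        self.n_v = t if has_litter else 0
        self.n = self.n_g + self.n_v + t

    @property
    def names(self):
        out = [f"G0[{i},{j}]" for i, j in self.g_pairs]
        if self.has_litter:
            out += [f"sigma_v2[{s}]" for s in range(self.t)]
        out += [f"sigma_e2[{s}]" for s in range(self.t)]
        return out

    def pack(self, G0, sv, se):
        parts = [np.array([G0[i, j] for i, j in self.g_pairs])]
        if self.has_litter:
            parts.append(np.asarray(sv, float))
        parts.append(np.asarray(se, float))
        return np.concatenate(parts)

    def unpack(self, theta):
        G0 = np.zeros((self.t, self.t))
        for k, (i, j) in enumerate(self.g_pairs):
            G0[i, j] = G0[j, i] = theta[k]
        sv = theta[self.n_g : self.n_g + self.n_v] if self.has_litter else None
        se = theta[self.n_g + self.n_v :]
        return G0, sv, se

    def valid(self, theta, floor):
        G0, sv, se = self.unpack(theta)
        if np.any(np.diag(G0) < floor) or np.any(se < floor):
            return False
        if self.has_litter and np.any(sv < floor):
            return False
        return np.linalg.eigvalsh(G0).min() > -1e-12 * max(1.0, np.trace(G0))

    def project(self, theta, floor):
        th = theta.copy()
        th[self.n_g :] = np.maximum(th[self.n_g :], floor)
        G0, sv, se = self.unpack(th)
        np.fill_diagonal(G0, np.maximum(np.diag(G0), floor))
        w, Q = np.linalg.eigh(G0)
        G0 = (Q * np.maximum(w, floor)) @ Q.T
        return self.pack(G0, sv, se)


# ---------------------------------------------------------------------------
# the REML engine


class _RemlProblem:
    def __init__(self, dm, K_inv, layout, rng, n_probes, exact, a_diag=None):
        self.dm = dm
        self.K_inv = sp.csc_matrix(K_inv)
        self.layout = layout
        self.exact = exact
        self.q = len(dm.animal_ids)
        self.t = len(dm.slots)
        self.n = dm.n_records
        parts = [dm.X, dm.Z] + ([dm.V] if dm.V is not None else [])
        self.W = sp.hstack(parts, format="csr")
        self.p = dm.X.shape[1]
        self.m = self.W.shape[1]
        self.lu_A = splu_symmetric(self.K_inv)
        self.logdet_A = -float(np.sum(np.log(np.abs(self.lu_A.U.diagonal()))))
        self.slot_mask = [dm.slot_of_record == s for s in range(self.t)]
        self.n_per_slot = np.array([m.sum() for m in self.slot_mask])
        if dm.V is not None:
            codes = np.array([dm.slots.index(s) for s, _ in dm.litter_index])
            self.v_cols_per_slot = [np.where(codes == s)[0] for s in range(self.t)]
        else:
            self.v_cols_per_slot = None
        # diagonal of A = 1 + F, used in the exact part of the score traces
        if a_diag is not None:
            self.a_diag = np.asarray(a_diag, float)
        elif self.q <= 4000:
            self.a_diag = np.diag(self.lu_A.solve(np.eye(self.q)))
        else:
            Zr = rng.choice([-1.0, 1.0], size=(self.q, 64))
            self.a_diag = np.mean(Zr * self.lu_A.solve(Zr), axis=1)
        if not exact:
            self.probes_rec = rng.choice([-1.0, 1.0], size=(self.n, n_probes))
            self.probes_eq = rng.choice([-1.0, 1.0], size=(self.m, n_probes))

    # -- structure multiplications -------------------------------------
    def _A_mul(self, M):
        return self.lu_A.solve(np.ascontiguousarray(M))

    def g_mul(self, pair, Xn):
        """Z (E_ab kron A) Z' applied to record-space columns Xn (n x k)."""
        a, b = pair
        k = Xn.shape[1]
        Wu = (self.dm.Z.T @ Xn).reshape(self.t, self.q, k)
        out = np.zeros_like(Wu)
        if a == b:
            out[a] = self._A_mul(Wu[a])
        else:
            out[a] = self._A_mul(Wu[b])
            out[b] = self._A_mul(Wu[a])
        return self.dm.Z @ out.reshape(self.t * self.q, k)

    def param_mul(self, idx, Xn):
        """G_i x for parameter idx on record-space columns."""
        lay = self.layout
        if idx < lay.n_g:
            return self.g_mul(lay.g_pairs[idx], Xn)
        if lay.has_litter and idx < lay.n_g + lay.n_v:
            s = idx - lay.n_g
            Vs = self.dm.V[:, self.v_cols_per_slot[s]]
            return Vs @ (Vs.T @ Xn)
        s = idx - lay.n_g - lay.n_v
        return self.slot_mask[s][:, None] * Xn

    def tr_rinv_gi(self, idx, r_inv_slot):
        """Exact tr(R^-1 G_i)."""
        lay = self.layout
        arow = self.dm.Z.indices % self.q  # animal of each record (single entry per row)
        if idx < lay.n_g:
            a, b = lay.g_pairs[idx]
            if a != b:
                return 0.0
            mask = self.slot_mask[a]
            return float(np.sum(self.a_diag[arow[mask]]) * r_inv_slot[a])
        if lay.has_litter and idx < lay.n_g + lay.n_v:
            s = idx - lay.n_g
            return float(self.n_per_slot[s] * r_inv_slot[s])
        s = idx - lay.n_g - lay.n_v
        return float(self.n_per_slot[s] * r_inv_slot[s])


def _loglik(prob, vc, lu, theta_hat, RHS, r_inv):
    dm = prob.dm
    G0, sv, se = vc.G0, vc.sigma_v2, vc.sigma_e2
    sign, logdet_G0 = np.linalg.slogdet(np.atleast_2d(G0))
    if sign <= 0:
        return -np.inf
    logdet_C = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    logdet_G = prob.q * logdet_G0 + prob.t * prob.logdet_A
    if dm.V is not None:
        for s in range(prob.t):
            logdet_G += len(prob.v_cols_per_slot[s]) * np.log(sv[s])
    logdet_R = float(np.sum(prob.n_per_slot * np.log(se)))
    yPy = float(dm.y @ (r_inv * dm.y) - theta_hat @ RHS)
    return -0.5 * (logdet_G + logdet_R + logdet_C + yPy)


def _solve_C(lu, B):
    B = np.asarray(B)
    if B.ndim == 1:
        return lu.solve(B)
    return lu.solve(np.ascontiguousarray(B))


def _ai_matrix(prob, lu, vc, theta_hat, r_inv):
    """Exact average-information matrix: only solves, no trace estimation."""
    dm, lay = prob.dm, prob.layout
    W = prob.W
    Py = r_inv * (dm.y - W @ theta_hat)
    k = lay.n
    wvecs = np.column_stack([prob.param_mul(i, Py[:, None])[:, 0] for i in range(k)])
    # P w = R^-1 (w - W C^-1 W' R^-1 w), batched over parameters
    Rw = r_inv[:, None] * wvecs
    Pw = r_inv[:, None] * (wvecs - W @ _solve_C(lu, W.T @ Rw))
    AI = 0.5 * (wvecs.T @ Pw)
    return 0.5 * (AI + AI.T), wvecs, Py


def _exact_score(prob, lu, vc, theta_hat, r_inv, wvecs, Py):
    """Exact REML score via dense trace algebra (small systems only)."""
    lay = prob.layout
    W = prob.W
    k = lay.n
    r_inv_slot = 1.0 / np.asarray(vc.sigma_e2, float)
    tr1 = np.array([prob.tr_rinv_gi(i, r_inv_slot) for i in range(k)])
    # tr2_i = tr(G_i R^-1 W C^-1 W' R^-1) with dense columns
    S = _solve_C(lu, (W.T @ sp.diags(r_inv)).toarray())  # m x n = C^-1 W' R^-1
    RT = r_inv[:, None] * (W @ S)  # R^-1 W C^-1 W' R^-1
    tr2 = np.array([float(np.trace(prob.param_mul(i, RT))) for i in range(k)])
    quad = wvecs.T @ Py
    return -0.5 * ((tr1 - tr2) - quad)


def _fd_score(layout, theta, base_ll, eval_ll, floor, vp_scale, skip=-1):
    """Forward finite-difference score of the exact restricted log-likelihood.

    The likelihood itself is exact and cheap to evaluate through the MME
    factorisation, so numerical differentiation gives the score without
    any trace estimation on systems too large for dense algebra.  The
    forward-difference bias is O(h) with h = 1e-4 of each parameter,
    well below the convergence tolerance of this path.
    """
    k = layout.n
    score = np.zeros(k)
    for i in range(k):
        if i == skip:
            continue
        h = max(1e-4 * abs(theta[i]), 1e-7 * vp_scale)
        up = theta.copy()
        up[i] += h
        score[i] = (eval_ll(up) - base_ll) / h
    return score


def _score_large(prob, layout, theta, base_ll, eval_ll, floor, vp_scale, quad, rank_x):
    """Large-system score: forward differences plus the tr(P V_y) = n - p identity.

    V_y is linear in the parameters, so sum_i theta_i tr(P G_i) = n - p
    exactly; the trace of the largest variance parameter is recovered
    from the others, saving one likelihood evaluation per iteration.
    """
    imax = int(np.argmax(theta))
    if theta[imax] <= 10 * floor:
        imax = -1
    score = _fd_score(layout, theta, base_ll, eval_ll, floor, vp_scale, skip=imax)
    if imax >= 0:
        traces = quad - 2.0 * score  # tr(P G_i) for the FD-computed components
        others = [i for i in range(layout.n) if i != imax]
        tr_imax = (prob.n - rank_x - float(theta[others] @ traces[others])) / theta[imax]
        score[imax] = -0.5 * (tr_imax - quad[imax])
    return score


def _em_update(prob, lu, vc, theta_hat):
    """One EM step; exact traces on the dense path, probe traces otherwise."""
    dm, lay = prob.dm, prob.layout
    b, u, v = split_solution(theta_hat, dm)
    U = u.to_numpy().T  # t x q
    Ainv = prob.K_inv
    UAU = np.zeros((prob.t, prob.t))
    for i in range(prob.t):
        for j in range(i + 1):
            UAU[i, j] = UAU[j, i] = float(U[i] @ (Ainv @ U[j]))

    if prob.exact:
        Cinv = _dense_C(lu, prob.m)
        p, q, t = prob.p, prob.q, prob.t
        Tu = np.zeros((t, t))
        for i in range(t):
            for j in range(i + 1):
                blk = Cinv[p + i * q : p + (i + 1) * q, p + j * q : p + (j + 1) * q]
                Tu[i, j] = Tu[j, i] = float(np.sum(Ainv.multiply(blk)))
        tv = te = None
        if dm.V is not None:
            off = p + t * q
            tv = np.array(
                [
                    float(np.trace(Cinv[off:, off:][np.ix_(c, c)]))
                    for c in prob.v_cols_per_slot
                ]
            )
        WC = prob.W @ Cinv
        diag_WCW = np.sum(np.asarray(WC) * prob.W.toarray(), axis=1)
        te = np.array([float(diag_WCW[m].sum()) for m in prob.slot_mask])
    else:
        Zm = prob.probes_eq
        S2 = _solve_C(lu, Zm)
        p, q, t = prob.p, prob.q, prob.t
        Tu = np.zeros((t, t))
        for i in range(t):
            for j in range(i + 1):
                zi = Zm[p + j * q : p + (j + 1) * q]  # u_j block of probes
                si = S2[p + i * q : p + (i + 1) * q]  # u_i block of solves
                Tu[i, j] = Tu[j, i] = float(np.mean(np.sum(zi * (Ainv @ si), axis=0)))
        tv = None
        if dm.V is not None:
            off = p + t * q
            tv = np.array(
                [
                    float(np.mean(np.sum(Zm[off:][c] * S2[off:][c], axis=0)))
                    for c in prob.v_cols_per_slot
                ]
            )
        Pm = prob.probes_rec
        T1 = prob.W @ _solve_C(lu, prob.W.T @ Pm)
        te = np.array(
            [float(np.mean(np.sum(Pm[m] * T1[m], axis=0))) for m in prob.slot_mask]
        )

    G0_new = (UAU + Tu) / prob.q
    sv_new = None
    if dm.V is not None:
        vv = v.to_numpy()
        sv_new = np.array(
            [
                (float(np.sum(vv[c] ** 2)) + tv[s]) / max(len(c), 1)
                for s, c in enumerate(prob.v_cols_per_slot)
            ]
        )
    resid = dm.y - prob.W @ theta_hat
    se_new = np.array(
        [
            (float(np.sum(resid[m] ** 2)) + te[s]) / prob.n_per_slot[s]
            for s, m in enumerate(prob.slot_mask)
        ]
    )
    return prob.layout.pack(G0_new, sv_new, se_new)


def _dense_C(lu, m):
    return lu.solve(np.eye(m))


def estimate_reml(
    table: pd.DataFrame,
    spec: ModelSpec,
    A_inverse,
    method: str = "ai",
    tol: float | None = None,
    ll_tol: float | None = None,
    max_iter: int | None = None,
    start: VarianceComponents | None = None,
    n_probes: int = 32,
    exact_limit: int = 3000,
    seed: int = 0,
    a_diag=None,
) -> VarianceComponents:
    """Estimate G0, litter and residual variances by AI- or EM-REML.

    The A-based model only is supported here (the evaluation uses A for
    variance components and H for breeding values).  Returns a
    VarianceComponents whose ``converged`` flag and ``history`` surface
    non-convergence instead of masking it.
    """
    if method not in ("ai", "em"):
        raise ConfigurationError(f"unknown REML method {method!r}")
    dm = build_design_matrices(table, spec, A_inverse.ids)
    t = len(dm.slots)
    layout = _ParamLayout(t, dm.V is not None)
    m_eq = dm.X.shape[1] + t * len(dm.animal_ids) + (dm.V.shape[1] if dm.V is not None else 0)
    exact = m_eq <= exact_limit and dm.n_records <= max(exact_limit, 3000)
    rng = np.random.default_rng(seed)
    prob = _RemlProblem(dm, A_inverse.values, layout, rng, n_probes, exact, a_diag=a_diag)

    if tol is None:
        tol = 1e-8 if exact else 1e-4
    if ll_tol is None:
        ll_tol = 1e-6 if exact else 1e-4
    if max_iter is None:
        max_iter = 500 if method == "em" else (100 if exact else 40)

    vp = np.array([np.var(dm.y[msk]) if msk.any() else 1.0 for msk in prob.slot_mask])
    vp = np.where(vp > 0, vp, 1.0)
    floor = VARIANCE_FLOOR_FRACTION * float(vp.mean())
    if start is None:
        G0 = np.diag(vp / 3.0)
        sv = vp / 3.0 if dm.V is not None else None
        se = vp / 3.0 if dm.V is not None else vp / 2.0
        if dm.V is None:
            G0 = np.diag(vp / 2.0)
        theta = layout.pack(G0, sv, se)
    else:
        theta = layout.pack(
            np.atleast_2d(start.G0), start.sigma_v2, np.asarray(start.sigma_e2, float)
        )

    history = []
    converged = False
    last_ll = -np.inf
    n_iter = 0
    n_warmup = 3 if method == "ai" else 0  # EM warm-up steps before AI, standard practice
    max_factor = 5.0  # no variance may change by more than this factor per AI step

    def make_vc(th):
        G0, sv, se = layout.unpack(th)
        return VarianceComponents(
            slots=dm.slots, G0=G0, sigma_v2=sv, sigma_e2=np.asarray(se, float)
        )

    def eval_point(th):
        vc = make_vc(th)
        try:
            LHS, RHS = assemble_mme(dm, vc, prob.K_inv)
            lu = splu_symmetric(LHS)
            theta_hat = lu.solve(RHS)
        except (RuntimeError, np.linalg.LinAlgError):
            # numerically singular point (e.g. G0 on the PSD boundary)
            return vc, None, None, None, -np.inf
        r_inv = 1.0 / np.asarray(vc.sigma_e2, float)[dm.slot_of_record]
        ll = _loglik(prob, vc, lu, theta_hat, RHS, r_inv)
        return vc, lu, theta_hat, r_inv, ll

    def capped(th_old, th_new):
        # variances restricted to [1/max_factor, max_factor] x previous value
        out = th_new.copy()
        var_idx = [k for k, (i, j) in enumerate(layout.g_pairs) if i == j]
        var_idx += list(range(layout.n_g, layout.n))
        for k in var_idx:
            out[k] = float(np.clip(out[k], th_old[k] / max_factor, th_old[k] * max_factor))
        return out

    def ll_only(th):
        return eval_point(th)[4]

    vc, lu, theta_hat, r_inv, ll = eval_point(theta)
    for n_iter in range(1, max_iter + 1):
        step_kind = "em" if (method == "em" or n_iter <= n_warmup) else "ai"
        if step_kind == "ai":
            AI, wvecs, Py = _ai_matrix(prob, lu, vc, theta_hat, r_inv)
            if prob.exact:
                score = _exact_score(prob, lu, vc, theta_hat, r_inv, wvecs, Py)
            else:
                score = _score_large(
                    prob, layout, theta, ll, ll_only, floor, float(vp.mean()),
                    quad=wvecs.T @ Py, rank_x=dm.X.shape[1],
                )
            try:
                delta = np.linalg.solve(AI + 1e-12 * np.eye(layout.n) * np.trace(AI), score)
            except np.linalg.LinAlgError:
                delta = None
            new = None
            if delta is not None and np.all(np.isfinite(delta)):
                for _ in range(12):
                    cand = capped(theta, theta + delta)
                    if layout.valid(cand, floor):
                        new = cand
                        break
                    delta *= 0.5
            if new is None:
                step_kind = "em-fallback"
                if prob.exact:
                    new = layout.project(_em_update(prob, lu, vc, theta_hat), floor)
                else:  # preconditioned gradient step, ascent-guarded below
                    delta = score / np.maximum(np.abs(np.diag(AI)), 1e-12)
                    new = layout.project(capped(theta, theta + delta), floor)
        else:
            new = layout.project(_em_update(prob, lu, vc, theta_hat), floor)

        new_vc, new_lu, new_theta_hat, new_r_inv, new_ll = eval_point(new)
        if step_kind in ("ai", "em-fallback"):
            # guard the ascent: halve the AI step while the likelihood drops
            halvings = 0
            while new_ll < ll - 1e-8 and halvings < 6:
                new = capped(theta, theta + (new - theta) / 2.0)
                new = layout.project(new, floor)
                new_vc, new_lu, new_theta_hat, new_r_inv, new_ll = eval_point(new)
                halvings += 1
            if new_ll < ll - 1e-8:
                step_kind = "em-fallback"
                new = layout.project(_em_update(prob, lu, vc, theta_hat), floor)
                new_vc, new_lu, new_theta_hat, new_r_inv, new_ll = eval_point(new)

        history.append(
            {"iteration": n_iter, "loglik": float(ll), "theta": theta.copy(), "step": step_kind}
        )
        if not np.isfinite(new_ll):
            log.warning("REML step led to a singular system; stopping at the last iterate")
            break
        rel = float(np.max(np.abs(new - theta) / np.maximum(np.abs(theta), 1e-3 * vp.mean())))
        dll = abs(new_ll - ll)
        theta = new
        vc, lu, theta_hat, r_inv, ll = new_vc, new_lu, new_theta_hat, new_r_inv, new_ll
        last_ll = ll
        if rel < tol and dll < ll_tol:
            converged = True
            break

    vc = make_vc(layout.project(theta, floor))
    # final likelihood and SEs at the solution
    LHS, RHS = assemble_mme(dm, vc, prob.K_inv)
    lu = splu_symmetric(LHS)
    theta_hat = lu.solve(RHS)
    r_inv = 1.0 / np.asarray(vc.sigma_e2, float)[dm.slot_of_record]
    ll = _loglik(prob, vc, lu, theta_hat, RHS, r_inv)
    try:
        AI, _, _ = _ai_matrix(prob, lu, vc, theta_hat, r_inv)
        param_cov = np.linalg.pinv(AI)
        se = {"param_names": layout.names, "se": np.sqrt(np.clip(np.diag(param_cov), 0, None))}
    except Exception:  # pragma: no cover - SEs are best-effort
        param_cov, se = None, None
    if not converged:
        log.warning("REML did not converge in %d iterations (method=%s)", n_iter, method)
    return replace(
        vc,
        se=se,
        param_cov=param_cov,
        converged=converged,
        n_iterations=n_iter,
        loglik=float(ll),
        history=history,
    )


# ---------------------------------------------------------------------------
# derived genetic parameters


def adjusted_h2(sigma_g2: float, sigma_v2: float, sigma_e2: float, n: float) -> float:
    """Heritability of the mean of n repeated records:
    h_n^2 = sigma_g^2 / (sigma_e^2 / n + sigma_g^2 + sigma_v^2)."""
    if n < 1:
        raise ConfigurationError("average number of parities n must be >= 1")
    return sigma_g2 / (sigma_e2 / n + sigma_g2 + sigma_v2)


def feasible_litter_variance(h2: float, n: float, target_hn2: float) -> float:
    """Invert the adjusted-heritability formula for sigma_v^2 on a unit
    phenotypic scale (sigma_e^2 = 1 - h2 - sigma_v^2)."""
    if n <= 1:
        raise ConfigurationError("inversion requires n > 1")
    return (h2 / target_hn2 - h2 - (1.0 - h2) / n) / (1.0 - 1.0 / n)


def _theta_gradient_se(vc: VarianceComponents, grad_fn):
    """Delta-method SE for a scalar function of theta; None without param_cov."""
    if vc.param_cov is None or vc.se is None:
        return None
    layout = _ParamLayout(len(vc.slots), vc.sigma_v2 is not None)
    g = grad_fn(layout)
    return float(np.sqrt(max(g @ vc.param_cov @ g, 0.0)))


def heritability(vc: VarianceComponents, slot: int = 0):
    """Per-record heritability h2 = sigma_g2 / (sigma_g2 + sigma_v2 + sigma_e2)."""
    g = float(np.atleast_2d(vc.G0)[slot, slot])
    v = float(vc.sigma_v2[slot]) if vc.sigma_v2 is not None else 0.0
    e = float(vc.sigma_e2[slot])
    total = g + v + e
    h2 = g / total

    def grad(layout):
        gvec = np.zeros(layout.n)
        gi = layout.g_pairs.index((slot, slot))
        gvec[gi] = (total - g) / total**2
        if layout.has_litter:
            gvec[layout.n_g + slot] = -g / total**2
        gvec[layout.n_g + layout.n_v + slot] = -g / total**2
        return gvec

    return {"h2": h2, "h2_se": _theta_gradient_se(vc, grad)}


def adjusted_heritability(vc: VarianceComponents, n: float, slot: int = 0):
    """Adjusted heritability of the mean of n survival records."""
    g = float(np.atleast_2d(vc.G0)[slot, slot])
    v = float(vc.sigma_v2[slot]) if vc.sigma_v2 is not None else 0.0
    e = float(vc.sigma_e2[slot])
    rep = heritability(vc, slot)
    rep.update({"h_n2": adjusted_h2(g, v, e, n), "n": n})
    return rep


def genetic_correlation(vc: VarianceComponents):
    """Genetic correlation matrix over trait slots with delta-method SEs."""
    G0 = np.atleast_2d(vc.G0)
    sd = np.sqrt(np.diag(G0))
    corr = G0 / np.outer(sd, sd)
    t = len(sd)
    se = np.full((t, t), np.nan)
    for i in range(t):
        for j in range(i):
            r = corr[i, j]

            def grad(layout, i=i, j=j, r=r):
                gvec = np.zeros(layout.n)
                gvec[layout.g_pairs.index((i, j))] = 1.0 / (sd[i] * sd[j])
                gvec[layout.g_pairs.index((i, i))] = -r / (2 * G0[i, i])
                gvec[layout.g_pairs.index((j, j))] = -r / (2 * G0[j, j])
                return gvec

            s = _theta_gradient_se(vc, grad)
            se[i, j] = se[j, i] = np.nan if s is None else s
    slots = list(vc.slots)
    return (
        pd.DataFrame(corr, index=slots, columns=slots),
        pd.DataFrame(se, index=slots, columns=slots),
    )
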