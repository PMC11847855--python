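"""Genomic relationship matrices, GBLUP solving and REML estimation.

Additive relationships use VanRaden's first method generalized to even
ploidy: ``Gu = W W' / (ploidy * sum_j p_j (1 - p_j))`` with ``W`` the
counted-allele dosages centered by ``ploidy * p``. Dominance relationships
use Vitezica's heterosis coding for diploids and a digenic-dominance
covariate centered by its Hardy-Weinberg expectation for tetraploids.
Epistatic relationship matrices are Hadamard products of the additive and
dominance matrices.

The mixed model is ``y = X b + sum_k Z u_k + e`` with generation as the only
fixed effect and ``u_k ~ N(0, G_k sigma_k^2)``. Solving goes through the
generalized-least-squares form (equivalent to Henderson's mixed-model
equations) or, when every relationship matrix carries a low-rank marker
factor, through the exactly equivalent marker-effect (ridge) system, which is
much faster at large n. Variance components come from average-information
REML with likelihood-monotone EM fallback steps, or from a profiled spectral
likelihood when there is a single factored genetic component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "GRM",
    "MixedModelFit",
    "additive_grm",
    "dominance_grm",
    "epistatic_grms",
    "solve_gblup",
    "reml_estimate",
]


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------


@dataclass
class GRM:
    """A genomic relationship matrix, optionally with a low-rank factor.

    When ``factor`` is present, ``matrix = factor @ factor.T`` exactly, which
    enables the marker-space solving and REML paths.
    """

    matrix: np.ndarray
    factor: np.ndarray | None = None
    kind: str = ""

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _marker_freqs(dosage: np.ndarray, ploidy: int, freqs) -> np.ndarray:
    if freqs is None:
        return dosage.mean(axis=0) / ploidy
    return np.asarray(freqs, dtype=float)


def additive_grm(marker_dosage: np.ndarray, ploidy: int, freqs=None) -> GRM:
    """VanRaden additive GRM at any even ploidy.

    ``marker_dosage`` holds counted-allele dosages in ``0..ploidy``. Markers
    fixed at the supplied/observed frequency (p in {0, 1}) are excluded with
    a warning.
    """
    dosage = np.asarray(marker_dosage, dtype=float)
    p = _marker_freqs(dosage, ploidy, freqs)
    keep = (p > 0.0) & (p < 1.0)
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} fixed marker(s) from the additive GRM")
        dosage, p = dosage[:, keep], p[keep]
    if dosage.shape[1] == 0:
        raise ValueError("no polymorphic markers left for the additive GRM")
    w = dosage - ploidy * p
    denom = ploidy * float((p * (1.0 - p)).sum())
    factor = w / np.sqrt(denom)
    return GRM(matrix=factor @ factor.T, factor=factor, kind="additive")


def _tetraploid_dominance_coding(dosage: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Digenic-dominance covariate t*(4-t) centered by its HWE expectation.

    Returns the centered coding and the per-marker HWE variance used for
    normalization (exact moments of t ~ Binomial(4, p)).
    """
    t_vals = np.arange(5)
    raw_vals = t_vals * (4 - t_vals)  # heteroallelic pair count
    q = 1.0 - p
    # pmf over t = 0..4 per marker, shape (5, m)
    pmf = np.array([comb(4, t) for t in t_vals])[:, None] * p[None, :] ** t_vals[:, None] * q[None, :] ** (
        4 - t_vals[:, None]
    )
    e1 = (pmf * raw_vals[:, None]).sum(axis=0)
    e2 = (pmf * (raw_vals**2)[:, None]).sum(axis=0)
    var = e2 - e1**2
    coding = dosage * (4.0 - dosage) - e1
    return coding, var


def dominance_grm(marker_dosage: np.ndarray, ploidy: int, freqs=None) -> GRM:
    """Dominance GRM: Vitezica coding (diploids) or centered digenic coding
    (tetraploids), normalized to unit expected diagonal under HWE.

    Degenerate markers (fixed frequency, or a genotype column with no
    variation) are excluded with a warning.
    """
    if ploidy not in (2, 4):
        raise ValueError(f"dominance GRM supports ploidy 2 or 4, got {ploidy}")
    dosage = np.asarray(marker_dosage, dtype=float)
    p = _marker_freqs(dosage, ploidy, freqs)
    keep = (p > 0.0) & (p < 1.0) & (dosage.var(axis=0) > 0.0)
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} degenerate marker(s) from the dominance GRM")
        dosage, p = dosage[:, keep], p[keep]
    if dosage.shape[1] == 0:
        raise ValueError("no usable markers left for the dominance GRM")
    q = 1.0 - p
    if ploidy == 2:
        # heterosis coding: t=0 -> -2p^2, t=1 -> 2pq, t=2 -> -2q^2
        coding = np.where(dosage == 1.0, 2.0 * p * q, np.where(dosage == 0.0, -2.0 * p**2, -2.0 * q**2))
        norm = ((2.0 * p * q) ** 2).sum()
    else:
        coding, var = _tetraploid_dominance_coding(dosage, p)
        norm = var.sum()
    factor = coding / np.sqrt(norm)
    return GRM(matrix=factor @ factor.T, factor=factor, kind="dominance")


def epistatic_grms(gu: GRM, gv: GRM) -> tuple[GRM, GRM, GRM]:
    """Hadamard-product epistatic GRMs (Guu, Guv, Gvv)."""
    if gu.matrix.shape != gv.matrix.shape:
        raise ValueError("Gu and Gv must have the same shape")
    return (
        GRM(gu.matrix * gu.matrix, kind="aa"),
        GRM(gu.matrix * gv.matrix, kind="ad"),
        GRM(gv.matrix * gv.matrix, kind="dd"),
    )


# ---------------------------------------------------------------------------
# Mixed-model machinery
# ---------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    """Fixed-effect and BLUP solutions plus variance components."""

    b: np.ndarray
    fixed_levels: np.ndarray
    solutions: dict[str, np.ndarray]
    variances: dict[str, float]
    sigma_e2: float
    converged: bool = True
    n_iter: int = 0
    loglik: float | None = None
    boundary: bool = False
    method: str = ""
    log: list = field(default_factory=list)

    @property
    def ebv(self) -> np.ndarray:
        """Additive BLUP (the 'u' component) — the selection criterion."""
        return self.solutions["u"]


def _design(generation_labels: np.ndarray, phen: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(generation_labels)
    levels = np.unique(labels[phen])
    x = (labels[phen, None] == levels[None, :]).astype(float)
    return x, levels


def solve_gblup(
    y: np.ndarray,
    generation_labels: np.ndarray,
    grms: dict[str, GRM],
    variances: dict[str, float],
    sigma_e2: float,
    ridge: float = 1e-6,
) -> MixedModelFit:
    """BLUP solutions for the specified random terms at fixed variances.

    ``y`` may contain NaN for genotyped-but-unphenotyped individuals; they
    receive BLUPs through the relationship matrices. If every GRM carries a
    marker factor the (exactly equivalent) marker-space system is solved;
    otherwise the dense GLS form with ridge-stabilized G matrices is used.
    """
    y = np.asarray(y, dtype=float)
    phen = np.isfinite(y)
    if not phen.any():
        raise ValueError("no phenotyped individuals")
    for name, var in variances.items():
        if var < 0:
            raise ValueError(f"variance of {name!r} must be >= 0")
    x, levels = _design(generation_labels, phen)
    yp = y[phen]
    n_all = len(y)

    active = {k: g for k, g in grms.items() if variances.get(k, 0.0) > 0.0}
    solutions = {k: np.zeros(n_all) for k in grms}

    use_factor = active and all(g.factor is not None for g in active.values()) and ridge == 0.0
    if active and all(g.factor is not None for g in active.values()):
        total_cols = sum(g.factor.shape[1] for g in active.values())
        use_factor = total_cols + x.shape[1] < phen.sum()
    if use_factor:
        names = list(active)
        fs = [active[k].factor for k in names]
        fp = np.hstack([f[phen] for f in fs])
        blk = np.hstack([x, fp])
        c = blk.T @ blk
        lam = np.concatenate(
            [np.zeros(x.shape[1])] + [np.full(f.shape[1], sigma_e2 / variances[k]) for k, f in zip(names, fs)]
        )
        c[np.diag_indices_from(c)] += lam
        rhs = blk.T @ yp
        sol = linalg.solve(c, rhs, assume_a="pos")
        b = sol[: x.shape[1]]
        off = x.shape[1]
        for k, f in zip(names, fs):
            r = f.shape[1]
            solutions[k] = f @ sol[off : off + r]
            off += r
        method = "marker"
    else:
        v = sigma_e2 * np.eye(int(phen.sum()))
        stabilized = {}
        for k, g in active.items():
            gm = g.matrix + ridge * np.eye(n_all)
            stabilized[k] = gm
            v += variances[k] * gm[np.ix_(phen, phen)]
        cho = linalg.cho_factor(v, lower=True)
        vix = linalg.cho_solve(cho, x)
        viy = linalg.cho_solve(cho, yp)
        b = linalg.solve(x.T @ vix, x.T @ viy, assume_a="pos")
        py = viy - vix @ b
        for k, gm in stabilized.items():
            solutions[k] = variances[k] * (gm[:, phen] @ py)
        method = "dense"

    return MixedModelFit(
        b=b,
        fixed_levels=levels,
        solutions=solutions,
        variances=dict(variances),
        sigma_e2=float(sigma_e2),
        method=method,
    )


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def _spectral_reml(y, x, factor, max_iter, tol):
    """Profiled REML for y = Xb + u + e with G = F F' (single component).

    The likelihood is profiled down to the variance ratio gamma =
    sigma_u2/sigma_e2 using the SVD of F; the 1-D profile is maximized with
    bounded scalar optimization on log(gamma).
    """
    n, p = x.shape
    u_mat, s, _ = linalg.svd(factor, full_matrices=False)
    lam = s**2
    uy, ux = u_mat.T @ y, u_mat.T @ x
    yy, xy, xx = y @ y, x.T @ y, x.T @ x
    log: list = []

    def neg_profile(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        w = 1.0 + gamma * lam  # eigenvalues of M = I + gamma F F'
        d = 1.0 / w - 1.0
        c = xx + (ux * d[:, None]).T @ ux  # X' M^-1 X
        cy = xy + (ux * d[:, None]).T @ uy
        sign, logdet_c = np.linalg.slogdet(c)
        b = linalg.solve(c, cy, assume_a="pos")
        ypy = yy + uy @ (d * uy) - cy @ b
        sigma_e2 = ypy / (n - p)
        nll = 0.5 * (np.log(w).sum() + logdet_c + (n - p) * np.log(sigma_e2) + (n - p))
        log.append({"log_gamma": float(log_gamma), "neg_loglik": float(nll)})
        return nll

    lo, hi = -15.0, 15.0
    res = optimize.minimize_scalar(
        neg_profile, bounds=(lo, hi), method="bounded", options={"xatol": tol, "maxiter": max_iter}
    )
    gamma = float(np.exp(res.x))
    w = 1.0 + gamma * lam
    d = 1.0 / w - 1.0
    c = xx + (ux * d[:, None]).T @ ux
    cy = xy + (ux * d[:, None]).T @ uy
    b = linalg.solve(c, cy, assume_a="pos")
    ypy = yy + uy @ (d * uy) - cy @ b
    sigma_e2 = float(ypy / (n - p))
    sigma_u2 = gamma * sigma_e2
    boundary = res.x <= lo + 1e-3 or res.x >= hi - 1e-3
    return sigma_u2, sigma_e2, -res.fun, bool(res.success), boundary, log


def reml_estimate(
    y: np.ndarray,
    generation_labels: np.ndarray,
    grms: dict[str, GRM],
    init_variances: dict[str, float] | None = None,
    sigma_e2_init: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    method: str = "auto",
    ridge: float = 1e-6,
) -> MixedModelFit:
    """REML variance components, then BLUPs at the estimates.

    ``method='spectral'`` (automatic for a single factored component) uses the
    profiled spectral likelihood; ``method='ai'`` runs average-information
    REML where a proposed AI step is taken only if it keeps all components
    above the variance floor and does not decrease the restricted likelihood,
    and an EM step (monotone in the likelihood) is substituted otherwise.
    Boundary estimates are clamped at a small positive floor and flagged;
    non-convergence is reported, never hidden.
    """
    y = np.asarray(y, dtype=float)
    phen = np.isfinite(y)
    x, _levels = _design(generation_labels, phen)
    yp = y[phen]
    n, p = x.shape
    if n < p + len(grms) + 1:
        raise ValueError("not enough records to estimate the requested variance components")

    if method == "auto":
        method = "spectral" if len(grms) == 1 and next(iter(grms.values())).factor is not None else "ai"

    if method == "spectral":
        (name,) = grms
        factor = grms[name].factor[phen]
        su2, se2, ll, ok, boundary, log = _spectral_reml(yp, x, factor, max_iter, tol)
        fit = solve_gblup(y, generation_labels, grms, {name: su2}, se2)
        fit.loglik, fit.converged, fit.boundary = ll, ok, boundary
        fit.n_iter, fit.method, fit.log = len(log), "spectral", log
        return fit

    # ----- dense AI-REML with EM fallback -----
    names = list(grms)
    g_list = [grms[k].matrix[np.ix_(phen, phen)] + ridge * np.eye(n) for k in names]
    vary = float(yp.var())
    floor = 1e-8 * vary
    k_g = len(names)
    theta = np.empty(k_g + 1)
    if init_variances is None:
        theta[:k_g] = vary / (2 * k_g)
    else:
        theta[:k_g] = [max(init_variances.get(k, vary / (2 * k_g)), floor) for k in names]
    theta[k_g] = sigma_e2_init if sigma_e2_init is not None else vary / 2

    def loglik_at(th: np.ndarray):
        v = th[k_g] * np.eye(n)
        for t, g in zip(th[:k_g], g_list):
            v += t * g
        cho = linalg.cho_factor(v, lower=True)
        logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
        vix = linalg.cho_solve(cho, x)
        viy = linalg.cho_solve(cho, yp)
        c = x.T @ vix
        sign, logdet_c = np.linalg.slogdet(c)
        b = linalg.solve(c, x.T @ viy, assume_a="pos")
        py = viy - vix @ b
        ll = -0.5 * (logdet_v + logdet_c + yp @ py)
        return ll, cho, vix, py, c

    ll, cho, vix, py, c = loglik_at(theta)
    log: list = [{"iter": 0, "loglik": float(ll), "variances": theta.copy(), "step": "init"}]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # P-based quantities; note y'P G P y = (Py)' G (Py) needs no full P @ G
        vi = linalg.cho_solve(cho, np.eye(n))
        pmat = vi - vix @ linalg.solve(c, vix.T, assume_a="pos")
        gpy = [g @ py for g in g_list] + [py]
        tr_pg = [float(np.einsum("ij,ji->", pmat, g)) for g in g_list] + [float(np.trace(pmat))]
        score = np.array([-0.5 * (tr_pg[i] - py @ gpy[i]) for i in range(k_g + 1)])
        ai = np.empty((k_g + 1, k_g + 1))
        pgpy = [pmat @ v for v in gpy]
        for i in range(k_g + 1):
            for j in range(i, k_g + 1):
                ai[i, j] = ai[j, i] = 0.5 * (gpy[i] @ pgpy[j])

        step = "ai"
        try:
            delta = linalg.solve(ai, score, assume_a="pos")
            proposal = theta + delta
        except linalg.LinAlgError:
            proposal = None
        accepted = False
        if proposal is not None and np.all(proposal > floor):
            ll_new, cho_new, vix_new, py_new, c_new = loglik_at(proposal)
            if ll_new >= ll - 1e-10:
                accepted = True
        if not accepted:
            # EM step: monotone in the restricted likelihood
            step = "em"
            proposal = theta + theta**2 * np.array(
                [(py @ gpy[i] - tr_pg[i]) / n for i in range(k_g + 1)]
            )
            proposal = np.maximum(proposal, floor)
            ll_new, cho_new, vix_new, py_new, c_new = loglik_at(proposal)

        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        theta, ll, cho, vix, py, c = proposal, ll_new, cho_new, vix_new, py_new, c_new
        log.append({"iter": it, "loglik": float(ll), "variances": theta.copy(), "step": step})
        if rel < tol:
            converged = True
            break

    boundary = bool(np.any(theta[: k_g + 1] <= floor * (1 + 1e-6)))
    variances = {k: float(t) for k, t in zip(names, theta[:k_g])}
    fit = solve_gblup(y, generation_labels, grms, variances, float(theta[k_g]), ridge=ridge)
    fit.loglik, fit.converged, fit.boundary = float(ll), converged, boundary
    fit.n_iter, fit.method, fit.log = it, "ai", log
    return fit
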