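"""Animal-model mixed-model equations and AI-REML variance components.

The single- and two-trait animal models are

    y = Xb + Wu + e,   u ~ N(0, H sigma_u2),   e ~ N(0, I sigma_e2)

(two-trait: u ~ MVN(0, T kron H), e ~ MVN(0, R kron I)), with year-of-birth
classes and an optional age-at-slaughter covariate as fixed effects, and —
for the conditional genome scan — the phenotypes of every non-target trait
as additional covariates.

Because each animal contributes at most one record per trait, the phenotyped
block of H can be eigendecomposed once and every REML iteration runs in the
rotated basis where all covariance derivatives are diagonal (single trait)
or 2x2 block diagonal (two traits with a shared record set).  This makes the
restricted likelihood, its gradient and the average-information matrix exact
and cheap.  Bivariate models whose two traits are recorded on different
animal sets fall back to a dense AI-REML path.

Standard errors come from the inverse average-information matrix at
convergence, with the delta method for heritability and correlations; they
are approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .types import (
    ModelDesign,
    MMESolution,
    NO_AGE_TRAITS,
    RelationshipMatrix,
    TRAIT_NAMES,
    VarComp,
)

__all__ = [
    "build_design",
    "solve_mme",
    "aireml_single",
    "aireml_bivariate",
    "varcomp_table",
]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    traits: pd.DataFrame,
    target: str,
    conditional: bool = False,
    trait_names: list[str] | None = None,
    use_age: bool | None = None,
    year_col: str = "birth_year",
    age_col: str = "age_at_slaughter",
    id_col: str = "animal_id",
) -> ModelDesign:
    """Build the fixed-effect design for one trait.

    Fixed effects are year-of-birth classes (one dummy per level, no
    intercept) plus the centered age covariate — omitted for TEND and FLAV,
    where age at slaughter is not a significant effect, unless ``use_age``
    overrides.  With ``conditional=True`` the phenotypes of every other
    trait enter as centered covariates and only complete cases are kept.
    """
    if trait_names is None:
        trait_names = [t for t in TRAIT_NAMES if t in traits.columns]
    if target not in traits.columns:
        raise KeyError(f"unknown trait {target!r}")
    if use_age is None:
        use_age = target not in NO_AGE_TRAITS
    use_age = use_age and age_col in traits.columns

    covar_cols: list[str] = [age_col] if use_age else []
    if conditional:
        covar_cols += [t for t in trait_names if t != target and t in traits.columns]

    needed = [target, year_col] + covar_cols
    keep = traits[needed].notna().all(axis=1)
    sub = traits.loc[keep]
    if len(sub) == 0:
        raise ValueError(f"no usable records for trait {target!r}")
    if sub[id_col].duplicated().any():
        raise ValueError("repeated records per animal are not supported")

    year_dummies = pd.get_dummies(sub[year_col].astype(int), prefix="year", dtype=float)
    blocks = [year_dummies.to_numpy()]
    names = list(year_dummies.columns)
    for c in covar_cols:
        x = sub[c].to_numpy(dtype=float)
        blocks.append((x - x.mean())[:, None])
        names.append(c)
    X = np.hstack(blocks)
    return ModelDesign(
        trait=target,
        y=sub[target].to_numpy(dtype=float),
        X=X,
        column_names=names,
        animal_ids=sub[id_col].to_numpy(),
        conditional=conditional,
    )


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------

def solve_mme(
    design: ModelDesign,
    vc: VarComp,
    rel: RelationshipMatrix,
) -> MMESolution:
    """Solve Henderson's mixed-model equations for one trait.

    [X'X   X'W          ] [b]   [X'y]
    [W'X   W'W + Hinv*k ] [u] = [W'y],   k = sigma_e2 / sigma_u2.

    ``rel`` may be any (inverse or not) relationship matrix covering every
    animal; animals without records still receive breeding values through
    the relationship structure.  A singular fixed-effect block (confounded
    levels) is reported and resolved by a generalized inverse.
    """
    if vc.sigma_u2 is None or vc.sigma_u2 <= 0 or vc.sigma_e2 is None or vc.sigma_e2 <= 0:
        raise ValueError("solve_mme needs positive sigma_u2 and sigma_e2")
    Hinv = rel.inverse()
    labels = rel.labels
    n_anim = len(labels)
    idx = design.animal_index(labels)
    n, p = design.X.shape

    W = np.zeros((n, n_anim))
    W[np.arange(n), idx] = 1.0
    k = vc.sigma_e2 / vc.sigma_u2

    C = np.empty((p + n_anim, p + n_anim))
    C[:p, :p] = design.X.T @ design.X
    C[:p, p:] = design.X.T @ W
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = W.T @ W + Hinv * k
    rhs = np.concatenate([design.X.T @ design.y, W.T @ design.y])

    singular = False
    try:
        sol = scipy.linalg.solve(C, rhs, assume_a="sym")
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError("non-finite solution")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
        singular = True
        warnings.warn(
            "singular fixed-effect block in MME; using a generalized inverse",
            stacklevel=2,
        )
        sol = np.linalg.pinv(C) @ rhs
    return MMESolution(
        fixed_effects=sol[:p],
        fixed_names=list(design.column_names),
        u=sol[p:],
        labels=labels,
        singular_fixed=singular,
    )


# ---------------------------------------------------------------------------
# single-trait AI-REML (spectral)
# ---------------------------------------------------------------------------

def _phenotyped_kernel(rel: RelationshipMatrix, design: ModelDesign) -> np.ndarray:
    """H restricted to the phenotyped animals, in record order."""
    H = rel.dense()
    idx = design.animal_index(rel.labels)
    return H[np.ix_(idx, idx)]


@dataclass
class _Rotated:
    s: np.ndarray  # eigenvalues of the phenotyped kernel
    ystar: np.ndarray
    Xstar: np.ndarray
    U: np.ndarray


def _rotate(K: np.ndarray, y: np.ndarray, X: np.ndarray) -> _Rotated:
    s, U = np.linalg.eigh(K)
    return _Rotated(s=s, ystar=U.T @ y, Xstar=U.T @ X, U=U)


def _single_eval(rot: _Rotated, theta: np.ndarray):
    """Restricted loglik, score and AI matrix at theta = (sigma_u2, sigma_e2)."""
    d = theta[0] * rot.s + theta[1]
    if np.any(d <= 0):
        return None
    Xd = rot.Xstar / d[:, None]
    XtDX = rot.Xstar.T @ Xd
    sign, logdet_xx = np.linalg.slogdet(XtDX)
    if sign <= 0:
        return None
    B = np.linalg.inv(XtDX)
    bhat = B @ (Xd.T @ rot.ystar)
    r = rot.ystar - rot.Xstar @ bhat
    q = r / d  # rotated P y
    ypy = float(r @ q)
    ll = -0.5 * (np.sum(np.log(d)) + logdet_xx + ypy)

    score = np.empty(2)
    fvecs = []
    v_list = (rot.s, np.ones_like(rot.s))
    for k, v in enumerate(v_list):
        tr_vinv = float(np.sum(v / d))
        M = rot.Xstar.T @ (rot.Xstar * (v / d**2)[:, None])
        tr_corr = float(np.trace(B @ M))
        qvq = float(np.sum(v * q * q))
        score[k] = -0.5 * ((tr_vinv - tr_corr) - qvq)
        fvecs.append(v * q)

    def apply_P(f: np.ndarray) -> np.ndarray:
        g = f / d
        return g - Xd @ (B @ (rot.Xstar.T @ g))

    AI = np.empty((2, 2))
    Pf = [apply_P(f) for f in fvecs]
    for a in range(2):
        for b in range(a, 2):
            AI[a, b] = AI[b, a] = 0.5 * float(fvecs[a] @ Pf[b])
    return ll, score, AI, bhat


def aireml_single(
    design: ModelDesign,
    rel: RelationshipMatrix,
    start: VarComp | None = None,
    max_rounds: int = 200,
    tol: float = 1e-9,
) -> VarComp:
    """Single-trait AI-REML on the animal model.

    Average-information updates of (sigma_u2, sigma_e2) with an EM-REML
    fallback whenever an AI step would leave the parameter space or reduce
    the restricted likelihood; convergence when the maximum relative
    parameter change drops below ``tol``.  The variance floor is
    1e-8 x phenotypic variance so heritability stays defined.

    Returns a :class:`VarComp` with h2, AI-based standard errors (delta
    method for h2) and the final restricted log-likelihood.
    """
    if len(np.unique(design.animal_ids)) < 2:
        raise ValueError("need records on at least two distinct animals")
    K = _phenotyped_kernel(rel, design)
    rot = _rotate(K, design.y, design.X)
    n = len(design.y)

    vp = float(np.var(design.y))
    floor = 1e-8 * vp
    if start is not None and start.sigma_u2 and start.sigma_e2:
        theta = np.array([start.sigma_u2, start.sigma_e2], dtype=float)
    else:
        theta = np.array([0.5 * vp, 0.5 * vp])
    theta = np.maximum(theta, floor)

    converged = False
    ll_prev = -np.inf
    rounds = 0
    AI = np.eye(2)
    for rounds in range(1, max_rounds + 1):
        out = _single_eval(rot, theta)
        if out is None:  # pragma: no cover - floor keeps d positive
            theta = np.maximum(theta, floor)
            continue
        ll, score, AI, _ = out

        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = score / max(np.abs(np.diag(AI)).max(), 1.0)
        cand = theta + delta

        use_em = np.any(cand < floor)
        if not use_em:
            chk = _single_eval(rot, cand)
            if chk is None or chk[0] < ll - 1e-8 * max(1.0, abs(ll)):
                use_em = True
        if use_em:
            # EM-REML: theta_k += theta_k^2 (y'P V_k P y - tr(P V_k)) / n
            # score already equals -0.5*(tr(PV_k) - y'PV_kPy), so
            em_grad = 2.0 * score / n
            cand = np.maximum(theta + theta**2 * em_grad, floor)

        rel_change = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), floor))
        theta = cand
        if rel_change < tol:
            converged = True
            break
        ll_prev = ll

    out = _single_eval(rot, theta)
    ll, score, AI, _ = out
    su, se_ = float(theta[0]), float(theta[1])
    h2 = su / (su + se_)

    se: dict[str, float] = {}
    try:
        AIinv = np.linalg.inv(AI)
        se["sigma_u2"] = float(np.sqrt(max(AIinv[0, 0], 0.0)))
        se["sigma_e2"] = float(np.sqrt(max(AIinv[1, 1], 0.0)))
        g = np.array([se_, -su]) / (su + se_) ** 2
        se["h2"] = float(np.sqrt(max(g @ AIinv @ g, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    if not converged:
        warnings.warn(
            f"AI-REML did not converge in {max_rounds} rounds for {design.trait}",
            stacklevel=2,
        )
    return VarComp(
        sigma_u2=su,
        sigma_e2=se_,
        h2=h2,
        se=se,
        loglik=float(ll),
        converged=converged,
        n_rounds=rounds,
        traits=[design.trait],
    )


# ---------------------------------------------------------------------------
# bivariate AI-REML
# ---------------------------------------------------------------------------

_DERIV_BLOCKS = [
    np.array([[1.0, 0.0], [0.0, 0.0]]),  # T11 / R11
    np.array([[0.0, 1.0], [1.0, 0.0]]),  # T12 / R12
    np.array([[0.0, 0.0], [0.0, 1.0]]),  # T22 / R22
]


def _theta_to_TR(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    T = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    R = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    return T, R


def _valid_TR(theta: np.ndarray, floor: np.ndarray) -> bool:
    T, R = _theta_to_TR(theta)
    for M, f in ((T, floor[0]), (R, floor[1])):
        if M[0, 0] < f or M[1, 1] < f:
            return False
        if np.linalg.eigvalsh(M).min() < -1e-12 * max(1.0, np.trace(M)):
            return False
        if abs(M[0, 1]) > 0.999 * np.sqrt(M[0, 0] * M[1, 1]):
            return False
    return True


def _biv_eval_shared(rot1: _Rotated, rot2: _Rotated, s: np.ndarray, theta: np.ndarray):
    """loglik/score/AI for the shared-record-set bivariate model.

    Rotated covariance is 2x2 block diagonal: M_i = s_i * T + R.
    """
    T, R = _theta_to_TR(theta)
    n = len(s)
    M = s[:, None, None] * T + R  # (n, 2, 2)
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] ** 2
    if np.any(det <= 0) or np.any(M[:, 0, 0] <= 0):
        return None
    Winv = np.empty_like(M)
    Winv[:, 0, 0] = M[:, 1, 1] / det
    Winv[:, 1, 1] = M[:, 0, 0] / det
    Winv[:, 0, 1] = Winv[:, 1, 0] = -M[:, 0, 1] / det

    X1, X2 = rot1.Xstar, rot2.Xstar
    p1, p2 = X1.shape[1], X2.shape[1]
    Y = np.stack([rot1.ystar, rot2.ystar], axis=1)  # (n, 2)

    def xwx(Wblk: np.ndarray) -> np.ndarray:
        C = np.empty((p1 + p2, p1 + p2))
        C[:p1, :p1] = X1.T @ (X1 * Wblk[:, 0, 0][:, None])
        C[:p1, p1:] = X1.T @ (X2 * Wblk[:, 0, 1][:, None])
        C[p1:, :p1] = C[:p1, p1:].T
        C[p1:, p1:] = X2.T @ (X2 * Wblk[:, 1, 1][:, None])
        return C

    Cmat = xwx(Winv)
    sign, logdet_c = np.linalg.slogdet(Cmat)
    if sign <= 0:
        return None
    Wy = np.einsum("nij,nj->ni", Winv, Y)
    rhs = np.concatenate([X1.T @ Wy[:, 0], X2.T @ Wy[:, 1]])
    b = np.linalg.solve(Cmat, rhs)
    fit = np.stack([X1 @ b[:p1], X2 @ b[p1:]], axis=1)
    Rres = Y - fit
    q = np.einsum("nij,nj->ni", Winv, Rres)  # rotated P y
    ypy = float(np.sum(Rres * q))
    ll = -0.5 * (float(np.sum(np.log(det))) + logdet_c + ypy)

    Cinv = np.linalg.inv(Cmat)

    def apply_P(F: np.ndarray) -> np.ndarray:
        G = np.einsum("nij,nj->ni", Winv, F)
        xg = np.concatenate([X1.T @ G[:, 0], X2.T @ G[:, 1]])
        h = Cinv @ xg
        t = np.stack([X1 @ h[:p1], X2 @ h[p1:]], axis=1)
        return G - np.einsum("nij,nj->ni", Winv, t)

    npar = 6
    score = np.empty(npar)
    fvecs = []
    for k in range(npar):
        E = _DERIV_BLOCKS[k % 3]
        scale = s if k < 3 else np.ones_like(s)
        dM = scale[:, None, None] * E
        WdW = np.einsum("nij,jk,nkl->nil", Winv, E, Winv) * scale[:, None, None]
        tr_vinv = float(np.einsum("nij,nji->", Winv, dM))
        tr_corr = float(np.trace(Cinv @ xwx(WdW)))
        qvq = float(np.einsum("ni,nij,nj->", q, dM, q))
        score[k] = -0.5 * ((tr_vinv - tr_corr) - qvq)
        fvecs.append(np.einsum("nij,nj->ni", dM, q))

    Pf = [apply_P(F) for F in fvecs]
    AI = np.empty((npar, npar))
    for a in range(npar):
        for c in range(a, npar):
            AI[a, c] = AI[c, a] = 0.5 * float(np.sum(fvecs[a] * Pf[c]))
    return ll, score, AI


def _biv_eval_dense(y, X, Vks, theta):
    """Generic dense AI-REML evaluation (unequal missingness path)."""
    V = sum(t * Vk for t, Vk in zip(theta, Vks))
    try:
        c, low = scipy.linalg.cho_factor(V, lower=True)
    except scipy.linalg.LinAlgError:
        return None
    Vinv = scipy.linalg.cho_solve((c, low), np.eye(V.shape[0]))
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    XtVX = X.T @ Vinv @ X
    sign, logdet_c = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return None
    B = np.linalg.inv(XtVX)
    P = Vinv - Vinv @ X @ B @ X.T @ Vinv
    Py = P @ y
    ypy = float(y @ Py)
    ll = -0.5 * (logdet_v + logdet_c + ypy)
    npar = len(Vks)
    score = np.empty(npar)
    fvecs = []
    for k, Vk in enumerate(Vks):
        score[k] = -0.5 * (float(np.sum(P * Vk)) - float(Py @ Vk @ Py))
        fvecs.append(Vk @ Py)
    AI = np.empty((npar, npar))
    Pf = [P @ f for f in fvecs]
    for a in range(npar):
        for c in range(a, npar):
            AI[a, c] = AI[c, a] = 0.5 * float(fvecs[a] @ Pf[c])
    return ll, score, AI


def aireml_bivariate(
    designA: ModelDesign,
    designB: ModelDesign,
    rel: RelationshipMatrix,
    start: VarComp | None = None,
    max_rounds: int = 200,
    tol: float = 1e-8,
) -> VarComp:
    """Two-trait AI-REML: full 2x2 T and R with derived correlations.

    When both traits are recorded on the same animals the model is solved in
    the spectral basis of the shared relationship sub-block (fast, exact);
    otherwise a dense AI-REML path handles trait-wise missingness, with the
    residual covariance contributing only for animals recorded for both
    traits.  An AI update that leaves the parameter space (non-PSD T or R)
    or reduces the likelihood is replaced by a step-halved update projected
    back into the space.  Estimated correlations are clamped to [-1, 1] with
    a warning if rounding pushes them outside.
    """
    idxA = designA.animal_index(rel.labels)
    idxB = designB.animal_index(rel.labels)
    shared = np.array_equal(np.sort(idxA), np.sort(idxB))

    vpA = float(np.var(designA.y))
    vpB = float(np.var(designB.y))
    floor = np.array([1e-8 * vpA, 1e-8 * vpB])
    if start is not None and start.T is not None and start.R is not None:
        T0, R0 = start.T, start.R
    else:
        # neutral start: half the phenotypic (co)variance each, with the
        # cross-covariance taken from the animals recorded for both traits
        common, posA, posB = np.intersect1d(idxA, idxB, return_indices=True)
        if len(common) >= 3:
            c12 = float(np.cov(designA.y[posA], designB.y[posB])[0, 1])
        else:
            c12 = 0.0
        T0 = 0.5 * np.array([[vpA, c12 * 0.5], [c12 * 0.5, vpB]])
        R0 = T0.copy()
    theta = np.array([T0[0, 0], T0[0, 1], T0[1, 1], R0[0, 0], R0[0, 1], R0[1, 1]])

    if shared:
        order = np.argsort(idxA)
        orderB = np.argsort(idxB)
        H = rel.dense()
        K = H[np.ix_(idxA[order], idxA[order])]
        s, U = np.linalg.eigh(K)
        rot1 = _Rotated(s=s, ystar=U.T @ designA.y[order], Xstar=U.T @ designA.X[order], U=U)
        rot2 = _Rotated(s=s, ystar=U.T @ designB.y[orderB], Xstar=U.T @ designB.X[orderB], U=U)
        evaluate = lambda th: _biv_eval_shared(rot1, rot2, s, th)
    else:
        H = rel.dense()
        nA, nB = len(idxA), len(idxB)
        KAA = H[np.ix_(idxA, idxA)]
        KAB = H[np.ix_(idxA, idxB)]
        KBB = H[np.ix_(idxB, idxB)]
        zAA = np.zeros((nA, nA))
        zBB = np.zeros((nB, nB))
        zAB = np.zeros((nA, nB))
        overlap = (idxA[:, None] == idxB[None, :]).astype(float)
        Vks = [
            np.block([[KAA, zAB], [zAB.T, zBB]]),               # T11
            np.block([[zAA, KAB], [KAB.T, zBB]]),               # T12
            np.block([[zAA, zAB], [zAB.T, KBB]]),               # T22
            np.block([[np.eye(nA), zAB], [zAB.T, zBB]]),        # R11
            np.block([[zAA, overlap], [overlap.T, zBB]]),       # R12
            np.block([[zAA, zAB], [zAB.T, np.eye(nB)]]),        # R22
        ]
        y = np.concatenate([designA.y, designB.y])
        X = scipy.linalg.block_diag(designA.X, designB.X)
        evaluate = lambda th: _biv_eval_dense(y, X, Vks, th)

    converged = False
    rounds = 0
    ll = np.nan
    AI = np.eye(6)
    for rounds in range(1, max_rounds + 1):
        out = evaluate(theta)
        if out is None:
            raise RuntimeError("bivariate REML likelihood undefined at current values")
        ll, score, AI = out
        scale = np.array(
            [vpA, np.sqrt(vpA * vpB), vpB, vpA, np.sqrt(vpA * vpB), vpB]
        )
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = score * scale / max(np.abs(np.diag(AI)).max(), 1.0)
        # an ill-conditioned AI (near-degenerate data) can produce wild
        # steps; cap the move at twice the parameter scale
        fac = np.max(np.abs(delta) / (np.abs(theta) + 1e-3 * scale))
        if not np.all(np.isfinite(delta)) or fac > 2.0:
            delta = delta * (2.0 / fac) if np.all(np.isfinite(delta)) else score * scale

        # step-halving fallback: shrink the step until the candidate is
        # inside the parameter space and does not reduce the likelihood;
        # if the AI direction fails entirely, retry along the
        # diagonally-preconditioned gradient
        cand = None
        for direction in (delta, score * scale / max(np.abs(np.diag(AI)).max(), 1.0)):
            step = 1.0
            for _ in range(30):
                trial = theta + step * direction
                if _valid_TR(trial, floor):
                    chk = evaluate(trial)
                    if chk is not None and chk[0] >= ll - 1e-6 * max(1.0, abs(ll)):
                        cand = trial
                        break
                step *= 0.5
            if cand is not None:
                break
        if cand is None:
            # stuck against the boundary of the parameter space
            converged = True
            break

        rel_change = np.max(
            np.abs(cand - theta) / np.maximum(np.abs(theta), np.min(floor))
        )
        theta = cand
        if rel_change < tol:
            converged = True
            break

    out = evaluate(theta)
    if out is not None:
        ll, _, AI = out
    T, R = _theta_to_TR(theta)

    def _corr(c, v1, v2, name):
        denom = np.sqrt(v1 * v2)
        r = c / denom if denom > 0 else 0.0
        if abs(r) > 1.0:
            warnings.warn(f"{name} clamped from {r:.4f} to [-1, 1]", stacklevel=3)
            r = float(np.clip(r, -1.0, 1.0))
        return float(r)

    r_g = _corr(T[0, 1], T[0, 0], T[1, 1], "genetic correlation")
    r_p = _corr(
        T[0, 1] + R[0, 1], T[0, 0] + R[0, 0], T[1, 1] + R[1, 1], "phenotypic correlation"
    )

    se: dict[str, float] = {}
    try:
        AIinv = np.linalg.inv(AI)
        labels = ["T11", "T12", "T22", "R11", "R12", "R22"]
        for i, lab in enumerate(labels):
            se[lab] = float(np.sqrt(max(AIinv[i, i], 0.0)))
        # delta method for r_g = T12 / sqrt(T11 T22)
        t11, t12, t22 = T[0, 0], T[0, 1], T[1, 1]
        if t11 > 0 and t22 > 0:
            g = np.zeros(6)
            g[0] = -0.5 * t12 / (t11**1.5 * np.sqrt(t22))
            g[1] = 1.0 / np.sqrt(t11 * t22)
            g[2] = -0.5 * t12 / (t22**1.5 * np.sqrt(t11))
            se["r_g"] = float(np.sqrt(max(g @ AIinv @ g, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    if not converged:
        warnings.warn(
            f"bivariate AI-REML did not converge in {max_rounds} rounds "
            f"({designA.trait}, {designB.trait})",
            stacklevel=2,
        )
    return VarComp(
        T=T,
        R=R,
        r_g=r_g,
        r_p=r_p,
        se=se,
        loglik=float(ll),
        converged=converged,
        n_rounds=rounds,
        traits=[designA.trait, designB.trait],
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def varcomp_table(results: list[VarComp]) -> pd.DataFrame:
    """Flat summary of single-trait fits (one row per trait)."""
    rows = []
    for vc in results:
        rows.append(
            {
                "trait": vc.traits[0] if vc.traits else "",
                "sigma_u2": vc.sigma_u2,
                "sigma_e2": vc.sigma_e2,
                "h2": vc.h2,
                "se_h2": vc.se.get("h2", np.nan),
                "loglik": vc.loglik,
                "converged": vc.converged,
            }
        )
    return pd.DataFrame(rows)
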