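"""REML variance components for the thermal-challenge animal model.

The model for the standardized resistance phenotype of fish k challenged on
day i from dam j is

    y_ijk = mu + day_i + dam_j + u_ijk + e_ijk

with day a fixed factor, dam an IID common-environment effect, and u an
additive genetic effect correlated through a pedigree or genomic
relationship matrix.  Estimation is average-information REML with an
EM-safeguarded step: an AI update that leaves the parameter space or
decreases the restricted likelihood is halved and, failing that, replaced
by the (monotone) EM update.  Standard errors come from the inverse average
information; ratios (h2, dam share, genetic correlations) use first-order
delta-method errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .relmat import RelationshipMatrix


@dataclass
class VarianceComponents:
    """REML estimates plus the derived genetic parameters."""

    components: dict[str, float]
    se: dict[str, float]
    loglik: float
    aic: float
    converged: bool
    boundary: bool
    n_iter: int
    n_obs: int
    trait: str
    fixed_effects: pd.Series
    dam_blup: pd.Series | None = None
    animal_blup: pd.Series | None = None
    h2: float | None = None
    h2_se: float | None = None
    dam_ratio: float | None = None
    dam_ratio_se: float | None = None
    r_g: float | None = None
    r_g_se: float | None = None
    history: list[float] = field(default_factory=list)

    @property
    def sigma_p2(self) -> float:
        return sum(v for k, v in self.components.items() if not k.startswith("cov"))


class RemlError(RuntimeError):
    pass


def _reml_core(
    y: np.ndarray,
    x: np.ndarray,
    qs: list[np.ndarray],
    is_variance: list[bool],
    theta0: np.ndarray,
    floors: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    cov_pairs: list[tuple[int, int, int]] | None = None,
):
    """Hybrid AI/EM REML for V = sum_i theta_i Q_i.

    ``is_variance`` marks parameters constrained to be positive (floored);
    covariance parameters are unconstrained in sign but each
    ``cov_pairs`` entry (cov_idx, var_a_idx, var_b_idx) is kept inside the
    corresponding correlation bound so reported correlations stay in
    [-1, 1]; every trial step must also keep V positive definite.
    """
    cov_pairs = cov_pairs or []
    n, n_par = len(y), len(qs)

    def evaluate(theta):
        v = np.zeros((n, n))
        for t, q in zip(theta, qs):
            v += t * q
        try:
            c, low = linalg.cho_factor(v, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
        vinv_x = vinv @ x
        xtvx = x.T @ vinv_x
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return None
        beta = np.linalg.solve(xtvx, vinv_x.T @ y)
        p = vinv - vinv_x @ np.linalg.solve(xtvx, vinv_x.T)
        py = p @ y
        ll = -0.5 * (logdet_v + logdet_x + float(y @ py))
        return {"ll": ll, "p": p, "py": py, "vinv": vinv, "beta": beta, "xtvx": xtvx}

    theta = theta0.copy()
    state = evaluate(theta)
    if state is None:
        raise RemlError("starting values give a singular covariance matrix")
    history = [state["ll"]]
    converged = False
    n_iter = 0
    stall_count = 0
    ai_inv = np.eye(n_par)

    for n_iter in range(1, max_iter + 1):
        p, py = state["p"], state["py"]
        qpy = [q @ py for q in qs]
        score = np.array(
            [-0.5 * (float(np.sum(p * q)) - float(py @ qp)) for q, qp in zip(qs, qpy)]
        )
        ai = 0.5 * np.array([[float(qi @ (p @ qj)) for qj in qpy] for qi in qpy])
        ai_reg = ai + 1e-10 * np.eye(n_par) * max(1.0, np.trace(ai))
        try:
            delta = np.linalg.solve(ai_reg, score)
        except np.linalg.LinAlgError:
            delta = score / max(1.0, np.abs(score).max())

        # EM fallback direction (monotone for variance parameters)
        em = theta.copy()
        for i in range(n_par):
            if is_variance[i]:
                em[i] = theta[i] + theta[i] ** 2 / n * (
                    float(py @ qpy[i]) - float(np.sum(p * qs[i]))
                )
                em[i] = max(em[i], floors[i])

        def project(cand):
            for i in range(n_par):
                if is_variance[i]:
                    cand[i] = max(cand[i], floors[i])
            for ci, ai_, bi in cov_pairs:
                bound = 0.999 * np.sqrt(cand[ai_] * cand[bi])
                cand[ci] = float(np.clip(cand[ci], -bound, bound))
            return cand

        new_state, new_theta, halvings = None, None, 0
        step = delta.copy()
        for k in range(12):  # step halving against boundary / likelihood drops
            cand = project(theta + step)
            trial = evaluate(cand)
            if trial is not None and trial["ll"] >= state["ll"] - 1e-8:
                new_state, new_theta, halvings = trial, cand, k
                break
            step *= 0.5
        if new_state is None:
            trial = evaluate(project(em))
            if trial is None:
                break  # EM invalid too; stop at current point
            new_state, new_theta, halvings = trial, em, 0

        change = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), floors))
        improvement = new_state["ll"] - state["ll"]
        theta, state = new_theta, new_state
        history.append(state["ll"])
        try:
            ai_inv = np.linalg.inv(ai_reg)
        except np.linalg.LinAlgError:
            pass
        # a step halved to nothing is a stall, not convergence
        if change < tol and halvings <= 1:
            converged = True
            break
        # flat restricted likelihood: accept the stationary ridge point
        if improvement < 1e-9 * max(1.0, abs(state["ll"])):
            stall_count += 1
            if stall_count >= 3:
                converged = change < 1e-4
                break
        else:
            stall_count = 0

    boundary = any(
        is_variance[i] and theta[i] <= floors[i] * (1.0 + 1e-6) for i in range(n_par)
    )
    if not converged and not boundary:
        warnings.warn(
            f"REML did not converge in {n_iter} iterations "
            f"(last logL {history[-1]:.4f})",
            RuntimeWarning,
        )
    return theta, state, ai_inv, converged, boundary, n_iter, history


def _day_design(table: pd.DataFrame, day_col: str) -> tuple[np.ndarray, list[str]]:
    levels = list(pd.unique(table[day_col]))
    x = np.ones((len(table), len(levels)))
    names = ["intercept"]
    for j, lev in enumerate(levels[1:], start=1):
        x[:, j] = (table[day_col] == lev).to_numpy(dtype=np.float64)
        names.append(f"{day_col}[{lev}]")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise RemlError("singular fixed-effects design (collinear day factor)")
    return x, names


def _dam_incidence(table: pd.DataFrame, dam_col: str) -> tuple[np.ndarray, list[str]]:
    levels, codes = np.unique(table[dam_col].astype(str), return_inverse=True)
    w = np.zeros((len(table), len(levels)))
    w[np.arange(len(table)), codes] = 1.0
    return w, list(levels)


def reml_fit(
    table: pd.DataFrame,
    trait: str,
    relationship: RelationshipMatrix,
    day_col: str = "group",
    dam_col: str = "dam",
    include_dam: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Univariate animal-model REML fit for one trait.

    Every phenotyped animal must be present in the relationship matrix.
    Returns variance components (additive, dam if fitted, residual),
    heritability and dam-share with delta-method SEs, BLUPs of the dam and
    animal effects, the restricted log-likelihood and AIC (-2 logL + 2 x
    number of variance parameters).
    """
    tab = table.dropna(subset=[trait]).reset_index(drop=True)
    n = len(tab)
    if n < 10:
        raise RemlError("too few phenotyped animals for REML")
    y = tab[trait].to_numpy(dtype=np.float64)
    x, x_names = _day_design(tab, day_col)
    k = relationship.subset(tab["id"].tolist()).values

    qs = [k]
    names = ["additive"]
    is_var = [True]
    if include_dam:
        w, dam_levels = _dam_incidence(tab, dam_col)
        qs.append(w @ w.T)
        names.append("dam")
        is_var.append(True)
    qs.append(np.eye(n))
    names.append("residual")
    is_var.append(True)

    vy = float(np.var(y, ddof=1))
    theta0 = np.array(
        [0.3 * vy] + ([0.1 * vy] if include_dam else []) + [0.6 * vy]
    )
    floors = np.full(len(qs), 1e-8 * vy)
    theta, state, ai_inv, converged, boundary, n_iter, history = _reml_core(
        y, x, qs, is_var, theta0, floors, max_iter=max_iter, tol=tol
    )

    comps = dict(zip(names, theta))
    ses = {nm: float(np.sqrt(max(ai_inv[i, i], 0.0))) for i, nm in enumerate(names)}
    sigma_p2 = float(theta.sum())
    idx_u = names.index("additive")

    def ratio_and_se(idx: int) -> tuple[float, float]:
        grad = np.full(len(theta), -theta[idx] / sigma_p2**2)
        grad[idx] += 1.0 / sigma_p2
        return theta[idx] / sigma_p2, float(np.sqrt(max(grad @ ai_inv @ grad, 0.0)))

    h2, h2_se = ratio_and_se(idx_u)
    dam_ratio = dam_ratio_se = None
    if include_dam:
        dam_ratio, dam_ratio_se = ratio_and_se(names.index("dam"))

    py = state["py"]
    animal_blup = pd.Series(theta[idx_u] * (k @ py), index=tab["id"], name="ebv")
    dam_blup = None
    if include_dam:
        dam_blup = pd.Series(
            theta[names.index("dam")] * (w.T @ py), index=dam_levels, name="dam_blup"
        )

    return VarianceComponents(
        components=comps,
        se=ses,
        loglik=state["ll"],
        aic=-2.0 * state["ll"] + 2.0 * len(theta),
        converged=converged,
        boundary=boundary,
        n_iter=n_iter,
        n_obs=n,
        trait=trait,
        fixed_effects=pd.Series(state["beta"], index=x_names),
        dam_blup=dam_blup,
        animal_blup=animal_blup,
        h2=h2,
        h2_se=h2_se,
        dam_ratio=dam_ratio,
        dam_ratio_se=dam_ratio_se,
        history=history,
    )


def reml_fit_bivariate(
    table_x: pd.DataFrame,
    trait_x: str,
    table_y: pd.DataFrame,
    trait_y: str,
    relationship: RelationshipMatrix,
    day_col: str = "group",
    dam_col: str = "dam",
    include_dam_x: bool = True,
    include_dam_y: bool = False,
    fix_residual_cov: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Bivariate animal-model REML yielding the genetic correlation.

    The two traits may be recorded on the same animals (residual covariance
    estimated) or on disjoint animals linked only through the relationship
    matrix, in which case the residual covariance is fixed at zero.
    ``fix_residual_cov=True`` forces the zero constraint even for shared
    animals; at small n the genetic and residual covariances ride a flat
    likelihood ridge, and fixing the residual term identifies the genetic
    correlation.
    """
    tx = table_x.dropna(subset=[trait_x]).reset_index(drop=True)
    ty = table_y.dropna(subset=[trait_y]).reset_index(drop=True)
    n1, n2 = len(tx), len(ty)
    n = n1 + n2
    # fit on unit-variance scales for AI conditioning; back-transform after
    s1 = float(tx[trait_x].std(ddof=1))
    s2 = float(ty[trait_y].std(ddof=1))
    if s1 <= 0 or s2 <= 0:
        raise RemlError("a trait has zero phenotypic variance")
    y = np.concatenate(
        [tx[trait_x].to_numpy(float) / s1, ty[trait_y].to_numpy(float) / s2]
    )

    x1, names1 = _day_design(tx, day_col)
    x2, names2 = _day_design(ty, day_col)
    x = np.zeros((n, x1.shape[1] + x2.shape[1]))
    x[:n1, : x1.shape[1]] = x1
    x[n1:, x1.shape[1]:] = x2
    x_names = [f"{trait_x}:{nm}" for nm in names1] + [f"{trait_y}:{nm}" for nm in names2]

    ids = tx["id"].tolist() + ty["id"].tolist()
    k_all = relationship.subset(ids).values
    k11, k22 = k_all[:n1, :n1], k_all[n1:, n1:]
    k12 = k_all[:n1, n1:]

    def block(b11=None, b22=None, b12=None):
        q = np.zeros((n, n))
        if b11 is not None:
            q[:n1, :n1] = b11
        if b22 is not None:
            q[n1:, n1:] = b22
        if b12 is not None:
            q[:n1, n1:] = b12
            q[n1:, :n1] = b12.T
        return q

    qs = [block(b11=k11), block(b22=k22), block(b12=k12)]
    names = ["additive_x", "additive_y", "cov_g"]
    is_var = [True, True, False]
    if include_dam_x:
        w1, _ = _dam_incidence(tx, dam_col)
        qs.append(block(b11=w1 @ w1.T))
        names.append("dam_x")
        is_var.append(True)
    if include_dam_y:
        w2, _ = _dam_incidence(ty, dam_col)
        qs.append(block(b22=w2 @ w2.T))
        names.append("dam_y")
        is_var.append(True)
    qs.append(block(b11=np.eye(n1)))
    qs.append(block(b22=np.eye(n2)))
    names += ["residual_x", "residual_y"]
    is_var += [True, True]

    shared = set(tx["id"]) & set(ty["id"])
    if shared and not fix_residual_cov:
        pos_y = {a: i for i, a in enumerate(ty["id"])}
        b12 = np.zeros((n1, n2))
        for i, a in enumerate(tx["id"]):
            if a in pos_y:
                b12[i, pos_y[a]] = 1.0
        qs.append(block(b12=b12))
        names.append("cov_e")
        is_var.append(False)

    v1 = float(np.var(y[:n1], ddof=1))
    v2 = float(np.var(y[n1:], ddof=1))
    start = {"additive_x": 0.3 * v1, "additive_y": 0.3 * v2, "cov_g": 0.0,
             "dam_x": 0.08 * v1, "dam_y": 0.08 * v2,
             "residual_x": 0.6 * v1, "residual_y": 0.6 * v2, "cov_e": 0.0}
    theta0 = np.array([start[nm] for nm in names])
    floors = np.array(
        [1e-8 * (v1 if nm.endswith("_x") else v2 if nm.endswith("_y") else np.sqrt(v1 * v2))
         for nm in names]
    )
    cov_pairs = [(names.index("cov_g"), names.index("additive_x"), names.index("additive_y"))]
    if "cov_e" in names:
        cov_pairs.append(
            (names.index("cov_e"), names.index("residual_x"), names.index("residual_y"))
        )
    theta, state, ai_inv, converged, boundary, n_iter, history = _reml_core(
        y, x, qs, is_var, theta0, floors, max_iter=max_iter, tol=tol,
        cov_pairs=cov_pairs,
    )

    # back-transform the unit-variance fit to the original trait scales
    unscale = np.array(
        [s1 * s1 if nm.endswith("_x") else s2 * s2 if nm.endswith("_y") else s1 * s2
         for nm in names]
    )
    theta = theta * unscale
    ai_inv = ai_inv * np.outer(unscale, unscale)
    comps = dict(zip(names, theta))
    ses = {nm: float(np.sqrt(max(ai_inv[i, i], 0.0))) for i, nm in enumerate(names)}

    g11, g22, g12 = comps["additive_x"], comps["additive_y"], comps["cov_g"]
    r_g = g12 / np.sqrt(g11 * g22) if g11 > 0 and g22 > 0 else np.nan
    grad = np.zeros(len(theta))
    if np.isfinite(r_g):
        grad[names.index("additive_x")] = -0.5 * r_g / g11
        grad[names.index("additive_y")] = -0.5 * r_g / g22
        grad[names.index("cov_g")] = 1.0 / np.sqrt(g11 * g22)
        r_g_se = float(np.sqrt(max(grad @ ai_inv @ grad, 0.0)))
    else:
        r_g_se = float("nan")

    return VarianceComponents(
        components=comps,
        se=ses,
        loglik=state["ll"],
        aic=-2.0 * state["ll"] + 2.0 * len(theta),
        converged=converged,
        boundary=boundary,
        n_iter=n_iter,
        n_obs=n,
        trait=f"{trait_x},{trait_y}",
        fixed_effects=pd.Series(
            state["beta"]
            * np.array([s1] * x1.shape[1] + [s2] * x2.shape[1]),
            index=x_names,
        ),
        r_g=float(r_g),
        r_g_se=r_g_se,
        history=history,
    )


def aic_compare(
    fit_with_dam: VarianceComponents, fit_without_dam: VarianceComponents
) -> tuple[str, float]:
    """Select between the dam and no-dam fits by AIC (lower wins; a tie
    keeps the simpler model).  Returns (selected, delta_aic = with - without).
    """
    if fit_with_dam.n_obs != fit_without_dam.n_obs or fit_with_dam.trait != fit_without_dam.trait:
        raise ValueError("AIC comparison requires the same data and trait")
    delta = fit_with_dam.aic - fit_without_dam.aic
    return ("with_dam" if delta < 0 else "without_dam"), float(delta)
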