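"""REML estimation for the nested GBLUP models.

Six univariate mixed models decompose the adjusted phenotypes into fixed
trial-design effects and random clone effects with marker-derived
covariances:

    A     y = Xb + Z a + e                      a ~ N(0, G_A s2_A)
    AH    y = Xb + b_h (Het - mean Het) + Z a + e
    AD    y = Xb + Z a + Z d + e                d ~ N(0, G_D s2_D)
    ADH   AD plus the heterozygosity covariate
    ADE   y = Xb + Z a + Z d + Z t + e          t ~ N(0, G_AA s2_E)
    ADEH  ADE plus the heterozygosity covariate

Estimation is average-information REML with fixed-point fallback steps.  All
solves use the Woodbury identity so the per-iteration cost is cubic in the
number of clones, not records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .kernels import HetVector, KernelMatrix

logger = logging.getLogger(__name__)

MODEL_LABELS = ("A", "AH", "AD", "ADH", "ADE", "ADEH")

_LABEL_KERNELS: dict[str, tuple[str, ...]] = {
    "A": ("G_A",),
    "AH": ("G_A",),
    "AD": ("G_A", "G_D"),
    "ADH": ("G_A", "G_D"),
    "ADE": ("G_A", "G_D", "G_AA"),
    "ADEH": ("G_A", "G_D", "G_AA"),
}

DEFAULT_FACTORS = ("year", "crop", "region", "trial")


@dataclass
class ModelSpec:
    """Which kernels, fixed factors and covariates a model fits."""

    label: str = "A"
    random_kernels: tuple[str, ...] | None = None
    include_het: bool | None = None
    fixed_factors: tuple[str, ...] = DEFAULT_FACTORS
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.label in _LABEL_KERNELS:
            if self.random_kernels is None:
                self.random_kernels = _LABEL_KERNELS[self.label]
            if self.include_het is None:
                self.include_het = self.label.endswith("H")
        elif self.label == "custom":
            if self.random_kernels is None:
                raise ValueError("custom model needs explicit random_kernels")
            if self.include_het is None:
                self.include_het = False
        else:
            raise ValueError(f"unknown model label {self.label!r}")
        self.random_kernels = tuple(self.random_kernels)


@dataclass
class Design:
    """Response, fixed design and record-to-clone incidence for one trait."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    clone_index: np.ndarray  # record -> kernel row
    clone_ids: list[str]  # kernel clone order


@dataclass
class RemlFit:
    """Variance components, fixed effects, BLUPs and likelihood of one model."""

    spec: ModelSpec
    var_components: dict[str, tuple[float, float]]  # name -> (estimate, se)
    boundary_flags: dict[str, bool]
    fixed_effects: pd.DataFrame  # term, estimate, se
    loglik: float
    blups: dict[str, np.ndarray]
    clone_ids: list[str]
    converged: bool
    n_iter: int
    columns: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def gebv(self) -> np.ndarray:
        """Genomic estimated breeding value: the additive BLUP."""
        return self.blups["G_A"]

    @property
    def gpcp(self) -> np.ndarray:
        """Genomic prediction of clonal performance: sum of genetic BLUPs."""
        return sum(self.blups[k] for k in self.spec.random_kernels)

    @property
    def sigma_p2(self) -> float:
        return sum(est for est, _ in self.var_components.values())

    def het_coefficient(self) -> tuple[float, float] | None:
        row = self.fixed_effects[self.fixed_effects["term"] == "het"]
        if row.empty:
            return None
        return float(row["estimate"].iloc[0]), float(row["se"].iloc[0])

    def summary(self) -> pd.DataFrame:
        sp2 = self.sigma_p2
        rows = []
        for name, (est, se) in self.var_components.items():
            rows.append({
                "component": name,
                "estimate": est,
                "se": se,
                "ratio": est / sp2 if sp2 > 0 else np.nan,
                "boundary": self.boundary_flags[name],
            })
        return pd.DataFrame(rows)


@dataclass
class LrtResult:
    stat: float
    df: int
    p_value: float
    significant: bool


def build_design(
    ph: pd.DataFrame,
    spec: ModelSpec,
    clone_ids: Sequence[str],
    het: HetVector | None = None,
    on_aliased: str = "error",
) -> Design:
    """Assemble y, the fixed design and the record-to-clone incidence.

    Fixed factors are treatment-coded with the first (sorted) level as the
    reference; single-level factors are dropped with a warning.  When the
    model includes heterozygosity, the per-record covariate Het - mean(Het)
    is appended (centred over the design records, so its column mean is 0).

    Trial factors nested inside region and year make the full dummy coding
    rank-deficient by construction; ``on_aliased="drop"`` removes the aliased
    columns (keeping the earliest) with a warning, mirroring how mixed-model
    software absorbs such singularities, while the default raises.
    """
    if spec.trait not in ph.columns:
        raise ValueError(f"trait {spec.trait!r} not in phenotype table")
    df = ph.loc[ph[spec.trait].notna()].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no records with trait {spec.trait!r}")
    pos = {c: i for i, c in enumerate(clone_ids)}
    unknown = set(df["clone"]) - set(pos)
    if unknown:
        raise ValueError(f"clones without kernel coverage: {sorted(unknown)[:5]}")
    clone_index = df["clone"].map(pos).to_numpy(int)

    y = df[spec.trait].to_numpy(float)
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for factor in spec.fixed_factors:
        levels = sorted(df[factor].astype(str).unique())
        if len(levels) < 2:
            logger.warning("factor %s has a single level; dropped from design", factor)
            continue
        for lev in levels[1:]:
            cols.append((df[factor].astype(str) == lev).to_numpy(float))
            names.append(f"{factor}[{lev}]")
    if spec.include_het:
        if het is None:
            raise ValueError(f"model {spec.label} requires a heterozygosity vector")
        het_map = dict(zip(het.clone_ids, het.values))
        v = df["clone"].map(het_map).to_numpy(float)
        cols.append(v - v.mean())
        names.append("het")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify columns that are linear combinations of earlier ones
        aliased_idx = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                aliased_idx.append(j)
            r = rj
        aliased = [names[j] for j in aliased_idx]
        if on_aliased != "drop":
            raise ValueError(f"rank-deficient fixed design; aliased columns: {aliased}")
        logger.warning("dropping %d aliased design columns (e.g. %s)",
                       len(aliased), aliased[:3])
        keep = [j for j in range(X.shape[1]) if j not in set(aliased_idx)]
        X = X[:, keep]
        names = [names[j] for j in keep]
    return Design(y=y, X=X, columns=names, clone_index=clone_index,
                  clone_ids=list(clone_ids))


class _WoodburyReml:
    """REML likelihood, scores and AI matrix via clone-dimension algebra.

    V = s2_e I + Z G Z' with G = sum_m s2_m K_m; Z the record-to-clone
    incidence.  With S = G^-1 + D / s2_e (D the diagonal of record counts),
    every V^-1 product reduces to c x c solves.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, clone_index: np.ndarray,
                 kernels: Sequence[np.ndarray]):
        self.y = y
        self.X = X
        self.idx = clone_index
        self.K = kernels
        self.n, self.f = X.shape
        self.c = kernels[0].shape[0]
        self.d = np.bincount(clone_index, minlength=self.c).astype(float)

    def _zt(self, v: np.ndarray) -> np.ndarray:
        """Z' v for a record vector (or matrix) v."""
        if v.ndim == 1:
            return np.bincount(self.idx, weights=v, minlength=self.c)
        out = np.zeros((self.c, v.shape[1]))
        np.add.at(out, self.idx, v)
        return out

    def _z(self, u: np.ndarray) -> np.ndarray:
        """Z u for a clone vector (or matrix) u."""
        return u[self.idx]

    def prepare(self, theta: np.ndarray) -> None:
        """Factorise for variance components theta = (s2_1..s2_k, s2_e)."""
        *sig, s2e = theta
        self.s2e = float(s2e)
        G = sum(s * K for s, K in zip(sig, self.K))
        G = G + 1e-10 * np.trace(G) / self.c * np.eye(self.c)
        self.cG = cho_factor(G, lower=True)
        Ginv = cho_solve(self.cG, np.eye(self.c))
        S = Ginv + np.diag(self.d / self.s2e)
        self.cS = cho_factor(S, lower=True)
        self.logdetV = (
            self.n * np.log(self.s2e)
            + 2.0 * np.sum(np.log(np.diag(self.cG[0])))
            + 2.0 * np.sum(np.log(np.diag(self.cS[0])))
        )
        W = np.column_stack([self.X, self.y])
        self.VinvW = self._vinv(W)
        XtVX = self.X.T @ self.VinvW[:, : self.f]
        self.XtVX = 0.5 * (XtVX + XtVX.T)
        self.cXtVX = cho_factor(self.XtVX)
        XtVy = self.X.T @ self.VinvW[:, -1]
        self.beta = cho_solve(self.cXtVX, XtVy)
        self.Py = self.VinvW[:, -1] - self.VinvW[:, : self.f] @ self.beta
        self.yPy = float(self.y @ self.Py)
        sign, logdet = np.linalg.slogdet(self.XtVX)
        self.loglik = -0.5 * (self.logdetV + logdet + self.yPy)

    def _vinv(self, v: np.ndarray) -> np.ndarray:
        ztv = self._zt(v)
        return v / self.s2e - self._z(cho_solve(self.cS, ztv)) / self.s2e**2

    def _pmat(self, v: np.ndarray) -> np.ndarray:
        """P v = V^-1 v - V^-1 X (X'V^-1 X)^-1 X' V^-1 v."""
        vv = self._vinv(v)
        return vv - self.VinvW[:, : self.f] @ cho_solve(self.cXtVX, self.X.T @ vv)

    def scores_and_ai(self) -> tuple[np.ndarray, np.ndarray]:
        k = len(self.K)
        # Z'V^-1 Z and Z'V^-1 X in clone dimension
        SinvD = cho_solve(self.cS, np.diag(self.d))
        ZtVZ = np.diag(self.d) / self.s2e - (self.d[:, None] * SinvD) / self.s2e**2
        VinvX = self.VinvW[:, : self.f]
        ZtVX = self._zt(VinvX)
        XtVXinv_XtVZ = cho_solve(self.cXtVX, ZtVX.T)

        ztPy = self._zt(self.Py)
        scores = np.empty(k + 1)
        vmats = []
        for m, K in enumerate(self.K):
            trVB = float(np.sum(ZtVZ * K))
            A = ZtVX.T @ (K @ ZtVX)
            trPB = trVB - float(np.trace(cho_solve(self.cXtVX, A)))
            KZtPy = K @ ztPy
            quad = float(ztPy @ KZtPy)
            scores[m] = -0.5 * (trPB - quad)
            vmats.append(self._z(KZtPy))
        # residual component
        trVinv = self.n / self.s2e - float(np.sum(np.diag(SinvD) * 1.0)) / self.s2e**2
        trPI = trVinv - float(np.trace(cho_solve(self.cXtVX, VinvX.T @ VinvX)))
        scores[k] = -0.5 * (trPI - float(self.Py @ self.Py))
        vmats.append(self.Py)

        V = np.column_stack(vmats)  # n x (k+1), columns B_m P y
        PV = np.column_stack([self._pmat(V[:, j]) for j in range(k + 1)])
        ai = 0.5 * (V.T @ PV)
        return scores, 0.5 * (ai + ai.T)


def reml_fit(
    design: Design,
    kernels: Mapping[str, KernelMatrix],
    spec: ModelSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
    n_em_steps: int = 3,
) -> RemlFit:
    """Average-information REML with fixed-point fallback.

    Variances start at var(y)/(k+1); the first ``n_em_steps`` updates are
    fixed-point (guaranteed positive), the rest Newton steps on the average
    information, halved when they reduce the restricted likelihood.
    Components hitting the lower bound are pinned at 1e-6 var(y) and flagged
    as boundary ("~0"); their SEs are reported as NaN.
    """
    names = list(spec.random_kernels)
    for name in names:
        if name not in kernels:
            raise ValueError(f"model {spec.label} needs kernel {name!r}")
    Ks = [np.asarray(kernels[name].values, float) for name in names]
    clone_ids = kernels[names[0]].clone_ids
    for name in names[1:]:
        if kernels[name].clone_ids != clone_ids:
            raise ValueError("kernels have mismatched clone order")
    if design.clone_ids != list(clone_ids):
        raise ValueError("design clone order does not match kernels")

    y, X = design.y, design.X
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few records for the fixed design")
    vy = float(np.var(y, ddof=1))
    floor = 1e-6 * vy
    k = len(Ks)
    theta = np.full(k + 1, vy / (k + 1))

    engine = _WoodburyReml(y, X, design.clone_index, Ks)
    engine.prepare(theta)
    loglik = engine.loglik
    converged = False
    warnings: list[str] = []
    ai = None
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        scores, ai = engine.scores_and_ai()
        free = theta > floor * 1.0001
        at_bound_pushing_down = (~free) & (scores < 0)
        active = ~at_bound_pushing_down

        use_ai = n_iter > n_em_steps
        step = np.zeros_like(theta)
        if use_ai:
            sub = ai[np.ix_(active, active)]
            try:
                cond = np.linalg.cond(sub)
                if cond > 1e12:
                    raise np.linalg.LinAlgError("ill-conditioned AI matrix")
                step[active] = np.linalg.solve(sub, scores[active])
            except np.linalg.LinAlgError:
                use_ai = False
                if "singular average-information matrix" not in warnings:
                    warnings.append("singular average-information matrix")
        if not use_ai:
            # multiplicative fixed point: s2 <- s2 * (y'PBPy) / tr(PB)
            w = engine.Py
            for m, K in enumerate(Ks):
                ztw = engine._zt(w)
                quad = float(ztw @ (K @ ztw))
                trPB = quad - 2.0 * scores[m]
                if trPB > 0:
                    step[m] = theta[m] * (quad / trPB) - theta[m]
            quad_e = float(w @ w)
            trPI = quad_e - 2.0 * scores[k]
            if trPI > 0:
                step[k] = theta[k] * (quad_e / trPI) - theta[k]

        new = np.maximum(theta + step, floor)
        # step halving if the restricted likelihood decreases
        for _ in range(12):
            engine.prepare(new)
            if engine.loglik >= loglik - 1e-10:
                break
            new = np.maximum(theta + 0.5 * (new - theta), floor)
        delta = abs(engine.loglik - loglik) / max(1.0, abs(engine.loglik))
        theta, loglik = new, engine.loglik
        if delta < tol:
            converged = True
            break

    if not converged:
        warnings.append("REML did not converge")
        logger.warning("REML (%s) did not converge in %d iterations", spec.label, max_iter)

    engine.prepare(theta)
    scores, ai = engine.scores_and_ai()
    pinned = theta <= floor * 1.0001
    se = np.full(k + 1, np.nan)
    free = ~pinned
    if free.any():
        try:
            cov = np.linalg.inv(ai[np.ix_(free, free)])
            se[free] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            warnings.append("singular average-information matrix")

    comp_names = names + ["residual"]
    var_components = {nm: (float(theta[i]), float(se[i])) for i, nm in enumerate(comp_names)}
    boundary = {nm: bool(pinned[i]) for i, nm in enumerate(comp_names)}

    # BLUPs from the mixed-model equations at the final estimates
    ztPy = engine._zt(engine.Py)
    blups = {nm: theta[m] * (Ks[m] @ ztPy) for m, nm in enumerate(names)}

    beta = engine.beta
    try:
        beta_cov = cho_solve(engine.cXtVX, np.eye(X.shape[1]))
        beta_se = np.sqrt(np.maximum(np.diag(beta_cov), 0.0))
    except np.linalg.LinAlgError:
        beta_se = np.full(X.shape[1], np.nan)
    fixed = pd.DataFrame({"term": design.columns, "estimate": beta, "se": beta_se})

    return RemlFit(
        spec=spec,
        var_components=var_components,
        boundary_flags=boundary,
        fixed_effects=fixed,
        loglik=float(loglik),
        blups=blups,
        clone_ids=list(clone_ids),
        converged=converged,
        n_iter=n_iter,
        columns=list(design.columns),
        warnings=warnings,
    )


def heritabilities(fit: RemlFit) -> tuple[float, float]:
    """Narrow-sense h2 = s2_A / s2_P and model-appropriate broad-sense H2.

    s2_P is the sum of all fitted genetic variances plus the residual; H2 sums
    the genetic components the model includes (boundary-pinned components
    contribute their pinned, effectively zero, estimate).
    """
    sp2 = fit.sigma_p2
    if sp2 <= 0:
        return 0.0, 0.0
    genetic = [fit.var_components[nm][0] for nm in fit.spec.random_kernels]
    s2a = fit.var_components[fit.spec.random_kernels[0]][0]
    return s2a / sp2, sum(genetic) / sp2


def heritability_from_components(
    var_a: float,
    var_d: float = 0.0,
    var_e: float = 0.0,
    var_resid: float = 0.0,
) -> tuple[float, float]:
    """h2 and H2 directly from printed variance components."""
    sp2 = var_a + var_d + var_e + var_resid
    if sp2 <= 0:
        return 0.0, 0.0
    return var_a / sp2, (var_a + var_d + var_e) / sp2


def lrt(full: RemlFit, reduced: RemlFit) -> LrtResult:
    """Likelihood-ratio test between nested REML fits.

    stat = 2 (logL_full - logL_reduced) referred to chi-squared with one
    degree of freedom, as commonly applied to one added variance component
    (the boundary makes this conservative).
    """
    return lrt_from_loglik(full.loglik, reduced.loglik,
                           _check_nested(full, reduced))


def _check_nested(full: RemlFit, reduced: RemlFit) -> int:
    if reduced.columns != full.columns:
        raise ValueError("REML log-likelihoods are not comparable across "
                         "different fixed designs")
    if set(reduced.spec.random_kernels) - set(full.spec.random_kernels):
        raise ValueError("models are not nested")
    extra = set(full.spec.random_kernels) - set(reduced.spec.random_kernels)
    return max(len(extra), 1)


def lrt_from_loglik(loglik_full: float, loglik_reduced: float, df: int = 1) -> LrtResult:
    stat = 2.0 * (loglik_full - loglik_reduced)
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    return LrtResult(stat=float(stat), df=df, p_value=p, significant=p < 0.05)
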