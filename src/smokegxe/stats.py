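"""Interaction logistic models, multiplicative and additive scales.

One logistic model per group × EPF,

    logit P(Y=1) = b0 + bG·G + bE·E + bGxE·G·E + covariates,

yields every quantity in the Knol–VanderWeele presentation:

* cell odds ratios against the doubly unexposed reference:
  OR10 = exp(bG), OR01 = exp(bE), OR11 = exp(bG + bE + bGxE);
* stratified ORs from the same fit (G within E=1: exp(bG + bGxE);
  E within G=1: exp(bE + bGxE)) — not from refitted per-stratum models,
  so the identities OR11 = OR01·OR(G|E=1) = OR10·OR(E|G=1) hold exactly;
* multiplicative-scale interaction exp(bGxE) with a Wald CI and p;
* additive-scale interaction RERI = OR11 − OR10 − OR01 + 1 with a
  delta-method variance through the coefficient covariance and a
  two-sided Wald p; a percentile bootstrap CI is available as an
  independent check.

RERI here is defined on odds ratios, treating them as rare-disease
approximations of risk ratios; ever-smoking prevalence in the motivating
cohorts is 55–60%, so results carry a metadata note to that effect.

Estimation is iteratively reweighted least squares with the covariance
taken as the inverse observed information; complete separation and rank
deficiency are surfaced as explicit errors rather than masked by
regularization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps
from scipy.special import expit

from .cohort import CellCounts, crosstab_cells, exposure_column

Z95 = float(sps.norm.ppf(0.975))  # 1.959964...

RARE_DISEASE_NOTE = (
    "RERI computed from odds ratios as rare-disease approximations of risk "
    "ratios; the outcome (ever smoking) is common (~55-60%), so interpret "
    "the additive scale with caution."
)


class SeparationError(RuntimeError):
    """The likelihood has no finite maximum (complete/quasi separation)."""


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient; names the offending columns."""


@dataclass
class LogisticFit:
    """A converged maximum-likelihood logistic regression fit."""

    params: np.ndarray
    cov: np.ndarray
    labels: tuple[str, ...]
    n: int
    llf: float
    converged: bool
    n_iter: int

    def idx(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no term {label!r}; terms are {self.labels}") from None

    def coef(self, label: str) -> float:
        return float(self.params[self.idx(label)])

    def se(self, label: str) -> float:
        return float(np.sqrt(self.cov[self.idx(label), self.idx(label)]))

    def lincomb_or(self, labels: Sequence[str]) -> tuple[float, float, float]:
        """exp(sum of coefficients) with a 95% Wald CI on the log scale."""
        e = np.zeros(len(self.params))
        for lab in labels:
            e[self.idx(lab)] += 1.0
        est = float(e @ self.params)
        se = float(np.sqrt(e @ self.cov @ e))
        return (
            float(np.exp(est)),
            float(np.exp(est - Z95 * se)),
            float(np.exp(est + Z95 * se)),
        )

    def wald_p(self, labels: Sequence[str]) -> float:
        e = np.zeros(len(self.params))
        for lab in labels:
            e[self.idx(lab)] += 1.0
        z = (e @ self.params) / np.sqrt(e @ self.cov @ e)
        return float(2.0 * sps.norm.sf(abs(z)))


def _check_rank(X: np.ndarray, labels: Sequence[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [labels[j] for j in piv[rank:]]
        raise RankDeficiencyError(
            f"design matrix is rank deficient; dependent columns: {bad}"
        )


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float] | np.ndarray,
    labels: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``X`` is the full design matrix including any intercept column.
    Convergence is declared when the largest absolute coefficient update
    falls below ``tol``; the covariance is the inverse observed
    information at the optimum.  Rank-deficient designs raise
    :class:`RankDeficiencyError` naming the dependent columns, and
    designs with separated outcomes raise :class:`SeparationError`
    instead of silently diverging.
    """
    if isinstance(X, pd.DataFrame):
        labels = tuple(X.columns) if labels is None else tuple(labels)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        labels = tuple(labels) if labels is not None else tuple(
            f"x{j}" for j in range(Xm.shape[1])
        )
    yv = np.asarray(y, dtype=float)
    if Xm.ndim != 2 or len(yv) != Xm.shape[0]:
        raise ValueError("X must be (n, p) with len(y) == n")
    if not np.isin(yv, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if np.isnan(Xm).any():
        raise ValueError("design matrix contains missing values")
    _check_rank(Xm, labels)

    beta = np.zeros(Xm.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xm @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        info = (Xm * w[:, None]).T @ Xm
        score = Xm.T @ (yv - p)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "information matrix is singular at the current iterate; "
                "the outcome is (quasi-)separated on the design"
            ) from None
        beta = beta + delta
        if np.max(np.abs(beta)) > 30.0:
            raise SeparationError(
                "coefficients diverging (|beta| > 30): complete or "
                "quasi-complete separation of the outcome"
            )
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged:
        raise SeparationError(
            f"IRLS did not converge in {max_iter} iterations (max |delta| = "
            f"{np.max(np.abs(delta)):.3g}); check for separation"
        )
    p = expit(Xm @ beta)
    info = (Xm * (p * (1 - p))[:, None]).T @ Xm
    cov = np.linalg.inv(info)
    eps = 1e-12
    llf = float(np.sum(yv * np.log(p + eps) + (1 - yv) * np.log(1 - p + eps)))
    return LogisticFit(
        params=beta, cov=cov, labels=labels, n=len(yv), llf=llf,
        converged=True, n_iter=it,
    )


def crude_or_2x2(
    a: float, b: float, c: float, d: float, continuity: bool = False
) -> tuple[float, float, float]:
    """Cross-product odds ratio with a 95% Woolf (log) confidence interval.

    ``a``/``b`` are cases/non-cases among the exposed, ``c``/``d`` among
    the unexposed: OR = (a·d)/(b·c).  A zero cell raises unless
    ``continuity`` adds the Haldane 0.5 to every cell.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(cells == 0):
        if not continuity:
            raise ValueError(
                "zero cell in 2x2 table; pass continuity=True for the +0.5 correction"
            )
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        float(or_),
        float(np.exp(np.log(or_) - Z95 * se)),
        float(np.exp(np.log(or_) + Z95 * se)),
    )


def crude_cell_or(
    cells: CellCounts, g: int, e: int, continuity: bool = False
) -> tuple[float, float, float]:
    """Crude OR of cell (g, e) against the doubly unexposed (0, 0) cell."""
    a = cells.cases(g, e)
    b = cells.total(g, e) - a
    c = cells.cases(0, 0)
    d = cells.total(0, 0) - c
    return crude_or_2x2(a, b, c, d, continuity=continuity)


def reri_from_ors(or11: float, or10: float, or01: float) -> float:
    """Relative excess risk due to interaction from the three cell ORs."""
    for name, v in (("or11", or11), ("or10", or10), ("or01", or01)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return or11 - or10 - or01 + 1.0


@dataclass(frozen=True)
class ReriResult:
    estimate: float
    variance: float
    ci_low: float
    ci_high: float
    p: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def reri_delta_ci(
    fit: LogisticFit, terms: tuple[str, str, str] = ("G", "E", "G:E")
) -> ReriResult:
    """Delta-method variance and Wald CI for the model-derived RERI.

    With b = (bG, bE, bGxE), RERI(b) = e^(bG+bE+bGxE) − e^bG − e^bE + 1 and
    the gradient is (OR11 − OR10, OR11 − OR01, OR11); the variance is
    gᵀ Σ g over the corresponding 3×3 coefficient-covariance block.
    """
    ix = [fit.idx(t) for t in terms]
    bg, be, bge = (float(fit.params[i]) for i in ix)
    sigma = fit.cov[np.ix_(ix, ix)]
    if np.min(np.linalg.eigvalsh((sigma + sigma.T) / 2)) < -1e-10:
        raise ValueError("coefficient covariance block is not positive semi-definite")
    or10, or01, or11 = np.exp(bg), np.exp(be), np.exp(bg + be + bge)
    reri = float(or11 - or10 - or01 + 1.0)
    grad = np.array([or11 - or10, or11 - or01, or11])
    var = float(grad @ sigma @ grad)
    se = np.sqrt(var)
    if se > 0:
        z = reri / se
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        p = float(reri == 0.0)
    return ReriResult(
        estimate=reri,
        variance=var,
        ci_low=float(reri - Z95 * se),
        ci_high=float(reri + Z95 * se),
        p=p,
    )


def _encode_gender(col: pd.Series) -> pd.Series:
    if col.dtype.kind in "ifu":
        return pd.to_numeric(col)
    mapped = col.map({"female": 1.0, "male": 0.0})
    if mapped.isna().any() and col.notna().any():
        bad = sorted(set(col[mapped.isna() & col.notna()]))
        raise ValueError(f"unknown gender categories {bad}")
    return mapped


def build_design(
    df: pd.DataFrame,
    epf: str,
    covariates: Sequence[str] = (),
    g_col: str = "G",
) -> pd.DataFrame:
    """Design matrix const + G + E + G:E + covariates for one EPF model."""
    e_col = exposure_column(epf)
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["G"] = pd.to_numeric(df[g_col])
    X["E"] = pd.to_numeric(df[e_col])
    X["G:E"] = X["G"] * X["E"]
    for c in covariates:
        X[c] = _encode_gender(df[c]) if c == "gender" else pd.to_numeric(df[c])
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(
            f"design contains missing values in {bad}; run complete_cases first"
        )
    return X


@dataclass
class InteractionResult:
    """Everything one Knol–VanderWeele block reports, from a single fit."""

    group: str
    epf: str
    n: int
    cells: CellCounts
    or10: tuple[float, float, float]
    or01: tuple[float, float, float]
    or11: tuple[float, float, float]
    stratum_g_in_e0: tuple[float, float, float]
    stratum_g_in_e1: tuple[float, float, float]
    stratum_e_in_g0: tuple[float, float, float]
    stratum_e_in_g1: tuple[float, float, float]
    multiplicative: tuple[float, float, float, float]  # ratio, lo, hi, p
    reri: ReriResult
    reri_bootstrap_ci: tuple[float, float] | None
    fit: LogisticFit
    notes: tuple[str, ...] = (RARE_DISEASE_NOTE,)


def multiplicative_scale(fit: LogisticFit) -> tuple[float, float, float, float]:
    """Multiplicative-scale interaction exp(bGxE): ratio, 95% CI, Wald p."""
    ratio, lo, hi = fit.lincomb_or(["G:E"])
    return ratio, lo, hi, fit.wald_p(["G:E"])


def interaction_analysis(
    df: pd.DataFrame,
    epf: str,
    covariates: Sequence[str] = (),
    group: str = "",
    y_col: str = "Y",
    g_col: str = "G",
    n_boot: int = 0,
    boot_seed: int = 0,
) -> InteractionResult:
    """Fit the single interaction model for one EPF and fill a full block.

    ``df`` must already be complete-case for outcome, G, the EPF exposure
    and the covariates.  All ORs (cells and strata) come from this one
    fit via coefficient sums, so the block's algebraic identities hold to
    machine precision.  Set ``n_boot`` > 0 to add a percentile-bootstrap
    RERI CI next to the delta-method one.
    """
    e_col = exposure_column(epf)
    cells = crosstab_cells(df, e_col, g_col=g_col, y_col=y_col)
    for key, (cases, total) in cells:
        if total == 0 or cases == 0 or cases == total:
            raise ValueError(
                f"degenerate exposure cell (G,E)={key}: {cases}/{total} cases; "
                "the interaction model is not identified"
            )
    X = build_design(df, epf, covariates, g_col=g_col)
    fit = fit_logistic(X, pd.to_numeric(df[y_col]).to_numpy())
    boot_ci = None
    if n_boot:
        boot_ci = reri_bootstrap_ci(
            df, epf, covariates, n_boot=n_boot, seed=boot_seed,
            y_col=y_col, g_col=g_col,
        )
    return InteractionResult(
        group=group,
        epf=epf,
        n=len(df),
        cells=cells,
        or10=fit.lincomb_or(["G"]),
        or01=fit.lincomb_or(["E"]),
        or11=fit.lincomb_or(["G", "E", "G:E"]),
        stratum_g_in_e0=fit.lincomb_or(["G"]),
        stratum_g_in_e1=fit.lincomb_or(["G", "G:E"]),
        stratum_e_in_g0=fit.lincomb_or(["E"]),
        stratum_e_in_g1=fit.lincomb_or(["E", "G:E"]),
        multiplicative=multiplicative_scale(fit),
        reri=reri_delta_ci(fit),
        reri_bootstrap_ci=boot_ci,
        fit=fit,
    )


def reri_bootstrap_ci(
    df: pd.DataFrame,
    epf: str,
    covariates: Sequence[str] = (),
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    y_col: str = "Y",
    g_col: str = "G",
    max_redraws: int = 10,
) -> tuple[float, float]:
    """Percentile bootstrap CI for RERI by case resampling of records.

    Resamples rows with replacement, refits the interaction model, and
    takes the alpha/2 and 1−alpha/2 percentiles of the RERI estimates.
    Resamples with an empty G×E cell are redrawn up to ``max_redraws``
    times before erroring.  Deterministic for a fixed seed.
    """
    if n_boot < 200:
        raise ValueError(f"n_boot must be >= 200, got {n_boot}")
    e_col = exposure_column(epf)
    X = build_design(df, epf, covariates, g_col=g_col).to_numpy()
    yv = pd.to_numeric(df[y_col]).to_numpy(dtype=float)
    ge = df[[g_col, e_col]].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n = len(df)
    labels = ("const", "G", "E", "G:E") + tuple(covariates)
    out = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            ix = rng.integers(0, n, n)
            sub = ge[ix]
            ok = all(
                np.any((sub[:, 0] == g) & (sub[:, 1] == e))
                for g in (0, 1)
                for e in (0, 1)
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"bootstrap resample {b}: empty exposure cell after "
                f"{max_redraws} redraws"
            )
        fit = fit_logistic(X[ix], yv[ix], labels=labels)
        bg, be, bge = fit.coef("G"), fit.coef("E"), fit.coef("G:E")
        out[b] = np.exp(bg + be + bge) - np.exp(bg) - np.exp(be) + 1.0
    lo, hi = np.percentile(out, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def continuous_pgs_interaction(
    df: pd.DataFrame,
    epf: str,
    covariates: Sequence[str] = (),
    y_col: str = "Y",
    pgs_col: str = "pgs",
) -> tuple[float, float, LogisticFit]:
    """Sensitivity model with the continuous score: Y ~ pgs·E + covariates.

    Returns the product-term coefficient, its two-sided Wald p, and the
    fit.  A constant exposure (or score) surfaces as a rank-deficiency
    error from the underlying fit.
    """
    e_col = exposure_column(epf)
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["pgs"] = pd.to_numeric(df[pgs_col])
    X["E"] = pd.to_numeric(df[e_col])
    X["pgs:E"] = X["pgs"] * X["E"]
    for c in covariates:
        X[c] = _encode_gender(df[c]) if c == "gender" else pd.to_numeric(df[c])
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(
            f"design contains missing values in {bad}; run complete_cases first"
        )
    fit = fit_logistic(X, pd.to_numeric(df[y_col]).to_numpy())
    return fit.coef("pgs:E"), fit.wald_p(["pgs:E"]), fit
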