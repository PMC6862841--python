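"""Multi-location yield-trial evaluation by REML.

Model: ``y = mu + g + loc + rep(loc) + block(rep(loc)) + g:loc + e`` with
every non-residual term random (preliminary trials) or with genotype fixed
(advanced trials).  Variance components are estimated by direct maximization
of the restricted log-likelihood, profiled over the residual variance and
optimized on the log variance-ratio scale with non-negativity enforced by
dropping components that collapse to zero.  Adjusted line values are
``mu + g_i`` (empirical BLUPs for random genotypes, generalized
least-squares means for fixed genotypes); maturity-confounded yield can be
re-fit with R8 as a fixed covariate.  Selection categories are compared by
Welch two-sample t-tests on per-line adjusted means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize
from scipy.stats import t as t_dist

from .selection import SelectionOutcome

__all__ = [
    "TrialModelSpec",
    "TrialFit",
    "AdjustedMeans",
    "CategoryComparison",
    "fit_trial_model",
    "adjusted_means",
    "yield_given_r8",
    "welch_t",
    "compare_categories",
    "top_rank_attribution",
    "significance_stars",
]

RANDOM_TERMS = ("genotype", "location", "rep", "block", "gxloc")


@dataclass
class TrialModelSpec:
    response: str = "yield_kg_ha"
    genotype_effect: str = "random"  # "random" (PYT) or "fixed" (AYT)
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if self.genotype_effect not in ("random", "fixed"):
            raise ValueError("genotype_effect must be 'random' or 'fixed'")


def _dummies(labels) -> np.ndarray:
    return pd.get_dummies(pd.Series(labels).astype(str)).to_numpy(dtype=float)


def _design(pheno: pd.DataFrame, spec: TrialModelSpec):
    """Random-term incidence matrices and the fixed-effect matrix."""
    loc = pheno["location"].astype(str)
    rep = loc + ":" + pheno["rep"].astype(str)
    blk = rep + ":" + pheno["block"].astype(str)
    geno = pheno["line_id"].astype(str)
    gxl = geno + ":" + loc

    z_all = {
        "genotype": geno,
        "location": loc,
        "rep": rep,
        "block": blk,
        "gxloc": gxl,
    }
    dropped = []
    z = {}
    for name in RANDOM_TERMS:
        labels = z_all[name]
        if name == "genotype" and spec.genotype_effect == "fixed":
            continue
        n_levels = labels.nunique()
        identifiable = n_levels >= 2 and n_levels < len(pheno)
        if name == "block":
            # blocks confounded with reps (one block per rep) are unidentifiable
            identifiable = identifiable and labels.nunique() > rep.nunique()
        if name == "gxloc":
            # with one location, g:loc duplicates the genotype term
            identifiable = identifiable and loc.nunique() >= 2
        if name == "rep":
            identifiable = identifiable and labels.nunique() > loc.nunique()
        if identifiable:
            z[name] = _dummies(labels)
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(f"dropping unidentifiable random terms: {dropped}")

    if spec.genotype_effect == "fixed":
        geno_levels = sorted(geno.unique())
        x = pd.get_dummies(geno)[geno_levels].to_numpy(dtype=float)
        x_names = [f"genotype:{g}" for g in geno_levels]
    else:
        x = np.ones((len(pheno), 1))
        x_names = ["intercept"]
        geno_levels = sorted(geno.unique())
    for cov in spec.covariates:
        xc = pheno[cov].to_numpy(dtype=float)
        x = np.column_stack([x, xc - xc.mean()])
        x_names.append(cov)
    return z, dropped, x, x_names, geno_levels


def _profiled_reml(log_gamma, z_list, x, y):
    """-2 restricted log-likelihood (up to a constant), profiled over sigma_e2."""
    n, p = x.shape
    h = np.eye(n)
    for lg, zz in zip(log_gamma, z_list):
        h += np.exp(lg) * zz
    try:
        ch = np.linalg.cholesky(h)
    except np.linalg.LinAlgError:
        return 1e30, None
    logdet_h = 2.0 * np.log(np.diag(ch)).sum()
    hi_y = sla.cho_solve((ch, True), y)
    hi_x = sla.cho_solve((ch, True), x)
    xtx = x.T @ hi_x
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        return 1e30, None
    beta = np.linalg.solve(xtx, x.T @ hi_y)
    quad = float(y @ hi_y - (x.T @ hi_y) @ beta)
    if quad <= 0:
        return 1e30, None
    sigma_e2 = quad / (n - p)
    nll = (n - p) * np.log(sigma_e2) + logdet_h + logdet_xtx
    return nll, (ch, beta, xtx, sigma_e2)


@dataclass
class TrialFit:
    spec: TrialModelSpec
    varcomps: dict[str, float]  # includes sigma_e2
    mu: float
    genotype_effects: pd.Series  # g_i (random BLUP or fixed deviation)
    genotype_se: pd.Series
    fixed_effects: pd.Series
    loglik: float  # restricted log-likelihood (up to a constant)
    dropped: list = field(default_factory=list)
    converged: bool = True


def fit_trial_model(pheno: pd.DataFrame, spec: TrialModelSpec) -> TrialFit:
    """REML fit of the multi-location trial model."""
    y = pheno[spec.response].to_numpy(dtype=float)
    z, dropped, x, x_names, geno_levels = _design(pheno, spec)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        bad = "genotype" if spec.genotype_effect == "fixed" else "covariates"
        raise ValueError(f"singular fixed-effect design ({bad})")

    names = list(z)
    zz_list = [z[k] @ z[k].T for k in names]
    scale = y.var() if y.var() > 0 else 1.0
    y_s = y / np.sqrt(scale)

    lb, ub = -12.0, 8.0
    while True:
        if names:
            x0 = np.full(len(names), -1.0)
            obj = lambda lg: _profiled_reml(lg, zz_list, x, y_s)[0]  # noqa: E731
            res = minimize(
                obj,
                x0,
                method="L-BFGS-B",
                bounds=[(lb, ub)] * len(names),
                options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
            )
            # derivative-free polish sharpens the optimum beyond gradient noise
            res2 = minimize(
                obj,
                res.x,
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxfev": 300},
            )
            best = res2 if res2.fun <= res.fun else res
            log_gamma = np.clip(best.x, lb, ub)
            converged = bool(res.success or res2.success)
        else:
            log_gamma = np.array([])
            converged = True
        # components pinned at the lower bound are truncated to zero and dropped
        keep = [i for i, lg in enumerate(log_gamma) if lg > lb + 0.5]
        if len(keep) == len(names):
            break
        for i, nm in enumerate(names):
            if i not in keep:
                dropped.append(nm)
        names = [names[i] for i in keep]
        zz_list = [zz_list[i] for i in keep]

    nll, aux = _profiled_reml(log_gamma, zz_list, x, y_s)
    ch, beta_s, xtx, sigma_e2_s = aux
    gammas = dict(zip(names, np.exp(log_gamma)))
    sigma_e2 = sigma_e2_s * scale
    varcomps = {nm: 0.0 for nm in RANDOM_TERMS if nm != "genotype" or
                spec.genotype_effect == "random"}
    varcomps.update({nm: g * sigma_e2 for nm, g in gammas.items()})
    varcomps["sigma_e2"] = sigma_e2

    beta = beta_s * np.sqrt(scale)
    hi = sla.cho_solve((ch, True), np.eye(n))
    hi_x = hi @ x
    xtx_inv = np.linalg.inv(xtx)
    resid = y - x @ beta
    hi_resid = hi @ resid
    beta_cov = xtx_inv * sigma_e2

    fixed = pd.Series(beta, index=x_names)
    if spec.genotype_effect == "fixed":
        g_cols = [i for i, nm in enumerate(x_names) if nm.startswith("genotype:")]
        gvals = beta[g_cols]
        mu = float(gvals.mean())
        geno_eff = pd.Series(gvals - mu, index=geno_levels)
        geno_se = pd.Series(np.sqrt(np.diag(beta_cov)[g_cols]), index=geno_levels)
    else:
        zg = _dummies(pheno["line_id"])
        levels_in = sorted(pheno["line_id"].astype(str).unique())
        if "genotype" in gammas:
            gam = gammas["genotype"]
            u = gam * (zg.T @ hi_resid)
            # prediction error variance of g via Z'PZ
            zp = zg.T @ hi @ zg - (zg.T @ hi_x) @ xtx_inv @ (hi_x.T @ zg)
            sg2 = gam * sigma_e2
            pev = np.clip(sg2 - (gam**2 * sigma_e2) * np.diag(zp), 0.0, None)
        else:
            u = np.zeros(len(levels_in))
            pev = np.zeros(len(levels_in))
        geno_eff = pd.Series(u, index=levels_in)
        geno_se = pd.Series(np.sqrt(pev), index=levels_in)
        mu = float(beta[x_names.index("intercept")])

    return TrialFit(
        spec=spec,
        varcomps=varcomps,
        mu=mu,
        genotype_effects=geno_eff,
        genotype_se=geno_se,
        fixed_effects=fixed,
        loglik=-0.5 * nll,
        dropped=dropped,
        converged=converged,
    )


@dataclass
class AdjustedMeans:
    trait: str
    table: pd.DataFrame  # line_id, adjusted, se

    def series(self) -> pd.Series:
        return self.table.set_index("line_id")["adjusted"]


def adjusted_means(fit: TrialFit) -> AdjustedMeans:
    """Per-line adjusted values mu + g_i on the response's unit scale."""
    tab = pd.DataFrame(
        {
            "line_id": fit.genotype_effects.index,
            "adjusted": fit.mu + fit.genotype_effects.to_numpy(),
            "se": fit.genotype_se.to_numpy(),
        }
    )
    return AdjustedMeans(trait=fit.spec.response, table=tab)


def yield_given_r8(
    pheno: pd.DataFrame, spec: TrialModelSpec | None = None,
    r8_col: str = "r8_dap",
) -> tuple[AdjustedMeans, TrialFit]:
    """Yield adjusted for maturity: refit with centered R8 as fixed covariate."""
    base = spec or TrialModelSpec()
    spec_cov = TrialModelSpec(
        response=base.response,
        genotype_effect=base.genotype_effect,
        covariates=tuple(base.covariates) + (r8_col,),
    )
    fit = fit_trial_model(pheno, spec_cov)
    return adjusted_means(fit), fit


# ---------------------------------------------------------------------------
# category comparison and top-rank attribution
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    for thr, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p <= thr:
            return stars
    return "ns"


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch two-sample t statistic, degrees of freedom and two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    diff = a.mean() - b.mean()
    if se2 == 0:
        return (0.0, float(a.size + b.size - 2), 1.0) if diff == 0 else (
            np.inf * np.sign(diff), float(a.size + b.size - 2), 0.0
        )
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    t = diff / np.sqrt(se2)
    return float(t), float(df), float(2.0 * t_dist.sf(abs(t), df))


@dataclass
class CategoryComparison:
    category_means: dict[str, float]
    category_n: dict[str, int]
    table: pd.DataFrame  # cat_a, cat_b, t, df, p, stars


def compare_categories(
    means: AdjustedMeans, membership: SelectionOutcome
) -> CategoryComparison:
    """Welch t-test on per-line adjusted means for every category pair.

    Lines selected by several categories contribute to each of their
    categories; per-pair stars are reported without multiplicity correction.
    """
    vals = means.series()
    samples = {}
    for cat, ids in membership.per_category.items():
        present = [i for i in ids if i in vals.index]
        if len(present) < 2:
            raise ValueError(f"category {cat} has fewer than 2 evaluated lines")
        samples[cat] = vals.loc[present].to_numpy()
    cats = sorted(samples)
    rows = []
    for i, ca in enumerate(cats):
        for cb in cats[i + 1 :]:
            t, df, p = welch_t(samples[ca], samples[cb])
            rows.append(
                {
                    "cat_a": ca,
                    "cat_b": cb,
                    "t": t,
                    "df": df,
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
    return CategoryComparison(
        category_means={c: float(samples[c].mean()) for c in cats},
        category_n={c: int(samples[c].size) for c in cats},
        table=pd.DataFrame(rows, columns=["cat_a", "cat_b", "t", "df", "p", "stars"]),
    )


def top_rank_attribution(
    ayt_means: AdjustedMeans,
    membership: SelectionOutcome,
    k: int = 10,
    yield_category: str = "Yield",
    acc_categories: tuple[str, ...] = ("ACC", "Yield|ACC"),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Top-k lines by adjusted mean, labeled with the categories that
    originally selected them, plus a summary partition of the k lines into
    canopy-informed (ACC and/or Yield|ACC, possibly with Yield), Yield-alone,
    and other (e.g. checks never selected)."""
    labels = membership.labels()
    tab = ayt_means.table.sort_values(
        ["adjusted", "line_id"], ascending=[False, True]
    ).head(k)
    rows = []
    summary = {"acc_informed": 0, "yield_alone": 0, "other": 0}
    for rank, r in enumerate(tab.itertuples(index=False), start=1):
        cats = labels.get(r.line_id, ())
        rows.append(
            {
                "rank": rank,
                "line_id": r.line_id,
                "adjusted": r.adjusted,
                "categories": "+".join(cats),
            }
        )
        if any(c in cats for c in acc_categories):
            summary["acc_informed"] += 1
        elif cats == (yield_category,):
            summary["yield_alone"] += 1
        else:
            summary["other"] += 1
    return pd.DataFrame(rows, columns=["rank", "line_id", "adjusted", "categories"]), summary
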