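"""Half-sib quantitative genetics on replicated multi-condition trials.

Variance components for the two-way random model (progeny and
progeny-by-condition random, condition fixed) are estimated by expected
mean squares on balanced data and by REML otherwise.  From the
components the module derives the genetic coefficient of variation, the
broad-sense heritability on a progeny-mean basis

    h2_B = s2g / (s2g + s2ge/c + s2e/(c*k)),

type-B genetic correlations across conditions, BLUP-adjusted progeny
phenotypes (shrunken progeny means used as the response in GWAS and
genomic selection), and phenotypic correlations among traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("progeny", "condition", "replicate", "trait", "value")


@dataclass
class VarianceComponents:
    """Estimated variance components of a replicated half-sib trial."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    c: int  # number of conditions
    k: int  # number of replicates
    per_condition_sigma2_g: dict[str, float] = field(default_factory=dict)
    truncated: bool = False  # any negative estimate truncated to 0
    method: str = "ems"
    grand_mean: float = 0.0
    condition_means: dict[str, float] = field(default_factory=dict)


def _select_trait(p: pd.DataFrame, trait: str | None) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in p.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    if trait is not None:
        p = p[p["trait"] == trait]
    if p.empty:
        raise ValueError(f"no records for trait {trait!r}")
    return p


def is_balanced(p: pd.DataFrame, trait: str | None = None) -> bool:
    """True when every progeny x condition x replicate cell is present once."""
    p = _select_trait(p, trait)
    counts = p.groupby(["progeny", "condition"], observed=True)["value"].count()
    n_prog = p["progeny"].nunique()
    n_cond = p["condition"].nunique()
    k = counts.iloc[0]
    return len(counts) == n_prog * n_cond and (counts == k).all()


def _ems_components(p: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments estimates from expected mean squares (balanced)."""
    n = p["progeny"].nunique()
    c = p["condition"].nunique()
    k = len(p) // (n * c)
    grand = p["value"].mean()
    prog_means = p.groupby("progeny", observed=True)["value"].mean()
    cond_means = p.groupby("condition", observed=True)["value"].mean()
    cell_means = p.groupby(["progeny", "condition"], observed=True)["value"].mean()

    ms_p = c * k * ((prog_means - grand) ** 2).sum() / (n - 1)
    inter = (
        cell_means
        - prog_means.reindex(cell_means.index.get_level_values(0)).to_numpy()
        - cond_means.reindex(cell_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ms_pc = k * (inter**2).sum() / ((n - 1) * (c - 1))
    resid = p["value"].to_numpy() - cell_means.loc[
        pd.MultiIndex.from_frame(p[["progeny", "condition"]])
    ].to_numpy()
    df_e = n * c * (k - 1)
    ms_e = (resid**2).sum() / df_e if df_e > 0 else 0.0

    s2e = ms_e
    s2ge = (ms_pc - ms_e) / k
    s2g = (ms_p - ms_pc) / (c * k)
    truncated = s2ge < 0 or s2g < 0
    vc = VarianceComponents(
        sigma2_g=max(s2g, 0.0),
        sigma2_ge=max(s2ge, 0.0),
        sigma2_e=max(s2e, 0.0),
        c=c,
        k=k,
        truncated=bool(truncated),
        method="ems",
        grand_mean=float(grand),
        condition_means=cond_means.to_dict(),
    )
    # single-condition one-way ANOVA per condition for CVg
    for cond, sub in p.groupby("condition", observed=True):
        pm = sub.groupby("progeny", observed=True)["value"].agg(["mean", "count"])
        ms_pc1 = (pm["count"].iloc[0]) * ((pm["mean"] - sub["value"].mean()) ** 2).sum() / (n - 1)
        within = sub["value"].to_numpy() - pm["mean"].reindex(sub["progeny"]).to_numpy()
        df_w = len(sub) - n
        ms_e1 = (within**2).sum() / df_w if df_w > 0 else 0.0
        vc.per_condition_sigma2_g[cond] = max((ms_pc1 - ms_e1) / k, 0.0)
    return vc


def _reml_components(p: pd.DataFrame) -> VarianceComponents:
    """REML estimates for the model value ~ condition (fixed) +
    progeny + progeny-by-condition (random).

    Observations from different progenies are independent, so the REML
    likelihood factors into small per-progeny blocks; the residual
    variance is profiled out and the two variance ratios
    gamma = (s2g/s2e, s2ge/s2e) are optimised directly.  Works for
    unbalanced tables (missing cells or replicates).
    """
    from scipy.linalg import cho_factor, cho_solve
    from scipy.optimize import minimize

    conds = sorted(p["condition"].unique())
    c = len(conds)
    cond_idx = {cc: i for i, cc in enumerate(conds)}
    n = len(p)

    blocks = []  # per progeny: (Xi, yi, same_condition indicator)
    for _, sub in p.groupby("progeny", observed=True):
        ci = np.array([cond_idx[cc] for cc in sub["condition"]])
        Xi = np.zeros((len(sub), c))
        Xi[np.arange(len(sub)), ci] = 1.0
        same = (ci[:, None] == ci[None, :]).astype(float)
        blocks.append((Xi, sub["value"].to_numpy(dtype=float), same))

    def profile(log_gamma: np.ndarray):
        gg, gge = np.exp(log_gamma)
        logdet_v = 0.0
        xtvx = np.zeros((c, c))
        xtvy = np.zeros(c)
        ytvy = 0.0
        for Xi, yi, same in blocks:
            ni = len(yi)
            Vi = np.eye(ni) + gg + gge * same
            cf = cho_factor(Vi, lower=True)
            logdet_v += 2.0 * np.log(np.diag(cf[0])).sum()
            Viy = cho_solve(cf, yi)
            ViX = cho_solve(cf, Xi)
            xtvx += Xi.T @ ViX
            xtvy += Xi.T @ Viy
            ytvy += yi @ Viy
        beta = np.linalg.solve(xtvx, xtvy)
        ypy = max(ytvy - xtvy @ beta, 1e-300)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        neg2ll = (n - c) * np.log(ypy) + logdet_v + logdet_x
        return neg2ll, ypy, beta

    # moment-based start from progeny means
    prog_means = p.groupby("progeny", observed=True)["value"].mean()
    vy = float(p["value"].var())
    s2g0 = max(float(prog_means.var()) * 0.5, vy * 1e-3)
    x0 = np.log([s2g0 / vy + 1e-6, s2g0 / vy + 1e-6])
    res = minimize(
        lambda lg: profile(np.clip(lg, -30.0, 30.0))[0],
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    lg = np.clip(res.x, -30.0, 30.0)
    _, ypy, _ = profile(lg)
    s2e = ypy / (n - c)
    gg, gge = np.exp(lg)
    s2g, s2ge = gg * s2e, gge * s2e
    at_floor = lg <= -29.0
    if at_floor[0]:
        s2g = 0.0
    if at_floor[1]:
        s2ge = 0.0

    n_prog = p["progeny"].nunique()
    k = max(int(round(n / (n_prog * c))), 1)
    cond_means = p.groupby("condition", observed=True)["value"].mean()
    vc = VarianceComponents(
        sigma2_g=float(s2g),
        sigma2_ge=float(s2ge),
        sigma2_e=float(s2e),
        c=c,
        k=k,
        truncated=bool(at_floor.any()),
        method="reml",
        grand_mean=float(p["value"].mean()),
        condition_means=cond_means.to_dict(),
    )
    for cond, sub in p.groupby("condition", observed=True):
        pm = sub.groupby("progeny", observed=True)["value"].mean()
        kk = len(sub) / n_prog
        ms_pc1 = kk * ((pm - sub["value"].mean()) ** 2).sum() / (n_prog - 1)
        within = sub["value"].to_numpy() - pm.reindex(sub["progeny"]).to_numpy()
        df_w = len(sub) - n_prog
        ms_e1 = (within**2).sum() / df_w if df_w > 0 else 0.0
        vc.per_condition_sigma2_g[cond] = max((ms_pc1 - ms_e1) / kk, 0.0)
    return vc


def fit_variance_components(p: pd.DataFrame, trait: str | None = None) -> VarianceComponents:
    """Estimate (s2g, s2ge, s2e) from a replicated phenotype table.

    Balanced tables use closed-form expected-mean-square estimates;
    unbalanced tables fall back to REML with a warning.  Negative
    estimates are truncated at zero and flagged.
    """
    p = _select_trait(p, trait)
    if p["progeny"].nunique() < 2:
        raise ValueError("need >= 2 progenies")
    if p["condition"].nunique() < 2:
        raise ValueError("need >= 2 conditions (sigma2_ge undefined otherwise)")
    if p.groupby(["progeny", "condition"], observed=True)["value"].count().max() < 2:
        raise ValueError("need >= 2 replicates")
    if np.ptp(p["value"].to_numpy()) == 0.0:
        c = p["condition"].nunique()
        k = int(len(p) / (p["progeny"].nunique() * c))
        return VarianceComponents(
            0.0, 0.0, 0.0, c, k,
            per_condition_sigma2_g={cond: 0.0 for cond in p["condition"].unique()},
            grand_mean=float(p["value"].iloc[0]),
            condition_means={cond: float(p["value"].iloc[0]) for cond in p["condition"].unique()},
        )
    if is_balanced(p):
        return _ems_components(p)
    warnings.warn("unbalanced phenotype table: falling back to REML", stacklevel=2)
    return _reml_components(p)


def cv_g(sigma2_g: float, trait_mean: float) -> float:
    """Genetic coefficient of variation, in percent: 100 * sqrt(s2g) / mean."""
    if sigma2_g < 0:
        raise ValueError("sigma2_g must be >= 0")
    if trait_mean == 0:
        raise ValueError("trait mean must be nonzero")
    return 100.0 * np.sqrt(sigma2_g) / trait_mean


def heritability_broad(vc: VarianceComponents) -> float:
    """Broad-sense heritability on a progeny-mean basis across conditions."""
    if vc.c < 1 or vc.k < 1:
        raise ValueError("c and k must be >= 1")
    denom = vc.sigma2_g + vc.sigma2_ge / vc.c + vc.sigma2_e / (vc.c * vc.k)
    if denom == 0:
        raise ValueError("all variance components are zero; heritability undefined")
    return vc.sigma2_g / denom


def heritability_single_condition(sigma2_g: float, sigma2_e: float, k: int) -> float:
    """Progeny-mean heritability within one condition: s2g / (s2g + s2e/k)."""
    denom = sigma2_g + sigma2_e / k
    if denom == 0:
        raise ValueError("variance components are zero; heritability undefined")
    return sigma2_g / denom


def genetic_correlation(r_p: float, h2_i: float, h2_j: float) -> float:
    """Type-B genetic correlation across two conditions.

    r_g = r_p / sqrt(h2_i * h2_j), truncated into [-1, 1] (reported
    tables conventionally cap the value at 1.00).
    """
    if not -1.0 <= r_p <= 1.0:
        raise ValueError("r_p must be in [-1, 1]")
    if not (0.0 < h2_i <= 1.0 and 0.0 < h2_j <= 1.0):
        raise ValueError("heritabilities must be in (0, 1]")
    return float(np.clip(r_p / np.sqrt(h2_i * h2_j), -1.0, 1.0))


def progeny_blups(p: pd.DataFrame, trait: str | None = None) -> pd.Series:
    """BLUP-adjusted progeny phenotypes for genomic analyses.

    Fits condition as fixed and progeny (and progeny-by-condition) as
    random; returns grand mean + BLUP of the progeny effect, one value
    per progeny.  On balanced data this is the progeny mean shrunken
    toward the grand mean by h2_B.  Deviations from the grand mean sum
    to zero by construction.
    """
    p = _select_trait(p, trait)
    vc = fit_variance_components(p)
    prog_means = p.groupby("progeny", observed=True)["value"].mean()
    grand = p["value"].mean()
    try:
        h2 = heritability_broad(vc)
    except ValueError:
        h2 = 0.0
    adjusted = grand + h2 * (prog_means - prog_means.mean())
    adjusted.name = trait if trait is not None else "adjusted"
    return adjusted


def phenotypic_correlations(adjusted: pd.DataFrame | dict) -> pd.DataFrame:
    """Pearson correlations between per-progeny trait vectors.

    Accepts a progeny x trait frame (or dict of Series sharing a progeny
    index).  Constant traits yield NaN entries and a warning.
    """
    frame = pd.DataFrame(adjusted)
    if frame.isna().any().any():
        raise ValueError("traits must share the progeny set (NaNs after alignment)")
    constant = frame.std(ddof=0) == 0
    if constant.any():
        warnings.warn(
            f"constant traits with undefined correlations: {list(frame.columns[constant])}",
            stacklevel=2,
        )
    corr = frame.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    corr.values[np.ix_(constant.to_numpy(), ~constant.to_numpy())] = np.nan
    corr.values[np.ix_(~constant.to_numpy(), constant.to_numpy())] = np.nan
    return corr
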