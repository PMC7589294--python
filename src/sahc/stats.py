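"""Inference layer: random-intercept mixed models with likelihood-ratio
tests, per-epoch one-way ANOVA with Tukey HSD, chi-squared tests of PSS
frequency, and Pearson correlations between delta responses.

Mixed models are fitted by maximum likelihood (not REML) so that
likelihood-ratio tests between models differing in fixed effects are
valid.  The full model crosses time, rotation-axis position and
foot-level g (all two- and three-way interactions); a reduced model for
an effect drops that effect together with every interaction containing
it.  Position is coded numerically as the axis offset from heart level
in multiples of the heart-to-crown distance (P3 = 0, P2 = 1, P1 = 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import (
    NonNestedModelsError,
    RankDeficiencyError,
    SahcError,
    ZeroVarianceError,
)

#: axis offset from heart level in units of (crown - heart)
POSITION_CODE = {"P1": 2.0, "P2": 1.0, "P3": 0.0}

DEFAULT_FACTORS = ("time", "position_code", "g_foot")


def add_position_code(table: pd.DataFrame, column: str = "position") -> pd.DataFrame:
    """Attach the numeric position code used by the mixed models."""
    out = table.copy()
    out["position_code"] = out[column].map(POSITION_CODE)
    if out["position_code"].isna().any():
        bad = sorted(set(out.loc[out["position_code"].isna(), column]))
        raise SahcError(f"unknown position labels: {bad}")
    return out


def _expand_terms(factors: tuple[str, ...], drop: str | None = None) -> list[str]:
    """All main effects and interactions of ``factors``; with ``drop``,
    remove that factor and every interaction containing it."""
    terms = []
    for r in range(1, len(factors) + 1):
        for combo in combinations(factors, r):
            if drop is not None and drop in combo:
                continue
            terms.append(":".join(combo))
    return terms


def build_formula(
    response: str = "delta",
    factors: tuple[str, ...] = DEFAULT_FACTORS,
    drop: str | None = None,
    interactions: bool = True,
) -> str:
    if interactions:
        terms = _expand_terms(factors, drop=drop)
    else:
        terms = [f for f in factors if f != drop]
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


@dataclass
class LmmFit:
    """Maximum-likelihood random-intercept linear mixed model fit."""

    formula: str
    params: pd.Series  # fixed effects
    bse: pd.Series  # fixed-effect SDs
    random_intercept_var: float
    residual_var: float
    llf: float
    n_obs: int
    n_groups: int
    converged: bool

    @property
    def n_fixed(self) -> int:
        return len(self.params)

    @property
    def fe_names(self) -> tuple[str, ...]:
        return tuple(self.params.index)


def _check_design_rank(model) -> None:
    X = np.asarray(model.exog, dtype=float)
    names = list(model.exog_names)
    rank = np.linalg.matrix_rank(X)
    if rank >= X.shape[1]:
        return
    # identify columns whose removal restores full column rank
    collinear = [
        names[j]
        for j in range(X.shape[1])
        if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
    ]
    raise RankDeficiencyError(
        f"fixed-effect design is rank deficient (rank {rank} < {X.shape[1]}); "
        f"collinear terms: {collinear}",
        collinear=collinear,
    )


def fit_lmm(
    table: pd.DataFrame,
    formula: str | None = None,
    response: str = "delta",
    factors: tuple[str, ...] = DEFAULT_FACTORS,
    groups: str = "participant",
    interactions: bool = True,
) -> LmmFit:
    """Fit a random-intercept linear mixed model by maximum likelihood.

    ``formula`` overrides the default full-factorial fixed-effect
    structure built from ``factors``.  Requires >= 2 groups with >= 2
    observations each.
    """
    if formula is None:
        formula = build_formula(response, factors, interactions=interactions)
    counts = table[groups].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise SahcError("need >= 2 participants with >= 2 observations each")
    model = smf.mixedlm(formula, data=table, groups=table[groups])
    _check_design_rank(model)
    # lbfgs is fastest but can degenerate when the random-intercept
    # variance hits the zero boundary (infinite llf, singular Hessian,
    # garbage betas); fall back to derivative-free optimizers there
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "nm"):
            try:
                result = model.fit(reml=False, method=method)
            except np.linalg.LinAlgError:
                continue
            if np.isfinite(result.llf) and result.converged:
                break
    if result is None or not np.isfinite(result.llf):
        raise SahcError("mixed-model likelihood optimization failed")
    k_fe = model.k_fe
    return LmmFit(
        formula=formula,
        params=result.params.iloc[:k_fe],
        bse=result.bse.iloc[:k_fe],
        random_intercept_var=float(np.asarray(result.cov_re).ravel()[0]),
        residual_var=float(result.scale),
        llf=float(result.llf),
        n_obs=int(model.nobs),
        n_groups=len(counts),
        converged=bool(result.converged),
    )


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test between nested mixed models."""

    effect: str
    statistic: float
    df: int
    pvalue: float


def lrt(full: LmmFit, reduced: LmmFit, effect: str = "") -> LrtResult:
    """LRT of ``full`` against a nested ``reduced`` model.

    Statistic = 2 * (llf_full - llf_reduced); df = fixed-parameter
    difference; p from the upper chi-squared tail.
    """
    full_terms = set(full.fe_names)
    red_terms = set(reduced.fe_names)
    if not red_terms <= full_terms:
        extra = sorted(red_terms - full_terms)
        raise NonNestedModelsError(f"reduced model has terms absent from full: {extra}")
    df = full.n_fixed - reduced.n_fixed
    stat = 2.0 * (full.llf - reduced.llf)
    if stat < -1e-6:
        raise SahcError(f"negative LRT statistic {stat:.3g}: full model fit worse than reduced")
    stat = max(stat, 0.0)
    if df == 0:
        p = 1.0 if stat < 1e-12 else 0.0
    else:
        p = float(sps.chi2.sf(stat, df))
    return LrtResult(effect=effect, statistic=stat, df=df, pvalue=p)


def lmm_effect_test(
    table: pd.DataFrame,
    effect: str,
    response: str = "delta",
    factors: tuple[str, ...] = DEFAULT_FACTORS,
    groups: str = "participant",
    interactions: bool = True,
) -> tuple[LmmFit, LmmFit, LrtResult]:
    """Fit full and effect-reduced models and test the effect by LRT."""
    if effect not in factors:
        raise SahcError(f"effect {effect!r} not among factors {factors}")
    full = fit_lmm(table, response=response, factors=factors, groups=groups,
                   interactions=interactions)
    reduced_formula = build_formula(response, factors, drop=effect, interactions=interactions)
    reduced = fit_lmm(table, formula=reduced_formula, groups=groups)
    return full, reduced, lrt(full, reduced, effect=effect)


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA with Tukey-HSD post hoc comparisons."""

    f_statistic: float
    pvalue: float
    df_between: int
    df_within: int
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject


def epoch_anova_tukey(values: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA across groups (e.g. positions at one epoch/g-level)
    followed by Tukey honestly-significant-difference comparisons."""
    if len(values) < 2:
        raise SahcError("need >= 2 groups")
    for name, v in values.items():
        if len(v) < 2:
            raise SahcError(f"group {name!r} has < 2 observations")
    groups = sorted(values)
    arrays = [np.asarray(values[g], dtype=float) for g in groups]
    f, p = sps.f_oneway(*arrays)
    data = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    tuk = pairwise_tukeyhsd(data, labels, alpha=alpha)
    table = pd.DataFrame(
        tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]]
    )
    n = data.size
    return AnovaTukeyResult(
        f_statistic=float(f),
        pvalue=float(p),
        df_between=len(groups) - 1,
        df_within=n - len(groups),
        tukey=table,
    )


def pss_chi_squared(counts: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared on a PSS+/PSS- by position contingency table.

    ``counts``: rows = positions, columns = (PSS+, PSS-) counts.  No
    continuity correction.
    """
    table = np.asarray(counts, dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise SahcError("counts must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise SahcError("contingency table has an all-zero margin")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def delta_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between paired final-run-minute deltas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise SahcError("need >= 3 paired points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVarianceError("one variable has zero variance; r undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def final_run_delta_table(epoch_table: pd.DataFrame) -> pd.DataFrame:
    """Wide per-run table of final-run-epoch deltas, one column per channel.

    Input is the long epoch table from preprocessing (one row per run,
    channel and epoch).
    """
    run_rows = epoch_table[epoch_table["phase"] == "run"]
    last_epoch = run_rows["epoch"].max()
    final = run_rows[run_rows["epoch"] == last_epoch]
    wide = final.pivot_table(
        index=["run", "participant", "position", "g_foot"],
        columns="channel",
        values="delta",
    ).reset_index()
    wide.columns.name = None
    return wide
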