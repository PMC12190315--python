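"""Inferential layer: distribution comparisons, location tests and
mixed-effects models.

Distribution shapes (pooled lick times, cumulative counts) are compared with
two-sample Kolmogorov-Smirnov tests and visualised with Gaussian KDEs.
Group locations are compared by Mann-Whitney U (reported as a normal-
approximation z) or Welch's t; ``method="auto"`` picks the rank test when a
Shapiro-Wilk test rejects normality in either group at alpha = 0.05, which
mirrors the common practice of mixing the two and can be overridden by
forcing either method.

Intake-versus-behavior relations across repeated sessions are fit with
linear mixed models: the named behaviors and genotype (plus their
interaction) as fixed effects and a random intercept per animal — the
minimal random-effects structure consistent with repeated sessions per
mouse.  The interaction is tested with a Wald F statistic; the denominator
degrees of freedom use the residual (n_obs − rank) convention, recorded in
the result metadata.  Bout-type-by-genotype contrasts use a two-way
mixed-design ANOVA (between = genotype, within = bout type).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import ConvergenceError, ValidationError

_log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float


@dataclass(frozen=True)
class LocationTestResult:
    method: str  # "rank" or "t"
    statistic: float  # z for rank, t for Welch
    p_value: float


@dataclass(frozen=True)
class MixedModelSpec:
    """Formula pieces for a linear mixed model.

    ``fixed_effects`` may contain interaction terms (``"a:b"`` or ``"a*b"``);
    ``grouping`` names the random-intercept factor (the animal).
    """

    response: str
    fixed_effects: tuple[str, ...]
    grouping: str

    def formula(self) -> str:
        return f"{self.response} ~ {' + '.join(self.fixed_effects)}"


@dataclass
class FitResult:
    coefficients: dict[str, float]
    interaction_test: tuple[float, tuple[float, float], float]  # (F, (df1, df2), p)
    random_effect_variance: float
    n_obs: int
    n_groups: int
    metadata: dict = field(default_factory=dict)


@dataclass
class MixedAnovaResult:
    table: pd.DataFrame
    contrasts: dict[str, tuple[float, float]]  # within-level -> (t, p)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> KSResult:
    """Two-sample KS test: sup |ECDF_a - ECDF_b| with the asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue))


def kde(
    values: Sequence[float],
    grid_points: int = 256,
    bandwidth_rule: str = "scott",
    bandwidth: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density on a grid spanning the data +/- 4 bandwidths.

    Returns (grid, density); the density numerically integrates to 1 within
    1e-3 (the 4-bandwidth margin keeps the truncated kernel tails below that
    tolerance).  ``bandwidth_rule="fixed"`` requires an absolute
    ``bandwidth`` in data units.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValidationError("kde requires at least 2 distinct values")
    std = float(np.std(x, ddof=1))
    if bandwidth_rule == "fixed":
        if bandwidth is None or bandwidth <= 0:
            raise ValidationError("fixed bandwidth rule requires bandwidth > 0")
        bw_method = bandwidth / std
    elif bandwidth_rule in ("scott", "silverman"):
        bw_method = bandwidth_rule
    else:
        raise ValidationError(f"unknown bandwidth rule {bandwidth_rule!r}")
    k = sps.gaussian_kde(x, bw_method=bw_method)
    h = k.factor * std
    grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, grid_points)
    return grid, k(grid)


def _rank_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U as a continuity-corrected, tie-corrected normal z."""
    n1, n2 = a.size, b.size
    u1 = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 0.0, 1.0
    sigma = np.sqrt(sigma2)
    diff = u1 - mu
    z = (abs(diff) - 0.5) / sigma
    z = max(z, 0.0) * np.sign(diff) if diff != 0 else 0.0
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def location_test(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> LocationTestResult:
    """Compare two group locations by rank (MWU z) or Welch t."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    if method not in ("auto", "rank", "t"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "auto":
        method = "rank"
        if a.size >= 3 and b.size >= 3:
            normal = True
            for x in (a, b):
                if np.unique(x).size < 2:
                    normal = False
                    break
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if sps.shapiro(x).pvalue < 0.05:
                        normal = False
                        break
            if normal:
                method = "t"
    if method == "t":
        if a.size < 2 or b.size < 2:
            raise ValidationError("Welch t requires n >= 2 in each sample")
        res = sps.ttest_ind(a, b, equal_var=False)
        return LocationTestResult("t", float(res.statistic), float(res.pvalue))
    z, p = _rank_z(a, b)
    return LocationTestResult("rank", z, p)


def fit_mixed_model(table: pd.DataFrame, spec: MixedModelSpec) -> FitResult:
    """Random-intercept linear mixed model fit by REML.

    The interaction test is a Wald F over every fixed-effect column whose
    name contains ``:`` (the patsy interaction expansion); the denominator df
    is ``n_obs - rank`` of the fixed design, recorded in ``metadata``.
    """
    import statsmodels.formula.api as smf

    needed = {spec.response, spec.grouping}
    for term in spec.fixed_effects:
        for name in term.replace("*", ":").split(":"):
            needed.add(name.strip())
    missing = needed - set(table.columns)
    if missing:
        raise ValidationError(f"table missing columns {sorted(missing)}")
    groups = table[spec.grouping]
    n_groups = groups.nunique()
    if n_groups < 2:
        raise ValidationError("mixed model requires >= 2 grouping levels")
    model = smf.mixedlm(spec.formula(), data=table, groups=groups)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        names = list(model.exog_names)
        raise ValidationError(
            f"singular fixed-effect design; columns {names} have rank {rank}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"mixed model failed to converge: {exc}") from exc
    interaction_names = [n for n in fit.fe_params.index if ":" in n]
    if not interaction_names:
        raise ValidationError(
            "no interaction term in fixed effects; include 'a*b' or 'a:b'"
        )
    n_obs = int(model.exog.shape[0])
    df_den = float(n_obs - rank)
    df_num = float(len(interaction_names))
    b = fit.fe_params[interaction_names].to_numpy()
    cov = fit.cov_params().loc[interaction_names, interaction_names].to_numpy()
    if np.all(np.isfinite(cov)) and np.linalg.cond(cov) < 1e12:
        fstat = float(b @ np.linalg.solve(cov, b) / df_num)
        p = float(sps.f.sf(fstat, df_num, df_den))
    elif np.allclose(b, 0.0):
        # degenerate (noise-free) fit with a zero interaction
        fstat, p = 0.0, 1.0
    else:
        # noise-free fit: a nonzero contrast against zero residual variance
        fstat, p = math.inf, 0.0
    return FitResult(
        coefficients={k: float(v) for k, v in fit.fe_params.items()},
        interaction_test=(fstat, (df_num, df_den), p),
        random_effect_variance=float(np.asarray(fit.cov_re)[0, 0]),
        n_obs=n_obs,
        n_groups=int(n_groups),
        metadata={
            "method": "reml",
            "df_method": "wald_f_residual",
            "interaction_terms": interaction_names,
            "converged": bool(fit.converged),
            "coefficient_se": {
                k: float(v) for k, v in fit.bse_fe.items()
            },
        },
    )


def mixed_anova(
    table: pd.DataFrame, dv: str, within: str, between: str, subject: str
) -> MixedAnovaResult:
    """Two-way mixed-design ANOVA (between-subjects x within-subjects).

    Every subject must be observed at every within level; missing cells are
    a validation error listing them.  Per-within-level Welch t contrasts
    between the two between-group levels accompany the omnibus table.
    """
    import pingouin as pg

    for col in (dv, within, between, subject):
        if col not in table.columns:
            raise ValidationError(f"table missing column {col!r}")
    levels = sorted(table[within].unique())
    missing_cells = []
    for subj, sub in table.groupby(subject):
        have = set(sub[within])
        for lev in levels:
            if lev not in have:
                missing_cells.append((subj, lev))
    if missing_cells:
        raise ValidationError(
            f"unbalanced within-structure; missing (subject, {within}) cells: "
            f"{missing_cells}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=table, dv=dv, within=within, between=between, subject=subject
        )
    contrasts: dict[str, tuple[float, float]] = {}
    group_levels = sorted(table[between].unique())
    if len(group_levels) == 2:
        g0, g1 = group_levels
        for lev in levels:
            sub = table[table[within] == lev]
            a = sub.loc[sub[between] == g0, dv].to_numpy(dtype=float)
            b = sub.loc[sub[between] == g1, dv].to_numpy(dtype=float)
            if a.size >= 2 and b.size >= 2:
                res = sps.ttest_ind(a, b, equal_var=False)
                contrasts[str(lev)] = (float(res.statistic), float(res.pvalue))
    return MixedAnovaResult(table=aov, contrasts=contrasts)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; no correction is applied by default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
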