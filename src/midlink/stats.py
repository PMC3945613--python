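"""Repeated-measures ANOVA, Dunnett many-to-one comparisons, permutation p-values.

Implements the statistical procedures used throughout the behavioral
pipeline from first principles (sum-of-squares decompositions, F reference
distributions, Monte-Carlo multivariate-t integration for Dunnett), rather
than delegating to a statistics package.  Designs must be complete and
balanced; unbalanced input is rejected, never silently averaged.

No sphericity correction is applied by default; a Greenhouse-Geisser
option is available on the one-way RM ANOVA for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "AnovaOutcome",
    "DunnettComparison",
    "DunnettReport",
    "rm_anova_oneway",
    "rm_anova_mixed",
    "dunnett",
    "permutation_p",
]


@dataclass(frozen=True)
class AnovaEffect:
    """One row of an ANOVA table: an effect tested against a named error stratum."""

    name: str
    ss: float
    df: int
    ms: float
    F: float
    p: float
    error_stratum: str

    def to_dict(self) -> dict:
        return {
            "effect": self.name,
            "ss": self.ss,
            "df": self.df,
            "ms": self.ms,
            "F": self.F,
            "p": self.p,
            "error_stratum": self.error_stratum,
        }


@dataclass(frozen=True)
class AnovaOutcome:
    """ANOVA table plus the error strata it was computed from."""

    effects: tuple[AnovaEffect, ...]
    error_strata: Mapping[str, tuple[float, int]]  # name -> (SS, df)

    def effect(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "effects": [e.to_dict() for e in self.effects],
            "error_strata": {k: {"ss": v[0], "df": v[1]} for k, v in self.error_strata.items()},
        }


_TINY = float(np.finfo(float).tiny)


def _f_p(F: float, df1: int, df2: int) -> float:
    """Upper-tail F p-value; F = 0 maps to p = 1 exactly.

    Floored at the smallest positive float so p stays in (0, 1] even
    when the survival function underflows.
    """
    if F == 0.0:
        return 1.0
    return max(float(sps.f.sf(F, df1, df2)), _TINY)


def _as_grid(data: np.ndarray, min_subjects: int = 2, min_levels: int = 2) -> np.ndarray:
    a = np.asarray(data, dtype=float)
    if a.ndim != 2:
        raise ValueError("design grid must be 2-D (subjects x conditions)")
    if not np.all(np.isfinite(a)):
        raise ValueError("design grid has missing or non-finite cells; balanced complete designs only")
    if a.shape[0] < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects, got {a.shape[0]}")
    if a.shape[1] < min_levels:
        raise ValueError(f"need at least {min_levels} condition levels, got {a.shape[1]}")
    return a


def rm_anova_oneway(data: np.ndarray, gg_correction: bool = False) -> AnovaOutcome:
    """One-way repeated-measures ANOVA on a subjects x conditions grid.

    Partitions total SS into condition, subject and residual strata;
    ``F = MS_condition / MS_residual`` with (C-1, (S-1)(C-1)) df.

    Parameters
    ----------
    data
        2-D array, rows = subjects (blocks), columns = condition levels.
        Every cell must be present (complete balanced design).
    gg_correction
        Apply the Greenhouse-Geisser epsilon to the degrees of freedom
        (off by default).
    """
    a = _as_grid(data)
    s, c = a.shape
    grand = a.mean()
    ss_total = float(((a - grand) ** 2).sum())
    ss_cond = float(s * ((a.mean(axis=0) - grand) ** 2).sum())
    ss_subj = float(c * ((a.mean(axis=1) - grand) ** 2).sum())
    ss_resid = max(ss_total - ss_cond - ss_subj, 0.0)
    df_cond, df_subj, df_resid = c - 1, s - 1, (s - 1) * (c - 1)
    ms_cond = ss_cond / df_cond
    ms_resid = ss_resid / df_resid

    df1, df2 = df_cond, df_resid
    if gg_correction:
        eps = _gg_epsilon(a)
        df1, df2 = df1 * eps, df2 * eps

    if ss_cond == 0.0:
        F, p = 0.0, 1.0
    elif ms_resid == 0.0:
        F, p = float("inf"), _TINY
    else:
        F = ms_cond / ms_resid
        p = max(float(sps.f.sf(F, df1, df2)), _TINY)
    effects = (
        AnovaEffect("condition", ss_cond, df_cond, ms_cond, F, p, "residual"),
    )
    return AnovaOutcome(effects, {"subject": (ss_subj, df_subj), "residual": (ss_resid, df_resid)})


def _gg_epsilon(a: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the condition covariance matrix."""
    c = a.shape[1]
    S = np.cov(a, rowvar=False)
    d = S - S.mean(axis=0)[None, :] - S.mean(axis=1)[:, None] + S.mean()
    num = np.trace(d) ** 2
    den = (c - 1) * (d**2).sum()
    return float(np.clip(num / den, 1.0 / (c - 1), 1.0))


def rm_anova_mixed(groups: Mapping[str, np.ndarray]) -> AnovaOutcome:
    """Mixed-design (split-plot) two-way ANOVA.

    Between factor = group (e.g. genotype), within factor = repeated level
    (e.g. time bin), subject nested in group.  The group effect is tested
    against subjects-within-groups; the within effect and the interaction
    against the residual.

    Parameters
    ----------
    groups
        Mapping group label -> 2-D array (subjects x within-levels).
        All groups must share the same within-level grid and (balanced
        design) the same number of subjects.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for the between factor")
    mats = {k: _as_grid(v, min_levels=1) for k, v in groups.items()}
    shapes = {m.shape for m in mats.values()}
    if len({sh[1] for sh in shapes}) != 1:
        raise ValueError("groups disagree on the within-subject level grid")
    if len({sh[0] for sh in shapes}) != 1:
        raise ValueError("unbalanced design: groups have unequal subject counts")
    g = len(mats)
    n, t = next(iter(mats.values())).shape
    if t < 2:
        raise ValueError("within factor needs at least 2 levels (not a repeated-measures design)")
    stack = np.stack([mats[k] for k in mats])  # (g, n, t)
    N = g * n
    grand = stack.mean()
    ss_total = float(((stack - grand) ** 2).sum())

    subj_means = stack.mean(axis=2)  # (g, n)
    grp_means = stack.mean(axis=(1, 2))  # (g,)
    time_means = stack.mean(axis=(0, 1))  # (t,)
    cell_means = stack.mean(axis=1)  # (g, t)

    ss_between_subj = float(t * ((subj_means - grand) ** 2).sum())
    ss_group = float(n * t * ((grp_means - grand) ** 2).sum())
    ss_subj_within = max(ss_between_subj - ss_group, 0.0)
    ss_time = float(N * ((time_means - grand) ** 2).sum())
    ss_inter = float(
        n * ((cell_means - grp_means[:, None] - time_means[None, :] + grand) ** 2).sum()
    )
    ss_resid = max(ss_total - ss_group - ss_subj_within - ss_time - ss_inter, 0.0)

    df_group, df_sw = g - 1, N - g
    df_time, df_inter, df_resid = t - 1, (g - 1) * (t - 1), (N - g) * (t - 1)
    ms_sw = ss_subj_within / df_sw
    ms_resid = ss_resid / df_resid

    def eff(name, ss, df, ms_err, df_err, stratum):
        ms = ss / df
        if ss == 0.0:
            F, p = 0.0, 1.0
        elif ms_err == 0.0:
            F, p = float("inf"), _TINY
        else:
            F = ms / ms_err
            p = _f_p(F, df, df_err)
        return AnovaEffect(name, ss, df, ms, F, p, stratum)

    effects = (
        eff("group", ss_group, df_group, ms_sw, df_sw, "subjects_within_groups"),
        eff("within", ss_time, df_time, ms_resid, df_resid, "residual"),
        eff("group_x_within", ss_inter, df_inter, ms_resid, df_resid, "residual"),
    )
    return AnovaOutcome(
        effects,
        {"subjects_within_groups": (ss_subj_within, df_sw), "residual": (ss_resid, df_resid)},
    )


@dataclass(frozen=True)
class DunnettComparison:
    level: str
    mean_diff: float
    se: float
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "mean_diff": self.mean_diff,
            "se": self.se,
            "t": self.t,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class DunnettReport:
    control: str
    comparisons: tuple[DunnettComparison, ...]
    alpha: float
    df_error: int
    n_mc: int

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.comparisons)

    def to_dict(self) -> dict:
        return {
            "control": self.control,
            "alpha": self.alpha,
            "df_error": self.df_error,
            "n_mc": self.n_mc,
            "comparisons": [c.to_dict() for c in self.comparisons],
        }


def dunnett_maxt_sf(t_obs: np.ndarray, k: int, df: int, n_mc: int, seed: int) -> np.ndarray:
    """P(max_i |T_i| >= |t_j|) for k equicorrelated (rho = 0.5) t variates.

    Monte-Carlo integration: Z_i = (X_i + X_0)/sqrt(2) with a shared
    standard-normal X_0 gives the exchangeable rho = 0.5 structure of
    balanced many-to-one contrasts; dividing by sqrt(chi2_df / df) yields
    the joint t scale.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal(n_mc)
    x = rng.standard_normal((n_mc, k))
    z = (x + x0[:, None]) / np.sqrt(2.0)
    w = np.sqrt(rng.chisquare(df, n_mc) / df)
    max_abs_t = np.abs(z).max(axis=1) / w
    t_obs = np.abs(np.asarray(t_obs, dtype=float))
    # add-one keeps the estimate in (0, 1]
    return (1.0 + (max_abs_t[None, :] >= t_obs[:, None]).sum(axis=1)) / (1.0 + n_mc)


def dunnett(
    data: np.ndarray,
    level_names: Sequence[str],
    control: str,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
) -> DunnettReport:
    """Dunnett many-to-one comparisons within a blocked (RM) design.

    Each non-control level is compared two-sidedly with the control using
    the pooled residual error of the one-way RM decomposition.  Adjusted
    p-values come from the joint distribution of the k correlated t
    statistics (equicorrelation 0.5 in a balanced design) via Monte-Carlo
    multivariate-t integration, floored at the raw t p-value so that
    ``p_adjusted >= p_raw`` holds on every run.

    Parameters
    ----------
    data
        blocks x levels response grid (complete, balanced).
    level_names
        Column labels of ``data``.
    control
        Label of the control level; every other level is compared to it.
    """
    a = _as_grid(data)
    names = list(level_names)
    if len(names) != a.shape[1]:
        raise ValueError("level_names length does not match grid columns")
    if control not in names:
        raise ValueError(f"control level {control!r} not present in {names}")
    s, c = a.shape
    ctrl_idx = names.index(control)
    others = [i for i in range(c) if i != ctrl_idx]
    k = len(others)

    # pooled residual error from the blocks x levels RM decomposition
    grand = a.mean()
    ss_total = ((a - grand) ** 2).sum()
    ss_cond = s * ((a.mean(axis=0) - grand) ** 2).sum()
    ss_blk = c * ((a.mean(axis=1) - grand) ** 2).sum()
    df_err = (s - 1) * (c - 1)
    ms_err = max(ss_total - ss_cond - ss_blk, 0.0) / df_err
    se = float(np.sqrt(2.0 * ms_err / s))

    means = a.mean(axis=0)
    diffs = means[others] - means[ctrl_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = np.where(se > 0, diffs / se, np.sign(diffs) * np.inf)
    tstats = np.where((se == 0) & (diffs == 0), 0.0, tstats)
    p_raw = np.maximum(2.0 * sps.t.sf(np.abs(tstats), df_err), _TINY)
    p_adj = dunnett_maxt_sf(tstats, k, df_err, n_mc, seed)
    p_adj = np.maximum(p_adj, np.minimum(p_raw, 1.0))

    comps = tuple(
        DunnettComparison(
            level=names[i],
            mean_diff=float(d),
            se=se,
            t=float(t),
            p_raw=float(min(pr, 1.0)),
            p_adjusted=float(pa),
            significant=bool(pa < alpha),
        )
        for i, d, t, pr, pa in zip(others, diffs, tstats, p_raw, p_adj)
    )
    return DunnettReport(control=control, comparisons=comps, alpha=alpha, df_error=df_err, n_mc=n_mc)


def permutation_p(
    observed: float,
    null_draws: Sequence[float],
    alternative: Literal["greater", "less", "two-sided"] = "greater",
) -> float:
    """Add-one permutation p-value; ties count toward the null (conservative).

    ``p = (1 + #{null >= observed}) / (1 + n)`` for the one-sided
    "greater" alternative; "two-sided" doubles the smaller tail, capped
    at 1.  Guarantees ``p >= 1/(n+1)`` and ``p <= 1``.
    """
    null = np.asarray(null_draws, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    n = null.size
    p_hi = (1.0 + (null >= observed).sum()) / (1.0 + n)
    p_lo = (1.0 + (null <= observed).sum()) / (1.0 + n)
    if alternative == "greater":
        return float(p_hi)
    if alternative == "less":
        return float(p_lo)
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * min(p_hi, p_lo)))
    raise ValueError(f"unknown alternative {alternative!r}")
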