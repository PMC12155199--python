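"""Longitudinal inference over trial timepoints.

The trial records each measure at up to four timepoints (BSL, T1, T2, T3)
per participant.  Complete data are analysed with a one-way
repeated-measures ANOVA whose degrees of freedom are deflated by the
Greenhouse-Geisser epsilon to guard against sphericity violations.  Data
with missing timepoints are analysed with a linear mixed model (random
intercept per participant, categorical timepoint fixed effect) fitted by
REML, whose Wald F for the time effect coincides with the RM ANOVA F on
complete balanced data.  Comparisons of each later timepoint against
baseline are adjusted for multiplicity with Dunnett's many-to-one method
on the within-participant change scores.  Group × time interactions
(onset or responder subsets) use the same mixed-model machinery.

All p-values are two-sided; the trial's significance threshold is 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

ALPHA = 0.05


@dataclass
class StatTestResult:
    """An omnibus F test with sphericity-corrected degrees of freedom."""

    F: float
    df_num: float
    df_den: float
    p: float
    epsilon: float | None = None
    method: str = ""
    converged: bool = True


@dataclass
class DunnettContrast:
    """One timepoint-vs-baseline contrast with its multiplicity adjustment."""

    timepoint: str
    estimate: float     # mean change from baseline
    t: float
    df: float
    n: int
    p_unadjusted: float
    p_adjusted: float


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W statistic and p-value).

    Requires at least three finite, non-constant observations.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3 finite values")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k × k timepoint covariance matrix.

    Equals 1 for perfectly spherical covariance and is floored at
    1/(k − 1); for k = 2 it is exactly 1.
    """
    k = cov.shape[0]
    if k < 2:
        raise ValueError("need at least 2 timepoints")
    if k == 2:
        return 1.0
    centerer = np.eye(k) - np.ones((k, k)) / k
    s = centerer @ cov @ centerer
    tr = np.trace(s)
    denom = (k - 1) * np.sum(s * s)
    if denom <= 0:
        return 1.0
    eps = tr * tr / denom
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def rm_anova_gg(matrix: np.ndarray) -> StatTestResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    Parameters
    ----------
    matrix
        Complete participants × timepoints array (no missing cells).

    Returns
    -------
    :class:`StatTestResult` with the within-subject F for the time effect,
    epsilon-deflated degrees of freedom, and the corrected p-value.
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("matrix must be participants x timepoints with >= 2 timepoints")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    if not np.all(np.isfinite(y)):
        raise ValueError("missing cells: use mixed_model_reml for incomplete data")
    n, k = y.shape
    grand = y.mean()
    ss_time = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_err = np.sum((y - grand) ** 2) - ss_time - ss_subj
    df_time, df_err = k - 1, (n - 1) * (k - 1)
    ms_err = ss_err / df_err
    if ms_err == 0:
        # all residual variation zero: F degenerate
        f = 0.0 if ss_time == 0 else np.inf
    else:
        f = (ss_time / df_time) / ms_err
    eps = gg_epsilon(np.cov(y, rowvar=False))
    p = float(stats.f.sf(f, df_time * eps, df_err * eps)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0
    return StatTestResult(F=float(f), df_num=df_time * eps, df_den=df_err * eps,
                          p=p, epsilon=eps, method="rm_anova_gg")


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: pd.Series):
    """REML fit with a tight-tolerance optimizer and a robust fallback."""
    model = smf.mixedlm(formula, data, groups=groups)
    fits = []
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # the converged flag is unreliable near the variance boundary, so
        # candidates are ranked by restricted log-likelihood instead
        try:
            r = model.fit(reml=True, method="cg", gtol=1e-12, maxiter=2000)
            fits.append(r)
            try:
                fits.append(model.fit(reml=True, method="bfgs", gtol=1e-12,
                                      maxiter=200, start_params=r.params_object))
            except Exception:
                pass
        except Exception as exc:
            last_exc = exc
        if not any(np.isfinite(r.llf) for r in fits):
            for kw in (dict(method="lbfgs", maxiter=2000),
                       dict(method="powell", xtol=1e-10, ftol=1e-10, maxiter=5000)):
                try:
                    fits.append(model.fit(reml=True, **kw))
                except Exception as exc:
                    last_exc = exc
    fits = [r for r in fits if np.isfinite(r.llf)]
    if not fits:
        raise RuntimeError(f"mixed model fit failed: {last_exc}")
    return max(fits, key=lambda r: r.llf)


def _wald_f(res, term_idx: list[int], df_den: float) -> tuple[float, float]:
    """Joint Wald F for a set of fixed-effect coefficients."""
    n_par = len(res.params)
    L = np.zeros((len(term_idx), n_par))
    for r, i in enumerate(term_idx):
        L[r, i] = 1.0
    chi2 = float(np.squeeze(res.wald_test(L, scalar=False).statistic))
    q = len(term_idx)
    f = chi2 / q
    return f, q


def _complete_case_epsilon(long: pd.DataFrame, timepoints: list[str]) -> float:
    """GG epsilon estimated from complete-case participants (1 if too few)."""
    wide = long.pivot_table(index="participant", columns="timepoint",
                            values="value", aggfunc="first")
    wide = wide.reindex(columns=timepoints).dropna()
    if len(wide) < len(timepoints):
        return 1.0
    return gg_epsilon(np.cov(wide.to_numpy(), rowvar=False))


def _as_long(data: pd.DataFrame) -> pd.DataFrame:
    need = {"participant", "timepoint", "value"}
    if not need.issubset(data.columns):
        raise ValueError(f"long data must have columns {sorted(need)}")
    out = data.dropna(subset=["value"]).copy()
    out["timepoint"] = out["timepoint"].astype(str)
    return out


def mixed_model_reml(data: pd.DataFrame, apply_gg: bool = True) -> StatTestResult:
    """Omnibus time-effect test from a REML linear mixed model.

    The model has a categorical timepoint fixed effect and a random
    intercept per participant — the minimal structure that behaves like a
    repeated-measures ANOVA while tolerating missing timepoints.  The Wald
    F for the time effect uses containment (between-within) denominator
    degrees of freedom, N_obs − n_participants − (k − 1); on complete
    balanced data it equals the RM ANOVA F.  When ``apply_gg`` is set the
    degrees of freedom are deflated by a Greenhouse-Geisser epsilon
    estimated from complete-case participants.

    Parameters
    ----------
    data
        Long format with columns ``participant``, ``timepoint``, ``value``;
        NaN values are dropped.
    """
    long = _as_long(data)
    timepoints = sorted(long["timepoint"].unique())
    k = len(timepoints)
    if k < 2:
        raise ValueError("need >= 2 timepoints with data")
    for tp in timepoints:
        if (long["timepoint"] == tp).sum() == 0:
            raise ValueError(f"timepoint {tp} has no observations")
    res = _fit_mixedlm("value ~ C(timepoint)", long, long["participant"])
    names = list(res.params.index)
    term_idx = [i for i, nm in enumerate(names) if nm.startswith("C(timepoint)")]
    n_sub = long["participant"].nunique()
    df_den = len(long) - n_sub - (k - 1)
    f, q = _wald_f(res, term_idx, df_den)
    eps = _complete_case_epsilon(long, timepoints) if apply_gg else 1.0
    p = float(stats.f.sf(f, q * eps, df_den * eps))
    return StatTestResult(F=f, df_num=q * eps, df_den=df_den * eps, p=p,
                          epsilon=eps, method="mixed_model_reml",
                          converged=bool(res.converged))


def dunnett_vs_baseline(
    matrix: np.ndarray,
    timepoints: list[str] | None = None,
    seed: int = 0,
) -> list[DunnettContrast]:
    """Within-participant comparisons of each later timepoint to baseline,
    adjusted with Dunnett's many-to-one method.

    Each contrast is a paired t test of the change from the baseline column
    (column 0), using the participants observed at both ends.  Adjusted
    p-values come from the equicoordinate multivariate t distribution with
    the balanced many-to-one correlation structure (0.5 between contrasts),
    evaluated by seeded quasi-Monte Carlo integration (absolute tolerance
    about 1e-4).  With a single contrast the adjustment degenerates to the
    paired t test.

    Parameters
    ----------
    matrix
        Participants × timepoints array; NaN marks a missed timepoint.
    timepoints
        Column labels; defaults to BSL, T1, ...
    seed
        Seed for the quasi-Monte Carlo integration (bit-reproducible).
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a baseline column and at least one later timepoint")
    k = y.shape[1]
    if timepoints is None:
        timepoints = ["BSL"] + [f"T{i}" for i in range(1, k)]
    m = k - 1

    raw = []
    for j in range(1, k):
        d = y[:, j] - y[:, 0]
        d = d[np.isfinite(d)]
        n = d.size
        if n < 2:
            raise ValueError(f"contrast {timepoints[j]} vs baseline has n < 2 paired observations")
        se = d.std(ddof=1) / np.sqrt(n)
        t = d.mean() / se if se > 0 else np.inf * np.sign(d.mean() or 1)
        raw.append((timepoints[j], float(d.mean()), float(t), n))

    df = min(n for *_, n in raw) - 1
    shape = np.full((m, m), 0.5) + 0.5 * np.eye(m)
    rng = np.random.default_rng(seed)
    out = []
    for tp, est, t, n in raw:
        p_un = 2.0 * float(stats.t.sf(abs(t), n - 1))
        if m == 1:
            p_adj = p_un
        else:
            mvt = stats.multivariate_t(shape=shape, df=df)
            inside = float(mvt.cdf(np.full(m, abs(t)), lower_limit=np.full(m, -abs(t)),
                                   random_state=rng))
            p_adj = min(1.0, max(1.0 - inside, p_un))
        out.append(DunnettContrast(timepoint=tp, estimate=est, t=t, df=float(n - 1),
                                   n=n, p_unadjusted=min(1.0, p_un), p_adjusted=p_adj))
    return out


def two_way_interaction(
    data: pd.DataFrame,
    apply_gg: bool = True,
    min_group_n: int = 2,
) -> StatTestResult:
    """Group × time interaction test for subset analyses.

    Fits the mixed model ``value ~ group * timepoint`` with a random
    intercept per participant by REML and reports the Wald F for the
    interaction terms with containment denominator degrees of freedom
    ((k − 1)(n − g) on balanced data), GG-deflated like the omnibus test.
    Groups with fewer than ``min_group_n`` participants are dropped with a
    warning.

    Parameters
    ----------
    data
        Long format with columns ``participant``, ``timepoint``, ``value``,
        ``group``.
    """
    long = _as_long(data)
    if "group" not in long.columns:
        raise ValueError("long data must carry a 'group' column")
    long["group"] = long["group"].astype(str)
    sizes = long.groupby("group")["participant"].nunique()
    small = sizes[sizes < min_group_n].index.tolist()
    if small:
        warnings.warn(f"dropping groups with < {min_group_n} participants: {small}", stacklevel=2)
        long = long[~long["group"].isin(small)]
    groups = sorted(long["group"].unique())
    timepoints = sorted(long["timepoint"].unique())
    g, k = len(groups), len(timepoints)
    if g < 2:
        raise ValueError("interaction test needs >= 2 groups")
    if k < 2:
        raise ValueError("interaction test needs >= 2 timepoints")

    res = _fit_mixedlm("value ~ C(group) * C(timepoint)", long, long["participant"])
    names = list(res.params.index)
    term_idx = [i for i, nm in enumerate(names) if ":" in nm and nm.startswith("C(group)")]
    n_sub = long["participant"].nunique()
    df_den = len(long) - n_sub - (k - 1) * (g - 1) - (k - 1)
    f, q = _wald_f(res, term_idx, df_den)
    eps = _complete_case_epsilon(long, timepoints) if apply_gg else 1.0
    p = float(stats.f.sf(f, q * eps, df_den * eps))
    return StatTestResult(F=f, df_num=q * eps, df_den=df_den * eps, p=p,
                          epsilon=eps, method="two_way_interaction",
                          converged=bool(res.converged))


def groupwise_dunnett(
    data: pd.DataFrame,
    timepoints: list[str],
    seed: int = 0,
) -> dict[str, list[DunnettContrast]]:
    """Within-group Dunnett contrasts vs baseline, one family per group."""
    long = _as_long(data)
    out: dict[str, list[DunnettContrast]] = {}
    for gname, sub in long.groupby("group"):
        wide = sub.pivot_table(index="participant", columns="timepoint",
                               values="value", aggfunc="first")
        wide = wide.reindex(columns=timepoints)
        try:
            out[str(gname)] = dunnett_vs_baseline(wide.to_numpy(), timepoints, seed=seed)
        except ValueError as exc:
            warnings.warn(f"group {gname}: {exc}", stacklevel=2)
    return out


def qq_residuals(residuals) -> tuple[np.ndarray, np.ndarray]:
    """Theoretical vs sample quantile pairs for a QQ plot of residuals.

    Returns standard-normal theoretical quantiles (Blom plotting positions)
    paired with the ordered residuals; makes no accept/reject decision.
    """
    r = np.asarray(residuals, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no residuals to plot")
    order = np.sort(r)
    n = r.size
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    return stats.norm.ppf(probs), order
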