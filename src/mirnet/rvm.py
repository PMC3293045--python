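"""Random-variance-model moderated F-test for small-sample staged designs.

Per-feature residual variances in a k-group one-way layout are modelled as
exchangeable: the inverse variance 1/sigma^2 follows a Gamma(a, b) prior
(shape a, scale b) fitted across all features by maximum likelihood. Under the
model the scaled residual variance s^2 * a * b follows an F(df, 2a)
distribution, which is the fitting likelihood. Testing then replaces the
per-feature variance with the shrunken

    sigma~^2 = ((n - k) * s^2 + 2/b) / ((n - k) + 2a)

and refers MS_between / sigma~^2 to F(k - 1, n - k + 2a); the prior is worth
2a extra denominator degrees of freedom, which is where the method's power at
n of 4-6 per group comes from. As a -> 0 and 2/b -> 0 the moderated statistic
collapses to the classical one-way ANOVA F.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .data_io import DataError, ExpressionMatrix, StageDesign

logger = logging.getLogger("mirnet")

_A_BOUNDARY = 1e5  # shape estimates beyond this are an at-the-boundary fit


class RVMConvergenceError(RuntimeError):
    """Prior fit failed; carries the last iterate and gradient norm."""

    def __init__(self, message: str, last_iterate=None, gradient_norm=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.gradient_norm = gradient_norm


@dataclass(frozen=True)
class RVMPrior:
    """Gamma(a, b) prior on the inverse residual variance (shape a, scale b)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b) and self.a > 0 and self.b > 0):
            raise DataError(f"RVM prior needs finite a>0, b>0; got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class RVMPriorFit:
    prior: RVMPrior
    converged: bool
    boundary: bool
    log_likelihood: float
    n_used: int
    n_zero_excluded: int


def rvm_negative_log_likelihood(log_ab: np.ndarray, variances: np.ndarray, df: float) -> float:
    """NLL of residual variances under s^2 * a * b ~ F(df, 2a)."""
    a, b = np.exp(log_ab)
    c = a * b
    ll = np.log(c) + stats.f.logpdf(c * variances, df, 2.0 * a)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(ll.sum())


def fit_rvm_prior(residual_variances: np.ndarray, df: float) -> RVMPriorFit:
    """Maximum-likelihood fit of the inverse-variance Gamma prior.

    Zero variances are excluded (and counted); fewer than 50 usable features
    triggers a warning. The optimisation is deterministic: Nelder-Mead from a
    fixed starting point in log-parameter space, polished by the likelihood
    value check against the start.
    """
    v = np.asarray(residual_variances, dtype=float)
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise DataError("residual variances must be finite and non-negative")
    n_zero = int((v == 0).sum())
    v = v[v > 0]
    if v.size == 0:
        raise DataError("no positive residual variances to fit")
    if v.size < 50:
        logger.warning("fitting RVM prior on only %d features; estimates may be unstable", v.size)

    x0 = np.log([1.0, 1.0 / np.mean(v)])  # start: a=1, b matched to mean variance
    res = optimize.minimize(
        rvm_negative_log_likelihood, x0, args=(v, float(df)),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
    )
    grad = optimize.approx_fprime(res.x, rvm_negative_log_likelihood, 1e-6, v, float(df))
    if not res.success or not np.all(np.isfinite(res.x)):
        raise RVMConvergenceError(
            f"RVM prior fit did not converge: {res.message}",
            last_iterate=np.exp(res.x), gradient_norm=float(np.linalg.norm(grad)),
        )
    a_hat, b_hat = np.exp(res.x)
    boundary = bool(a_hat > _A_BOUNDARY or a_hat < 1.0 / _A_BOUNDARY)
    if boundary:
        logger.warning("RVM prior shape a=%.3g at boundary; variances look degenerate", a_hat)
    return RVMPriorFit(
        prior=RVMPrior(a=float(a_hat), b=float(b_hat)),
        converged=not boundary,
        boundary=boundary,
        log_likelihood=-float(res.fun),
        n_used=int(v.size),
        n_zero_excluded=n_zero,
    )


@dataclass
class DifferentialTable:
    """Per-feature moderated-F results plus per-stage contrasts vs reference."""

    table: pd.DataFrame  # f_raw, f_rvm, df1, df2, p_value, q_value, lfc_<stage>..., flag
    prior: RVMPrior
    design: StageDesign

    def significant(self, p_cut: float = 0.05, q_cut: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[(t["p_value"] < p_cut) & (t["q_value"] < q_cut)]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_stats(matrix: ExpressionMatrix, design: StageDesign):
    """Per-feature group means, pooled within-group variance and complete-case mask."""
    X = matrix.values
    stages = design.stages
    sample_idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    cols = {st: [sample_idx[s] for s in design.samples_in(st) if s in sample_idx] for st in stages}
    missing_stage = [st for st, c in cols.items() if len(c) == 0]
    if missing_stage:
        raise DataError(f"stages with no samples in the matrix: {missing_stage}")
    used_cols = sorted(c for cc in cols.values() for c in cc)
    complete = ~np.isnan(X[:, used_cols]).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropping %d features with missing values in tested samples", n_dropped)

    n = len(used_cols)
    k = len(stages)
    means = np.full((X.shape[0], k), np.nan)
    ss_within = np.zeros(X.shape[0])
    for j, st in enumerate(stages):
        sub = X[:, cols[st]]
        means[:, j] = sub.mean(axis=1)
        ss_within += ((sub - means[:, [j]]) ** 2).sum(axis=1)
    n_per = np.array([len(cols[st]) for st in stages], dtype=float)
    grand = (means * n_per).sum(axis=1) / n
    ms_between = ((n_per * (means - grand[:, None]) ** 2).sum(axis=1)) / (k - 1)
    s2 = ss_within / (n - k)
    return means, ms_between, s2, complete, n, k, cols


def rvm_f_test(matrix: ExpressionMatrix, design: StageDesign,
               prior: RVMPrior | None = None) -> DifferentialTable:
    """Moderated one-way F screen across the staged design.

    When ``prior`` is None it is fitted on the matrix's own residual variances.
    Features with missing values in tested samples are dropped from testing;
    features with zero between- and within-group variance get p = 1, flagged.
    """
    if len(design.stages) < 2:
        raise DataError("need at least 2 groups")
    means, ms_between, s2, complete, n, k, _ = _group_stats(matrix, design)
    if prior is None:
        prior = fit_rvm_prior(s2[complete & (s2 > 0)], df=n - k).prior

    df1 = k - 1
    df2 = (n - k) + 2.0 * prior.a
    s2_mod = ((n - k) * s2 + 2.0 / prior.b) / ((n - k) + 2.0 * prior.a)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_raw = ms_between / s2
        f_rvm = ms_between / s2_mod
    p = stats.f.sf(f_rvm, df1, df2)

    flag = np.where(complete, "", "missing_dropped")
    degenerate = complete & (ms_between == 0) & (s2 == 0)
    p = np.where(degenerate, 1.0, p)
    flag = np.where(degenerate, "zero_variance", flag)
    p = np.where(complete, p, np.nan)

    q = np.full_like(p, np.nan)
    tested = complete
    q[tested] = bh_fdr(p[tested])

    ref_j = design.stages.index(design.reference_stage)
    out = pd.DataFrame(
        {
            "f_raw": np.where(complete, f_raw, np.nan),
            "f_rvm": np.where(complete, f_rvm, np.nan),
            "df1": df1,
            "df2": df2,
            "p_value": p,
            "q_value": q,
            "flag": flag,
        },
        index=matrix.data.index,
    )
    for j, st in enumerate(design.stages):
        if st == design.reference_stage:
            continue
        out[f"lfc_{st}"] = means[:, j] - means[:, ref_j]
    return DifferentialTable(table=out, prior=prior, design=design)


def stage_direction_calls(matrix: ExpressionMatrix, design: StageDesign,
                          diff: DifferentialTable, p_cut: float = 0.05,
                          q_cut: float = 0.05, stage_rule: str = "welch",
                          stage_p_cut: float = 0.05,
                          lfc_cut: float = 1.0) -> dict[str, dict[str, list[str]]]:
    """Per-stage up/down lists for features passing the global moderated-F gate.

    A feature enters a stage list when the global gate (p and BH q below the
    cuts) holds AND the per-stage contrast rule fires: ``welch`` = two-sample
    Welch t-test of the stage versus the reference at ``stage_p_cut``;
    ``foldchange`` = |log2 fold change| >= ``lfc_cut``. Direction is the sign
    of the stage-minus-reference mean difference.
    """
    if stage_rule not in ("welch", "foldchange"):
        raise DataError(f"unknown stage rule {stage_rule!r}")
    sig = diff.significant(p_cut, q_cut).index
    X = matrix.data
    ref_samples = design.samples_in(design.reference_stage)
    calls: dict[str, dict[str, list[str]]] = {}
    for st in design.non_reference_stages:
        st_samples = design.samples_in(st)
        sub = X.loc[sig]
        a = sub[st_samples].to_numpy(dtype=float)
        b = sub[ref_samples].to_numpy(dtype=float)
        delta = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
        if stage_rule == "welch":
            with np.errstate(invalid="ignore", divide="ignore"):
                tt = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
            fires = tt.pvalue < stage_p_cut
        else:
            fires = np.abs(delta) >= lfc_cut
        up = [f for f, ok, d in zip(sig, fires, delta) if ok and d > 0]
        down = [f for f, ok, d in zip(sig, fires, delta) if ok and d <= 0]
        calls[st] = {"up": up, "down": down}
    return calls


def direction_map(calls: dict[str, dict[str, list[str]]], stage: str | None = None) -> dict[str, str]:
    """Flatten stage calls to feature -> up/down (union over stages when stage is None).

    When a feature is called in both directions across stages, the call from
    the latest stage listed wins (progression-ordered overwrite).
    """
    out: dict[str, str] = {}
    items = calls.items() if stage is None else [(stage, calls[stage])]
    for _, dd in items:
        for direction in ("down", "up"):
            for f in dd[direction]:
                out[f] = direction
    return out
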