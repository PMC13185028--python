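"""Negative-binomial differential selection of sgRNAs between two sample groups.

The model follows the standard count-based differential-abundance hierarchy for
pooled screens: per-guide counts K_ij are negative binomial with mean q_ig * s_j
(group normalized abundance times a per-sample size factor) and per-guide
dispersion alpha_i. Three departures from a generic RNA-seq analysis are
deliberate and reflect the screen design:

* size factors come from the safe-harbor control guides only (median-of-ratios
  restricted to controls), because genuine selection shifts the bulk of the
  targeting library;
* the reported log2 fold change is the raw maximum-likelihood estimate, with no
  shrinkage — downstream calling applies empirical effect-size cutoffs taken
  from the safe-harbor null, which must act on raw effects;
* no outlier-based count filtering: the library has only two guides per gene,
  so every guide's evidence is kept and the gene-level rule handles conflicts.

Dispersion estimation is empirical-Bayes in structure: per-guide maximum
likelihood (profiling out group means), a mean-dispersion trend
alpha_trend(mu) = a1/mu + a0, and a final maximum a-posteriori estimate under a
log-normal prior centered on the trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .library import N_CTRL_MIN, CountMatrix, GuideLibrary, check_groups_for_comparison

LN2 = np.log(2.0)

ALPHA_FLOOR = 1e-8
ALPHA_CAP = 10.0


class DiffSelError(ValueError):
    """Raised when a differential comparison cannot be set up or normalized."""


@dataclass
class SizeFactors:
    """Per-sample normalization factors from control-guide median-of-ratios."""

    factors: np.ndarray
    sample_ids: list[str]
    control_ids: list[str]
    n_controls_used: int

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if not np.all(np.isfinite(self.factors)) or np.any(self.factors <= 0):
            raise DiffSelError(f"size factors must be positive and finite: {self.factors}")


@dataclass
class DispersionFit:
    """Gene-wise, trend, and final (MAP) negative-binomial dispersions."""

    genewise: np.ndarray
    trend_a0: float
    trend_a1: float
    final: np.ndarray
    sigma_prior_sq: float
    base_mean: np.ndarray
    tested: np.ndarray
    at_bound: np.ndarray
    residual_df: int = 1

    def trend(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            t = self.trend_a0 + self.trend_a1 / mu
        return np.clip(t, ALPHA_FLOOR, ALPHA_CAP)

    @property
    def prior_df(self) -> float:
        """Information content of the dispersion prior, in chi-square df units.

        The log-normal prior with variance sigma_prior_sq carries the same
        information as d0 extra residual df, where trigamma(d0/2) equals
        sigma_prior_sq (the variance of a log dispersion estimate at d0 df).
        """
        return 2.0 * _inverse_trigamma(self.sigma_prior_sq)

    @property
    def effective_df(self) -> float:
        """Degrees of freedom of the moderated t reference for Wald statistics."""
        return self.residual_df + self.prior_df


def _inverse_trigamma(v: float) -> float:
    """Solve trigamma(x) = v for x > 0 (Newton; trigamma is decreasing)."""
    if v <= 0:
        return np.inf
    x = 0.5 + 1.0 / v  # close-form starting point, exact as v -> 0
    for _ in range(50):
        f = float(polygamma(1, x)) - v
        fprime = float(polygamma(2, x))
        step = f / fprime
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-12 * max(1.0, x):
            return x_new
        x = x_new
    return x


def estimate_size_factors(
    matrix: CountMatrix,
    control_ids: set[str] | list[str],
    n_ctrl_min: int = N_CTRL_MIN,
) -> SizeFactors:
    """Median-of-ratios size factors computed on control guides only.

    For each control guide with strictly positive counts in every sample, the
    ratio of its count to its geometric mean across samples is formed; the size
    factor of a sample is the median of these ratios. Controls containing any
    zero are excluded (their geometric mean would vanish).
    """
    if len(matrix.samples) < 2:
        raise DiffSelError("size-factor estimation requires >=2 samples")
    control_ids = set(control_ids)
    if not control_ids:
        raise DiffSelError("control set is empty")
    rows = [i for i, g in enumerate(matrix.guide_ids) if g in control_ids]
    if not rows:
        raise DiffSelError("no control guide present in the count matrix")
    K = matrix.counts[rows].astype(float)
    usable = np.all(K > 0, axis=1)
    if not usable.any():
        raise DiffSelError(
            "cannot normalize: no control guide has positive counts in all samples"
        )
    n_used = int(usable.sum())
    if n_used < n_ctrl_min:
        warnings.warn(
            f"only {n_used} control guides usable for size factors "
            f"(< {n_ctrl_min}); estimates may be unstable",
            stacklevel=2,
        )
    Ku = K[usable]
    log_geomean = np.mean(np.log(Ku), axis=1)
    ratios = Ku / np.exp(log_geomean)[:, None]
    s = np.median(ratios, axis=0)
    used_ids = [matrix.guide_ids[rows[i]] for i in np.flatnonzero(usable)]
    return SizeFactors(
        factors=s,
        sample_ids=matrix.sample_ids,
        control_ids=used_ids,
        n_controls_used=n_used,
    )


def normalize(matrix: CountMatrix, size_factors: SizeFactors) -> np.ndarray:
    """Counts divided by their sample's size factor."""
    return matrix.counts / size_factors.factors[None, :]


# ---------------------------------------------------------------------------
# NB likelihood machinery (vectorized across guides)
# ---------------------------------------------------------------------------


def _fit_group_mean(K: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """MLE of the group normalized mean q for each guide, by Newton in log q.

    K: (G, m) counts for one group's samples; s: (m,) size factors;
    alpha: (G,) dispersions. Rows with all-zero counts return q = 0.
    """
    K = np.asarray(K, dtype=float)
    allzero = K.sum(axis=1) == 0
    q0 = np.maximum((K / s).mean(axis=1), 1e-12)
    x = np.log(q0)
    inv_a = 1.0 / alpha
    for _ in range(40):
        m = np.exp(x)[:, None] * s
        am = alpha[:, None] * m
        common = (K + inv_a[:, None]) * am / (1.0 + am)
        score = (K - common).sum(axis=1)
        info = (common / (1.0 + am)).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        np.clip(step, -3.0, 3.0, out=step)
        x = x + step
        if np.max(np.abs(step)) < 1e-12:
            break
    q = np.exp(x)
    q[allzero] = 0.0
    return q


def _nb_loglik(K: np.ndarray, s: np.ndarray, alpha: np.ndarray, q: np.ndarray) -> np.ndarray:
    """NB log-likelihood per guide (summed over one group's samples)."""
    K = np.asarray(K, dtype=float)
    r = (1.0 / alpha)[:, None]
    m = np.maximum(q[:, None] * s, 1e-300)
    ll = (
        gammaln(K + r)
        - gammaln(r)
        - gammaln(K + 1.0)
        + r * np.log(r / (r + m))
        + K * np.log(m / (r + m))
    )
    # all-zero guides with q=0: exact limit is 0 per sample
    out = ll.sum(axis=1)
    out[q == 0] = 0.0
    return out


def _profile_loglik(groups_K, s_groups, alpha: np.ndarray, cox_reid: bool = True) -> np.ndarray:
    """Per-guide NB log-likelihood with group means profiled out.

    With ``cox_reid`` the Cox-Reid adjustment -0.5 log det(X'WX) is applied
    (here the design is group indicators, so the determinant factors into the
    per-group sums of GLM weights w = mu/(1 + alpha*mu)). Plain profile
    likelihood at 3-vs-2 replicates underestimates the dispersion enough to
    make the Wald test visibly anticonservative; the adjustment restores
    near-nominal calibration.
    """
    total = np.zeros(groups_K[0].shape[0])
    for Kg, sg in zip(groups_K, s_groups):
        q = _fit_group_mean(Kg, sg, alpha)
        total += _nb_loglik(Kg, sg, alpha, q)
        if cox_reid:
            m = q[:, None] * sg
            w = (m / (1.0 + alpha[:, None] * m)).sum(axis=1)
            total -= 0.5 * np.log(np.maximum(w, 1e-300))
    return total


def _maximize_alpha(objective, n_guides: int) -> np.ndarray:
    """Maximize a per-guide objective over log-dispersion by grid + refinement.

    ``objective(alpha_vector) -> (G,) values``. Coarse global grid, then two
    local refinements; final resolution ~1% on the dispersion scale.
    """
    lo, hi = np.log(ALPHA_FLOOR), np.log(ALPHA_CAP)
    coarse = np.linspace(lo, hi, 36)
    best_val = np.full(n_guides, -np.inf)
    best_x = np.full(n_guides, coarse[0])
    for x in coarse:
        v = objective(np.full(n_guides, np.exp(x)))
        better = v > best_val
        best_val[better] = v[better]
        best_x[better] = x
    spacing = coarse[1] - coarse[0]
    for width, n_pts in ((spacing, 17), (spacing / 8.0, 13)):
        offsets = np.linspace(-width, width, n_pts)
        center = best_x.copy()
        for off in offsets:
            x = np.clip(center + off, lo, hi)
            v = objective(np.exp(x))
            better = v > best_val
            best_val[better] = v[better]
            best_x[better] = x[better]
    return np.exp(best_x)


def _fit_trend(
    mu: np.ndarray, disp: np.ndarray, log_bias: float = 0.0
) -> tuple[float, float, bool]:
    """Fit alpha_trend(mu) = a0 + a1/mu to gene-wise dispersions.

    Least squares on the log scale with non-negativity bounds, iteratively
    excluding points far off the trend (ratio outside [1e-4, 15]).

    ``log_bias`` is the known downward median-bias of a per-guide dispersion
    MLE on the log scale (psi(df/2) - log(df/2) under the chi-square
    approximation to the dispersion estimator, about -0.37 at df = 3): the
    trend is fit to log(alpha_hat) - log_bias so it targets the underlying
    dispersion rather than the median of its noisy estimates. Returns
    (a0, a1, ok); ok=False signals the constant-trend fallback was used.
    """
    use = np.isfinite(disp) & (disp > 0) & np.isfinite(mu) & (mu > 0)
    x_all, y_all = mu[use], disp[use]
    debias = float(np.exp(-log_bias))
    if x_all.size < 10:
        fallback = (
            float(np.median(disp[np.isfinite(disp)])) * debias
            if np.isfinite(disp).any()
            else ALPHA_FLOOR
        )
        return fallback, 0.0, False

    keep = np.ones(x_all.size, dtype=bool)
    a0, a1 = float(np.median(y_all)) * debias, 1.0
    for _ in range(10):
        x, y = x_all[keep], y_all[keep]
        if x.size < 10:
            return float(np.median(y_all)) * debias, 0.0, False

        def resid(params, x=x, y=y):
            pred = np.maximum(params[0] + params[1] / x, 1e-12)
            return np.log(y) - log_bias - np.log(pred)

        try:
            fit = optimize.least_squares(
                resid, x0=[max(a0, 1e-6), max(a1, 1e-6)], bounds=([0.0, 0.0], [np.inf, np.inf])
            )
        except Exception:
            return float(np.median(y_all)) * debias, 0.0, False
        a0, a1 = fit.x
        pred_all = np.maximum((a0 + a1 / x_all) * np.exp(log_bias), 1e-12)
        ratio = y_all / pred_all
        new_keep = (ratio > 1e-4) & (ratio < 15.0)
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return float(a0), float(a1), True


def fit_dispersions(
    matrix: CountMatrix,
    size_factors: SizeFactors,
    groups: list[str],
) -> DispersionFit:
    """Empirical-Bayes NB dispersion estimation for a grouped count matrix.

    groups: per-sample group labels (aligned with matrix.samples). Gene-wise
    dispersions are profile-likelihood MLEs with group-specific means; a
    mean-dispersion trend a1/mu + a0 is fit to non-boundary estimates; final
    dispersions maximize likelihood plus a log-normal prior centered on the
    trend, with prior variance estimated from the spread of gene-wise
    estimates around the trend (floored at 0.25).
    """
    if len(groups) != len(matrix.samples):
        raise DiffSelError("groups must align with matrix samples")
    labels = sorted(set(groups))
    idx_groups = [[j for j, g in enumerate(groups) if g == lab] for lab in labels]
    s = size_factors.factors
    K = matrix.counts.astype(float)
    G = K.shape[0]
    tested = K.sum(axis=1) > 0
    base_mean = (K / s).mean(axis=1)

    groups_K = [K[:, idx] for idx in idx_groups]
    s_groups = [s[idx] for idx in idx_groups]

    genewise = _maximize_alpha(lambda a: _profile_loglik(groups_K, s_groups, a), G)
    genewise[~tested] = np.nan
    at_bound = np.zeros(G, dtype=bool)
    at_bound[tested] = (genewise[tested] <= ALPHA_FLOOR * 3) | (
        genewise[tested] >= ALPHA_CAP / 1.2
    )

    m, p = len(matrix.samples), len(labels)
    df = max(m - p, 1)
    # median-bias of the log dispersion MLE under the chi-square approximation
    log_bias = float(polygamma(0, df / 2.0) - np.log(df / 2.0))
    trend_input = np.where(tested & ~at_bound, genewise, np.nan)
    a0, a1, ok = _fit_trend(base_mean, trend_input, log_bias=log_bias)
    if not ok:
        warnings.warn(
            "too few usable guides for dispersion trend; using constant trend",
            stacklevel=2,
        )

    with np.errstate(divide="ignore"):
        trend_vals = np.clip(a0 + a1 / base_mean, ALPHA_FLOOR, ALPHA_CAP)

    use = tested & ~at_bound & np.isfinite(genewise) & (base_mean > 0)
    if use.sum() >= 3:
        log_resid = np.log(genewise[use] / trend_vals[use])
        s_lr_sq = float(np.var(log_resid, ddof=1))
    else:
        s_lr_sq = 0.0
    # chi-square sampling-variance proxy for a log dispersion MLE at m-p df
    sampling_var = float(polygamma(1, df / 2.0))
    sigma_prior_sq = max(s_lr_sq - sampling_var, 0.25)

    log_trend = np.log(trend_vals)

    def map_objective(alpha: np.ndarray) -> np.ndarray:
        ll = _profile_loglik(groups_K, s_groups, alpha)
        prior = -((np.log(alpha) - log_trend) ** 2) / (2.0 * sigma_prior_sq)
        return ll + prior

    final = _maximize_alpha(map_objective, G)
    final = np.clip(final, ALPHA_FLOOR, ALPHA_CAP)
    # dispersion outliers: a gene-wise estimate far above the trend (beyond
    # twice the log-residual spread) is real signal of extra variability, not
    # sampling noise; shrinking it toward the trend would inflate the Wald
    # statistic, so the gene-wise estimate is kept
    if use.sum() >= 3:
        s_lr = float(np.sqrt(max(s_lr_sq, sampling_var)))
        outlier = tested & np.isfinite(genewise) & (
            np.log(genewise) > log_trend + 2.0 * s_lr
        )
        final[outlier] = genewise[outlier]
    final[~tested] = np.nan

    return DispersionFit(
        genewise=genewise,
        trend_a0=a0,
        trend_a1=a1,
        final=final,
        sigma_prior_sq=sigma_prior_sq,
        base_mean=base_mean,
        tested=tested,
        at_bound=at_bound,
        residual_df=df,
    )


def wald_test(
    matrix: CountMatrix,
    size_factors: SizeFactors,
    dispersions: DispersionFit,
    contrast: tuple[str, str],
    library: GuideLibrary | None = None,
) -> pd.DataFrame:
    """Per-guide NB Wald test of group B versus group A.

    Fits the two-group NB regression (intercept + group indicator, offsets
    log s_j) at the fixed final dispersion; the group coefficient in log2
    units is the reported log2 fold change and its standard error comes from
    the observed Fisher information. Because the plugged-in dispersion is an
    estimate, the two-sided p-value uses a moderated t reference whose df add
    the dispersion-prior information to the residual df (quasi-likelihood
    style) rather than a normal reference, which is visibly anticonservative
    at few replicates. Guides with zero counts in both groups are untested.

    Returns a DataFrame with columns guide_id, base_mean, log2fc, se, wald_p,
    tested (plus gene and set_label when a library is supplied); FDR is added
    separately by :func:`bh_adjust` so the test family stays explicit.
    """
    group_a, group_b = contrast
    check_groups_for_comparison(matrix.samples, group_a, group_b)
    labels = matrix.group_labels()
    idx_a = [j for j, g in enumerate(labels) if g == group_a]
    idx_b = [j for j, g in enumerate(labels) if g == group_b]
    s = size_factors.factors
    K = matrix.counts.astype(float)
    Ka, Kb = K[:, idx_a], K[:, idx_b]
    sa, sb = s[idx_a], s[idx_b]

    tested = (Ka.sum(axis=1) + Kb.sum(axis=1)) > 0
    alpha = np.where(np.isfinite(dispersions.final), dispersions.final, ALPHA_FLOOR)
    alpha = np.clip(alpha, ALPHA_FLOOR, ALPHA_CAP)

    qa = _fit_group_mean(Ka, sa, alpha)
    qb = _fit_group_mean(Kb, sb, alpha)
    # a group with complete dropout gets a half-count floor so the fold change
    # stays finite; the large |log2fc| then reflects the dropout
    floor_a = 0.5 / sa.sum()
    floor_b = 0.5 / sb.sum()
    qa_f = np.where(qa > 0, qa, floor_a)
    qb_f = np.where(qb > 0, qb, floor_b)

    ln_fc = np.log(qb_f) - np.log(qa_f)
    log2fc = ln_fc / LN2

    def obs_info(Kg, sg, q):
        m = q[:, None] * sg
        am = alpha[:, None] * m
        return ((Kg + (1.0 / alpha)[:, None]) * am / (1.0 + am) ** 2).sum(axis=1)

    wa = obs_info(Ka, sa, qa_f)
    wb = obs_info(Kb, sb, qb_f)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ln = np.sqrt(1.0 / wa + 1.0 / wb)
        z = ln_fc / se_ln
    df_eff = min(dispersions.effective_df, 1e6)
    wald_p = 2.0 * t_dist.sf(np.abs(z), df_eff)
    se_log2 = se_ln / LN2

    converged = np.isfinite(se_ln) & (se_ln > 0)
    tested = tested & converged

    base_mean = (np.concatenate([Ka / sa, Kb / sb], axis=1)).mean(axis=1)

    out = pd.DataFrame(
        {
            "guide_id": matrix.guide_ids,
            "base_mean": base_mean,
            "log2fc": np.where(tested, log2fc, np.nan),
            "se": np.where(tested, se_log2, np.nan),
            "wald_p": np.where(tested, wald_p, np.nan),
            "tested": tested,
        }
    )
    if library is not None:
        lib = library.to_frame()[["guide_id", "gene", "set_label"]]
        out = out.merge(lib, on="guide_id", how="left")
        out = out[["guide_id", "gene", "set_label", "base_mean", "log2fc", "se", "wald_p", "tested"]]
    out.attrs["contrast"] = (group_a, group_b)
    out.attrs["comparison_id"] = f"{group_b}_vs_{group_a}"
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN inputs stay NaN.

    The family size m is the number of non-NaN (tested) p-values.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def differential_selection(
    matrix: CountMatrix,
    library: GuideLibrary,
    group_a: str,
    group_b: str,
    n_ctrl_min: int = N_CTRL_MIN,
) -> pd.DataFrame:
    """End-to-end differential selection for one contrast (B versus A).

    Subsets the matrix to the two groups, estimates safe-harbor size factors
    and dispersions on that subset, runs the Wald test, and BH-adjusts the
    p-values over the full tested family (safe harbors included; they are
    excluded only at gene-level calling).
    """
    check_groups_for_comparison(matrix.samples, group_a, group_b)
    labels = matrix.group_labels()
    keep = [j for j, g in enumerate(labels) if g in (group_a, group_b)]
    sub = CountMatrix(
        guide_ids=list(matrix.guide_ids),
        samples=[matrix.samples[j] for j in keep],
        counts=matrix.counts[:, keep],
        unmapped=np.asarray(matrix.unmapped)[keep],
        ambiguous=np.asarray(matrix.ambiguous)[keep],
    )
    sf = estimate_size_factors(sub, set(library.safe_harbor_ids), n_ctrl_min=n_ctrl_min)
    disp = fit_dispersions(sub, sf, [sub.samples[j].group for j in range(len(sub.samples))])
    table = wald_test(sub, sf, disp, (group_a, group_b), library=library)
    table["fdr"] = bh_adjust(table["wald_p"].to_numpy())
    return table


__all__ = [
    "ALPHA_FLOOR",
    "ALPHA_CAP",
    "DiffSelError",
    "SizeFactors",
    "DispersionFit",
    "estimate_size_factors",
    "normalize",
    "fit_dispersions",
    "wald_test",
    "bh_adjust",
    "differential_selection",
]
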