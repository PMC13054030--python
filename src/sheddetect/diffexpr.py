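"""Differential expression for counts and intensities.

Counts follow the classical count-based route: TMM library-composition
normalization, a pooled method-of-moments negative-binomial dispersion, and
a two-sided conditional exact test on per-group sums.  Intensities follow
the microarray-style route: log2 transform, per-sample median centering,
per-feature two-group linear model with empirical-Bayes variance shrinkage
(moderated t).  Both end in Benjamini-Hochberg FDR control and strict
fold-change / FDR significance gates (|FC| > 1.5, FDR < 0.05 for mRNA;
|FC| > 1.2, FDR < 0.05 for protein by default, knockdown over control).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln, digamma, polygamma, logsumexp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "moderated_t",
    "bh_adjust",
    "call_differential",
    "normalize_intensities",
    "DispersionEstimate",
]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def tmm_factors(
    counts: ExpressionMatrix,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    M-values (log2 relative expression vs the reference sample) are trimmed
    by ``trim_m`` in each tail, A-values (log2 average abundance) by
    ``trim_a`` in each tail, and the surviving M-values are averaged with
    inverse-asymptotic-variance (precision) weights.  Factors are rescaled
    so that their geometric mean is 1; multiplying library sizes by these
    factors gives effective library sizes.

    The reference defaults to the sample whose 75th expression percentile
    (on library-size-scaled counts) is closest to the mean across samples.
    """
    X = counts.values
    if counts.kind != "counts":
        raise ValueError("tmm_factors expects a counts matrix")
    if X.shape[0] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = X.sum(axis=1)
    if (lib <= 0).any():
        bad = [counts.sample_ids[i] for i in np.where(lib <= 0)[0]]
        raise ValueError(f"samples with zero library size: {bad}")

    if reference is None:
        uq = np.percentile(X / lib[:, None], 75, axis=1)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.sample_ids.index(reference)

    ref = X[ref_idx]
    nref = lib[ref_idx]
    factors = np.ones(X.shape[0])
    for i in range(X.shape[0]):
        if i == ref_idx:
            continue
        factors[i] = _tmm_pair(X[i], lib[i], ref, nref, trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def _tmm_pair(obs, nobs, ref, nref, trim_m, trim_a):
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    o, r = obs[keep], ref[keep]
    po, pr = o / nobs, r / nref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (nobs - o) / (nobs * o) + (nref - r) / (nref * r)
    # degenerate: all M identical (e.g. identical samples) -> factor 2^M
    if np.allclose(m, m[0]):
        return float(2.0 ** m[0])
    n = len(m)
    m_rank = stats.rankdata(m, method="ordinal")
    a_rank = stats.rankdata(a, method="ordinal")
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - np.floor(n * trim_a)
    keep2 = (m_rank >= lo_m) & (m_rank <= hi_m) & (a_rank >= lo_a) & (a_rank <= hi_a)
    if not keep2.any():
        return 1.0
    wm = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
    return float(2.0 ** wm)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------


class DispersionEstimate:
    """Pooled (and optionally per-feature) NB dispersion.

    Attributes
    ----------
    common_dispersion : float
        Method-of-moments estimate pooled over all features and conditions,
        floored at 0 (Poisson limit).
    per_feature_dispersion : ndarray or None
        Tagwise estimates shrunk toward the common value.
    """

    def __init__(self, common_dispersion: float, per_feature_dispersion=None):
        if not np.isfinite(common_dispersion) or common_dispersion < 0:
            raise ValueError("dispersion must be finite and >= 0")
        self.common_dispersion = float(common_dispersion)
        self.per_feature_dispersion = (
            None if per_feature_dispersion is None else np.asarray(per_feature_dispersion, float)
        )


def _scaled_counts(counts: ExpressionMatrix, factors: pd.Series) -> np.ndarray:
    """Counts rescaled so every sample has the mean effective library size."""
    lib = counts.values.sum(axis=1)
    eff = lib * factors.reindex(counts.sample_ids).to_numpy()
    target = np.exp(np.mean(np.log(eff)))
    return counts.values * (target / eff)[:, None]


def estimate_common_dispersion(
    counts: ExpressionMatrix,
    design: SampleDesign,
    factors: pd.Series | None = None,
    tagwise: bool = False,
    prior_weight: float = 20.0,
) -> DispersionEstimate:
    """Method-of-moments NB dispersion on effective-library-adjusted counts.

    For each feature and condition, the sample mean m and variance v satisfy
    v = m + phi * m**2 under the NB model; phi is estimated by pooling
    (v - m) against m**2 over all features and both conditions and floored
    at 0.  With ``tagwise=True`` per-feature estimates are shrunk toward the
    common value with ``prior_weight`` pseudo-features of weight.
    """
    if factors is None:
        factors = tmm_factors(counts)
    z = _scaled_counts(counts, factors)
    groups = [np.asarray([s in set(design.samples(c)) for s in counts.sample_ids])
              for c in SampleDesign.CONDITIONS]
    for c, g in zip(SampleDesign.CONDITIONS, groups):
        if g.sum() < 2:
            raise ValueError(f"condition {c!r} needs >= 2 samples")
    num = np.zeros(z.shape[1])
    den = np.zeros(z.shape[1])
    for g in groups:
        zg = z[g]
        m = zg.mean(axis=0)
        v = zg.var(axis=0, ddof=1)
        num += v - m
        den += m**2
    common = max(0.0, float(num.sum() / den.sum())) if den.sum() > 0 else 0.0
    per_feature = None
    if tagwise:
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(den > 0, num / den, 0.0)
        raw = np.clip(raw, 0.0, None)
        per_feature = (prior_weight * common + raw * 1.0) / (prior_weight + 1.0)
    return DispersionEstimate(common, per_feature)


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------


def _conditional_log_weights(total: int, n1: int, n2: int, dispersion: float) -> np.ndarray:
    """Unnormalized log-probabilities of every split (k, total-k).

    Group sums of NB(1/phi) replicates are NB(n_i/phi); conditional on the
    total, the success probability cancels and only the gamma terms remain.
    With dispersion 0 the conditional law is Binomial(total, n1/(n1+n2)).
    """
    k = np.arange(total + 1)
    if dispersion == 0:
        logp = np.log(n1 / (n1 + n2))
        logq = np.log(n2 / (n1 + n2))
        return (
            gammaln(total + 1) - gammaln(k + 1) - gammaln(total - k + 1)
            + k * logp + (total - k) * logq
        )
    r1, r2 = n1 / dispersion, n2 / dispersion
    return (
        gammaln(k + r1) - gammaln(k + 1) - gammaln(r1)
        + gammaln(total - k + r2) - gammaln(total - k + 1) - gammaln(r2)
    )


def exact_test_pvalues_for_total(
    total: int,
    n1: int,
    n2: int,
    dispersion: float,
    convention: str = "minlike",
) -> np.ndarray:
    """Two-sided conditional exact p-value for every split of ``total``.

    ``minlike``: sum of all conditional outcomes whose probability does not
    exceed that of the observed split.  ``doubling``: twice the smaller tail
    (both including the observed split), capped at 1.
    """
    logw = _conditional_log_weights(total, n1, n2, dispersion)
    w = np.exp(logw - logsumexp(logw))
    w /= w.sum()
    if convention == "minlike":
        order = np.argsort(w, kind="stable")
        sorted_w = w[order]
        csum = np.cumsum(sorted_w)
        # p(k) = sum of w over outcomes with w <= w(k), ties resolved by value
        idx = np.searchsorted(sorted_w, w * (1 + 1e-12), side="right") - 1
        p = csum[np.clip(idx, 0, len(w) - 1)]
        return np.minimum(p, 1.0)
    if convention == "doubling":
        lower = np.cumsum(w)
        upper = np.cumsum(w[::-1])[::-1]
        return np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    raise ValueError(f"unknown two-sided convention {convention!r}")


def nb_exact_test(
    counts: ExpressionMatrix,
    design: SampleDesign,
    factors: pd.Series | None = None,
    dispersion: DispersionEstimate | float = 0.0,
    prior_count: float = 0.125,
    convention: str = "minlike",
) -> pd.DataFrame:
    """Conditional NB exact test per feature, knockdown vs control.

    Counts are rescaled to a common effective library size, summed within
    each condition, and the two-sided exact probability of a split at least
    as extreme is computed from the NB conditional distribution (binomial in
    the Poisson limit).  log2 fold changes use normalized group means with
    ``prior_count`` added per sample to avoid infinities.
    """
    if isinstance(dispersion, DispersionEstimate):
        phi_common = dispersion.common_dispersion
        phi_tag = dispersion.per_feature_dispersion
    else:
        phi_common = float(dispersion)
        phi_tag = None
    if not np.isfinite(phi_common) or phi_common < 0:
        raise ValueError("dispersion must be finite and >= 0")
    if factors is None:
        factors = tmm_factors(counts)

    z = _scaled_counts(counts, factors)
    ctrl = np.asarray([s in set(design.samples("control")) for s in counts.sample_ids])
    kd = np.asarray([s in set(design.samples("knockdown")) for s in counts.sample_ids])
    n1, n2 = int(ctrl.sum()), int(kd.sum())
    if n1 < 1 or n2 < 1:
        raise ValueError("both conditions must be present")

    s_ctrl = z[ctrl].sum(axis=0)
    s_kd = z[kd].sum(axis=0)
    mean_expr = z.mean(axis=0)

    p = np.ones(counts.n_features)
    lfc = np.zeros(counts.n_features)
    untestable = np.zeros(counts.n_features, dtype=bool)
    cache: dict[tuple[int, float], np.ndarray] = {}
    for j in range(counts.n_features):
        k_obs = int(round(s_ctrl[j]))
        k_kd = int(round(s_kd[j]))
        total = k_obs + k_kd
        phi = float(phi_tag[j]) if phi_tag is not None else phi_common
        if total == 0:
            untestable[j] = True
            continue
        key = (total, phi)
        pv = cache.get(key)
        if pv is None:
            pv = exact_test_pvalues_for_total(total, n1, n2, phi, convention)
            if len(cache) < 4096:
                cache[key] = pv
        p[j] = pv[k_obs]
        lfc[j] = np.log2(
            ((s_kd[j] + prior_count * n2) / n2) / ((s_ctrl[j] + prior_count * n1) / n1)
        )

    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "feature_id": counts.feature_ids,
            "log2fc": lfc,
            "mean_expression": mean_expr,
            "pvalue": p,
            "fdr": fdr,
            "significant": False,
            "untestable": untestable,
        }
    )


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def normalize_intensities(intensities: ExpressionMatrix, method: str = "median") -> ExpressionMatrix:
    """log2-transform and normalize a reporter-intensity matrix per sample.

    ``median``: subtract each sample's median log2 intensity.  ``loess``:
    median centering followed by one pass of cyclic-loess straightening of
    each sample against the across-sample mean profile.  Non-positive
    intensities become missing.
    """
    if intensities.kind == "log_intensities":
        return intensities
    if intensities.kind != "intensities":
        raise ValueError("expected an intensity matrix")
    vals = intensities.values.copy()
    vals[~(vals > 0)] = np.nan
    logv = np.log2(vals)
    med = np.nanmedian(logv, axis=1, keepdims=True)
    logv = logv - med + np.nanmean(med)
    if method == "loess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        mean_profile = np.nanmean(logv, axis=0)
        for i in range(logv.shape[0]):
            ok = np.isfinite(logv[i]) & np.isfinite(mean_profile)
            if ok.sum() < 10:
                continue
            fit = lowess(logv[i, ok] - mean_profile[ok], mean_profile[ok],
                         frac=0.4, return_sorted=False)
            logv[i, ok] -= fit
    elif method != "median":
        raise ValueError(f"unknown normalization {method!r}")
    return ExpressionMatrix(
        logv, list(intensities.sample_ids), list(intensities.feature_ids), "log_intensities"
    )


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y (monotone decreasing)
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit a scaled inverse-chi-square prior to observed variances.

    Matches the mean and variance of log(s2) against the theoretical moments
    implied by chi-square sampling of variances; returns (prior_df,
    prior_s2).  prior_df is inf when variances are more concordant than
    chi-square sampling alone would produce.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    d = df[ok].astype(float)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, d / 2.0))
    if evar > 0:
        prior_df = 2.0 * _trigamma_inverse(evar)
        prior_s2 = np.exp(emean + digamma(prior_df / 2.0) - np.log(prior_df / 2.0))
    else:
        prior_df = np.inf
        prior_s2 = np.exp(emean)
    return float(prior_df), float(prior_s2)


def moderated_t(
    log_intensities: ExpressionMatrix,
    design: SampleDesign,
    prior_df: float | None = None,
    var_floor: float = 1e-8,
    norm: str = "median",
) -> pd.DataFrame:
    """Two-group empirical-Bayes moderated t-test per feature.

    Per-feature residual variances are shrunk toward a common prior fitted
    by moment-matching of log variances (scaled inverse-chi-square), and the
    moderated t is referred to a t distribution with prior + residual
    degrees of freedom.  Missing values reduce per-feature df; features with
    fewer than 2 observations in either group are flagged untestable.
    ``prior_df`` overrides the fitted prior df (0 recovers the ordinary
    t-test, inf a fully pooled variance).
    """
    em = normalize_intensities(log_intensities, method=norm)
    X = em.values
    ctrl = np.asarray([s in set(design.samples("control")) for s in em.sample_ids])
    kd = np.asarray([s in set(design.samples("knockdown")) for s in em.sample_ids])

    def _group_stats(mask):
        g = X[mask]
        fin = np.isfinite(g)
        n = fin.sum(axis=0)
        mean = np.where(n > 0, np.where(fin, g, 0.0).sum(axis=0) / np.maximum(n, 1), np.nan)
        with np.errstate(invalid="ignore"):
            ss = np.where(fin, (g - mean) ** 2, 0.0).sum(axis=0)
        return n, mean, ss

    n1, m1, ss1 = _group_stats(ctrl)
    n2, m2, ss2 = _group_stats(kd)

    testable = (n1 >= 2) & (n2 >= 2)
    df_resid = np.where(testable, n1 + n2 - 2, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(testable, (ss1 + ss2) / np.maximum(df_resid, 1), np.nan)
    zero_var = testable & (s2 < var_floor)
    if zero_var.any():
        logger.warning("%d features with (near-)zero variance floored at %g",
                       int(zero_var.sum()), var_floor)
        s2 = np.where(zero_var, var_floor, s2)

    if prior_df is None:
        d0, s20 = fit_variance_prior(s2[testable], df_resid[testable])
    else:
        d0 = float(prior_df)
        _, s20 = fit_variance_prior(s2[testable], df_resid[testable])
    d0_eff = min(d0, 1e12)

    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isfinite(d0) and d0 > 0:
            s2_post = (d0 * s20 + df_resid * s2) / (d0 + df_resid)
        elif d0 == 0:
            s2_post = s2.copy()
        else:  # infinite prior df: fully pooled
            s2_post = np.full_like(s2, s20)
        se = np.sqrt(s2_post * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
        lfc = m2 - m1
        tstat = lfc / se
        df_total = np.minimum(d0_eff + df_resid, 1e12)
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)

    p = np.where(testable, p, np.nan)
    lfc = np.where(np.isfinite(lfc), lfc, 0.0)
    fdr = bh_adjust(p)
    fin = np.isfinite(X)
    n_obs = fin.sum(axis=0)
    overall_mean = np.where(n_obs > 0, np.where(fin, X, 0.0).sum(axis=0) / np.maximum(n_obs, 1), 0.0)
    return pd.DataFrame(
        {
            "feature_id": em.feature_ids,
            "log2fc": lfc,
            "mean_expression": overall_mean,
            "pvalue": np.where(testable, p, 1.0),
            "fdr": np.where(testable, fdr, 1.0),
            "significant": False,
            "untestable": ~testable,
            "tstat": np.where(testable, tstat, 0.0),
            "prior_df": d0,
            "prior_var": s20,
        }
    )


# ---------------------------------------------------------------------------
# multiple testing and calling
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, NaN-safe."""
    p = np.asarray(pvalues, dtype=float)
    flat = p.ravel()
    ok = np.isfinite(flat)
    if ((flat[ok] < 0) | (flat[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(flat.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    return out.reshape(p.shape)


def call_differential(
    results: pd.DataFrame,
    fc_threshold: float,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag features with |FC| strictly above threshold and FDR strictly below alpha."""
    if fc_threshold <= 1:
        raise ValueError("fold-change threshold must exceed 1")
    if not 0 < fdr_alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    out = results.copy()
    gate = (np.abs(out["log2fc"]) > np.log2(fc_threshold)) & (out["fdr"] < fdr_alpha)
    if "untestable" in out.columns:
        gate &= ~out["untestable"].astype(bool)
    out["significant"] = gate.to_numpy()
    return out
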