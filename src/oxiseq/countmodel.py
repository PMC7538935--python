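"""Two-group negative-binomial count contrast.

An intentionally self-contained engine for the IP-vs-input and FA-vs-CA
contrasts: median-of-ratios size factors, pooled method-of-moments
dispersion, a Wald test on the log fold change of NB group means, and
Benjamini-Hochberg adjustment. Compared with full RNA-seq packages it has
no fold-change shrinkage, no outlier refitting and no independent
filtering — every number it reports is traceable to a closed-form
expression on the counts.

Model
-----
Counts for transcript *i* in sample *j* are NB with mean ``s_j * mu_g(j)``
and variance ``mu + alpha_i * mu**2``, where ``s_j`` is the sample's size
factor, ``g(j)`` its group and ``alpha_i`` the transcript's dispersion.
The reported effect is

    log2fc = log2((mu_B + c) / (mu_A + c)),   c = pseudocount,

with group means estimated as means of normalized counts, and its standard
error comes from the Fisher information of the NB means model at the
estimated dispersion: I_g = sum_j s_j*(mu_g+c) / (1 + alpha*s_j*(mu_g+c)).
The Wald p-value is the two-sided normal tail of log2fc/se.

Fractional (RSEM expected) counts are used as-is for size factors but
rounded half-to-even before the likelihood-based steps, which assume
integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError
from .io import CountMatrix

LOG2 = np.log(2.0)

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_DISPERSION_FLOOR = 1e-4


@dataclass(frozen=True)
class NormalizationResult:
    """Per-sample size factors and the method that produced them."""

    size_factors: pd.Series  # positive, indexed by sample_id
    method: str  # "median_of_ratios" or "total_count"


def _lower_median(x: np.ndarray) -> float:
    """Median with the lower-median convention for even-length input."""
    x = np.sort(x)
    return float(x[(len(x) - 1) // 2])


def size_factors(counts: CountMatrix | pd.DataFrame) -> NormalizationResult:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample: the (lower) median, over transcripts whose counts are
    positive in every sample, of count / geometric-row-mean. If no such
    transcript exists the method falls back to total-count normalization
    with a warning; an all-zero matrix is an error.
    """
    vals = counts.values if isinstance(counts, CountMatrix) else counts
    mat = vals.to_numpy(float)
    if mat.size == 0 or not (mat > 0).any():
        raise ValidationError("no usable rows for normalization (all counts zero)")
    usable = (mat > 0).all(axis=1)
    if usable.any():
        logmat = np.log(mat[usable])
        logratio = logmat - logmat.mean(axis=1, keepdims=True)
        raw = np.exp([_lower_median(logratio[:, j]) for j in range(mat.shape[1])])
        method = "median_of_ratios"
    else:
        import warnings

        warnings.warn(
            "no transcript with positive counts in all samples; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValidationError("no usable rows for normalization (empty library)")
        raw = totals
        method = "total_count"
    raw = np.asarray(raw, float)
    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationResult(pd.Series(factors, index=vals.columns), method)


def estimate_dispersion(
    counts: CountMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    size_factors: pd.Series,
    floor: float = DEFAULT_DISPERSION_FLOOR,
) -> pd.Series:
    """Pooled method-of-moments NB dispersion per transcript.

    With normalized counts x = K/s, the within-group sample variances
    (ddof=1) are pooled over the two groups weighted by their degrees of
    freedom, the mean m is taken over all samples of both groups, and

        alpha = max(floor, (s2 - m) / m**2).

    Degenerate rows (m = 0, or no group with >=2 samples) get the floor.
    """
    vals = counts.values if isinstance(counts, CountMatrix) else counts
    groups = [list(group_a), list(group_b)]
    norm = vals[groups[0] + groups[1]].to_numpy(float) / size_factors[
        groups[0] + groups[1]
    ].to_numpy(float)
    m = norm.mean(axis=1)
    ss = np.zeros(len(vals))
    df = 0
    col = 0
    for g in groups:
        n = len(g)
        block = norm[:, col : col + n]
        col += n
        if n >= 2:
            ss += block.var(axis=1, ddof=1) * (n - 1)
            df += n - 1
    alpha = np.full(len(vals), floor)
    if df > 0:
        s2 = ss / df
        ok = m > 0
        alpha[ok] = np.maximum(floor, (s2[ok] - m[ok]) / m[ok] ** 2)
    return pd.Series(alpha, index=vals.index)


def moderate_dispersion(
    counts: CountMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    size_factors: pd.Series,
    floor: float = DEFAULT_DISPERSION_FLOOR,
    trim: float = 0.1,
) -> pd.Series:
    """Transcript dispersions stabilized by sharing strength across rows.

    With two replicates per group the per-transcript moment estimate has
    only two degrees of freedom, and plugging it straight into a
    normal-tail Wald test badly inflates the type-I error. Following the
    conservative convention of early NB differential-expression engines,
    each transcript gets

        alpha_i = max(per-transcript MoM estimate, alpha_trend),

    where ``alpha_trend`` is the trimmed mean (default 10% each tail) of
    the raw (unfloored) per-transcript estimates — an experiment-wide
    dispersion level the noisy per-row values cannot fall below. The
    trend uses within-group variability only, so planted or real group
    differences do not leak into it.
    """
    vals = counts.values if isinstance(counts, CountMatrix) else counts
    gene = estimate_dispersion(vals, group_a, group_b, size_factors, floor=floor)
    groups = [list(group_a), list(group_b)]
    norm = vals[groups[0] + groups[1]].to_numpy(float) / size_factors[
        groups[0] + groups[1]
    ].to_numpy(float)
    m = norm.mean(axis=1)
    na = len(groups[0])
    ss = np.zeros(len(vals))
    df = 0
    for block, n in ((norm[:, :na], na), (norm[:, na:], len(groups[1]))):
        if n >= 2:
            ss += block.var(axis=1, ddof=1) * (n - 1)
            df += n - 1
    ok = m > 0
    if df > 0 and ok.sum() >= 2:
        raw = (ss[ok] / df - m[ok]) / m[ok] ** 2
        trend = max(floor, float(stats.trim_mean(raw, trim)))
    else:
        trend = floor
    return pd.Series(np.maximum(gene.to_numpy(), trend), index=vals.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with NA passthrough.

    Present values must lie in [0, 1]; NaN entries stay NaN and do not
    count toward the number of tests.
    """
    p = np.asarray(p, float)
    present = ~np.isnan(p)
    vals = p[present]
    if ((vals < 0) | (vals > 1)).any():
        bad = vals[(vals < 0) | (vals > 1)][0]
        raise ValidationError(f"p-value outside [0, 1]: {bad}")
    out = np.full(p.shape, np.nan)
    if vals.size:
        out[present] = multipletests(vals, method="fdr_bh")[1]
    return out


def nb_wald_contrast(
    counts: CountMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    norm: NormalizationResult | None = None,
    dispersions: pd.Series | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    dispersion_floor: float = DEFAULT_DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Wald test of group B over group A on NB count data.

    Returns a DataFrame indexed by transcript with columns ``base_mean``
    (mean normalized count over both groups), ``log2fc``, ``se``, ``p``
    and ``p_adj``. Rows with zero counts across both groups have NaN
    p / p_adj (nothing to test); log2fc is always finite thanks to the
    pseudocount.
    """
    vals = counts.values if isinstance(counts, CountMatrix) else counts
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ConfigurationError("both contrast groups need at least one sample")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ConfigurationError(f"samples in both groups: {sorted(overlap)}")
    sub = vals[group_a + group_b]
    if norm is None:
        norm = size_factors(sub)
    s = norm.size_factors[group_a + group_b].to_numpy(float)
    if (s <= 0).any():
        raise ValidationError("size factors must be positive")

    # integer counts for the likelihood-based steps; banker's rounding
    k_int = np.rint(sub.to_numpy(float))
    if dispersions is None:
        int_df = pd.DataFrame(k_int, index=sub.index, columns=sub.columns)
        dispersions = moderate_dispersion(
            int_df, group_a, group_b, norm.size_factors, floor=dispersion_floor
        )
    alpha = dispersions.reindex(sub.index).to_numpy(float)

    na, nb = len(group_a), len(group_b)
    x = k_int / s  # normalized counts
    mu_a = x[:, :na].mean(axis=1)
    mu_b = x[:, na:].mean(axis=1)
    base_mean = x.mean(axis=1)

    c = pseudocount
    log2fc = np.log2((mu_b + c) / (mu_a + c))

    # Fisher information of the NB means model, evaluated at the
    # pseudocounted means so the se stays finite for all-zero groups
    def info(mu: np.ndarray, s_g: np.ndarray) -> np.ndarray:
        mu_j = np.outer(mu + c, s_g)
        return (mu_j / (1.0 + alpha[:, None] * mu_j)).sum(axis=1)

    var_ln = 1.0 / info(mu_a, s[:na]) + 1.0 / info(mu_b, s[na:])
    se = np.sqrt(var_ln) / LOG2

    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    untestable = (k_int.sum(axis=1) == 0)
    p[untestable] = np.nan

    res = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=sub.index.rename("transcript_id"),
    )
    return res
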