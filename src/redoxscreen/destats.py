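"""Count normalization and per-gene differential tests for the 4x3 design.

The selection criteria downstream consume three per-gene quantities only:
condition means of normalized expression, log2 fold changes, and BH
q-values.  Counts are normalized to counts-per-million (CPM); fold changes
are ratios of pseudocounted CPM condition means; p-values come from a
two-sample t statistic on ``log2(CPM + pc)``.

With triplicate conditions a per-gene variance estimate has only ~4 degrees
of freedom, far too noisy to reach genome-wide significance for realistic
effects.  The default test therefore moderates the per-gene pooled variance
with an empirical-Bayes scaled-inverse-chi-square prior fitted across all
genes of the comparison (the standard small-replicate treatment in
expression analysis); the prior adds its degrees of freedom to the
statistic.  ``method="welch"`` gives the plain unequal-variance Welch t for
comparison and for designs with many replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

VAR_FLOOR = 1e-12  # applied when both groups are constant but unequal


# ---------------------------------------------------------------------------
# normalization and summaries


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: ``counts * 1e6 / library_size`` per sample column."""
    libsize = counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts * 1e6 / libsize


def condition_means(norm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of normalized expression per (gene, condition).

    ``design`` must assign a condition to every sample column of ``norm``.
    """
    missing = [s for s in norm.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples absent from design: {missing}")
    out = {}
    for cond, sub in design.loc[list(norm.columns)].groupby("condition", sort=True):
        cols = list(sub.index)
        if not cols:
            raise ValueError(f"condition {cond!r} has no samples")
        out[cond] = norm[cols].mean(axis=1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# t statistics


def _welch(y1: np.ndarray, y2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t over gene rows; returns (t, p)."""
    n1, n2 = y1.shape[1], y2.shape[1]
    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    v1, v2 = y1.var(axis=1, ddof=1), y2.var(axis=1, ddof=1)
    both_zero = (v1 == 0) & (v2 == 0)
    se2 = v1 / n1 + v2 / n2
    se2 = np.where(both_zero, VAR_FLOOR, se2)
    t = (m1 - m2) / np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    df = np.where(both_zero, n1 + n2 - 2, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(both_zero & (m1 == m2), 1.0, p)
    return t, p


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for the relevant range
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / y < 1e-10):
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled-inv-chi2 prior (d0, s0^2) to observed variances.

    Works on ``log s^2`` whose distribution under the hierarchical model is a
    shifted log-F; matching its mean and variance gives the prior degrees of
    freedom and scale.  Returns ``(d0, s0sq)`` with ``d0 = inf`` when the
    observed spread is no larger than the sampling spread (all genes share
    one variance).
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return 0.0, float(s2[0]) if s2.size else 0.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * float(_trigamma_inverse(np.array(evar)))
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def _moderated(y1: np.ndarray, y2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equal-variance t with empirical-Bayes variance moderation across genes."""
    n1, n2 = y1.shape[1], y2.shape[1]
    df = n1 + n2 - 2
    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    ss = y1.var(axis=1, ddof=1) * (n1 - 1) + y2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    d0, s0sq = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_post = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_post = np.full_like(s2, d0 + df)
    s2_post = np.maximum(s2_post, VAR_FLOOR)
    t = (m1 - m2) / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    p = np.where(
        np.isinf(df_post),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), df_post),
    )
    p = np.where((s2 == 0) & (m1 == m2) & (s2_post <= VAR_FLOOR), 1.0, p)
    return t, p


def differential_test(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    pair: tuple[str, str],
    pseudocount: float = 0.5,
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-gene differential expression for one ordered condition pair.

    Parameters
    ----------
    norm
        Normalized (CPM) gene x sample matrix.
    pair
        ``(numerator, denominator)`` condition names; the reported
        ``log2fc = log2((mean_num + pc) / (mean_den + pc))`` is positive when
        the numerator condition is higher.
    pseudocount
        Added to CPM both inside the log-transform for testing and to the
        condition means for the fold change, keeping every value finite.
    method
        ``"moderated"`` (default) or ``"welch"``.

    Returns a DataFrame indexed by gene with ``log2fc``, ``p`` and BH ``q``
    computed across all genes of this comparison.
    """
    num, den = pair
    cols_num = [s for s in norm.columns if design.loc[s, "condition"] == num]
    cols_den = [s for s in norm.columns if design.loc[s, "condition"] == den]
    if len(cols_num) < 2 or len(cols_den) < 2:
        raise ValueError(f"need >=2 replicates per side for {num} vs {den}")
    a = norm[cols_num].to_numpy(float)
    b = norm[cols_den].to_numpy(float)
    log2fc = np.log2(a.mean(axis=1) + pseudocount) - np.log2(b.mean(axis=1) + pseudocount)
    y1 = np.log2(a + pseudocount)
    y2 = np.log2(b + pseudocount)
    if method == "welch":
        _, p = _welch(y1, y2)
    elif method == "moderated":
        _, p = _moderated(y1, y2)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": bh_adjust(p)}, index=norm.index
    )


# ---------------------------------------------------------------------------
# RT-qPCR utilities


def qpcr_relative_expression(ct_target: float, ct_reference: float) -> float:
    """Delta-Ct relative expression, ``2**-(ct_target - ct_reference)``.

    The reference is the internal-control transcript (Act5C in the assays
    this mirrors); one cycle difference is a two-fold expression difference.
    """
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (-(ct_target - ct_reference)))


def fold_induction(re_treated: float, re_control: float) -> float:
    """Ratio of relative expressions between a treated and a control group."""
    if re_control <= 0:
        raise ValueError("control relative expression must be positive")
    return float(re_treated / re_control)
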