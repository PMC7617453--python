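"""Differential analysis of labeled nascent-proteome spectral counts.

Nascent-proteome capture experiments (BONCAT / OPP) yield protein × sample
spectral-count matrices.  The workflow here mirrors the common label-free
proteomics stack: total-count normalization, log2 transform with zeros as
missing, left-censored Gaussian imputation, and an empirical-Bayes moderated
t-test with Benjamini–Hochberg correction.  A robust standardized log2-ratio
("Zq-style": ratio minus median over 1.4826·MAD, i.e. in units of standard
deviation) is provided for secretome-style comparisons; the full WSPP
hierarchical weighting is deliberately not implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_counts",
    "log2_with_missing",
    "impute_missing",
    "moderated_test",
    "differential_enrichment",
    "zq_standardize",
]


def normalize_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column so its total equals the mean raw column total.

    Zeros are preserved (they mark non-detection, not measured zero signal).
    Idempotent: normalizing a normalized matrix changes nothing.
    """
    totals = matrix.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero sample column(s): {bad}")
    target = float(totals.mean())
    return matrix * (target / totals)


def log2_with_missing(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2-transform, turning zeros (non-detections) into NaN."""
    with np.errstate(divide="ignore"):
        out = np.log2(matrix.where(matrix > 0))
    return out


def impute_missing(
    matrix: pd.DataFrame,
    shift: float = 1.8,
    width: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Left-censored imputation of missing log2 intensities.

    Missing entries in each sample column are drawn from
    ``Normal(mean - shift*sd, (width*sd)^2)`` computed over that column's
    observed values — the conventional assumption that non-detected proteins
    sit below the detection limit.  Fully reproducible given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = matrix.copy()
    for col in out.columns:
        vals = out[col]
        observed = vals.dropna()
        n_miss = int(vals.isna().sum())
        if n_miss == 0:
            continue
        if len(observed) < 2:
            raise ValueError(f"sample {col!r} has fewer than 2 observed values")
        mu, sd = float(observed.mean()), float(observed.std(ddof=1))
        draws = rng.normal(mu - shift * sd, width * sd, size=n_miss)
        out.loc[vals.isna(), col] = draws
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def _fit_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Works on log variances (their distribution under the model is a shifted
    log-F), matching mean and variance via digamma/trigamma.  Returns
    ``(d0, s0_sq)``; ``d0 = inf`` signals full shrinkage and ``d0 = nan`` a
    degenerate fit (caller falls back to the ordinary t-test).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 3:
        return math.nan, math.nan
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + math.log(df / 2)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2))
    if e_var <= 0:
        # observed variances less dispersed than chi2 alone: infinite prior df
        s0 = math.exp(e_mean)
        return math.inf, s0
    half_d0 = _trigamma_inverse(e_var)
    d0 = 2 * half_d0
    s0 = math.exp(e_mean + special.digamma(half_d0) - math.log(half_d0))
    if not (np.isfinite(d0) and np.isfinite(s0) and s0 > 0):
        return math.nan, math.nan
    return d0, s0


@dataclass
class ModeratedResult:
    """Per-protein differential result plus the fitted variance prior."""

    table: pd.DataFrame  # log2fc, t, df, p, q [, zq, imputed_fraction_*]
    d0: float
    s0_sq: float
    ordinary_fallback: bool
    contrast: tuple[str, str]


def moderated_test(
    matrix: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
) -> ModeratedResult:
    """Empirical-Bayes moderated two-group t-test on log2 intensities.

    Per protein: log2FC = mean(first group) − mean(second group); residual
    variances are shrunk toward a scaled inverse-chi-square prior fitted by
    method of moments, the t statistic uses the posterior variance with
    ``df + d0`` degrees of freedom, and q-values are Benjamini–Hochberg.
    When the prior fit is degenerate the ordinary t-test is used and flagged
    (``ordinary_fallback``).
    """
    g1, g2 = contrast
    for g in contrast:
        if g not in set(groups):
            raise ValueError(f"contrast group {g!r} not in design")
    cols1 = [s for s in matrix.columns if groups.get(s) == g1]
    cols2 = [s for s in matrix.columns if groups.get(s) == g2]
    n1, n2 = len(cols1), len(cols2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each contrast group needs at least 2 samples")

    x1 = matrix[cols1].to_numpy(float)
    x2 = matrix[cols2].to_numpy(float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    fc = m1 - m2
    df_resid = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    se_factor = math.sqrt(1 / n1 + 1 / n2)

    d0, s02 = _fit_prior(s2, df_resid)
    fallback = math.isnan(d0)
    if fallback:
        s2_post = s2
        df_total = float(df_resid)
    elif math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = math.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / (np.sqrt(s2_post) * se_factor)
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "log2fc": fc,
            "t": t,
            "df": df_total,
            "p": p,
            "q": q,
        },
        index=matrix.index,
    )
    return ModeratedResult(
        table=table, d0=d0, s0_sq=s02, ordinary_fallback=bool(fallback), contrast=contrast
    )


def differential_enrichment(
    counts: pd.DataFrame,
    design: pd.Series,
    contrast: tuple[str, str],
    shift: float = 1.8,
    width: float = 0.3,
    seed: int = 0,
) -> ModeratedResult:
    """Full spectral-count workflow: normalize → log2 → impute → moderated t.

    Adds the per-group imputed fraction and the Zq-style standardized
    log2-ratio of the contrast to the result table.
    """
    counts = counts.fillna(0.0)  # NA-as-zero load policy
    norm = normalize_counts(counts)
    logm = log2_with_missing(norm)
    miss = logm.isna()
    imputed = impute_missing(logm, shift=shift, width=width, seed=seed)
    res = moderated_test(imputed, design, contrast)

    g1, g2 = contrast
    cols1 = [s for s in counts.columns if design.get(s) == g1]
    cols2 = [s for s in counts.columns if design.get(s) == g2]
    res.table[f"imputed_fraction_{g1}"] = miss[cols1].mean(axis=1)
    res.table[f"imputed_fraction_{g2}"] = miss[cols2].mean(axis=1)
    try:
        res.table["zq"] = zq_standardize(res.table["log2fc"].to_numpy())
    except ValueError:
        res.table["zq"] = np.nan
    return res


def zq_standardize(log2_ratios: np.ndarray) -> np.ndarray:
    """Standardize log2-ratios to units of standard deviation (Zq-style).

    ``Zq = (ratio - median) / (1.4826 * MAD)`` — a robust z-score; the
    1.4826 factor makes the MAD a consistent normal-scale estimate.
    """
    x = np.asarray(log2_ratios, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 3:
        raise ValueError("need at least 3 finite log2-ratios")
    med = float(np.median(finite))
    mad = float(np.median(np.abs(finite - med)))
    if mad == 0:
        raise ValueError("MAD is zero; Zq undefined")
    return (x - med) / (1.4826 * mad)
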