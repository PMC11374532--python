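"""Simplified negative-binomial Wald differential-expression test.

The model is the standard count-DE workhorse: counts are normalized by
median-of-ratios size factors, per-gene NB dispersions (Var = mu + alpha*mu^2)
are estimated by method of moments within replicate groups and shrunk toward a
trimmed-mean prior, and each two-group contrast is tested with a Wald z on the
log2 ratio of group means (delta-method standard error), followed by
Benjamini-Hochberg adjustment.  DEG calls use |log2FC| >= 1 (inclusive) and
adjusted p < 0.05 (strict) by default.

This is deliberately a compact reimplementation of the genre, not a wrapper:
there is no fold-change shrinkage, no independent filtering and no outlier
refitting; genes with zero counts in both groups of a contrast are excluded
from testing and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group contrast; log2FC is numerator over denominator."""

    name: str
    numerator: tuple[str, int]  # (condition, day)
    denominator: tuple[str, int]

    def __post_init__(self):
        if self.numerator == self.denominator:
            raise ConfigError(f"contrast {self.name}: groups must be disjoint")


@dataclass
class DegSet:
    """Thresholded DEG identifiers for one contrast, with per-gene sign."""

    name: str
    signs: dict[str, int] = field(default_factory=dict)
    day: int | None = None

    @property
    def genes(self) -> set[str]:
        return set(self.signs)

    def __len__(self) -> int:
        return len(self.signs)

    def __contains__(self, gene: str) -> bool:
        return gene in self.signs


def group_samples(design: pd.DataFrame, group: tuple[str, int]) -> list[str]:
    cond, day = group
    mask = (design["condition"] == cond) & (design["day"] == int(day))
    samples = list(design.index[mask])
    if not samples:
        raise DataError(f"no samples for group {cond}{day}")
    return samples


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios normalization factors.

    Uses genes with nonzero counts in every sample as the reference set; the
    factor for a sample is the median ratio of its counts to the per-gene
    geometric means.  With ``pseudo_reference=True`` the geometric mean is
    instead taken over each gene's nonzero entries, for sparse matrices where
    no gene is observed everywhere.
    """
    if pseudo_reference:
        logs = np.log(counts.where(counts > 0))
        log_geomean = logs.mean(axis=1)
        keep = log_geomean.notna()
        if not keep.any():
            raise DataError("count matrix is entirely zero")
        ratios = logs.loc[keep].sub(log_geomean[keep], axis=0)
        return np.exp(ratios.median(axis=0)).rename("size_factor")
    positive = counts.loc[(counts > 0).all(axis=1)]
    if positive.empty:
        raise DataError(
            "no gene has nonzero counts in all samples; cannot form the "
            "median-of-ratios reference (retry with pseudo_reference=True)"
        )
    log_geomean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geomean, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series,
    n_prior: float = 5.0,
    trim: float = 0.01,
    floor: float = 1e-8,
    floor_at_prior: bool = True,
) -> pd.Series:
    """Per-gene NB dispersion: group-pooled method of moments, then shrinkage.

    The gene-wise estimate is ``max(0, (s2 - mu) / mu**2)`` where ``s2`` is the
    within-group pooled variance of normalized counts and ``mu`` their overall
    mean.  Estimates are shrunk toward the trimmed mean over genes with weight
    ``n_prior / (n_prior + n_reps)`` on the prior, ``n_reps`` being the average
    replicate count per group.

    With ``floor_at_prior`` (the default) the shrunken values are additionally
    bounded below by the prior itself: at two or three replicates the
    gene-wise moment estimate is too noisy for below-prior values to be
    evidence of genuinely low dispersion, and trusting them makes the Wald
    test anticonservative, so shrinkage is one-sided — genes may only look
    *more* dispersed than the consensus, never less.
    """
    norm = counts.div(factors.reindex(counts.columns), axis=1)
    labels = design.loc[counts.columns].apply(
        lambda r: f"{r['condition']}{r['day']}", axis=1
    )
    groups = norm.T.groupby(labels)
    k = groups.ngroups
    n = norm.shape[1]
    if n - k < 1:
        raise DataError("need at least one replicated group to estimate dispersion")
    # pooled within-group sum of squares
    ss = pd.DataFrame(0.0, index=norm.index, columns=[0])[0]
    for _, block in groups:
        dev = block.sub(block.mean(axis=0), axis=1)
        ss = ss + (dev**2).sum(axis=0)
    s2 = ss / (n - k)
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = ((s2 - mu) / mu**2).clip(lower=0.0)
    alpha = alpha.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    informative = alpha[mu > 1.0].sort_values()
    # prior: mean with only the upper tail trimmed -- the gene-wise estimator
    # is right-skewed and clipped at zero, so symmetric trimming would bias
    # the prior downward; one-sided trimming keeps robustness to outliers
    if len(informative):
        keep = max(1, int(np.ceil(len(informative) * (1.0 - trim))))
        prior = float(informative.iloc[:keep].mean())
    else:
        prior = 0.0
    n_reps = n / k
    w = n_prior / (n_prior + n_reps)
    shrunk = w * prior + (1.0 - w) * alpha
    if floor_at_prior:
        shrunk = shrunk.clip(lower=prior)
    return shrunk.clip(lower=floor).rename("dispersion")


def wald_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: ContrastSpec,
    factors: pd.Series,
    dispersions: pd.Series,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB Wald test.

    Returns a table with columns ``baseMean, log2FC, lfcSE, pvalue, padj,
    tested``; genes with zero counts in both groups carry ``tested=False`` and
    NaN statistics, and are excluded from the BH family.
    """
    s1 = group_samples(design, contrast.numerator)
    s0 = group_samples(design, contrast.denominator)
    if len(s1) < 2 or len(s0) < 2:
        raise DataError(f"contrast {contrast.name}: both groups need >= 2 replicates")
    f1 = factors.reindex(s1).to_numpy()
    f0 = factors.reindex(s0).to_numpy()
    x1 = counts[s1].to_numpy() / f1
    x0 = counts[s0].to_numpy() / f0
    m1 = x1.mean(axis=1)
    m0 = x0.mean(axis=1)
    alpha = dispersions.reindex(counts.index).to_numpy()

    tested = ~((counts[s1].sum(axis=1) == 0) & (counts[s0].sum(axis=1) == 0)).to_numpy()
    lfc = np.log2(m1 + pseudocount) - np.log2(m0 + pseudocount)

    def var_mean(m, fs):
        # Var of the mean of normalized counts: (1/n^2) sum_i (mu/s_i + a mu^2)
        return (m[:, None] / fs[None, :] + alpha[:, None] * m[:, None] ** 2).sum(
            axis=1
        ) / len(fs) ** 2

    ln2sq = np.log(2.0) ** 2
    var_lfc = (
        var_mean(m1, f1) / (m1 + pseudocount) ** 2
        + var_mean(m0, f0) / (m0 + pseudocount) ** 2
    ) / ln2sq
    se = np.sqrt(var_lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.where(lfc == 0, 0.0, np.inf))
    p = 2.0 * stats.norm.sf(np.abs(z))

    table = pd.DataFrame(
        {
            "baseMean": np.concatenate([x1, x0], axis=1).mean(axis=1),
            "log2FC": lfc,
            "lfcSE": se,
            "pvalue": p,
            "tested": tested,
        },
        index=counts.index,
    )
    table.loc[~table["tested"], ["baseMean", "log2FC", "lfcSE", "pvalue"]] = np.nan
    table["padj"] = np.nan
    table.loc[table["tested"], "padj"] = adjust_bh(
        table.loc[table["tested"], "pvalue"].to_numpy()
    )
    return table


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_degs(
    table: pd.DataFrame,
    name: str = "",
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
    day: int | None = None,
) -> DegSet:
    """Threshold a DE table into a DegSet: |log2FC| >= lfc_min AND padj < padj_max."""
    if lfc_min <= 0 or padj_max <= 0:
        raise ConfigError("thresholds must be positive")
    t = table[table.get("tested", pd.Series(True, index=table.index))]
    hit = (t["log2FC"].abs() >= lfc_min) & (t["padj"] < padj_max)
    signs = {g: (1 if v > 0 else -1) for g, v in t.loc[hit, "log2FC"].items()}
    return DegSet(name=name, signs=signs, day=day)
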