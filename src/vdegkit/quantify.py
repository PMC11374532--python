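"""TPM quantification, expressed-gene filtering, PCA QC and the small
hormone-period correlation helper.

TPM for gene g in sample s is the length-normalized rate
``(count/length) / sum_g(count/length) * 1e6``; a period's expression level is
the arithmetic mean TPM over its replicates, and a gene counts as expressed in
a period when that mean is >= 1 (genes below 1 TPM in every period are dropped
from the default enrichment population).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConfigError, DataError


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million; every sample column sums to 1e6."""
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise DataError(f"gene lengths missing for: {list(missing[:5])}")
    if (lengths.reindex(counts.index) <= 0).any():
        raise DataError("gene lengths must be positive")
    rate = counts.div(lengths.reindex(counts.index), axis=0)
    denom = rate.sum(axis=0)
    dead = denom.index[denom == 0]
    if len(dead):
        raise DataError(f"sample(s) with all-zero counts: {list(dead)}")
    return rate.div(denom, axis=1) * 1e6


def period_label(condition: str, day: int) -> str:
    return f"{condition}{int(day)}"


def period_means(tpm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean TPM over replicates per (condition, day) cell, columns like 'C0'."""
    labels = design.apply(lambda r: period_label(r["condition"], r["day"]), axis=1)
    return tpm.T.groupby(labels.reindex(tpm.columns)).mean().T


def filter_expressed(
    pmeans: pd.DataFrame, min_tpm: float = 1.0
) -> tuple[pd.DataFrame, pd.Index]:
    """Per-period expressed flags (mean TPM >= min_tpm; the boundary counts as
    expressed) and the set of genes expressed in at least one period."""
    flags = pmeans >= min_tpm
    return flags, pmeans.index[flags.any(axis=1)]


def pca_qc(
    tpm: pd.DataFrame,
    design: pd.DataFrame,
    genes: pd.Index | None = None,
    n_components: int = 2,
    log_transform: str = "log2p1",
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(TPM+1) by default, genes centered.

    ``log_transform`` may be ``"log2p1"`` or ``"none"`` (PCA directly on
    TPM).  Returns per-sample coordinates on the first components, annotated
    with the design, and the explained-variance fractions.
    """
    if tpm.shape[1] < max(3, n_components):
        raise DataError("need at least 3 samples (and >= n_components) for PCA")
    if log_transform not in ("log2p1", "none"):
        raise ConfigError(f"unknown log_transform {log_transform!r}")
    x = np.log2(tpm + 1.0) if log_transform == "log2p1" else tpm.astype(float)
    if genes is not None:
        x = x.loc[x.index.intersection(genes)]
    mat = x.to_numpy().T  # samples x genes
    mat = mat - mat.mean(axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(mat)
    out = pd.DataFrame(
        coords, index=x.columns, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    out = out.join(design[["condition", "day"]], how="left")
    return out, pca.explained_variance_ratio_


def hormone_period_correlation(
    hormones: pd.DataFrame, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each analyte's per-period values against each
    expression (or indicator) profile over the shared periods.

    Zero-variance vectors give an undefined correlation, reported as NaN.
    """
    periods = hormones.columns.intersection(profiles.columns)
    if len(periods) < 3:
        raise ConfigError("need >= 3 shared periods for correlation")
    h = hormones[periods].astype(float)
    p = profiles[periods].astype(float)
    out = pd.DataFrame(np.nan, index=h.index, columns=p.index)
    for a in h.index:
        va = h.loc[a].to_numpy()
        for b in p.index:
            vb = p.loc[b].to_numpy()
            mask = ~(np.isnan(va) | np.isnan(vb))
            if mask.sum() < 3:
                continue
            x, y = va[mask], vb[mask]
            if x.std() == 0 or y.std() == 0:
                continue
            out.loc[a, b] = np.corrcoef(x, y)[0, 1]
    return out
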