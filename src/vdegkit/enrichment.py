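"""Hypergeometric over-representation tests for GO terms, functional BINs and
TF families.

For a study set of n genes drawn from a population of M genes of which K are
annotated to a term, the enrichment p-value is the upper hypergeometric tail
P(X >= k).  GO-style results are BH-adjusted (within namespace by default);
BIN-style results follow the raw p <= 0.05 convention, with BH also reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import adjust_bh
from .errors import DataError


def _annotation_frame(annotation) -> pd.DataFrame:
    if isinstance(annotation, pd.DataFrame):
        df = annotation.copy()
        if "namespace" not in df.columns:
            df["namespace"] = "all"
        return df[["gene", "term", "namespace"]]
    rows = [(g, term, "all") for term, genes in annotation.items() for g in genes]
    return pd.DataFrame(rows, columns=["gene", "term", "namespace"])


def hypergeom_enrich(
    study: set[str],
    population: set[str],
    annotation,
    adjust: str = "BH",
    by_namespace: bool = True,
) -> pd.DataFrame:
    """Term over-representation of `study` within `population`.

    ``annotation`` is a (gene, term[, namespace]) frame or a term->genes
    mapping; annotations outside the population are ignored, genes without any
    annotation still count in M and n.  Returns one row per term with k, n, K,
    M, pvalue and (when adjust='BH') padj computed within namespace groups.
    """
    study, population = set(study), set(population)
    offenders = study - population
    if offenders:
        raise DataError(f"study genes outside the population: {sorted(offenders)[:5]}")
    ann = _annotation_frame(annotation)
    ann = ann[ann["gene"].isin(population)]
    m_pop = len(population)
    n_study = len(study)
    rows = []
    for (term, namespace), block in ann.groupby(["term", "namespace"]):
        members = set(block["gene"])
        big_k = len(members)
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, m_pop, big_k, n_study))
        rows.append((term, namespace, k, n_study, big_k, m_pop, p))
    out = pd.DataFrame(
        rows, columns=["term", "namespace", "k", "n", "K", "M", "pvalue"]
    )
    if out.empty:
        out["padj"] = []
        return out
    if adjust == "BH":
        if by_namespace:
            out["padj"] = out.groupby("namespace")["pvalue"].transform(
                lambda s: adjust_bh(s.to_numpy())
            )
        else:
            out["padj"] = adjust_bh(out["pvalue"].to_numpy())
    else:
        out["padj"] = out["pvalue"]
    return out.sort_values(["padj", "pvalue", "term"]).reset_index(drop=True)


def tf_family_enrich(
    profile_sets: dict[int, set[str]], tf_families: pd.Series
) -> pd.DataFrame:
    """Family over-representation per profile, population = the TF universe.

    ``tf_families`` maps TF gene -> family label.  Same hypergeometric
    machinery as :func:`hypergeom_enrich` with families as pseudo-terms; raw
    p < 0.05 is the conventional threshold, reported via the ``significant``
    column.
    """
    universe = set(tf_families.index)
    ann = pd.DataFrame(
        {"gene": tf_families.index, "term": tf_families.to_numpy()}
    )
    frames = []
    for pid, members in sorted(profile_sets.items()):
        res = hypergeom_enrich(set(members) & universe, universe, ann, adjust="none")
        res.insert(0, "profile", pid)
        frames.append(res)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["profile", "term", "namespace", "k", "n", "K", "M", "pvalue", "padj"]
    )
    out["significant"] = out["pvalue"] < 0.05
    return out.rename(columns={"term": "family"})
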