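"""Model-profile clustering of log2 fold-change trajectories.

Short time courses are clustered against a fixed library of temporal
templates rather than by data-driven clustering: every template starts at 0
and moves by at most ``c`` units between consecutive time points, a greedy
max-min selection keeps ``m`` maximally dissimilar templates, each gene's
trajectory (0, log2FC_d1, ..) is assigned to the template it correlates with
best, and profile significance is judged by comparing observed memberships to
the expectation under within-gene permutation of the post-baseline values
(exhaustive over the 24 orderings of four values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError


@dataclass
class ProfileModel:
    profile_id: int
    template: tuple[float, ...]  # length n_days, starts at 0


def build_trajectories(
    tables: dict[int, pd.DataFrame], genes: list[str]
) -> pd.DataFrame:
    """Per-gene log2FC vectors (0, d1..dk) from one strategy's DE tables.

    Entries come from each day's table regardless of significance; genes
    absent from any table are dropped.
    """
    days = sorted(tables)
    keep, rows, dropped = [], [], []
    for g in genes:
        if all(g in tables[d].index and pd.notna(tables[d].loc[g, "log2FC"]) for d in days):
            keep.append(g)
            rows.append([0.0] + [float(tables[d].loc[g, "log2FC"]) for d in days])
        else:
            dropped.append(g)
    if dropped:
        warnings.warn(f"{len(dropped)} gene(s) missing from a DE table were dropped "
                      f"(first: {dropped[0]})", stacklevel=2)
    cols = [0] + days
    return pd.DataFrame(rows, index=keep, columns=cols)


def _corr_matrix(vectors: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows of `vectors` and rows of `templates`;
    zero-variance rows (flat profiles/trajectories) correlate 0 with everything."""

    def standardize(m):
        centered = m - m.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        out = np.zeros_like(centered)
        out[ok] = centered[ok] / sd[ok]
        return out, ok

    v, v_ok = standardize(vectors)
    t, t_ok = standardize(templates)
    return (v @ t.T) / vectors.shape[1]


def enumerate_templates(c: int = 1, n_transitions: int = 4) -> np.ndarray:
    """All (2c+1)^n_transitions cumulative templates, in enumeration order."""
    if c < 1:
        raise ConfigError("c must be >= 1")
    steps = list(product(range(-c, c + 1), repeat=n_transitions))
    return np.column_stack(
        [np.zeros(len(steps)), np.cumsum(np.array(steps), axis=1)]
    ) if n_transitions else np.zeros((1, 1))


def generate_model_profiles(
    c: int = 1, n_transitions: int = 4, m: int = 26
) -> list[ProfileModel]:
    """Greedy max-min selection of m templates under distance 1 - Pearson.

    Selection starts from the flat template (which by convention correlates 0
    with everything, so it is retained as a catch-all); selected templates are
    renumbered 0..m-1 in their original enumeration order.
    """
    cand = enumerate_templates(c, n_transitions)
    n_cand = cand.shape[0]
    if m > n_cand:
        raise ConfigError(f"m={m} exceeds the {n_cand} candidate templates")
    corr = _corr_matrix(cand, cand)
    dist = 1.0 - corr
    flat = int(np.flatnonzero((cand == 0).all(axis=1))[0])
    selected = [flat]
    remaining = [i for i in range(n_cand) if i != flat]
    while len(selected) < m:
        mindist = np.array([dist[i, selected].min() for i in remaining])
        best = remaining[int(np.argmax(mindist))]  # argmax takes lowest index on ties
        selected.append(best)
        remaining.remove(best)
    selected.sort()
    return [
        ProfileModel(profile_id=i, template=tuple(cand[j]))
        for i, j in enumerate(selected)
    ]


def assign_genes(
    trajectories: pd.DataFrame, profiles: list[ProfileModel]
) -> pd.DataFrame:
    """Assign each trajectory to its best-correlated template.

    Ties break to the lowest profile id; zero-variance trajectories go to the
    flat profile.
    """
    templates = np.array([p.template for p in profiles])
    if templates.shape[1] != trajectories.shape[1]:
        raise DataError("trajectory length does not match template length")
    flat_ids = [p.profile_id for p in profiles if np.all(np.array(p.template) == 0)]
    if not flat_ids:
        raise ConfigError("profile set must include the flat template")
    corr = _corr_matrix(trajectories.to_numpy(dtype=float), templates)
    best = corr.argmax(axis=1)  # first (lowest-id) max on ties
    r = corr[np.arange(corr.shape[0]), best]
    traj_sd = trajectories.to_numpy(dtype=float).std(axis=1)
    out = pd.DataFrame(
        {
            "profile": [profiles[b].profile_id for b in best],
            "r": r,
        },
        index=trajectories.index,
    )
    out.loc[traj_sd == 0, "profile"] = flat_ids[0]
    out.loc[traj_sd == 0, "r"] = 0.0
    return out


def profile_significance(
    assignment: pd.DataFrame,
    trajectories: pd.DataFrame,
    profiles: list[ProfileModel],
    b: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-expected profile sizes and binomial-tail significance.

    Each gene's post-baseline values are permuted exhaustively when the
    course is short (4! = 24 orderings for a five-point course); for longer
    courses ``b`` permutations are sampled with ``seed``.  The expected size
    of profile m is the summed per-gene assignment probability under
    permutation, and the observed size is tested against Binomial(N, E_m/N)
    with an upper tail and a Bonferroni correction across profiles.
    """
    n_genes = trajectories.shape[0]
    n_post = trajectories.shape[1] - 1
    templates = np.array([p.template for p in profiles])
    ids = [p.profile_id for p in profiles]
    perms = list(permutations(range(n_post)))
    exhaustive = len(perms) <= b
    if not exhaustive:
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(n_post)) for _ in range(b)]
    prob = np.zeros((n_genes, len(profiles)))
    traj = trajectories.to_numpy(dtype=float)
    flat_col = ids.index(next(p.profile_id for p in profiles if np.all(np.array(p.template) == 0)))
    for perm in perms:
        permuted = np.column_stack([traj[:, 0], traj[:, 1:][:, perm]])
        corr = _corr_matrix(permuted, templates)
        best = corr.argmax(axis=1)
        zero = permuted.std(axis=1) == 0
        best[zero] = flat_col
        prob[np.arange(n_genes), best] += 1.0
    prob /= len(perms)
    expected = prob.sum(axis=0)
    observed = np.array(
        [(assignment["profile"] == pid).sum() for pid in ids], dtype=int
    )
    n = max(n_genes, 1)
    pvals = np.array(
        [
            stats.binom.sf(obs - 1, n, exp / n) if exp > 0 else (1.0 if obs == 0 else 0.0)
            for obs, exp in zip(observed, expected)
        ]
    )
    padj = np.minimum(pvals * len(profiles), 1.0)
    return pd.DataFrame(
        {
            "profile": ids,
            "template": [",".join(f"{v:g}" for v in p.template) for p in profiles],
            "observed": observed,
            "expected": expected,
            "pvalue": pvals,
            "padj": padj,
            "significant": padj <= alpha,
            "exhaustive_permutations": len(perms) if exhaustive else 0,
            "sampled_permutations": 0 if exhaustive else len(perms),
        }
    ).set_index("profile")
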