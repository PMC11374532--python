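"""Regulatory-module prioritization.

Three evidence layers are combined the way Fig-5-style TF->target networks are
usually built in plant transcriptomics:

1. expression support — per-target random-forest regressions of the target on
   all TF expression profiles; normalized variance-reduction importances are
   the edge weights, kept above a threshold (default 0.1);
2. motif support — the TF's binding motif found in the target's promoter, per
   motif library, with ATG-relative coordinates (-1 = base immediately 5' of
   the ATG; a 6-mer planted at -1594 spans -1594..-1589 inclusive);
3. tiering — tier 1: expression edge only; tier 2: motif support in exactly
   one library; tier 3: support in both libraries.

Candidate targets are finally ranked by the mean of their per-day log2 fold
changes across the treatment-vs-control and treatment-vs-baseline contrasts.

Consensus motifs are matched exactly (IUPAC codes allowed, an N base in the
promoter never matches); PWM motifs are scored by log-odds against a 0-order
background with an exact tail probability obtained by dynamic programming over
the integer-discretized score distribution, FIMO-style.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import ConfigError, DataError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Motif:
    """A binding motif: IUPAC consensus or a 4-column PWM (rows = positions)."""

    motif_id: str
    library: str
    consensus: str | None = None
    pwm: np.ndarray | None = None  # shape (width, 4), columns in ACGT order
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if (self.consensus is None) == (self.pwm is None):
            raise ConfigError("motif needs exactly one of consensus or pwm")
        if self.consensus is not None:
            self.consensus = self.consensus.upper()
            if len(self.consensus) < 4:
                raise ConfigError("consensus length must be >= 4")
            bad = set(self.consensus) - set(IUPAC)
            if bad:
                raise ConfigError(f"non-IUPAC characters in consensus: {bad}")
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
                raise ConfigError("pwm must have shape (width, 4)")
            if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
                raise ConfigError("pwm rows must sum to 1")

    @property
    def width(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[0]


def load_consensus_tsv(path) -> list[Motif]:
    """Consensus motif table with columns motif, library, consensus."""
    df = pd.read_csv(path, sep="\t")
    return [
        Motif(motif_id=r["motif"], library=r["library"], consensus=r["consensus"])
        for _, r in df.iterrows()
    ]


def load_minimal_meme(path, library: str) -> list[Motif]:
    """Minimal MEME-format PWMs via Biopython."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for rec in records:
        pwm = np.column_stack([rec.pwm[b] for b in BASES])
        out.append(Motif(motif_id=rec.name, library=library, pwm=pwm))
    return out


# ---------------------------------------------------------------------------
# expression edges


def infer_edges(
    expression: pd.DataFrame,
    tfs: list[str],
    targets: list[str],
    n_trees: int = 1000,
    seed: int = 0,
    weight_min: float = 0.1,
    max_features: str | float = "sqrt",
) -> pd.DataFrame:
    """Tree-ensemble importance edges, GENIE3-style.

    ``expression`` is genes x samples (log2(TPM+1) recommended); each gene is
    standardized, each target regressed on all TFs except itself with a seeded
    random forest, and impurity importances (normalized to sum 1 per target)
    become edge weights.  Edges with weight > ``weight_min`` are returned.
    """
    if expression.shape[1] < 8:
        raise DataError("need >= 8 samples to infer edges")
    missing = [t for t in tfs if t not in expression.index]
    if missing:
        raise DataError(f"TFs absent from the expression matrix: {missing[:5]}")
    x = expression.to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0), 0.0)
    zf = pd.DataFrame(z, index=expression.index, columns=expression.columns)
    rows = []
    ss = np.random.SeedSequence([int(seed) % (2**31), 77])
    child_seeds = {t: int(s.generate_state(1)[0] % (2**31)) for t, s in zip(targets, ss.spawn(len(targets)))}
    for target in targets:
        if target not in zf.index:
            continue
        preds = [tf for tf in tfs if tf != target]
        if not preds:
            continue
        y = zf.loc[target].to_numpy()
        if expression.loc[target].std() == 0:
            warnings.warn(f"target {target!r} has zero variance; skipped", stacklevel=2)
            continue
        xmat = zf.loc[preds].to_numpy().T
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=child_seeds[target],
            n_jobs=1,
        )
        rf.fit(xmat, y)
        imp = rf.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        for tf, w in zip(preds, imp):
            rows.append((tf, target, float(w)))
    edges = pd.DataFrame(rows, columns=["tf", "target", "weight"])
    return edges[edges["weight"] > weight_min].reset_index(drop=True)


# ---------------------------------------------------------------------------
# motif scanning


def _consensus_regex(consensus: str) -> re.Pattern:
    return re.compile("(?=(" + "".join(f"[{IUPAC[c]}]" for c in consensus) + "))")


def _pwm_score_table(motif: Motif, scale: int = 1000) -> tuple[np.ndarray, dict[int, float]]:
    """Integer log-odds matrix and the exact tail probability of each total
    score under the 0-order background (dynamic programming convolution)."""
    bg = np.asarray(motif.background, dtype=float)
    with np.errstate(divide="ignore"):
        logodds = np.log2((motif.pwm + 1e-9) / bg)
    scores = np.rint(logodds * scale).astype(int)
    dist: dict[int, float] = {0: 1.0}
    for row in scores:
        nxt: dict[int, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + int(row[b])
                nxt[key] = nxt.get(key, 0.0) + p * bg[b]
        dist = nxt
    keys = np.array(sorted(dist))
    probs = np.array([dist[k] for k in keys])
    tail = np.cumsum(probs[::-1])[::-1]
    tail_map = {int(k): float(t) for k, t in zip(keys, tail)}
    return scores, tail_map


def scan_motifs(
    promoters: dict[str, str], motifs: list[Motif], threshold: float = 1e-5
) -> pd.DataFrame:
    """Scan promoters on both strands; coordinates are ATG-relative.

    A forward-strand string offset i in a promoter of length L maps to
    start = i - L, end = start + width - 1 (inclusive).  Consensus motifs use
    exact IUPAC matching; PWM motifs report a hit when the exact score-tail
    probability is <= ``threshold``.
    """
    pwm_tables = {
        m.motif_id: _pwm_score_table(m) for m in motifs if m.pwm is not None
    }
    rows = []
    for gene, seq in promoters.items():
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise DataError(f"promoter {gene!r} contains invalid characters: {bad}")
        L = len(seq)
        for motif in motifs:
            w = motif.width
            if motif.consensus is not None:
                pat = _consensus_regex(motif.consensus)
                for m in pat.finditer(seq):
                    i = m.start()
                    rows.append((gene, motif.motif_id, motif.library, i - L,
                                 i - L + w - 1, "+", np.nan, 0.0))
                rc = revcomp(seq)
                for m in _consensus_regex(motif.consensus).finditer(rc):
                    j = m.start()
                    i = L - j - w
                    rows.append((gene, motif.motif_id, motif.library, i - L,
                                 i - L + w - 1, "-", np.nan, 0.0))
            else:
                scores, tail = pwm_tables[motif.motif_id]
                idx = np.array([BASES.find(c) for c in seq])
                for strand in "+-":
                    s_idx = idx if strand == "+" else np.array(
                        [BASES.find(c) for c in revcomp(seq)]
                    )
                    for j in range(L - w + 1):
                        window = s_idx[j : j + w]
                        if (window < 0).any():
                            continue  # N never matches
                        total = int(scores[np.arange(w), window].sum())
                        p = tail.get(total)
                        if p is None:
                            keys = np.array(sorted(tail))
                            p = tail[int(keys[keys >= total][0])] if (keys >= total).any() else 0.0
                        if p <= threshold:
                            i = j if strand == "+" else L - j - w
                            score_bits = total / 1000.0
                            rows.append((gene, motif.motif_id, motif.library,
                                         i - L, i - L + w - 1, strand, score_bits, p))
    return pd.DataFrame(
        rows,
        columns=["gene", "motif", "library", "start", "end", "strand", "score", "pvalue"],
    )


# ---------------------------------------------------------------------------
# tiering and ranking


def tier_edges(
    edges: pd.DataFrame, hits: pd.DataFrame, tf_motifs: pd.DataFrame
) -> pd.DataFrame:
    """Attach per-library motif support and the evidence tier to each edge.

    ``tf_motifs`` has columns (tf, motif, library).  Tier 1: expression edge
    only; tier 2: the TF's motif hits the target promoter in exactly one
    library; tier 3: hits in both.
    """
    motif_lib = tf_motifs.set_index("motif")["library"].to_dict()
    tf_of_motif = tf_motifs.set_index("motif")["tf"].to_dict()
    libraries = sorted(tf_motifs["library"].unique())
    support: dict[tuple[str, str], set[str]] = {}
    for _, h in hits.iterrows():
        tf = tf_of_motif.get(h["motif"])
        if tf is None:
            continue
        support.setdefault((tf, h["gene"]), set()).add(motif_lib[h["motif"]])
    out = edges.copy()
    per_lib = {lib: [] for lib in libraries}
    tiers = []
    for _, e in out.iterrows():
        libs = support.get((e["tf"], e["target"]), set())
        for lib in libraries:
            per_lib[lib].append(lib in libs)
        tiers.append(1 + min(len(libs), 2))
    for lib in libraries:
        out[f"hits_{lib}"] = per_lib[lib]
    out["tier"] = tiers
    return out


def rank_candidates(
    targets: list[str],
    tc_tables: dict[int, pd.DataFrame],
    ts_tables: dict[int, pd.DataFrame],
) -> pd.DataFrame:
    """Rank candidate targets by mean log2FC across the TC and TS contrasts.

    The score averages the per-day log2FC over both contrast families (eight
    values for a four-day course); ties break on the maximum single-day value;
    genes missing from any table rank last and are flagged.
    """
    rows = []
    for gene in targets:
        vals = []
        missing = False
        for tables in (tc_tables, ts_tables):
            for day in sorted(tables):
                t = tables[day]
                if gene in t.index and pd.notna(t.loc[gene, "log2FC"]):
                    vals.append(float(t.loc[gene, "log2FC"]))
                else:
                    missing = True
        score = float(np.mean(vals)) if vals else -np.inf
        peak = float(np.max(vals)) if vals else -np.inf
        rows.append((gene, score, peak, missing))
    out = pd.DataFrame(rows, columns=["gene", "rank_score", "max_log2FC", "missing"])
    out = out.sort_values(
        ["missing", "rank_score", "max_log2FC", "gene"],
        ascending=[True, False, False, True],
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
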