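"""Seeded synthetic data for the dual-condition fruit-set time course.

The generator emulates the layout of the study design the pipeline targets:
berries sampled at days 0, 1, 2, 4 and 8 after treatment, a control (C) and a
cytokinin-treatment (T) arm sharing a single day-0 baseline, three biological
replicates per cell, negative-binomial counts.  Genes are planted into classes
that map one-to-one onto the per-day three-way DEG Venn regions used by the
VDEG screen:

``null``
    constant mean everywhere; should never be called.
``ns_equal``
    the same time effect in both arms (Venn region d: DE against baseline in
    both arms but not between arms — must NOT become a VDEG).
``cppu_only``
    effect only in the treatment arm (region f).
``both_diff``
    same-sign effects in both arms whose magnitudes differ by ``effect_lfc``
    (region g).
``ns_suppressed``
    effect only in the control arm, i.e. the natural response is held at
    baseline under treatment (region e).

Everything is deterministic given ``SimConfig.seed``; each generator draws from
a named substream so the pieces can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

CLASS_NAMES = ("null", "ns_equal", "cppu_only", "both_diff", "ns_suppressed")

DEFAULT_CLASS_FRACTIONS = {
    "null": 0.70,
    "ns_equal": 0.075,
    "cppu_only": 0.075,
    "both_diff": 0.075,
    "ns_suppressed": 0.075,
}

TF_FAMILIES = ("MYB", "ERF", "bHLH", "WRKY", "NAC", "bZIP")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    ``baseline_mean_log`` is the (location, scale) of the natural-log-normal
    distribution of per-gene baseline mean counts.  ``dispersion`` is the NB
    dispersion alpha with Var = mu + alpha * mu**2.  ``effect_lfc`` is the
    planted effect in log2 units.  ``lib_size_spread`` is the sigma of the
    log-normal multiplicative library-size factors.
    """

    n_genes: int = 2000
    n_reps: int = 3
    days: tuple[int, ...] = (0, 1, 2, 4, 8)
    baseline_mean_log: tuple[float, float] = (4.0, 1.0)
    dispersion: float = 0.1
    effect_lfc: float = 2.0
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    lib_size_spread: float = 0.15
    promoter_length: int = 2000
    n_tfs: int = 20
    n_edges: int = 10
    edge_coefficient: float = 3.0
    edge_noise_sd: float = 0.25
    tf_walk_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_reps < 2:
            raise ConfigError("n_reps must be >= 2")
        days = tuple(self.days)
        if days[0] != 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigError("days must be strictly increasing and start at 0")
        self.days = days
        missing = set(CLASS_NAMES) - set(self.class_fractions)
        if missing:
            raise ConfigError(f"class_fractions missing classes: {sorted(missing)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_fractions must sum to 1, got {total!r}")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.n_tfs < 0 or self.n_edges < 0:
            raise ConfigError("n_tfs and n_edges must be >= 0")
        if self.n_tfs > self.n_genes:
            raise ConfigError("n_tfs cannot exceed n_genes")

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream derived from the root seed."""
        digest = sum((i + 1) * b for i, b in enumerate(stream.encode())) % (2**31)
        return np.random.default_rng([int(self.seed) % (2**31), digest])


@dataclass
class TruthLabels:
    """Ground truth recorded by the generators."""

    classes: dict[str, str]
    tf_families: dict[str, str]
    edges: list[tuple[str, str, float]]
    motif_occurrences: list[tuple[str, str, int, str]]  # gene, motif, start, strand
    lib_factors: dict[str, float] = field(default_factory=dict)
    planted_term: str | None = None

    def genes_of_class(self, label: str) -> list[str]:
        return [g for g, c in self.classes.items() if c == label]

    def to_json(self) -> str:
        payload = {
            "classes": self.classes,
            "tf_families": self.tf_families,
            "edges": [list(e) for e in self.edges],
            "motif_occurrences": [list(o) for o in self.motif_occurrences],
            "lib_factors": self.lib_factors,
            "planted_term": self.planted_term,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthLabels":
        d = json.loads(text)
        return cls(
            classes=d["classes"],
            tf_families=d["tf_families"],
            edges=[tuple(e) for e in d["edges"]],
            motif_occurrences=[tuple(o) for o in d["motif_occurrences"]],
            lib_factors=d.get("lib_factors", {}),
            planted_term=d.get("planted_term"),
        )


def make_design(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: C0 plus (C, T) x post-baseline days x replicates."""
    rows = []
    for rep in range(1, config.n_reps + 1):
        rows.append((f"C0_r{rep}", "C", 0, rep))
    for day in config.days[1:]:
        for cond in ("C", "T"):
            for rep in range(1, config.n_reps + 1):
                rows.append((f"{cond}{day}_r{rep}", cond, day, rep))
    return pd.DataFrame(rows, columns=["sample", "condition", "day", "replicate"]).set_index(
        "sample"
    )


def _class_log2_effect(label: str, cond: str, day: int, effect: float) -> float:
    """Planted log2 offset from baseline for a (class, condition, day) cell."""
    if day == 0 or label == "null":
        return 0.0
    if label == "ns_equal":
        return effect
    if label == "cppu_only":
        return effect if cond == "T" else 0.0
    if label == "ns_suppressed":
        return effect if cond == "C" else 0.0
    if label == "both_diff":
        # same-sign effects in both arms separated by `effect`, both clearing
        # the DEG threshold so the gene joins all three per-day DEG sets
        return 2.0 * effect if cond == "T" else effect
    raise ConfigError(f"unknown class label {label!r}")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def expected_log2_means(config: SimConfig, truth: TruthLabels) -> pd.DataFrame:
    """Noise-free generative log2 mean offsets per gene and (condition, day) cell.

    Used by tests to check the Venn-membership pattern of each class
    analytically, without sampling noise.
    """
    cells = [("C", 0)] + [(c, d) for d in config.days[1:] for c in ("C", "T")]
    genes = list(truth.classes)
    out = pd.DataFrame(0.0, index=genes, columns=[f"{c}{d}" for c, d in cells])
    for gene in genes:
        label = truth.classes[gene]
        for cond, day in cells:
            out.loc[gene, f"{cond}{day}"] = _class_log2_effect(
                label, cond, day, config.effect_lfc
            )
    return out


def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, TruthLabels]:
    """Draw the count matrix, design, gene lengths and truth labels.

    TF genes (the first ``n_tfs`` gene ids) are forced to class ``null`` and
    instead follow smooth per-day random-walk trajectories so the network
    stage has informative regulators; about half the TFs walk differently in
    the two arms.  Planted TF->target edges are recorded in the truth but the
    expression dependency itself is applied by :func:`simulate_tf_targets`.
    """
    design = make_design(config)
    width = max(4, len(str(config.n_genes - 1)))
    genes = [f"g{i:0{width}d}" for i in range(config.n_genes)]

    rng_cls = config.rng("classes")
    fractions = [config.class_fractions[c] for c in CLASS_NAMES]
    labels = rng_cls.choice(len(CLASS_NAMES), size=config.n_genes, p=fractions)
    classes = {g: CLASS_NAMES[k] for g, k in zip(genes, labels)}

    tfs = genes[: config.n_tfs]
    tf_families = {}
    for i, tf in enumerate(tfs):
        classes[tf] = "null"
        tf_families[tf] = TF_FAMILIES[i % len(TF_FAMILIES)]

    rng_base = config.rng("baseline")
    base_mean = rng_base.lognormal(*config.baseline_mean_log, size=config.n_genes)
    lengths = pd.Series(
        config.rng("lengths").integers(300, 5000, size=config.n_genes),
        index=genes,
        name="length",
    )

    rng_lib = config.rng("libsize")
    lib_factors = pd.Series(
        rng_lib.lognormal(0.0, config.lib_size_spread, size=design.shape[0]),
        index=design.index,
    )

    # per-gene, per-cell log2 offsets
    cells = [("C", 0)] + [(c, d) for d in config.days[1:] for c in ("C", "T")]
    offset = {cell: np.zeros(config.n_genes) for cell in cells}
    for j, gene in enumerate(genes):
        lab = classes[gene]
        if lab != "null":
            for cond, day in cells:
                offset[(cond, day)][j] = _class_log2_effect(
                    lab, cond, day, config.effect_lfc
                )

    # TF trajectories: random walk over days, shared or arm-specific
    rng_tf = config.rng("tf_walk")
    n_days = len(config.days)
    for j, tf in enumerate(tfs):
        shared = rng_tf.random() < 0.5
        walk_c = np.concatenate([[0.0], np.cumsum(rng_tf.normal(0, config.tf_walk_sd, n_days - 1))])
        walk_t = walk_c if shared else np.concatenate(
            [[0.0], np.cumsum(rng_tf.normal(0, config.tf_walk_sd, n_days - 1))]
        )
        for di, day in enumerate(config.days):
            if day == 0:
                continue
            offset[("C", day)][j] = walk_c[di]
            offset[("T", day)][j] = walk_t[di]

    rng_counts = config.rng("counts")
    counts = np.zeros((config.n_genes, design.shape[0]), dtype=np.int64)
    for s, sample in enumerate(design.index):
        cond = design.loc[sample, "condition"]
        day = int(design.loc[sample, "day"])
        mu = base_mean * np.exp2(offset[(cond, day)]) * lib_factors[sample]
        counts[:, s] = _nb_sample(rng_counts, mu, config.dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=design.index)

    # planted edges: targets drawn from non-TF null genes
    rng_edges = config.rng("edges")
    candidates = [g for g in genes[config.n_tfs :] if classes[g] == "null"]
    edges: list[tuple[str, str, float]] = []
    if tfs and config.n_edges > 0:
        targets = rng_edges.choice(candidates, size=min(config.n_edges, len(candidates)), replace=False)
        for i, tgt in enumerate(targets):
            tf = tfs[int(rng_edges.integers(len(tfs)))]
            edges.append((tf, str(tgt), float(config.edge_coefficient)))

    truth = TruthLabels(
        classes=classes,
        tf_families=tf_families,
        edges=edges,
        motif_occurrences=[],
        lib_factors={s: float(v) for s, v in lib_factors.items()},
    )
    return counts_df, design, lengths, truth


def simulate_tf_targets(
    config: SimConfig,
    truth: TruthLabels,
    counts: pd.DataFrame,
) -> pd.DataFrame:
    """Overlay planted TF->target dependencies onto the count matrix.

    For each planted edge the target's per-sample log2 mean becomes
    ``intercept + coefficient * z`` where ``z`` is the TF's standardized
    log2 expression across all samples, plus Gaussian noise; counts are then
    re-drawn NB.  Returns a new count matrix.
    """
    out = counts.copy()
    rng = config.rng("tf_targets")
    lib = pd.Series(truth.lib_factors).reindex(counts.columns)
    for tf, target, coeff in truth.edges:
        tf_expr = np.log2(counts.loc[tf].to_numpy() / lib.to_numpy() + 1.0)
        sd = tf_expr.std()
        z = (tf_expr - tf_expr.mean()) / sd if sd > 0 else np.zeros_like(tf_expr)
        base = max(float(counts.loc[target].mean()), 1.0)
        log2_mu = np.log2(base) + coeff * z + rng.normal(0, config.edge_noise_sd, z.size)
        mu = np.exp2(log2_mu) * lib.to_numpy()
        out.loc[target] = _nb_sample(rng, mu, config.dispersion)
    return out


def make_motif_libraries(config: SimConfig, truth: TruthLabels) -> pd.DataFrame:
    """One consensus motif per TF in library ``libA``; ~80% of TFs also get a
    distinct motif in ``libB``.  Returns columns (motif, library, tf, consensus)."""
    rng = config.rng("motifs")
    rows = []
    seen: set[str] = set()

    def fresh(width: int) -> str:
        while True:
            s = "".join(rng.choice(list("ACGT"), size=width))
            if s not in seen and revcomp(s) not in seen:
                seen.add(s)
                return s

    for i, tf in enumerate(truth.tf_families):
        rows.append((f"{tf}_A", "libA", tf, fresh(6)))
        if rng.random() < 0.8:
            rows.append((f"{tf}_B", "libB", tf, fresh(7)))
    return pd.DataFrame(rows, columns=["motif", "library", "tf", "consensus"])


def _place_edge_motifs(
    config: SimConfig, truth: TruthLabels, motifs: pd.DataFrame, rng: np.random.Generator
) -> None:
    """Record random, non-overlapping planting coordinates for each planted
    edge's motifs in the target promoter (libA always, libB when the TF has
    one)."""
    by_tf = motifs.groupby("tf")
    occupied: dict[str, list[tuple[int, int]]] = {}
    for gene, motif, start, strand in truth.motif_occurrences:
        w = len(motifs.set_index("motif").loc[motif, "consensus"])
        occupied.setdefault(gene, []).append((start, start + w - 1))
    for tf, target, _coeff in truth.edges:
        if tf not in by_tf.groups:
            continue
        for _, row in by_tf.get_group(tf).iterrows():
            w = len(row.consensus)
            spans = occupied.setdefault(target, [])
            for _attempt in range(200):
                start = int(rng.integers(-config.promoter_length, -w + 1))
                end = start + w - 1
                if all(end < a - 1 or start > b + 1 for a, b in spans):
                    spans.append((start, end))
                    truth.motif_occurrences.append(
                        (target, row.motif, start, "+" if rng.random() < 0.5 else "-")
                    )
                    break


def simulate_promoters(
    config: SimConfig,
    truth: TruthLabels,
    motifs: pd.DataFrame,
    genes: list[str] | None = None,
) -> dict[str, str]:
    """Build promoter sequences with planted motifs and a scrubbed background.

    Promoters are i.i.d. uniform ACGT of ``promoter_length`` bp, written 5'->3'
    and ending immediately before the ATG (ATG-relative start -L .. -1).  Any
    occurrence already listed in ``truth.motif_occurrences`` is honoured;
    occurrences for planted edges are placed at random coordinates and
    recorded.  Background matches of any library consensus (either strand)
    outside recorded sites are removed by local resampling, so consensus scans
    yield exactly the recorded hits.
    """
    L = config.promoter_length
    consensus_by_motif = motifs.set_index("motif")["consensus"].to_dict()
    longest = max((len(s) for s in consensus_by_motif.values()), default=0)
    if longest > L:
        raise ConfigError("motif longer than promoter")
    for gene, motif, start, strand in truth.motif_occurrences:
        w = len(consensus_by_motif[motif])
        if start < -L or start + w - 1 > -1:
            raise ConfigError(
                f"planted occurrence of {motif} at {start} outside promoter"
            )

    rng = config.rng("promoters")
    _place_edge_motifs(config, truth, motifs, rng)

    if genes is None:
        genes = list(truth.classes)
    planted: dict[str, list[tuple[int, str, str]]] = {g: [] for g in genes}
    for gene, motif, start, strand in truth.motif_occurrences:
        if gene not in planted:
            continue
        word = consensus_by_motif[motif]
        if strand == "-":
            word = revcomp(word)
        planted[gene].append((start + L, word, strand))

    scrub_words = set()
    for w in consensus_by_motif.values():
        scrub_words.add(w)
        scrub_words.add(revcomp(w))

    promoters: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for gene in genes:
        seq = rng.choice(bases, size=L)
        protected = np.zeros(L, dtype=bool)
        for off, word, _strand in planted[gene]:
            seq[off : off + len(word)] = list(word)
            protected[off : off + len(word)] = True
        s = "".join(seq)
        for _round in range(100):
            dirty: set[int] = set()
            for word in scrub_words:
                i = s.find(word)
                while i != -1:
                    span = range(i, i + len(word))
                    if not all(protected[j] for j in span):
                        dirty.update(j for j in span if not protected[j])
                    i = s.find(word, i + 1)
            if not dirty:
                break
            arr = np.array(list(s))
            idx = sorted(dirty)
            arr[idx] = rng.choice(bases, size=len(idx))
            s = "".join(arr)
        else:  # pragma: no cover
            raise ConfigError("could not scrub promoter background")
        promoters[gene] = s
    return promoters


def simulate_annotations(
    config: SimConfig, truth: TruthLabels, n_terms: int = 15, enriched_frac: float = 0.6
) -> pd.DataFrame:
    """Gene->term annotation with one term planted enriched among the
    ``cppu_only`` genes (recorded in ``truth.planted_term``)."""
    rng = config.rng("annotations")
    genes = list(truth.classes)
    namespaces = ("BP", "MF", "CC")
    rows = []
    planted_term = "TERM:planted_cppu"
    truth.planted_term = planted_term
    cppu = set(truth.genes_of_class("cppu_only"))
    for g in genes:
        p = enriched_frac if g in cppu else 0.02
        if rng.random() < p:
            rows.append((g, planted_term, "BP"))
    for t in range(n_terms):
        term = f"TERM:{t:04d}"
        ns = namespaces[t % 3]
        members = rng.random(len(genes)) < 0.05
        for g, m in zip(genes, members):
            if m:
                rows.append((g, term, ns))
    return pd.DataFrame(rows, columns=["gene", "term", "namespace"])


def write_bundle(path, config: SimConfig) -> dict[str, str]:
    """Generate the full synthetic input bundle and write it as plain text.

    Returns a manifest of written files.  Convenience wrapper used by the CLI
    ``simulate`` command and the examples.
    """
    from pathlib import Path

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    counts, design, lengths, truth = simulate_counts(config)
    counts = simulate_tf_targets(config, truth, counts)
    motifs = make_motif_libraries(config, truth)
    promoters = simulate_promoters(config, truth, motifs)
    annotation = simulate_annotations(config, truth)

    files = {}

    def save(name, fn):
        p = out / name
        fn(p)
        files[name] = str(p)

    save("counts.tsv", lambda p: counts.rename_axis("gene").to_csv(p, sep="\t"))
    save("design.tsv", lambda p: design.reset_index().to_csv(p, sep="\t", index=False))
    save(
        "gene_lengths.tsv",
        lambda p: lengths.rename_axis("gene").to_frame().to_csv(p, sep="\t"),
    )
    save("annotation.tsv", lambda p: annotation.to_csv(p, sep="\t", index=False))
    save(
        "tf_families.tsv",
        lambda p: pd.DataFrame(
            sorted(truth.tf_families.items()), columns=["gene", "family"]
        ).to_csv(p, sep="\t", index=False),
    )
    save("motifs.tsv", lambda p: motifs.to_csv(p, sep="\t", index=False))
    save("truth.json", lambda p: p.write_text(truth.to_json()))

    def write_fasta(p):
        with open(p, "w") as fh:
            for gene, seq in promoters.items():
                fh.write(f">{gene}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    save("promoters.fasta", write_fasta)
    targets = sorted({t for _, t, _ in truth.edges})
    save(
        "focus_targets.txt",
        lambda p: p.write_text("\n".join(targets) + ("\n" if targets else "")),
    )
    return files
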