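"""Pipeline orchestration: configuration, staged artifacts and the summary.

The stages mirror the analysis order of a dual-condition fruit-set time
course: quantify -> per-strategy DE -> VDEG screen -> profile clustering ->
enrichment -> network -> candidate ranking.  Every stage reads its upstream
artifacts from the run directory and writes plain-text outputs there, so a
single stage can be re-run from cached artifacts with identical results.  All
randomness flows from one root seed via named substreams.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import de, enrichment, profiles as profiles_mod, quantify, regnet, simulate, vdeg
from .errors import ConfigError, DataError, StageError

log = logging.getLogger("vdegkit")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "vdegkit_run",
    "inputs": {
        "counts": None,
        "design": None,
        "lengths": None,
        "annotation": None,
        "tf_families": None,
        "promoters": None,
        "motifs": None,
        "targets": None,
    },
    "sim": {},  # SimConfig overrides for the simulate command
    "quantify": {"expressed_min_tpm": 1.0, "log_transform": "log2p1"},
    "de": {"lfc_min": 1.0, "padj_max": 0.05, "prior_n": 5.0, "pseudocount": 0.5},
    "vdeg": {"share_min_periods": 3},
    "profiles": {"c": 1, "m": 26, "alpha": 0.05},
    "enrich": {"adjust": "BH", "by_namespace": True},
    "network": {
        "n_trees": 1000,
        "weight_min": 0.1,
        "motif_threshold": 1e-5,
        "max_targets": 50,
    },
}

STAGES = ("quantify", "de", "vdeg", "profiles", "enrich", "network", "rank")


def load_config(source) -> dict:
    """Merge a config mapping (or YAML/JSON file path) over the defaults.

    Unknown keys anywhere in the tree are rejected.
    """
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        import yaml

        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        user = yaml.safe_load(path.read_text()) or {}

    def merge(defaults, overrides, crumb):
        out = copy.deepcopy(defaults)
        for key, val in (overrides or {}).items():
            if key not in defaults and crumb != "sim":
                raise ConfigError(f"unknown config key: {crumb + '.' if crumb else ''}{key}")
            if isinstance(defaults.get(key), dict):
                out[key] = merge(defaults[key], val, key)
            else:
                out[key] = val
        return out

    cfg = merge(DEFAULT_CONFIG, user, "")
    # sim keys are validated by SimConfig itself
    valid_sim = {f.name for f in simulate.SimConfig.__dataclass_fields__.values()}
    unknown = set(cfg["sim"]) - valid_sim
    if unknown:
        raise ConfigError(f"unknown sim config keys: {sorted(unknown)}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


class PipelineRun:
    """A run directory plus the stage methods that populate it."""

    def __init__(self, config: dict):
        self.config = load_config(config)
        self.outdir = Path(self.config["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"stages": {}, "inputs": {}, "seed": self.config["seed"]}
        if not any(
            isinstance(h, logging.FileHandler)
            and Path(getattr(h, "baseFilename", "")) == (self.outdir / "run.log").resolve()
            for h in log.handlers
        ):
            handler = logging.FileHandler(self.outdir / "run.log")
            handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
            log.addHandler(handler)

    # -- inputs ------------------------------------------------------------

    def _input_path(self, key: str, required: bool = True) -> Path | None:
        val = self.config["inputs"].get(key)
        if val is None:
            if required:
                raise ConfigError(f"inputs.{key} is not configured")
            return None
        path = Path(val)
        if not path.exists():
            raise DataError(f"inputs.{key} does not exist: {path}")
        self.manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
        return path

    def load_counts(self):
        counts = _read_tsv(self._input_path("counts")).astype(np.int64)
        design = pd.read_csv(self._input_path("design"), sep="\t").set_index("sample")
        lengths = _read_tsv(self._input_path("lengths"))["length"]
        if (counts.to_numpy() < 0).any():
            raise DataError("count matrix contains negative entries")
        return counts, design, lengths

    # -- stages ------------------------------------------------------------

    def stage_quantify(self) -> None:
        counts, design, lengths = self.load_counts()
        qdir = self.outdir / "quantify"
        qdir.mkdir(exist_ok=True)
        tpm = quantify.compute_tpm(counts, lengths)
        pmeans = quantify.period_means(tpm, design)
        flags, expressed = quantify.filter_expressed(
            pmeans, self.config["quantify"]["expressed_min_tpm"]
        )
        coords, evr = quantify.pca_qc(
            tpm, design, genes=expressed,
            log_transform=self.config["quantify"]["log_transform"],
        )
        tpm.rename_axis("gene").to_csv(qdir / "tpm.tsv", sep="\t")
        pmeans.rename_axis("gene").to_csv(qdir / "period_means.tsv", sep="\t")
        (qdir / "expressed_genes.txt").write_text("\n".join(expressed) + "\n")
        coords.rename_axis("sample").to_csv(qdir / "pca.tsv", sep="\t")
        (qdir / "pca_variance.json").write_text(
            json.dumps({"explained_variance_ratio": [float(v) for v in evr]})
        )
        self._done("quantify", dict(self.config["quantify"]))

    def stage_de(self) -> None:
        counts, design, lengths = self.load_counts()
        ddir = self.outdir / "de"
        ddir.mkdir(exist_ok=True)
        params = self.config["de"]
        factors = de.size_factors(counts)
        dispersions = de.estimate_dispersion(
            counts, design, factors, n_prior=params["prior_n"]
        )
        factors.rename_axis("sample").to_frame().to_csv(ddir / "size_factors.tsv", sep="\t")
        dispersions.rename_axis("gene").to_frame().to_csv(ddir / "dispersions.tsv", sep="\t")
        for strategy in vdeg.STRATEGIES:
            for spec in vdeg.build_contrasts(design, strategy):
                table = de.wald_test(
                    counts, design, spec, factors, dispersions,
                    pseudocount=params["pseudocount"],
                )
                table.rename_axis("gene").to_csv(ddir / f"{spec.name}.tsv", sep="\t")
        self._done("de", dict(params))

    def _load_de_tables(self, design) -> dict[str, dict[int, pd.DataFrame]]:
        ddir = self.outdir / "de"
        days = sorted(int(d) for d in design["day"].unique() if int(d) != 0)
        out: dict[str, dict[int, pd.DataFrame]] = {}
        for strategy in vdeg.STRATEGIES:
            out[strategy] = {}
            for d in days:
                path = ddir / f"{strategy}_d{d}.tsv"
                if not path.exists():
                    raise StageError(f"de stage artifact missing: {path}")
                out[strategy][d] = _read_tsv(path)
        return out

    def _deg_sets(self, tables, strategy, days) -> dict[int, de.DegSet]:
        params = self.config["de"]
        return {
            d: de.call_degs(
                tables[strategy][d],
                name=f"{strategy}_d{d}",
                lfc_min=params["lfc_min"],
                padj_max=params["padj_max"],
                day=d,
            )
            for d in days
        }

    def stage_vdeg(self) -> None:
        counts, design, lengths = self.load_counts()
        vdir = self.outdir / "vdeg"
        vdir.mkdir(exist_ok=True)
        tables = self._load_de_tables(design)
        days = sorted(tables["TC"])
        sets = {s: self._deg_sets(tables, s, days) for s in vdeg.STRATEGIES}
        frames = []
        for d in days:
            rec = vdeg.vdeg_classify(sets["NS"][d], sets["TS"][d], sets["TC"][d])
            rec = vdeg.vdeg_direction(rec, tables["TC"][d])
            frames.append(rec)
        records = pd.concat(frames, ignore_index=True)
        records.to_csv(vdir / "vdegs.tsv", sep="\t", index=False)

        k = self.config["vdeg"]["share_min_periods"]
        up = {d: set(records.query("day == @d and direction == 'up'")["gene"]) for d in days}
        down = {d: set(records.query("day == @d and direction == 'down'")["gene"]) for d in days}
        shared_up, shared_down = vdeg.shared_across_periods(up, down, k=k)
        (vdir / "shared_up.txt").write_text("\n".join(sorted(shared_up)) + "\n")
        (vdir / "shared_down.txt").write_text("\n".join(sorted(shared_down)) + "\n")

        venns = {
            strategy: vdeg.venn_summary(
                {f"{strategy}_d{d}": sets[strategy][d].genes for d in days}
            )
            for strategy in vdeg.STRATEGIES
        }
        (vdir / "venn.json").write_text(json.dumps(venns, sort_keys=True, indent=1))
        vdeg.upset_table(
            {f"TC_d{d}": sets["TC"][d].genes for d in days}
        ).to_csv(vdir / "tc_upset.tsv", sep="\t", index=False)
        self._done("vdeg", {"share_min_periods": k})

    def stage_profiles(self) -> None:
        counts, design, lengths = self.load_counts()
        pdir = self.outdir / "profiles"
        pdir.mkdir(exist_ok=True)
        params = self.config["profiles"]
        tables = self._load_de_tables(design)
        days = sorted(tables["TC"])
        tf_path = self._input_path("tf_families", required=False)
        tf_genes = (
            set(pd.read_csv(tf_path, sep="\t")["gene"]) if tf_path else set()
        )
        n_transitions = len(days)
        models = profiles_mod.generate_model_profiles(
            c=params["c"], n_transitions=n_transitions, m=params["m"]
        )
        for strategy in vdeg.STRATEGIES:
            sets = self._deg_sets(tables, strategy, days)
            detfs = sorted(
                set.union(*(s.genes for s in sets.values())) & tf_genes
            ) if tf_genes else []
            traj = profiles_mod.build_trajectories(tables[strategy], detfs)
            if traj.empty:
                assignment = pd.DataFrame(columns=["profile", "r"])
                signif = profiles_mod.profile_significance(
                    assignment, traj.reindex(columns=[0] + days), models,
                    alpha=params["alpha"],
                )
            else:
                assignment = profiles_mod.assign_genes(traj, models)
                signif = profiles_mod.profile_significance(
                    assignment, traj, models, alpha=params["alpha"]
                )
            assignment.rename_axis("gene").to_csv(
                pdir / f"{strategy}_assignment.tsv", sep="\t"
            )
            signif.to_csv(pdir / f"{strategy}_profiles.tsv", sep="\t")
            if tf_genes and not assignment.empty:
                fam = pd.read_csv(tf_path, sep="\t").set_index("gene")["family"]
                profile_sets = {
                    int(pid): set(block.index)
                    for pid, block in assignment.groupby("profile")
                }
                fam_enrich = enrichment.tf_family_enrich(profile_sets, fam)
                fam_enrich.to_csv(
                    pdir / f"{strategy}_family_enrichment.tsv", sep="\t", index=False
                )
        self._done("profiles", dict(params))

    def stage_enrich(self) -> None:
        edir = self.outdir / "enrich"
        edir.mkdir(exist_ok=True)
        ann = pd.read_csv(self._input_path("annotation"), sep="\t")
        population = set(
            (self.outdir / "quantify" / "expressed_genes.txt").read_text().split()
        )
        params = self.config["enrich"]
        for direction in ("up", "down"):
            path = self.outdir / "vdeg" / f"shared_{direction}.txt"
            study = set(path.read_text().split()) & population
            res = enrichment.hypergeom_enrich(
                study, population, ann,
                adjust=params["adjust"], by_namespace=params["by_namespace"],
            )
            res.to_csv(edir / f"shared_{direction}_enrichment.tsv", sep="\t", index=False)
        self._done("enrich", dict(params))

    def _network_targets(self, tf_genes: set[str]) -> list[str]:
        path = self._input_path("targets", required=False)
        if path is not None:
            return [g for g in path.read_text().split() if g]
        cap = self.config["network"]["max_targets"]
        shared = sorted(
            set((self.outdir / "vdeg" / "shared_up.txt").read_text().split())
            | set((self.outdir / "vdeg" / "shared_down.txt").read_text().split())
        )
        return [g for g in shared if g not in tf_genes][:cap]

    def stage_network(self) -> None:
        ndir = self.outdir / "network"
        ndir.mkdir(exist_ok=True)
        params = self.config["network"]
        tpm = _read_tsv(self.outdir / "quantify" / "tpm.tsv")
        expr = np.log2(tpm + 1.0)
        tf_map = pd.read_csv(self._input_path("tf_families"), sep="\t")
        tfs = [g for g in tf_map["gene"] if g in expr.index]
        targets = self._network_targets(set(tfs))
        edges = regnet.infer_edges(
            expr, tfs, targets,
            n_trees=params["n_trees"], seed=self.config["seed"],
            weight_min=params["weight_min"],
        )
        motifs = regnet.load_consensus_tsv(self._input_path("motifs"))
        promoters = _read_fasta(self._input_path("promoters"))
        promoters = {g: s for g, s in promoters.items() if g in set(targets)}
        hits = regnet.scan_motifs(promoters, motifs, threshold=params["motif_threshold"])
        tf_motifs = pd.read_csv(self._input_path("motifs"), sep="\t")[
            ["tf", "motif", "library"]
        ]
        evidence = regnet.tier_edges(edges, hits, tf_motifs)
        edges.to_csv(ndir / "edges.tsv", sep="\t", index=False)
        hits.to_csv(ndir / "motif_hits.tsv", sep="\t", index=False)
        evidence.to_csv(ndir / "edge_evidence.tsv", sep="\t", index=False)
        self._done("network", {k: params[k] for k in ("n_trees", "weight_min", "motif_threshold")})

    def stage_rank(self) -> None:
        counts, design, lengths = self.load_counts()
        rdir = self.outdir / "rank"
        rdir.mkdir(exist_ok=True)
        tables = self._load_de_tables(design)
        evidence = pd.read_csv(self.outdir / "network" / "edge_evidence.tsv", sep="\t")
        targets = sorted(set(evidence["target"])) if not evidence.empty else []
        ranked = regnet.rank_candidates(targets, tables["TC"], tables["TS"])
        ranked.to_csv(rdir / "ranked_candidates.tsv", sep="\t", index=False)
        report = []
        for _, e in evidence.iterrows():
            row = ranked[ranked["gene"] == e["target"]]
            report.append(
                {
                    "tf": e["tf"],
                    "target": e["target"],
                    "weight": float(e["weight"]),
                    "tier": int(e["tier"]),
                    "rank_score": float(row["rank_score"].iloc[0]) if not row.empty else None,
                }
            )
        report.sort(key=lambda r: (-(r["rank_score"] if r["rank_score"] is not None else -1e30), r["tf"], r["target"]))
        (rdir / "modules.json").write_text(json.dumps(report, sort_keys=True, indent=1))
        self._done("rank", {})

    # -- orchestration -----------------------------------------------------

    def _done(self, stage: str, params: dict) -> None:
        self.manifest["stages"][stage] = {"status": "done", "params": params}
        self._write_manifest()
        log.info("stage %s complete (params=%s, inputs=%s)", stage, params,
                 {k: v["sha256"][:12] for k, v in self.manifest["inputs"].items()})

    def _write_manifest(self) -> None:
        (self.outdir / "MANIFEST.json").write_text(
            json.dumps(self.manifest, sort_keys=True, indent=1)
        )

    def run(self, stages: tuple[str, ...] = STAGES, write_summary: bool | None = None) -> dict:
        if write_summary is None:
            write_summary = tuple(stages) == tuple(STAGES)
        for stage in stages:
            method = getattr(self, f"stage_{stage}")
            try:
                method()
            except Exception as exc:
                self.manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
                self._write_manifest()
                if isinstance(exc, (ConfigError, DataError)):
                    raise
                raise StageError(f"stage {stage} failed: {exc}") from exc
        if not write_summary:
            return {"stages": list(stages)}
        summary = self.summarize()
        (self.outdir / "summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=1)
        )
        return summary

    def summarize(self) -> dict:
        counts, design, lengths = self.load_counts()
        tables = self._load_de_tables(design)
        days = sorted(tables["TC"])
        summary: dict = {"seed": self.config["seed"], "days": days}
        summary["deg_counts"] = {
            s: {str(d): len(self._deg_sets(tables, s, days)[d]) for d in days}
            for s in vdeg.STRATEGIES
        }
        records = pd.read_csv(self.outdir / "vdeg" / "vdegs.tsv", sep="\t")
        per_day = {}
        for d in days:
            block = records[records["day"] == d]
            per_day[str(d)] = {
                "total": int(len(block)),
                "up": int((block["direction"] == "up").sum()),
                "down": int((block["direction"] == "down").sum()),
                "by_class": {k: int((block["klass"] == k).sum()) for k in ("e", "f", "g")},
            }
        summary["vdeg"] = per_day
        summary["shared_up"] = sorted(
            (self.outdir / "vdeg" / "shared_up.txt").read_text().split()
        )
        summary["shared_down"] = sorted(
            (self.outdir / "vdeg" / "shared_down.txt").read_text().split()
        )
        sig = {}
        for strategy in vdeg.STRATEGIES:
            t = pd.read_csv(self.outdir / "profiles" / f"{strategy}_profiles.tsv", sep="\t")
            sig[strategy] = [int(p) for p in t.loc[t["significant"], "profile"]]
        summary["significant_profiles"] = sig
        enriched = {}
        for direction in ("up", "down"):
            t = pd.read_csv(
                self.outdir / "enrich" / f"shared_{direction}_enrichment.tsv", sep="\t"
            )
            enriched[direction] = [
                {"term": r["term"], "padj": float(r["padj"])}
                for _, r in t.iterrows()
                if r["padj"] < 0.05
            ]
        summary["enriched_terms"] = enriched
        evidence = pd.read_csv(self.outdir / "network" / "edge_evidence.tsv", sep="\t")
        summary["edges"] = [
            {
                "tf": r["tf"],
                "target": r["target"],
                "weight": round(float(r["weight"]), 10),
                "tier": int(r["tier"]),
            }
            for _, r in evidence.sort_values(["target", "tf"]).iterrows()
        ]
        ranked = pd.read_csv(self.outdir / "rank" / "ranked_candidates.tsv", sep="\t")
        summary["ranked_candidates"] = [
            {"gene": r["gene"], "rank_score": round(float(r["rank_score"]), 10)}
            for _, r in ranked.iterrows()
        ]
        return summary


def run_pipeline(config) -> dict:
    """Run every stage in order and return the summary dict."""
    return PipelineRun(config).run()


def simulate_command(config) -> dict[str, str]:
    """Generate the synthetic input bundle configured under ``sim`` and point
    the run's ``inputs`` at it.  Returns the file manifest."""
    cfg = load_config(config)
    sim_kwargs = dict(cfg["sim"])
    sim_kwargs.setdefault("seed", cfg["seed"])
    sim_cfg = simulate.SimConfig(**sim_kwargs)
    outdir = Path(cfg["outdir"]) / "inputs"
    files = simulate.write_bundle(outdir, sim_cfg)
    manifest_path = Path(cfg["outdir"]) / "inputs_manifest.json"
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    manifest_path.write_text(json.dumps(files, sort_keys=True, indent=1))
    return files


def config_for_bundle(bundle_dir, outdir, seed: int = 0, **overrides) -> dict:
    """Convenience: a config whose inputs point at a simulate_command bundle."""
    b = Path(bundle_dir)
    cfg = {
        "seed": seed,
        "outdir": str(outdir),
        "inputs": {
            "counts": str(b / "counts.tsv"),
            "design": str(b / "design.tsv"),
            "lengths": str(b / "gene_lengths.tsv"),
            "annotation": str(b / "annotation.tsv"),
            "tf_families": str(b / "tf_families.tsv"),
            "promoters": str(b / "promoters.fasta"),
            "motifs": str(b / "motifs.tsv"),
            "targets": str(b / "focus_targets.txt"),
        },
    }
    cfg.update(overrides)
    return cfg
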