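"""Generator properties: determinism, planted effect sizes, promoter planting."""

import numpy as np
import pandas as pd
import pytest

import vdegkit as vk
from vdegkit.errors import ConfigError
from vdegkit.simulate import expected_log2_means, revcomp


def all_null_fractions():
    return {"null": 1.0, "ns_equal": 0, "cppu_only": 0, "both_diff": 0, "ns_suppressed": 0}


class TestSimulateCounts:
    def test_seeded_determinism(self):
        cfg = vk.SimConfig(n_genes=100, seed=7)
        c1, d1, l1, t1 = vk.simulate_counts(cfg)
        c2, d2, l2, t2 = vk.simulate_counts(vk.SimConfig(n_genes=100, seed=7))
        pd.testing.assert_frame_equal(c1, c2)
        assert t1.classes == t2.classes and t1.edges == t2.edges

    def test_all_null_config_plants_nothing(self):
        cfg = vk.SimConfig(n_genes=50, seed=3, n_tfs=0, n_edges=0,
                           class_fractions=all_null_fractions())
        *_, truth = vk.simulate_counts(cfg)
        assert all(c == "null" for c in truth.classes.values())

    def test_sample_layout(self, small_sim, small_cfg):
        counts, design, lengths, _ = small_sim
        assert counts.shape == (300, 27)
        assert (design.query("day == 0")["condition"] == "C").all()
        for day in small_cfg.days[1:]:
            cell = design[(design["day"] == day) & (design["condition"] == "T")]
            assert len(cell) == small_cfg.n_reps
        assert (lengths > 0).all()

    def test_realized_cppu_effect_matches_planted_mean(self):
        # empirical mean log2 ratio (T day-4 vs C0 group means) of cppu_only
        # genes should recover the planted 2.0 within sampling error
        cfg = vk.SimConfig(n_genes=2000, seed=1)
        counts, design, _, truth = vk.simulate_counts(cfg)
        lib = pd.Series(truth.lib_factors)
        norm = counts.div(lib, axis=1)
        t4 = norm[design.index[(design["condition"] == "T") & (design["day"] == 4)]]
        c0 = norm[design.index[design["day"] == 0]]
        genes = truth.genes_of_class("cppu_only")
        ratio = np.log2(t4.loc[genes].mean(axis=1) / c0.loc[genes].mean(axis=1))
        assert abs(ratio.mean() - cfg.effect_lfc) < 0.15

    def test_class_venn_membership_is_exact_on_generative_means(self, small_cfg):
        # noise-free log2 means must reproduce each class's intended Venn
        # pattern: membership in A (C-arm vs C0), B (T-arm vs C0), X (T vs C)
        *_, truth = vk.simulate_counts(small_cfg)
        mu = expected_log2_means(small_cfg, truth)
        lfc = small_cfg.effect_lfc
        day = 4
        for gene, label in truth.classes.items():
            if gene in truth.tf_families:
                continue
            a = abs(mu.loc[gene, f"C{day}"] - mu.loc[gene, "C0"]) >= lfc
            b = abs(mu.loc[gene, f"T{day}"] - mu.loc[gene, "C0"]) >= lfc
            x = abs(mu.loc[gene, f"T{day}"] - mu.loc[gene, f"C{day}"]) >= lfc
            pattern = {"null": (0, 0, 0), "ns_equal": (1, 1, 0), "cppu_only": (0, 1, 1),
                       "both_diff": (1, 1, 1), "ns_suppressed": (1, 0, 1)}[label]
            assert (a, b, x) == tuple(map(bool, pattern)), (gene, label)

    def test_truth_class_counts_recount(self, small_cfg):
        # the multinomial class draw is reproducible from the same substream
        *_, truth = vk.simulate_counts(small_cfg)
        rng = small_cfg.rng("classes")
        from vdegkit.simulate import CLASS_NAMES

        fractions = [small_cfg.class_fractions[c] for c in CLASS_NAMES]
        labels = rng.choice(len(CLASS_NAMES), size=small_cfg.n_genes, p=fractions)
        non_tf = list(truth.classes)[small_cfg.n_tfs :]
        for gene, k in zip(list(truth.classes), labels):
            if gene in non_tf:
                assert truth.classes[gene] == CLASS_NAMES[k]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"n_reps": 1},
            {"days": (1, 2)},
            {"days": (0, 2, 1)},
            {"class_fractions": {"null": 0.5, "ns_equal": 0.1, "cppu_only": 0.1,
                                 "both_diff": 0.1, "ns_suppressed": 0.1}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            vk.SimConfig(**kwargs)


class TestSimulatePromoters:
    def _setup(self, seed=2, n_genes=30):
        cfg = vk.SimConfig(n_genes=n_genes, seed=seed, n_tfs=4, n_edges=3)
        *_, truth = vk.simulate_counts(cfg)
        motifs = vk.make_motif_libraries(cfg, truth)
        return cfg, truth, motifs

    def test_planted_consensus_lands_at_recorded_offset(self):
        cfg, truth, motifs = self._setup()
        motifs = pd.concat(
            [motifs, pd.DataFrame([{"motif": "MYBBOX", "library": "libA",
                                    "tf": "g0000", "consensus": "TAACCA"}])],
            ignore_index=True,
        )
        gene = list(truth.classes)[-1]
        truth.motif_occurrences.append((gene, "MYBBOX", -1594, "+"))
        proms = vk.simulate_promoters(cfg, truth, motifs)
        # ATG-relative -1594 in a 2000 bp promoter is string offset 406
        assert proms[gene][406:412] == "TAACCA"

    def test_minus_strand_plants_reverse_complement(self):
        cfg, truth, motifs = self._setup(seed=4)
        motifs = pd.concat(
            [motifs, pd.DataFrame([{"motif": "MYBBOX", "library": "libA",
                                    "tf": "g0000", "consensus": "TAACCA"}])],
            ignore_index=True,
        )
        gene = list(truth.classes)[-1]
        truth.motif_occurrences.append((gene, "MYBBOX", -1000, "-"))
        proms = vk.simulate_promoters(cfg, truth, motifs)
        assert proms[gene][1000:1006] == revcomp("TAACCA") == "TGGTTA"

    def test_scrubbed_background_has_no_spurious_consensus(self):
        cfg, truth, motifs = self._setup(seed=6)
        truth.edges = []  # nothing planted
        proms = vk.simulate_promoters(cfg, truth, motifs)
        assert truth.motif_occurrences == []
        for word in motifs["consensus"]:
            for seq in proms.values():
                assert word not in seq and revcomp(word) not in seq

    def test_motif_longer_than_promoter_rejected(self):
        cfg, truth, _ = self._setup()
        cfg.promoter_length = 4
        motifs = pd.DataFrame(
            [{"motif": "m", "library": "libA", "tf": "g0000", "consensus": "ACGTA"}]
        )
        with pytest.raises(ConfigError):
            vk.simulate_promoters(cfg, truth, motifs)


class TestSimulateTfTargets:
    def test_zero_coefficient_leaves_targets_independent(self):
        cfg = vk.SimConfig(n_genes=200, seed=9, n_tfs=5, n_edges=5,
                           edge_coefficient=0.0)
        counts, design, _, truth = vk.simulate_counts(cfg)
        counts = vk.simulate_tf_targets(cfg, truth, counts)
        lib = pd.Series(truth.lib_factors).reindex(counts.columns)
        rs = []
        for tf, target, _ in truth.edges:
            x = np.log2(counts.loc[tf] / lib + 1.0)
            y = np.log2(counts.loc[target] / lib + 1.0)
            rs.append(np.corrcoef(x, y)[0, 1])
        # null correlation at n=27 has sd ~ 1/sqrt(26) ~ 0.196: individual r
        # must stay within ~2.3 sigma and the average magnitude near its
        # folded-normal expectation, far below any planted-edge signal
        assert max(abs(r) for r in rs) < 0.45
        assert np.mean(np.abs(rs)) < 0.25

    def test_strong_edge_low_noise_gives_high_correlation(self):
        cfg = vk.SimConfig(n_genes=100, seed=9, n_tfs=3, n_edges=1,
                           edge_coefficient=4.0, edge_noise_sd=0.01)
        counts, design, _, truth = vk.simulate_counts(cfg)
        counts = vk.simulate_tf_targets(cfg, truth, counts)
        tf, target, _ = truth.edges[0]
        x = np.log2(counts.loc[tf] + 1.0)
        y = np.log2(counts.loc[target] + 1.0)
        assert np.corrcoef(x, y)[0, 1] > 0.95
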