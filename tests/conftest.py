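import numpy as np
import pandas as pd
import pytest

import vdegkit as vk


@pytest.fixture(scope="session")
def small_cfg():
    return vk.SimConfig(n_genes=300, seed=7, n_tfs=8, n_edges=5)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """A small fully-simulated experiment with TF-target overlay applied."""
    counts, design, lengths, truth = vk.simulate_counts(small_cfg)
    counts = vk.simulate_tf_targets(small_cfg, truth, counts)
    return counts, design, lengths, truth


@pytest.fixture(scope="session")
def small_de(small_sim):
    """Size factors, dispersions and all twelve contrast tables."""
    counts, design, _lengths, _truth = small_sim
    factors = vk.size_factors(counts)
    dispersions = vk.estimate_dispersion(counts, design, factors)
    tables = {}
    for strategy in ("TC", "NS", "TS"):
        tables[strategy] = {}
        for spec in vk.build_contrasts(design, strategy):
            day = spec.numerator[1]
            tables[strategy][day] = vk.wald_test(
                counts, design, spec, factors, dispersions
            )
    return factors, dispersions, tables


def deg_sets_for_day(tables, day):
    a = vk.call_degs(tables["NS"][day], name=f"NS_d{day}", day=day)
    b = vk.call_degs(tables["TS"][day], name=f"TS_d{day}", day=day)
    x = vk.call_degs(tables["TC"][day], name=f"TC_d{day}", day=day)
    return a, b, x


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full synthetic pipeline run (modest size, reused read-only)."""
    root = tmp_path_factory.mktemp("pipe")
    cfg = {
        "seed": 5,
        "outdir": str(root),
        "sim": {"n_genes": 400, "n_tfs": 10, "n_edges": 5},
        "network": {"n_trees": 200},
    }
    vk.simulate_command(cfg)
    full = vk.config_for_bundle(root / "inputs", root, seed=5, network={"n_trees": 200})
    summary = vk.run_pipeline(full)
    return root, summary
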