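import logging

import numpy as np
import pandas as pd
import pytest

from secrescreen import library, pipeline, quant, simulate
from secrescreen.essentiality import essentiality_scores

logging.getLogger("secrescreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_sim():
    """A 20-gene simulated genome + annotation + truth, shared read-only."""
    cfg = simulate.SimConfig(n_genes=20, guides_per_gene=4, nb_mean=200.0, seed=11)
    genome, features = simulate.simulate_genome(cfg)
    truth = simulate.make_ground_truth(cfg)
    return cfg, genome, features, truth


@pytest.fixture(scope="session")
def small_library(small_sim):
    cfg, genome, features, _ = small_sim
    res = library.design_guides(
        genome, features, params=library.DesignParams(guides_per_gene=4)
    )
    return res.guides


def scores_from_counts(counts: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """counts -> CPM -> LFC -> per-gene essentiality scores."""
    lfc = quant.compute_lfc(quant.normalize(counts))
    return essentiality_scores(lfc, **kwargs)


@pytest.fixture(scope="session")
def acceptance_sim_scores():
    """Scores on the packaged acceptance simulation (default SimConfig)."""
    cfg = simulate.SimConfig()
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    lib = pd.DataFrame(
        {
            "guide_id": [f"{g}_g{k}" for g in genes for k in range(cfg.guides_per_gene)],
            "gene_id": np.repeat(genes, cfg.guides_per_gene),
        }
    )
    truth = simulate.make_ground_truth(cfg, genes)
    counts = simulate.simulate_screen_counts(lib, truth, cfg)
    return truth, scores_from_counts(counts)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo pipeline run shared by orchestration tests."""
    outdir = tmp_path_factory.mktemp("demo")
    manifest = pipeline.run_pipeline(pipeline.demo_config(17), outdir)
    return outdir, manifest
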