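import logging

import numpy as np
import pytest

from asbscan import asb_core, synthetic_data as sd

logging.getLogger("asbscan").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A complete small synthetic CUT&RUN dataset with planted features."""
    cfg = sd.SyntheticConfig(seed=7, n_het_sites=150, genome_length=90_000, n_genes=8)
    out = tmp_path_factory.mktemp("synth")
    art, truth = sd.build_synthetic_genome(cfg, out_dir=str(out))
    sheet = sd.simulate_cutrun_counts(art, cfg, truth, str(out))
    return {"cfg": cfg, "art": art, "truth": truth, "sheet": sheet, "dir": str(out)}


@pytest.fixture(scope="session")
def called_table(small_dataset):
    """The ASB pipeline run on the small dataset, with truth merged in."""
    ds = small_dataset
    table, summary = asb_core.call_asb(
        ds["dir"] + "/samples.tsv", ds["art"].genome, ds["art"].motifs,
        ds["art"].motif_map, [ds["dir"] + "/exclude.bed"],
        asb_core.ASBConfig(seed=7), ds["art"].genes)
    merged = table.merge(
        ds["truth"].sites[["pos", "true_theta", "is_asb", "is_cnv_artifact",
                           "is_mapping_trap", "motif_disrupted_tf", "category"]],
        on="pos", how="left")
    return {"table": table, "summary": summary, "merged": merged}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
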