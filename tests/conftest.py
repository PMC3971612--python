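import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import syntropy as sy

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_otu_table() -> sy.OtuTable:
    counts = pd.DataFrame(
        [[10, 0, 5, 3], [2, 8, 0, 1], [4, 4, 4, 4]],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=pd.Index(["otuA", "otuB", "otuC", "otuD"], name="otu_id"),
    )
    tax = pd.Series(
        [
            "k__Bacteria;p__Firmicutes;c__;o__;f__;g__Blautia;s__",
            "k__Bacteria;p__Firmicutes;c__;o__;f__;g__Blautia;s__",
            "k__Bacteria;p__Bacteroidetes;c__;o__;f__;g__Bacteroides;s__",
            "k__Bacteria;p__Proteobacteria;c__;o__;f__;g__;s__",
        ],
        index=counts.columns,
    )
    return sy.OtuTable(counts, tax)


@pytest.fixture
def small_bundle():
    """A small paired synthetic dataset with every planted structure."""
    cfg = sy.SynthConfig(
        seed=7, n_subjects=40, n_otus=60, n_metabolites=80, n_modules=2,
        module_sizes=(12, 15), n_planted_links=8, link_effect=0.7,
        n_guilds=1, guild_size=8, guild_corr=0.7, read_depth_mean=5000,
        n_pathways=12, shared_metabolite_fraction=0.8,
    )
    return sy.generate_paired_dataset(cfg)
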