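import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from phylodens import synthetic as syn
from phylodens import treekit as tk

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree():
    return tk.read_newick(TOY_NEWICK)


@pytest.fixture
def toy_vcv(toy_tree):
    return tk.build_vcv(toy_tree)


@pytest.fixture(scope="session")
def small_sim():
    """A 60-species, 2-sites-per-species synthetic dataset (study defaults)."""
    cfg = syn.SimConfig(n_species=60, sites_per_species=2, seed=42)
    return syn.simulate_table(cfg)


def random_yule(seed, n=12):
    return syn.simulate_tree(n, seed=seed)
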