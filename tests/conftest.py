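import dataclasses

import numpy as np
import pandas as pd
import pytest

from methdmr.simulate import CpGConfig, ExprConfig, GenomeConfig, LipidConfig, LinkConfig, QpcrConfig, SimConfig, SpikeInConfig


def small_sim_config(seed: int = 0, **cpg_overrides) -> SimConfig:
    """A downsized stated-world configuration for fast per-test simulations."""
    cpg_kwargs = dict(n_sites=2000, n_planted_dmrs=5)
    cpg_kwargs.update(cpg_overrides)
    cpg = CpGConfig(**cpg_kwargs)
    return SimConfig(
        seed=seed,
        genome=GenomeConfig(n_chroms=1, chrom_length=1_000_000),
        cpg=cpg,
        expr=ExprConfig(n_genes=400, n_planted_degs=20),
        lipid=LipidConfig(n_features=200, n_planted=10),
        links=LinkConfig(n_pairs=4),
        n_genes_annot=60,
    )


@pytest.fixture
def sim_config():
    return small_sim_config(seed=0)


def grouped_sites(meth_A, total_A, meth_B, total_B, spacing=50, chrom="chr1", start=1000):
    """Build a grouped-site table from parallel count lists."""
    n = len(meth_A)
    pos = start + spacing * np.arange(n)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": "+",
            "meth_A": meth_A,
            "total_A": total_A,
            "meth_B": meth_B,
            "total_B": total_B,
        }
    )
    df["level_A"] = df["meth_A"] / df["total_A"]
    df["level_B"] = df["meth_B"] / df["total_B"]
    return df
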