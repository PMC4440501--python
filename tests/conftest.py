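import numpy as np
import pandas as pd
import pytest

from strandex.io import CountMatrix, SampleMeta
from strandex.simulate import SimConfig, generate_catalogue


def make_metas(species="Nv"):
    """Full 12-sample design: 4 groups x 3 replicates."""
    return [
        SampleMeta(f"{species}_{g}_r{r}", species, g, r)
        for g in ("naive", "h0", "h4", "h24")
        for r in (1, 2, 3)
    ]


def make_counts(rows: dict, species="Nv"):
    """CountMatrix from transcript -> 12 counts (naive, h0, h4, h24 x 3 reps)."""
    metas = make_metas(species)
    df = pd.DataFrame(rows, index=[m.sample_id for m in metas]).T
    return CountMatrix(df), metas


@pytest.fixture(scope="session")
def small_catalogue():
    """A compact two-species catalogue exercising every category."""
    cfg = SimConfig(
        seed=5,
        n_sense=40,
        n_antisense_to_protein=5,
        n_antisense_to_sense=5,
        n_antisense_to_both=3,
        n_lncrna=8,
        n_unknown=6,
        n_panel_genes=6,
        n_panel_antisense=3,
        n_opposing=3,
    )
    return cfg, generate_catalogue(cfg)
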