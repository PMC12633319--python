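import numpy as np
import pandas as pd
import pytest

from hgtcooc.genome_io import RANKS
from hgtcooc.syndata import (
    SimConfig,
    simulate_genomes,
    simulate_occupancy,
    simulate_taxonomy_and_tree,
)


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def community(default_cfg):
    """One fully simulated community at the default study conditions."""
    taxonomy, newick = simulate_taxonomy_and_tree(default_cfg)
    genomes, inventories, gt = simulate_genomes(
        default_cfg, taxonomy, newick, verify_background=False
    )
    coverage, metadata = simulate_occupancy(default_cfg, gt)
    return {
        "cfg": default_cfg,
        "taxonomy_df": taxonomy,
        "taxonomy": {
            row["genome"]: tuple(row[r] for r in RANKS)
            for _, row in taxonomy.iterrows()
        },
        "newick": newick,
        "genomes": genomes,
        "inventories": inventories,
        "gt": gt,
        "coverage": coverage,
        "metadata": metadata,
    }


def make_taxonomy(**overrides) -> tuple[str, ...]:
    base = dict(
        domain="d1", phylum="p1", class_="c1", order="o1",
        family="f1", genus="g1", species="s1",
    )
    base.update(overrides)
    return (
        base["domain"], base["phylum"], base["class_"], base["order"],
        base["family"], base["genus"], base["species"],
    )


@pytest.fixture
def presence_matrix():
    """Small handmade presence matrix builder."""

    def build(columns: dict[str, list[int]], fractions=None):
        from hgtcooc.occurrence import OccurrenceMatrix

        presence = pd.DataFrame(
            {g: np.asarray(v, dtype=bool) for g, v in columns.items()}
        )
        presence.index = [f"S{i + 1}" for i in range(len(presence))]
        abundance = presence.astype(float) * 2.0
        return OccurrenceMatrix(
            presence=presence,
            abundance=abundance,
            sample_fractions=fractions or {},
        )

    return build
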