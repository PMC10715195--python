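import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from srbkit import fixtures as fx


@pytest.fixture(scope="session")
def mixed_proteome():
    """A labelled proteome with every decoy class present."""
    config = fx.FixtureConfig(
        n_taxa=4,
        seqs_per_taxon=6,
        decoy_mix={"no_tm": 0.15, "single_tm": 0.15, "fused": 0.1, "non_cd36": 0.1},
        cys_pairs=((30, 120), (60, 200)),
        motif_specs=(("M1", "QDERHKNSTY", 250),),
        seed=11,
    )
    records, truths = fx.gen_synthetic_proteome(config)
    hits = fx.domain_hits_for(records, truths)
    return config, records, truths, hits


@pytest.fixture(scope="session")
def gold_family():
    """A gold alignment: one lineage carries a 25-residue insertion."""
    config = fx.GoldAlignmentConfig(
        n_rows=8,
        ancestor_len=150,
        sub_rate=0.05,
        insertions={3: (60, 25)},
        cys_pairs=((20, 100), (40, 130)),
        seed=12,
    )
    return config, *fx.gen_gold_alignment(config)


@pytest.fixture(scope="session")
def structure_pair():
    """Reference + query with a planted 30-residue apex insertion, sigma 0.3 Å."""
    spec = fx.StructureSpec()
    ref, query, truth = fx.make_structure_pair(spec, 30, seed=13, query_noise=0.3)
    return ref, query, truth
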