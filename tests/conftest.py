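import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import retromod as rm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

ALL_CLASSES = ["full_length", "ID1", "Dpol", "solo_LTR", "other"]


@pytest.fixture(scope="session")
def consensus():
    return rm.build_consensus(7500, seed=11)


@pytest.fixture(scope="session")
def genome():
    return rm.generate_genome(6, seed=3)


@pytest.fixture(scope="session")
def planted(genome):
    """Genome with one sense insertion of every structural class."""
    specs = [
        rm.class_spec(
            cls, genome.consensus, f"e{i}", f"gene{i + 1:03d}",
            u_over_i_effect=2.0 + i, c_over_b_effect=1.5,
        )
        for i, cls in enumerate(ALL_CLASSES)
    ]
    mutated, truth = rm.plant_insertions(genome, specs)
    return mutated, truth


def make_paired_expr(ratios, base=1.0):
    """Expression frame with given per-pair C/B ratios."""
    rows = []
    for i, r in enumerate(ratios, 1):
        rows.append((f"P{i}B", "assay", base, "inserted", "B", f"P{i}"))
        rows.append((f"P{i}C", "assay", base * r, "inserted", "C", f"P{i}"))
    return pd.DataFrame(
        rows, columns=["sample_id", "assay_id", "nrq", "strain", "genotype", "pair_id"]
    )


def make_unpaired_expr(uninserted, inserted):
    rows = [(f"U{i}", "assay", v, "uninserted", "B", "") for i, v in enumerate(uninserted)]
    rows += [(f"I{i}", "assay", v, "inserted", "B", "") for i, v in enumerate(inserted)]
    return pd.DataFrame(
        rows, columns=["sample_id", "assay_id", "nrq", "strain", "genotype", "pair_id"]
    )


def make_array_events(pair_ratios, event_id="ev1", base_incl=100.0, base_excl=50.0):
    """Array frame where pair i has r_C/r_B equal to pair_ratios[i]."""
    rows = []
    for i, r in enumerate(pair_ratios, 1):
        rows.append((event_id, f"P{i}B", f"P{i}", "B", base_incl, base_excl))
        rows.append((event_id, f"P{i}C", f"P{i}", "C", base_incl * r, base_excl))
    return pd.DataFrame(
        rows, columns=["event_id", "sample_id", "pair_id", "genotype", "inclusion", "exclusion"]
    )
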