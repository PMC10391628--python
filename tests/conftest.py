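import numpy as np
import pandas as pd
import pytest

from bcrep.simulate import CohortSpec, generate_sample, make_germline_reference, population_usage
from bcrep.util import substream


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a rearrangement table from sparse row dicts with sane defaults."""
    defaults = {
        "sample_id": "s1",
        "v_call": "IGHV1*01",
        "d_call": "IGHD1*01",
        "j_call": "IGHJ1*01",
        "junction": "TGTGCAAGATGG",
        "junction_aa": "CARW",
        "isotype": "IgM",
        "sequence_alignment": "ATGGCC",
        "germline_alignment": "ATGGCC",
        "productive": True,
        "consensus_count": 1,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults, sequence_id=f"seq{i:03d}")
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(
        n_mice_per_group=2,
        ages=(16, 24),
        diets=("AL", "DR"),
        seqs_per_sample=400,
        n_clones_base=120,
        n_v=8,
        n_d=4,
        n_j=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_germline(small_spec):
    genes, lengths = make_germline_reference(
        small_spec.n_v, small_spec.n_d, small_spec.n_j, small_spec.seed
    )
    return genes


@pytest.fixture(scope="session")
def small_sample(small_spec, small_germline):
    """One 400-sequence synthetic spleen sample with its ground truth."""
    pop = population_usage(small_spec, small_spec.seed)
    meta = {"sample_id": "AL_24m_m1_spleen", "tissue": "spleen", "diet": "AL", "age_months": 24}
    rng = substream(small_spec.seed, "sample", meta["sample_id"])
    return generate_sample(small_spec, meta, small_germline, pop, rng)
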