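import numpy as np
import pytest
from hypothesis import settings

from pepseq.edits import default_edit_spec
from pepseq.library import encode_library, phosphomimetic_variants, tile_protein

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

AA20 = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(AA20, length))


@pytest.fixture(scope="session")
def edit_spec():
    return default_edit_spec()


@pytest.fixture(scope="session")
def small_library():
    """Encoded 10-member library: 5 wt tiles, 3 phosphomimetics, 2 controls."""
    records = tile_protein(random_protein(265, seed=11), source="GENE1")  # 5 tiles
    records += phosphomimetic_variants(records[0])[:3]
    records += tile_protein(random_protein(85, seed=12), source="HK1", variant_class="control")
    records += tile_protein(random_protein(85, seed=13), source="HK2", variant_class="control")
    return encode_library(records, seed=101)
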