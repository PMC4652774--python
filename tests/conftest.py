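import numpy as np
import pytest

from fmseek.fmd_index import build_index, build_text
from fmseek.lookup_table import build_lookup


def random_db(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_index():
    """One 3 kb subject, r=8, k=11 lookup table; shared by many tests."""
    rng = np.random.default_rng(42)
    db = random_db(rng, 3000)
    text = build_text([("subj0", db)], rng_seed=0)
    index = build_index(text, r=8)
    build_lookup(index, k=11)
    return db, index


@pytest.fixture(scope="session")
def multi_index():
    """Three subjects of mixed sizes with a shared repeat."""
    rng = np.random.default_rng(7)
    common = random_db(rng, 120)
    dbs = [
        ("alpha", random_db(rng, 1500) + common + random_db(rng, 400)),
        ("beta", common + random_db(rng, 900)),
        ("gamma", random_db(rng, 700)),
    ]
    text = build_text(dbs, rng_seed=0)
    index = build_index(text, r=8)
    build_lookup(index, k=11)
    return dict(dbs), index
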