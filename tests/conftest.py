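import numpy as np
import pytest
from hypothesis import settings

import repseq as rs

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_meta(sample_id="s1", mouse="control_m1", tissue="lung", subset="eTreg",
              challenge="control"):
    return rs.SampleMeta(sample_id, mouse, tissue, subset, challenge)


def make_repertoire(counts, meta=None, v="TRAV1", j="TRAJ1", prefix="CA", suffix="F"):
    """A small repertoire with the given counts and distinct junctions."""
    import zlib

    from repseq.simulate import back_translate

    rng = np.random.default_rng(zlib.crc32(str(list(counts)).encode()))
    clones = []
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for i, c in enumerate(counts):
        aa = prefix + "".join(alphabet[int(k)] for k in rng.integers(0, 20, 6)) + alphabet[i % 20] + suffix
        clones.append(
            rs.Clonotype(back_translate(aa, rng), aa, v, j, count=int(c))
        )
    return rs.Repertoire.build(meta or make_meta(), clones)


@pytest.fixture(scope="session")
def model():
    return rs.default_model()


@pytest.fixture(scope="session")
def demo_cohort():
    """The bundled demo cohort at seed 1, shared across tests."""
    return rs.generate_cohort(rs.demo_design(1))
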