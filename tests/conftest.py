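import numpy as np
import pytest

from gcskewsim import CircularSequence, FixtureSpec, make_fixture_genome


@pytest.fixture(scope="session")
def fixture_200k():
    """A 200 kb planted-truth genome (point terminus opposite ori)."""
    seq, ann, truth = make_fixture_genome(FixtureSpec(length=200_000, seed=7))
    return seq, ann, truth


@pytest.fixture(scope="session")
def ecoli_like_annotation():
    """E. coli-scale Ter/dif geometry with the printed TerC coordinates."""
    from gcskewsim import SiteAnnotation, TerSite
    L = 4_641_652
    # ori placed so the locus opposite it is the printed 1,603,784 bp
    ori = 1_603_784 + L // 2
    return SiteAnnotation(
        genome_length=L, ori=ori, dif=1_588_773, shift_point=1_550_412,
        ter_sites=(
            TerSite("TerC", 1_607_184, "clockwise"),
            TerSite("TerB", 1_681_747, "clockwise"),
            TerSite("TerA", 1_339_771, "counterclockwise"),
            TerSite("TerD", 1_279_758, "counterclockwise"),
            TerSite("TerE", 1_209_758, "counterclockwise"),
        ))


def random_sequence(length, seed, p=(0.25, 0.25, 0.25, 0.25), id="rand"):
    rng = np.random.default_rng(seed)
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length,
                     p=list(p))
    return CircularSequence(id, arr.tobytes().decode())
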