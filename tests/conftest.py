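import pytest

from motifteach.space import TeachingSpace, default_space


@pytest.fixture(scope="session")
def full_space() -> TeachingSpace:
    """The full 1024 x 220 ten-bead space (built once per session)."""
    return default_space()


@pytest.fixture(scope="session")
def reduced_space() -> TeachingSpace:
    """Length-6 necklaces over the four 2-bead motifs: 64 x 4.

    Every one of the four hypotheses tiles a 6-bead necklace exactly, so
    all columns are nonempty and the space exercises the same code paths
    at a size where slow reference implementations stay cheap.
    """
    return TeachingSpace(necklace_length=6, motif_pool=("00", "01", "10", "11"))


@pytest.fixture(scope="session")
def worked_example(full_space):
    """The running worked example: motifs {000, 11, 001}."""
    h = ("11", "000", "001")
    return {
        "h": h,
        "col": full_space.col(h),
        "simple": "0000000111",
        "clumpy": "0001100011",
    }
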