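import pytest

from octadkit import load_fixture_cross, load_fixture_table
from octadkit.io import CrossDef, MarkerDef, Octad, SporeRecord


@pytest.fixture(scope="session")
def cross():
    """The packaged Sjk10 x Sjk19 cross definition (4 markers)."""
    return load_fixture_cross()


@pytest.fixture(scope="session")
def table(cross):
    """The packaged nine-ascus linear-octad genotype table."""
    return load_fixture_table(cross)


@pytest.fixture(scope="session")
def two_marker_cross():
    """Minimal cross: two centromere-linked markers on one chromosome."""
    return CrossDef(
        markers=(
            MarkerDef("locA", "chr1", "left", 1.0, "A", "a"),
            MarkerDef("locB", "chr1", "left", 10.0, "B", "b"),
        )
    )


def make_octad(genotypes, ascus_id="x", dead=(), linear=True):
    """Build an octad from 8 genotype tuples; positions A-H in order.

    ``dead`` positions get viable=False (genotype kept as given unless the
    entry is None, in which case all-unknown).
    """
    from octadkit.io import POSITIONS, UNKNOWN

    spores = []
    n_markers = len(next(g for g in genotypes if g is not None))
    for pos, g in zip(POSITIONS, genotypes):
        viable = pos not in dead
        if g is None:
            g = tuple(UNKNOWN for _ in range(n_markers))
            viable = False
        spores.append(
            SporeRecord(ascus_id=ascus_id, position=pos, viable=viable, genotype=g)
        )
    return Octad(ascus_id=ascus_id, spores=tuple(spores), linear=linear)
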