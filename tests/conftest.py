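import numpy as np
import pytest

from cgfold.cg_model_io import CGConformation, Nucleotide
from cgfold.fixtures import FixtureSpec, build_ideal_pair_or_helix


@pytest.fixture
def two_residue_conf() -> CGConformation:
    """A minimal 2-residue conformation with hand-placed beads."""
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 3.0, (5, 3)).round(3)
    g = rng.normal(10.0, 3.0, (5, 3)).round(3)
    return CGConformation([
        Nucleotide("A", 1, "A", a),
        Nucleotide("A", 2, "G", g),
    ])


@pytest.fixture
def helix8():
    """8-bp ideal duplex plus its designed pair list."""
    return build_ideal_pair_or_helix(FixtureSpec(kind="ideal_helix", stem=8))


@pytest.fixture
def hairpin20():
    """20-nt hairpin fixture (8-bp stem, 4-nt loop) plus designed pairs."""
    return build_ideal_pair_or_helix(FixtureSpec(kind="hairpin", stem=8, loop=4))


@pytest.fixture
def coil20():
    conf, _ = build_ideal_pair_or_helix(
        FixtureSpec(kind="coil", sequence="GGGGGGGGAAAACCCCCCCC")
    )
    return conf
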