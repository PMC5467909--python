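import numpy as np
import pytest

from ttfield import (
    DEFAULT_TISSUE_TABLE,
    TissueTable,
    TumorSpec,
    build_head_phantom,
    build_slab_phantom,
    embed_tumor,
)


@pytest.fixture(scope="session")
def two_layer_slab():
    """5+5 mm slab at 1 mm resolution with sigma = 1 / 2 S/m layers."""
    mesh = build_slab_phantom([(5.0, "gm"), (5.0, "wm")], 20.0, 1.0)
    table = TissueTable({**DEFAULT_TISSUE_TABLE, "gm": 1.0, "wm": 2.0})
    return mesh, table


@pytest.fixture(scope="session")
def head_refined():
    """Default head phantom graded around a deep-right tumour position."""
    return build_head_phantom(
        resolution=7.0, refine_center=(40.0, 0.0, 0.0),
        refine_radius=14.0, fine_resolution=2.0,
    )


@pytest.fixture(scope="session")
def head_symmetric():
    """Uniform-lattice head phantom (mirror-symmetric mesh)."""
    return build_head_phantom(resolution=6.0)


@pytest.fixture(scope="session")
def head_with_tumor(head_refined):
    return embed_tumor(head_refined, TumorSpec((40.0, 0.0, 0.0)))
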