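import numpy as np
import pytest

from ghostabc.models import PANEL
from ghostabc.synthetic import toy_genotype_matrix


@pytest.fixture
def toy_panel_matrix():
    """Five hand-written sites across the seven-genome panel."""
    dosages = np.array(
        [
            [0, 0, 1, 0, 0, 0, 0],
            [2, 2, 0, 0, 1, 0, 0],
            [0, 1, 1, 1, 0, 0, 2],
            [0, 0, 0, 0, 0, 0, 1],
            [2, 2, 2, 2, 2, 2, 1],
        ],
        dtype=np.int8,
    )
    return toy_genotype_matrix(dosages, PANEL)


@pytest.fixture(scope="session")
def admixed_panel_03():
    """Planted 30% European-like ancestry in the African-like target X."""
    from ghostabc.simulate import desk_fragments
    from ghostabc.synthetic import make_admixed_panel

    geno, manifest = make_admixed_panel(
        0.3, fragments=desk_fragments(400, 20_000), rng_seed=2024
    )
    return geno, manifest


@pytest.fixture(scope="session")
def admixed_panel_null():
    """Same panel, no admixture pulse: the D-statistic null."""
    from ghostabc.simulate import desk_fragments
    from ghostabc.synthetic import make_admixed_panel

    geno, manifest = make_admixed_panel(
        0.0, fragments=desk_fragments(400, 20_000), rng_seed=2025
    )
    return geno, manifest
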