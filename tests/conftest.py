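import numpy as np
import pytest

from pegkin.reactivity import published_linear_model
from pegkin.structure import AmineSite, parse_pdb
from pegkin.synthetic import ToySpec, make_toy_structure


@pytest.fixture
def linear_model():
    return published_linear_model()


@pytest.fixture
def line_structure():
    """3 lysines on a line, 7 Å NZ spacing, leading half helix-annotated."""
    return parse_pdb(make_toy_structure(
        ToySpec(n_lysines=3, placement="line", spacing=7.0, helix_fraction=0.4)))


def make_sites(rates, positions, pka=10.0):
    """AmineSites whose linear-model prediction equals the requested rates.

    Inverts rate = α·esa + β·pKa + γ for the published coefficients so
    geometry and kinetics can be chosen independently.
    """
    sites = []
    for i, (rate, pos) in enumerate(zip(rates, positions)):
        esa = (rate + 1.32 * pka - 15.02) / 0.06
        sites.append(AmineSite(
            site_id=f"A:K{i + 1}", kind="lysine", chain_id="A",
            residue_number=i + 1, nitrogen_coords=np.asarray(pos, dtype=float),
            esa=esa, pka=pka, ss_class="helix"))
    return sites


@pytest.fixture
def site_factory():
    return make_sites
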