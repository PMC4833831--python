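import numpy as np
import pytest

from ticycle import toy_alchemy as ta
from ticycle.synthetic_data import PlantedRecipe, gen_planted_structure


@pytest.fixture
def lj_pair_states():
    """A-state LJ+Coulomb pair that disappears in the B state."""
    a = ta.NonbondedPairState(c6=2.5e-3, c12=2.5e-6, q_i=0.5, q_j=0.5)
    b = ta.NonbondedPairState()
    return a, b


@pytest.fixture
def harmonic_system():
    """1D single particle, tether spring 1 -> 4 kJ/mol/nm^2 at 300 K."""
    return ta.ToyAlchemicalSystem(
        dimensionality=1, tethers=(ta.Tether((0.0,), 1.0, 4.0),)
    )


@pytest.fixture
def pair_system():
    """Two tethered 1D particles with a disappearing LJ+Coulomb pair.

    Tethers are stiff (150 kJ/mol/nm^2) so the swapped particle ordering
    carries negligible Boltzmann weight: in 1D a Metropolis chain cannot
    cross the LJ core, so a soft-tether system would be non-ergodic
    relative to the full configuration integral.
    """
    a = ta.NonbondedPairState(c6=2.5e-3, c12=2.5e-6, q_i=0.4, q_j=-0.4)
    b = ta.NonbondedPairState()
    return ta.ToyAlchemicalSystem(
        dimensionality=1,
        tethers=(ta.Tether((0.0,), 150.0, 150.0), ta.Tether((0.4,), 150.0, 150.0)),
        pairs={(0, 1): (a, b)},
    )


@pytest.fixture
def planted():
    """Structure with contacts at 0.25/0.45/0.70 nm, a like-charge decoy,
    two ideal H-bonds and one bent decoy."""
    recipe = PlantedRecipe(
        opposite_charge_nm=(0.25, 0.45, 0.70),
        like_charge_nm=(0.25,),
        hbond_nm=(0.28, 0.30),
        bent_hbond=((0.28, 60.0),),
    )
    return gen_planted_structure(recipe, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
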