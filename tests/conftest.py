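import math

import pytest

from gatekmc.gate import DiffusionModel, GateGeometry


@pytest.fixture
def single_bond_pure_unbinding() -> GateGeometry:
    """One bond, no rebinding, instantaneous displacement: the gate
    opening time is exactly one exponential waiting time."""
    return GateGeometry(
        n_units=1,
        valency=1,
        local_host_concentration=0.0,
        diffusion=DiffusionModel(D0=math.inf),
    )


def pure_unbinding_geometry(n_bonds: int) -> GateGeometry:
    """N independent bonds, no rebinding, instant displacement: opening
    time is the maximum of N i.i.d. exponentials (at zero force)."""
    return GateGeometry(
        n_units=n_bonds,
        valency=1,
        local_host_concentration=0.0,
        diffusion=DiffusionModel(D0=math.inf),
    )
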