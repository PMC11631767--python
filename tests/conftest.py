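import numpy as np
import pytest

from lockrkit.switch_thermo import ReadoutModel, SwitchParams, Totals


@pytest.fixture
def base_params() -> SwitchParams:
    """A plausible sensor: closed state favoured by 3 kcal/mol, micromolar
    key:cage affinity, ~100 nM target affinity (nanomolar sensing regime)."""
    return SwitchParams(dG_close=-3.0, Kd_key=1e-6, Kd_target=1e-7)


@pytest.fixture
def base_totals() -> Totals:
    return Totals(C_tot=1e-6, K_tot=1e-6, T_tot=0.0)


@pytest.fixture
def readout() -> ReadoutModel:
    return ReadoutModel(R_min=1.0, R_max=2.0)


def random_param_sets(rng: np.random.Generator, n: int):
    """Random but physically sensible switch instances."""
    for _ in range(n):
        yield (
            SwitchParams(
                dG_close=rng.uniform(-6.0, 2.0),
                Kd_key=10 ** rng.uniform(-9.0, -5.0),
                Kd_target=10 ** rng.uniform(-9.0, -5.0),
            ),
            Totals(
                C_tot=10 ** rng.uniform(-8.0, -5.0),
                K_tot=10 ** rng.uniform(-8.0, -5.0),
                T_tot=10 ** rng.uniform(-9.0, -5.0),
            ),
        )
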