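import numpy as np
import pytest
from rdkit import Chem

from qex.desirability import ADSParams, DesirabilityFunction
from qex.fixtures import FixtureSpec, generate_actives, generate_benchmark
from qex.properties import PROPERTY_NAMES, AlertSet
from qex.scoring import QEXModel


@pytest.fixture(scope="session")
def brenk_alerts() -> AlertSet:
    return AlertSet.default()


@pytest.fixture(scope="session")
def demo_alert_path():
    import importlib.resources as ir
    return str(ir.files("qex") / "data" / "demo_alerts_synthetic.txt")


@pytest.fixture(scope="session")
def small_actives():
    """500 synthetic actives from the default property families."""
    return generate_actives(FixtureSpec(n_active=500, seed=1))


@pytest.fixture(scope="session")
def small_benchmark():
    """Well-separated synthetic benchmark: 300 actives vs 2000 inactives."""
    spec = FixtureSpec(n_active=300, n_inactive=2000, separation=3.0, seed=7)
    return generate_benchmark(spec)


def flat_desirability(name: str, floor_value: float) -> DesirabilityFunction:
    """A desirability equal to 1 at x=0 and ``floor_value`` at x <= -50.

    Uses a symmetric ADS bump on a baseline: a = floor_value,
    b = 4*(1 - floor_value) so the raw maximum (at x = 0) is exactly 1.
    """
    params = ADSParams(a=floor_value, b=4.0 * (1.0 - floor_value),
                       c=0.0, d=0.0, e=1.0, f=1.0)
    return DesirabilityFunction(params=params, norm_max=1.0,
                                property_name=name, fit_domain=(-1.0, 1.0),
                                peak=0.0)


def manual_model(qvalues, weights=None) -> QEXModel:
    """A hand-built model whose desirability for property i equals
    ``qvalues[i]`` at x = -100 and 1.0 at x = 0 (closed-form test rig)."""
    fns = tuple(flat_desirability(name, q)
                for name, q in zip(PROPERTY_NAMES, qvalues))
    w = np.ones(8) if weights is None else np.asarray(weights, float)
    return QEXModel(desirabilities=fns, weights=w, metadata={"synthetic": True})


@pytest.fixture
def rig_model_factory():
    return manual_model


def mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, f"bad test SMILES {smiles}"
    return m
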