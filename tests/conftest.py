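import numpy as np
import pytest

import fluxtopes as ft


@pytest.fixture(scope="session")
def toy():
    return ft.toy_model()


@pytest.fixture(scope="session")
def toy_topes(toy):
    return ft.enumerate_topes(toy)


@pytest.fixture(scope="session")
def toy_efms(toy, toy_topes):
    efm_set, summary = ft.enumerate_efms_via_topes(toy, result=toy_topes)
    return efm_set, summary


@pytest.fixture(scope="session")
def toy_bounded(toy):
    """Toy model with upper bounds 10 on the uptake reactions R1, R3."""
    from dataclasses import replace
    ub = np.array([10.0, np.inf, 10.0, np.inf, np.inf, np.inf])
    return replace(toy, ub=ub)


@pytest.fixture
def chain():
    """Two-reaction unbranched chain: fluxes are always proportional."""
    return ft.MetabolicNetwork(
        N=np.array([[1.0, -1.0]]),
        metabolite_ids=("A",),
        reaction_ids=("R1", "R2"),
        reversible=np.array([True, True]),
    )
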