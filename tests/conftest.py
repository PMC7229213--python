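import warnings

import numpy as np
import pytest

import netgs
from netgs.io import _build_model


@pytest.fixture(scope="session")
def minimal():
    """The checked-in 8-reaction photoautotrophic network and its compositions."""
    model, comps = netgs.make_toy_model("minimal")
    return model, comps


@pytest.fixture(scope="session")
def minimal_ref(minimal):
    model, _ = minimal
    return netgs.solve_reference_fba(model, netgs.RatioConstraints.fixed())


def make_chain(k: int = 3, cap: float = 10.0):
    """A pure linear chain uptake -> ... -> biomass; all fluxes equal."""
    mets = [f"M{i}" for i in range(k)]
    records = [{"id": "UPTAKE", "stoich": {mets[0]: 1}, "lb": 0.0, "ub": cap, "tag": ""}]
    for i in range(k - 1):
        records.append(
            {"id": f"CONV{i}", "stoich": {mets[i]: -1, mets[i + 1]: 1},
             "lb": 0.0, "ub": 1000.0, "tag": ""}
        )
    records.append(
        {"id": "BIOMASS", "stoich": {mets[-1]: -1}, "lb": 0.0, "ub": 1000.0, "tag": "biomass"}
    )
    return _build_model(mets, records, model_id=f"chain{k}")


@pytest.fixture()
def chain():
    return make_chain()


@pytest.fixture(scope="session")
def small_panel(minimal):
    """A 120-accession simulated panel on the minimal network (shared, read-only)."""
    model, comps = minimal
    cfg = netgs.SimConfig(n_accessions=120, n_markers=300, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return netgs.simulate_panel(model, comps, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
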