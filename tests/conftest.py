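import numpy as np
import pytest

from traitsynergy import SingleFactorModel, keyed_item_matrix, load_item_specs, score_composite
from traitsynergy.simulate import generate_population, make_config
from traitsynergy.windows import run_window_analysis

TEST_COLS = [f"test_{j}" for j in range(1, 13)]


@pytest.fixture(scope="session")
def specs():
    return load_item_specs()


@pytest.fixture(scope="session")
def rg_sim():
    """Large reliability-gradient dataset with fitted intelligence scores."""
    cfg = make_config("reliability_gradient", {"n": 100_000, "seed": 1})
    data, truth = generate_population(cfg)
    model = SingleFactorModel().fit(data[TEST_COLS])
    iq = model.transform(data[TEST_COLS])
    return {"cfg": cfg, "data": data, "truth": truth, "model": model, "iq": iq}


@pytest.fixture(scope="session")
def rg_windows(rg_sim, specs):
    """Window analysis of the dependable composite on the gradient dataset."""
    data, iq = rg_sim["data"], rg_sim["iq"]
    items = keyed_item_matrix(data, specs, "dependable")
    comp = score_composite(data, specs, "dependable")
    win = run_window_analysis(
        iq, items, comp,
        {"gpa": data["gpa"].to_numpy(), "degree": data["degree"].to_numpy()},
    )
    return {"items": items, "composite": comp, "win": win}


@pytest.fixture(scope="session")
def homo_sim():
    """Homoscedastic (k = 0) dataset: no reliability gradient by construction."""
    cfg = make_config(
        "custom",
        {"n": 100_000, "seed": 2, "outcome_coefs": (0.46, 0.0, 0.2, 0.0, 0.0)},
    )
    data, truth = generate_population(cfg)
    model = SingleFactorModel().fit(data[TEST_COLS])
    iq = model.transform(data[TEST_COLS])
    return {"cfg": cfg, "data": data, "truth": truth, "iq": iq}


@pytest.fixture(scope="session")
def homo_windows(homo_sim, specs):
    data, iq = homo_sim["data"], homo_sim["iq"]
    items = keyed_item_matrix(data, specs, "dependable")
    comp = score_composite(data, specs, "dependable")
    win = run_window_analysis(iq, items, comp, {"gpa": data["gpa"].to_numpy()})
    return {"items": items, "composite": comp, "win": win}


@pytest.fixture(scope="session")
def null_sim():
    """Null-scenario dataset: every outcome coefficient is zero."""
    cfg = make_config("null", {"n": 100_000, "seed": 7})
    data, truth = generate_population(cfg)
    model = SingleFactorModel().fit(data[TEST_COLS])
    iq = model.transform(data[TEST_COLS])
    return {"cfg": cfg, "data": data, "truth": truth, "iq": iq}
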