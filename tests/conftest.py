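"""Shared synthetic fixtures; everything is generated at test time."""

import warnings

import numpy as np
import pytest
from hypothesis import settings

import cytomix as cm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# noisy-convergence warnings from small fixtures are expected in tests
warnings.filterwarnings("ignore", message="archetypal analysis poorly converged")


@pytest.fixture(scope="session")
def truth():
    return cm.make_ground_truth(seed=1)


@pytest.fixture(scope="session")
def cells(truth):
    return cm.sample_cells(truth, n_cells_per_subpop=100, seed=2)


@pytest.fixture(scope="session")
def cpm(cells):
    return cm.cpm_normalize(cells)


@pytest.fixture(scope="session")
def true_labels(cells):
    return cells.cell_meta["subpop"]


@pytest.fixture(scope="session")
def signature(cpm, true_labels, cells):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        de = cm.wilcoxon_de(cpm, true_labels, alpha=0.01)
        return cm.build_signature(cpm, true_labels, de, cells_raw=cells)


@pytest.fixture(scope="session")
def bulk20(truth):
    """20 bulk mixtures at the study conditions: noise 0.1, platform shift on."""
    rng = np.random.default_rng(7)
    F = rng.dirichlet(np.ones(truth.n_subpops), 20)
    bulk, fractions = cm.mix_bulk(truth, F, noise_sd=0.1,
                                  apply_platform_shift=True, seed=8)
    return cm.cpm_normalize(bulk), fractions


@pytest.fixture(scope="session")
def screen(truth):
    design = cm.ScreenDesign(
        perturbagens=["drugA", "drugB", "drugC", "drugD"],
        doses={"drugA": [0.1, 1.0], "drugB": [0.1, 1.0],
               "drugC": [0.5, 5.0], "drugD": [0.5, 5.0]},
    )
    truth.kill_rates = cm.make_kill_rates(design, truth, seed=21)
    bulk, meta, comps = cm.simulate_perturbation_screen(
        truth, design, noise_sd=0.1, seed=31)
    return design, bulk, meta, comps
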