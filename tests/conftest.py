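import numpy as np
import pytest

from pulmuq import default_network, la_pressure, mpa_inflow
from pulmuq.solver import SolverConfig, run_simulation
from pulmuq.structured_tree import (
    SpectralGrid,
    TreeParameters,
    generate_tree_index,
    grand_admittance,
)

# coarse-but-stable settings used for whole-network test simulations
FAST = dict(dx=0.25, dt_target=2.05e-4, max_cycles=250)
N_MODES = 256


@pytest.fixture(scope="session")
def net():
    return default_network()


@pytest.fixture(scope="session")
def nominal_beds(net):
    """Beds at the prior-midpoint tree parameters, subtrees kept for RIA D1."""
    grid = SpectralGrid(0.85, N_MODES)
    beds = {}
    for a, v in net.terminal_pairs:
        p = TreeParameters(root_radius=net[a].radius)
        beds[a] = grand_admittance(
            generate_tree_index(p), p, grid, venous_root_radius=net[v].radius,
            keep_subtrees=(a == "RIA D1"),
        )
    return beds


@pytest.fixture(scope="session")
def nominal_field(net, nominal_beds):
    """Converged default-network simulation at prior-midpoint parameters."""
    return run_simulation(
        net, nominal_beds, mpa_inflow(0.85), la_pressure(0.85), SolverConfig(**FAST)
    )


@pytest.fixture(scope="session")
def sobol_study(tmp_path_factory):
    """Shared small ensemble + degree-2 surrogates for sensitivity checks.

    72 prior samples on the coarse grid; quantities: MPA pressure time
    series, MPA wave-type energies, per-vessel cyclic stretch.
    """
    from pulmuq.pce import ParameterPrior, fit_ols, sample_prior
    from pulmuq.study import StudyConfig, run_ensemble, stack_outputs

    cfg = StudyConfig(
        **FAST, n_modes=N_MODES, N_train=72, N_val=0, order=2, seed=7,
        out_dir=str(tmp_path_factory.mktemp("sobol_study")),
    )
    prior = ParameterPrior()
    thetas, xi = sample_prior(prior, cfg.N_train, cfg.seed)
    results, errors = run_ensemble(thetas, cfg)
    outputs, ok = stack_outputs(results)
    surrogates = {}
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # N < 2J by design at this scale
        for key in list(outputs):
            if key.startswith(("p:MPA", "wia:", "vessel_cs")):
                surrogates[key] = fit_ols(
                    xi[ok], outputs[key], order=2, prior=prior, canonical=True
                )
    return dict(config=cfg, outputs=outputs, surrogates=surrogates, prior=prior)
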