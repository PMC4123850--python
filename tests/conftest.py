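import pytest

import eagleadapt as ea


@pytest.fixture(scope="session")
def base():
    """Published parameter set: 25 sites, mean hare level."""
    return ea.SiteParams()


@pytest.fixture(scope="session")
def grid50():
    return ea.BeliefGrid(50)


@pytest.fixture(scope="session")
def solved50(base, grid50):
    """Lazily solved policies at grid order 50, shared across tests.

    Call as ``solved50(case_name, mode=None, strategy="active")``; results
    are cached so each (case, mode, strategy) is solved once per session.
    """
    cache: dict = {}

    def get(case_name: str, mode: str | None = None, strategy: str = "active"):
        case = ea.get_preset(case_name)
        eff_mode = "none" if strategy == "passive" else (mode or case.signal_mode)
        key = (case_name, eff_mode, strategy)
        if key not in cache:
            cache[key] = ea.solve_case(
                case, base, mode=mode, grid=grid50, strategy=strategy
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def solved20(base):
    """Coarse-grid (order 20) active policies used by the simulations."""
    cache: dict = {}
    grid = ea.BeliefGrid(20)

    def get(case_name: str, mode: str):
        key = (case_name, mode)
        if key not in cache:
            cache[key] = ea.solve_case(
                ea.get_preset(case_name), base, mode=mode, grid=grid
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def small_params():
    """Six-site variant for cheap exact enumerations and simulations."""
    return ea.SiteParams().with_(n_sites=6)
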