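import pytest
from hypothesis import settings

import mapalign as ma

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

#: desk-scale study conditions used by the converged-run tests
DESK_GRID = 30
SMALL_GRID = 20
STEPS_PER_NEURON = 15_000
INIT_MEAN = 50.0
RUN_SEEDS = (101, 202, 303)


@pytest.fixture(scope="session")
def converged():
    """Memoized factory for converged annealing runs.

    Several acceptance checks interrogate the same canonical runs; caching
    them keeps the suite within a sane runtime.
    """
    cache = {}

    def get(model, genotype, seed, n=DESK_GRID, steps_per_neuron=STEPS_PER_NEURON,
            init="random", snapshot_interval=500_000):
        key = (model, genotype, seed, n, steps_per_neuron, init, snapshot_interval)
        if key not in cache:
            grid = ma.build_grid(n)
            params = ma.genotype_params(model, genotype)
            state = ma.init_connectivity(grid, init, INIT_MEAN, seed=seed)
            sched = ma.AnnealSchedule(steps_per_neuron=steps_per_neuron,
                                      snapshot_interval=snapshot_interval,
                                      seed=seed)
            traj = ma.anneal(state, params, sched)
            cache[key] = (state, traj)
        return cache[key]

    return get


@pytest.fixture
def grid8():
    return ma.build_grid(8)


@pytest.fixture
def grid6():
    return ma.build_grid(6)


def random_state(grid, mean=3.0, seed=0):
    return ma.init_connectivity(grid, "random", mean, seed=seed)


@pytest.fixture
def all_conditions():
    """All (model_kind, genotype) cells of the study design."""
    return [(m, g) for m in ("correlational", "integrational")
            for g in ("WT", "Isl2EphA3", "Isl2EphA3_b2KO")]
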