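"""Shared fixtures: reduced-scale synthetic sessions and fitted state spaces.

Simulation sizes here are deliberately smaller than the study-scale defaults
(fewer units and trials, short inter-trial intervals) so the whole suite
exercises every stage end-to-end; the generator's noise levels, effect
sizes, and timing rules are the defaults throughout.
"""

import pytest

import gpstop as g
from gpstop.params import params_to_dict
from gpstop.pipeline import AnalysisConfig, prepare_session


def reduced_params(n_neurons=60, n_go=130, n_stop=30):
    task = g.TaskParams(n_go_trials=n_go, n_stop_trials=n_stop, iti_range=(1.0, 2.0))
    race = g.RaceParams()
    pop = g.PopulationParams(n_neurons=n_neurons)
    return task, race, pop


def reduced_config(seed=3, n_shuffles=300, **kw):
    task, race, pop = reduced_params(**kw)
    return AnalysisConfig(seed=seed, generator=params_to_dict(task, race, pop),
                          n_shuffles=n_shuffles)


@pytest.fixture(scope="session")
def session_config():
    return reduced_config()


@pytest.fixture(scope="session")
def session_data(session_config):
    """A classified, smoothed, aligned and PCA-fitted reduced session."""
    return prepare_session(session_config)


@pytest.fixture(scope="session")
def small_session():
    """A small raw synthetic session (trials + spikes + ground truth)."""
    task, race, pop = reduced_params(n_neurons=20, n_go=60, n_stop=15)
    return g.generate_session(task, race, pop, seed=7)


@pytest.fixture(scope="session")
def task_defaults():
    return g.TaskParams()
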