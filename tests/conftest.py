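"""Shared fixtures: hand-built trait tables and small synthetic surveys."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import funcdisp as fd
from funcdisp.traits import default_definitions

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_traits() -> fd.TraitTable:
    """Six species, the five canonical traits, simple round values."""
    data = pd.DataFrame(
        {
            "life_history": ["annual", "perennial", "perennial", "annual",
                             "perennial", "perennial"],
            "shoot_height": [10.0, 20.0, 40.0, 80.0, 160.0, 320.0],
            "specific_leaf_area": [5.0, 10.0, 20.0, 15.0, 25.0, 30.0],
            "leaf_dry_mass_content": [0.30, 0.25, 0.20, 0.15, 0.10, 0.05],
            "flowering_duration": [2.0, 3.0, 4.0, 5.0, 6.0, 8.0],
        },
        index=pd.Index([f"sp{i}" for i in range(1, 7)], name="species"),
    )
    return fd.TraitTable(data, default_definitions())


@pytest.fixture
def toy_distance() -> fd.TraitDistanceMatrix:
    """Hand-written 4-species distance matrix (not ultrametric)."""
    D = np.array(
        [
            [0.0, 1.0, 2.0, 3.0],
            [1.0, 0.0, 3.0, 2.0],
            [2.0, 3.0, 0.0, 1.0],
            [3.0, 2.0, 1.0, 0.0],
        ]
    )
    return fd.TraitDistanceMatrix(D, ["a", "b", "c", "d"])


@pytest.fixture(scope="session")
def small_survey() -> fd.SyntheticSurvey:
    """Small neutral survey shared across tests (2 regions, 4 lakes)."""
    scen = fd.SyntheticScenario(
        seed=11,
        lakes_per_region=2,
        strata_per_lake=(2, 3),
        plots_per_stratum=(3, 4),
        pool_size=20,
    )
    return fd.simulate_scenario(scen)


@pytest.fixture(scope="session")
def filtered_survey() -> fd.SyntheticSurvey:
    """Small survey with strong environmental filtering."""
    scen = fd.SyntheticScenario(
        seed=12,
        lakes_per_region=2,
        strata_per_lake=(3, 3),
        plots_per_stratum=(4, 4),
        pool_size=30,
        filtering_strength=6.0,
    )
    return fd.simulate_scenario(scen)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def brute_alpha_pw(weights: dict, d) -> float:
    """Explicit double loop over ordered species pairs."""
    present = [s for s, w in weights.items() if w > 0]
    tot = sum(weights[s] for s in present)
    f = {s: weights[s] / tot for s in present}
    num = den = 0.0
    for i in present:
        for j in present:
            if i != j:
                num += f[i] * f[j] * d(i, j)
                den += f[i] * f[j]
    return num / den


def brute_alpha_nn(weights: dict, d) -> float:
    present = [s for s, w in weights.items() if w > 0]
    tot = sum(weights[s] for s in present)
    out = 0.0
    for i in present:
        out += weights[i] / tot * min(d(i, j) for j in present if j != i)
    return out


def brute_beta_dpw(wa: dict, wb: dict, d) -> float:
    pa = [s for s, w in wa.items() if w > 0]
    pb = [s for s, w in wb.items() if w > 0]
    ta, tb = sum(wa[s] for s in pa), sum(wb[s] for s in pb)
    return sum(wa[i] / ta * wb[j] / tb * d(i, j) for i in pa for j in pb)


def brute_beta_dnn(wa: dict, wb: dict, d) -> float:
    pa = [s for s, w in wa.items() if w > 0]
    pb = [s for s, w in wb.items() if w > 0]
    ta, tb = sum(wa[s] for s in pa), sum(wb[s] for s in pb)
    left = sum(wa[i] / ta * min(d(i, j) for j in pb) for i in pa)
    right = sum(wb[j] / tb * min(d(i, j) for i in pa) for j in pb)
    return 0.5 * (left + right)


def dist_fn(dist: fd.TraitDistanceMatrix):
    return lambda i, j: dist.between(i, j)
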