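import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from connectogroup.atlas import generic_atlas
from connectogroup.core import Cohort, CohortManifest, Connectome
from connectogroup.synthetic import SimulationConfig, simulate_cohort


def make_connectome(weights, metric="SC", filtering="unfiltered", subject="s1"):
    w = np.asarray(weights, dtype=float)
    return Connectome(subject, metric, filtering, w, generic_atlas(w.shape[0]))


def random_weighted_graph(rng, n, density=0.6, dyadic=False):
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    if dyadic:
        vals = rng.choice([0.5, 1.0, 2.0, 4.0], size=(n, n))
    else:
        vals = rng.uniform(0.2, 3.0, size=(n, n))
    mask = rng.uniform(size=(n, n)) < density
    w = np.where(mask, vals, 0.0)
    w = np.triu(w, 1)
    return w + w.T


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 subjects, 10 regions, SC only — shared across fast tests."""
    cfg = SimulationConfig(n_hc=6, n_pd=6, n_regions=10, seed=11, metrics=("SC",))
    cohort, trace = simulate_cohort(cfg)
    return cohort, trace


@pytest.fixture
def toy_manifest():
    rows = [{"subject_id": f"s{i}", "group": "HC" if i < 4 else "PD",
             "sex": "F" if i % 2 else "M", "age": 60.0 + i} for i in range(8)]
    return CohortManifest(pd.DataFrame(rows))


def cohort_from_matrices(matrices, groups, metric="SC", filtering="unfiltered"):
    """Build a cohort directly from a list of weight matrices."""
    n = matrices[0].shape[0]
    labels = generic_atlas(n)
    rows, conns = [], {}
    for k, (w, g) in enumerate(zip(matrices, groups)):
        sid = f"s{k}"
        rows.append({"subject_id": sid, "group": g, "sex": "F", "age": 60.0})
        conns[(sid, metric, filtering)] = Connectome(sid, metric, filtering, w, labels)
    return Cohort(CohortManifest(pd.DataFrame(rows)), conns, labels)
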