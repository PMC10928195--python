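import dataclasses

import numpy as np
import pandas as pd
import pytest

from overyield import GeneratorConfig, StudyDesign, simulate_experiment
from overyield import schema as S
from overyield.pipeline import analysis_table
from overyield.simulate import deposition_map


def brute_force_partition(M, ry_e, Y):
    """Term-by-term evaluation of the partition equations.

    Independent oracle: plain Python sums, no shared code with the
    implementation under test.
    """
    n = len(M)
    ry = [Y[i] / M[i] for i in range(n)]
    d_ry = [ry[i] - ry_e[i] for i in range(n)]
    nbe = sum(Y) - sum(ry_e[i] * M[i] for i in range(n))
    m_bar = sum(M) / n
    d_bar = sum(d_ry) / n
    ce = n * m_bar * d_bar
    cov = sum((M[i] - m_bar) * (d_ry[i] - d_bar) for i in range(n)) / n
    se = n * cov
    return nbe, ce, se, sum(ry)


def make_mono_table(study, year, n_rate, species_to_m):
    """Hand-built monoculture reference table for scalar partition calls."""
    rows = [
        {S.STUDY: study, S.YEAR: year, S.N_RATE: n_rate,
         S.SPECIES: sp, "M": m, "n_reps": 1}
        for sp, m in species_to_m.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_config():
    """One short study: fast to simulate, still exercises every path."""
    studies = (
        StudyDesign("A", 4, (1, 2, 4), (0, 100), 8.0, mixture_reps=3),
    )
    return dataclasses.replace(GeneratorConfig(seed=42), studies=studies)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def default_interaction_run():
    """Full default design under the interaction preset, partitioned."""
    cfg = GeneratorConfig(seed=7).with_preset("interaction")
    data, truth = simulate_experiment(cfg)
    table, drops = analysis_table(data, deposition_map(cfg), adjustment_c=1.0)
    return cfg, data, truth, table, drops
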