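"""Study-level evaluation runs: recovery and model-selection experiments.

These functions run the whole pipeline many times over independent
generator seeds and summarise how well the models recover the generating
parameters, and which model AIC selects under which data regime.  They
are used by the reproduction script and the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import models as M
from . import schema as S
from .partitioning import MixtureObservation, partition
from .pipeline import analysis_table
from .simulate import GeneratorConfig, deposition_map, simulate_experiment, simulate_mixture

# one scenario per headline slope: generator preset, model, term, truth
SLOPE_SCENARIOS = {
    "richness_interaction": {
        "preset": "richness_shift",
        "target": -10.0,
        "term": "C(n_treatment)[T.1]:log2_richness",
        "fit": lambda t: M.fit_h1a_richness(t, "ce"),
    },
    "log_rate_slope": {
        "preset": "rate_decline",
        "target": -8.0,
        "term": "log_rate",
        "fit": lambda t: M.fit_h1b_rate(t, "ce", include_ambient=True),
    },
    "time_interaction": {
        "preset": "time_divergence",
        "target": -1.5,
        "term": "C(n_treatment)[T.1]:year",
        "fit": lambda t: M.fit_h2_time(t, "S01", "ce"),
    },
    "cumulative_quadratic": {
        "preset": "interaction",
        "target": 3.2,
        "term": "log_cum2",
        "fit": lambda t: M.fit_h3_cumulative(t, "nbe", "both"),
    },
}


def _sub_seed(seed: int, i: int) -> int:
    return (seed * 100_003 + 7919 * i + 1) % (2**31 - 1)


def _run_table(preset: str, seed: int, adjustment_c: float = 1.0):
    cfg = GeneratorConfig(seed=seed).with_preset(preset)
    data, truth = simulate_experiment(cfg)
    table, _ = analysis_table(data, deposition_map(cfg), adjustment_c)
    return table, truth


def partition_additivity_deviation(seed: int) -> tuple[float, int]:
    """Max relative |NBE - (CE + SE)| over a full simulated experiment."""
    table, _ = _run_table("interaction", seed)
    dev = (table["nbe"] - (table["ce"] + table["se"])).abs()
    rel = dev / np.maximum(1.0, table["nbe"].abs())
    return float(rel.max()), len(table)


def roundtrip_inversion_error(seed: int, n_communities: int = 500) -> tuple[float, int]:
    """Max |recovered - target| effect over noise-free random communities.

    Communities are drawn with enough monoculture spread and moderate
    targets that clipping cannot occur; any clipped community would be a
    defect and raises.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_communities):
        n = int(rng.integers(2, 9))
        M_vec = rng.uniform(80.0, 600.0, size=n)
        while M_vec.std() < 0.2 * M_vec.mean():
            M_vec = rng.uniform(80.0, 600.0, size=n)
        # near-even sowing and bounded targets keep every relative yield
        # positive, so clipping cannot trigger
        u = rng.uniform(0.8, 1.2, size=n)
        props = u / u.sum()
        ce_t = float(rng.uniform(-10.0, 60.0))
        se_t = float(rng.uniform(-15.0, 15.0))
        y, clipped = simulate_mixture(M_vec, props, ce_t, se_t)
        if clipped:
            raise AssertionError("clipping in a range designed to exclude it")
        species = {f"s{j}": (float(props[j]), float(y[j])) for j in range(n)}
        monos = pd.DataFrame(
            [{S.STUDY: "A", S.YEAR: 2, S.N_RATE: 0.0, S.SPECIES: f"s{j}",
              "M": float(M_vec[j]), "n_reps": 1} for j in range(n)]
        )
        res = partition(MixtureObservation("A", f"p{i}", 2, species), monos)
        worst = max(worst, abs(res.ce - ce_t), abs(res.se - se_t))
    return worst, n_communities


def slope_recovery_rates(seed: int, n_reps: int = 100) -> dict[str, dict]:
    """Share of replicates recovering each generating slope within 3 SE."""
    out: dict[str, dict] = {}
    for name, sc in SLOPE_SCENARIOS.items():
        hits = 0
        n_obs = n_table = 0
        for i in range(n_reps):
            table, _ = _run_table(sc["preset"], _sub_seed(seed, i))
            fit = sc["fit"](table)
            n_obs = max(n_obs, fit.n_obs)
            n_table = max(n_table, len(table))
            if abs(fit.params[sc["term"]] - sc["target"]) <= 3 * fit.bse[sc["term"]]:
                hits += 1
        out[name] = {"rate_pct": 100.0 * hits / n_reps, "n_reps": n_reps,
                     "n_obs": n_obs, "n_plot_years": n_table,
                     "target": sc["target"]}
    return out


def aic_regime_preference(seed: int, n_reps: int = 100) -> dict[str, dict]:
    """How often AIC prefers the cumulative-N model, by generating regime.

    Under the interaction (multiplicative time x rate) regime the
    quadratic log-cumulative-N model should win; under the additive
    regime the rate + time model should win.
    """
    out: dict[str, dict] = {}
    for regime in ("interaction", "additive"):
        cum_wins = 0
        n_obs = 0
        for i in range(n_reps):
            table, _ = _run_table(regime, _sub_seed(seed + 17, i))
            sub = table[(table["annual_rate_total"] > 0) & (table["cum_total"] > 0)]
            h3 = M.fit_h3_cumulative(sub, "nbe", "both")
            alt = M.fit_rate_time_additive(sub, "nbe")
            rank = M.compare_aic([h3, alt])
            cum_wins += rank["model"].iloc[0] == "h3_cumulative"
            n_obs = max(n_obs, h3.n_obs)
        out[regime] = {"cumulative_win_pct": 100.0 * cum_wins / n_reps,
                       "n_reps": n_reps, "n_obs": n_obs}
    return out
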