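"""Synthetic multi-study grassland biodiversity x N-addition experiments.

The generator emulates the statistical structure the downstream analysis
assumes: several studies differing in duration (1-23 yr), sown richness
on a log2 ladder (1-20), experimental N rates 0-500 kg/ha/yr on top of a
static site deposition rate, monoculture plots for every species, multi-
year measurements with first-order autoregressive (AR1) plot noise.

Complementarity (CE) and selection (SE) effects are injected by exact
algebraic inversion of the additive partition: given target CE and SE and
the expected monoculture yields M_i of a plot's composition,

    dRY_i = CE / (n * mean(M)) + beta * (M_i - mean(M)),
    beta  = SE / (n * var_pop(M)),
    Y_i   = (RY_e,i + dRY_i) * M_i   (clipped at 0, flagged if clipped)

so that partitioning the noise-free output recovers (CE, SE) exactly.
Target functions ``ce_fun(time, rate, richness, treated)`` receive the
experiment year, the total annual N rate (experimental + deposition,
kg/ha/yr), the sown richness and the binary fertilisation flag; presets
covering the canonical regimes (additive time + rate, time x rate
interaction, richness shift, rate decline, time divergence) are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import schema as S

__all__ = [
    "StudyDesign",
    "GeneratorConfig",
    "PRESETS",
    "default_studies",
    "simulate_monocultures",
    "simulate_mixture",
    "simulate_experiment",
    "conceptual_trends",
    "ConceptualCurve",
]

TargetFun = Callable[[float, float, int, int], float]


# ---------------------------------------------------------------------------
# target-function presets

def _ce_interaction(t, rate, richness, treated):
    """CE convex in log cumulative N: declines, then levels off."""
    x = math.log(max(t * rate, 1.0))
    return 120.0 - 36.0 * x + 3.2 * x * x


def _se_interaction(t, rate, richness, treated):
    """SE rising with cumulative N, crossing from negative to positive."""
    x = math.log(max(t * rate, 1.0))
    return -30.0 + 7.0 * x


def _ce_additive(t, rate, richness, treated):
    """Independent time and rate effects: CE grows with time, drops with log rate."""
    return 60.0 + 5.0 * t - 10.0 * math.log(max(rate, 1.0))


def _se_additive(t, rate, richness, treated):
    return -15.0 - 1.0 * t + 4.0 * math.log(max(rate, 1.0))


def _ce_richness_shift(t, rate, richness, treated):
    """CE rises with log2 richness under ambient, flat under N (interaction -10)."""
    return 20.0 + 10.0 * math.log2(richness) * (1 - treated)


def _se_richness_shift(t, rate, richness, treated):
    return -5.0 + 3.0 * treated


def _ce_rate_decline(t, rate, richness, treated):
    """CE declines with the log total annual N rate (slope -8)."""
    return 70.0 - 8.0 * math.log(max(rate, 1.0))


def _se_rate_decline(t, rate, richness, treated):
    return -10.0 + 3.0 * math.log(max(rate, 1.0))


def _ce_time_divergence(t, rate, richness, treated):
    """CE grows 2 g/m2/yr per year ambient, 0.5 under N (interaction -1.5)."""
    return 15.0 + (2.0 - 1.5 * treated) * t


def _se_time_divergence(t, rate, richness, treated):
    return -10.0 + 0.5 * t * treated


def _zero(t, rate, richness, treated):
    return 0.0


PRESETS: dict[str, tuple[TargetFun, TargetFun]] = {
    "interaction": (_ce_interaction, _se_interaction),
    "additive": (_ce_additive, _se_additive),
    "richness_shift": (_ce_richness_shift, _se_richness_shift),
    "rate_decline": (_ce_rate_decline, _se_rate_decline),
    "time_divergence": (_ce_time_divergence, _se_time_divergence),
    "null": (_zero, _zero),
}


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class StudyDesign:
    """Design of one study: duration, richness ladder, N rates, deposition."""

    study_id: str
    n_years: int
    richness_levels: tuple[int, ...]
    n_rates: tuple[float, ...]  # experimental rates, 0 = ambient
    deposition: float  # kg/ha/yr, static
    mixture_reps: int = 3
    species_pool_size: int | None = None  # default: max richness + 4

    @property
    def pool_size(self) -> int:
        # a pool larger than the deepest mixture leaves room to draw
        # compositions with spread among monoculture yields (full-ladder
        # studies get 20 species, the top of the emulated richness range)
        return self.species_pool_size or max(self.richness_levels) + 4


def default_studies() -> tuple[StudyDesign, ...]:
    """The default 15-study design.

    One long-running study (23 yr, full richness ladder, ambient + low N)
    plays the BioCON role; the others last 3-5 years, five of them with
    the full log2 ladder, the rest with shallow richness gradients, some
    without unfertilised ambient plots, with experimental rates spanning
    0-500 kg/ha/yr and site deposition 6-15 kg/ha/yr.
    """
    d = StudyDesign
    full = (1, 2, 4, 8, 16)
    return (
        d("S01", 23, full, (0, 40), 6.0, mixture_reps=3),
        d("S02", 4, full, (0, 80), 10.0, mixture_reps=4),
        d("S03", 5, full, (0, 160), 12.0, mixture_reps=4),
        d("S04", 3, (1, 2, 4), (0, 100), 8.0),
        d("S05", 5, full, (0, 240), 15.0, mixture_reps=4),
        d("S06", 3, (1, 2), (120, 360), 9.0),
        d("S07", 5, full, (0, 320), 11.0, mixture_reps=4),
        d("S08", 4, (1, 2, 4), (60, 180), 14.0),
        d("S09", 3, (1, 2), (360,), 7.0),
        d("S10", 3, (1, 2, 4), (100, 500), 13.0),
        d("S11", 5, (1, 2), (50, 200), 10.0),
        d("S12", 4, (1, 2, 4), (0, 150), 9.0),
        d("S13", 4, (1, 2, 4), (0, 250), 12.0),
        d("S14", 3, (1, 2, 4), (0, 400), 8.0),
        d("S15", 3, (1, 2), (80, 320), 10.0),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic experiment generator.

    ``noise_sd`` is the stationary standard deviation (g/m2/yr) of the
    AR1 perturbation added to each mixture plot's CE and SE targets;
    ``mono_noise_sd`` is the log-scale sd of the multiplicative AR1 noise
    on monoculture yields.  ``n_response`` is the multiplicative response
    of monoculture productivity to the total annual N rate.
    """

    seed: int
    studies: tuple[StudyDesign, ...] = field(default_factory=default_studies)
    baseline_mean: float = 350.0  # g/m2/yr, mean monoculture productivity
    baseline_sd: float = 0.4  # lognormal sigma across species
    n_response: Callable[[float], float] = lambda rate: 1.0 + 0.0012 * rate
    ce_fun: TargetFun = _ce_interaction
    se_fun: TargetFun = _se_interaction
    ar1_rho: float = 0.4
    noise_sd: float = 15.0
    mono_noise_sd: float = 0.05
    mono_reps: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.noise_sd < 0 or self.mono_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        for st in self.studies:
            if min(st.richness_levels) < 1:
                raise ValueError(f"richness levels must be >= 1 ({st.study_id})")
            if max(st.richness_levels) > st.pool_size:
                raise ValueError(
                    f"richness {max(st.richness_levels)} exceeds species pool "
                    f"{st.pool_size} in study {st.study_id}"
                )
            if min(st.n_rates) < 0 or st.deposition < 0:
                raise ValueError(f"rates must be >= 0 ({st.study_id})")

    def with_preset(self, name: str) -> "GeneratorConfig":
        ce, se = PRESETS[name]
        return replace(self, ce_fun=ce, se_fun=se)


def _ar1_series(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR1 series of length n with marginal sd ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    z = rng.standard_normal(n)
    z[0] *= sd
    if n > 1:
        z[1:] *= sd * math.sqrt(1.0 - rho * rho)
    return lfilter([1.0], [1.0, -rho], z)


def _species_baselines(rng: np.random.Generator, cfg: GeneratorConfig, k: int) -> np.ndarray:
    """Lognormal species baselines stratified across the distribution.

    Jittered, shuffled quantiles rather than iid draws: every study pool
    then spans the productivity range, as real species pools do, and no
    pool collapses onto near-identical monoculture yields.
    """
    from scipy.stats import norm

    mu = math.log(cfg.baseline_mean) - 0.5 * cfg.baseline_sd**2
    q = (np.arange(k) + 0.5 + rng.uniform(-0.3, 0.3, size=k)) / k
    z = norm.ppf(np.clip(q, 0.01, 0.99))
    rng.shuffle(z)
    return np.exp(mu + cfg.baseline_sd * z)


# ---------------------------------------------------------------------------
# simulation

def simulate_monocultures(config: GeneratorConfig) -> pd.DataFrame:
    """Monoculture plots only, in the canonical species-yield schema."""
    return simulate_experiment(config)[0].query(f"{S.SOWN_PROP} == 1.0")


def simulate_mixture(
    M: np.ndarray,
    sown_proportions: np.ndarray,
    target_ce: float,
    target_se: float,
) -> tuple[np.ndarray, bool]:
    """Per-species yields of one mixture realising the target CE and SE.

    Returns the yields and a flag telling whether clipping at zero
    occurred (in which case the realised effects deviate from target).
    Raises if a nonzero SE is requested while all M are identical.
    """
    M = np.asarray(M, dtype=float)
    p = np.asarray(sown_proportions, dtype=float)
    n = len(M)
    if n < 2:
        raise ValueError("a mixture needs at least 2 species")
    var_m = float(((M - M.mean()) ** 2).mean())
    if var_m == 0.0:
        if target_se != 0.0:
            raise ValueError("target_se must be 0 when all monoculture means are equal")
        beta = 0.0
    else:
        beta = target_se / (n * var_m)
    d_ry = target_ce / (n * M.mean()) + beta * (M - M.mean())
    y = (p + d_ry) * M
    clipped = bool((y < 0).any())
    return np.clip(y, 0.0, None), clipped


def simulate_experiment(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full multi-study dataset plus its ground-truth table.

    Returns
    -------
    data : DataFrame
        canonical species-yield schema (one harvest per year), containing
        monoculture and mixture plots for every richness x rate x year
        cell of every study.
    truth : DataFrame
        per mixture plot-year: richness, experimental and total N rates,
        the binary fertilisation flag, the noise-free target CE/SE, and a
        ``clipped`` flag where zero-clipping perturbed the targets.
    """
    rng = np.random.default_rng(config.seed)
    cols: dict[str, list] = {c: [] for c in S.CANONICAL_COLUMNS}
    truth_cols: dict[str, list] = {
        c: []
        for c in [
            S.STUDY, S.PLOT, S.YEAR, "richness", S.N_RATE, "rate_total",
            "treated", "target_ce", "target_se", "clipped",
        ]
    }

    def emit(study, plot, years, species, biomass, prop, rate, treat):
        k = len(biomass)
        cols[S.STUDY].extend([study] * k)
        cols[S.PLOT].extend([plot] * k)
        cols[S.YEAR].extend(years)
        cols[S.HARVEST].extend([1] * k)
        cols[S.SPECIES].extend(species)
        cols[S.BIOMASS].extend(biomass)
        cols[S.SOWN].extend([1] * k)
        cols[S.SOWN_PROP].extend(prop)
        cols[S.N_RATE].extend([rate] * k)
        cols[S.N_TREATMENT].extend([treat] * k)

    for st in config.studies:
        pool = [f"{st.study_id}-sp{j:02d}" for j in range(1, st.pool_size + 1)]
        base = _species_baselines(rng, config, st.pool_size)
        years = np.arange(1, st.n_years + 1)
        plot_no = 0
        # monocultures: every species x rate x replicate
        for rate in st.n_rates:
            total_rate = rate + st.deposition
            mult = config.n_response(total_rate)
            treat = int(rate > 0)
            for j, sp in enumerate(pool):
                for _ in range(config.mono_reps):
                    plot_no += 1
                    plot = f"{st.study_id}-p{plot_no:04d}"
                    eps = _ar1_series(rng, st.n_years, config.ar1_rho, config.mono_noise_sd)
                    y = base[j] * mult * np.exp(eps)
                    emit(st.study_id, plot, years, [sp] * st.n_years, y,
                         [1.0] * st.n_years, rate, treat)
        # mixtures: richness >= 2 cells
        for n_sp in [r for r in st.richness_levels if r >= 2]:
            for rate in st.n_rates:
                total_rate = rate + st.deposition
                mult = config.n_response(total_rate)
                treat = int(rate > 0)
                for _ in range(st.mixture_reps):
                    plot_no += 1
                    plot = f"{st.study_id}-p{plot_no:04d}"
                    # require spread among the composition's monoculture
                    # yields: the SE inversion divides by var_pop(M), so
                    # near-identical species would demand huge relative-
                    # yield deviations and force clipping
                    for _try in range(100):
                        idx = rng.choice(st.pool_size, size=n_sp, replace=False)
                        M = base[idx] * mult
                        if M.std() >= 0.2 * M.mean():
                            break
                    else:
                        raise RuntimeError(
                            f"species pool of {st.study_id} has too little "
                            "yield spread for SE injection"
                        )
                    props = np.full(n_sp, 1.0 / n_sp)
                    eps_ce = _ar1_series(rng, st.n_years, config.ar1_rho, config.noise_sd)
                    eps_se = _ar1_series(rng, st.n_years, config.ar1_rho, config.noise_sd)
                    for t_i, yr in enumerate(years):
                        ce0 = config.ce_fun(yr, total_rate, n_sp, treat)
                        se0 = config.se_fun(yr, total_rate, n_sp, treat)
                        y, clipped = simulate_mixture(
                            M, props, ce0 + eps_ce[t_i], se0 + eps_se[t_i]
                        )
                        emit(st.study_id, plot, [yr] * n_sp,
                             [pool[i] for i in idx], y, props, rate, treat)
                        truth_cols[S.STUDY].append(st.study_id)
                        truth_cols[S.PLOT].append(plot)
                        truth_cols[S.YEAR].append(yr)
                        truth_cols["richness"].append(n_sp)
                        truth_cols[S.N_RATE].append(rate)
                        truth_cols["rate_total"].append(total_rate)
                        truth_cols["treated"].append(treat)
                        truth_cols["target_ce"].append(ce0)
                        truth_cols["target_se"].append(se0)
                        truth_cols["clipped"].append(clipped)
    data = pd.DataFrame(cols)
    truth = pd.DataFrame(truth_cols)
    return data, truth


def deposition_map(config: GeneratorConfig) -> dict[str, float]:
    """Per-study static deposition rates, keyed by study id."""
    return {st.study_id: st.deposition for st in config.studies}


# ---------------------------------------------------------------------------
# conceptual curves

@dataclass
class ConceptualCurve:
    """A biodiversity-effect component traced against cumulative N.

    ``grid`` has columns time, rate, cum_n, value; ``quad_coef`` is the
    leading coefficient of the quadratic-in-log(cum_n) trend fitted to
    the construction (positive = convex, negative = concave).
    """

    grid: pd.DataFrame
    mode: str
    component: str
    quad_coef: float
    n_omitted: int = 0


def conceptual_trends(
    time_trend: Callable[[float], float],
    rate_trend: Callable[[float], float],
    mode: str,
    time_grid: Sequence[float],
    rate_grid: Sequence[float],
    component: str = "ce",
) -> ConceptualCurve:
    """Construct a cumulative-N curve from a time trend and a rate trend.

    additive mode
        the two effects are independent; the curve is the pointwise
        product value(t, r) = f(t) * g(r) over the (time x rate) grid,
        traced against cum_n = t * r.
    multiplicative mode
        the products of the sampled trend data are treated as data: a
        quadratic in log(cum_n) is fitted to them and evaluated on the
        grid, so the curve is the fitted trend itself.

    Grid points with non-positive cum_n are omitted (log scale) and
    counted in ``n_omitted``.  Both modes report the fitted quadratic's
    leading coefficient as the curvature summary.
    """
    if mode not in ("additive", "multiplicative"):
        raise ValueError(f"mode must be 'additive' or 'multiplicative', got {mode!r}")
    t = np.asarray(list(time_grid), dtype=float)
    r = np.asarray(list(rate_grid), dtype=float)
    T, R = np.meshgrid(t, r, indexing="ij")
    cum = (T * R).ravel()
    val = np.array([time_trend(tt) for tt in t])[:, None] * np.array(
        [rate_trend(rr) for rr in r]
    )[None, :]
    val = val.ravel()
    keep = cum > 0
    n_omitted = int((~keep).sum())
    cum, val = cum[keep], val[keep]
    Tk, Rk = T.ravel()[keep], R.ravel()[keep]
    x = np.log(cum)
    coefs = np.polyfit(x, val, 2)
    if mode == "multiplicative":
        val = np.polyval(coefs, x)
    grid = pd.DataFrame({"time": Tk, "rate": Rk, "cum_n": cum, "value": val})
    return ConceptualCurve(
        grid=grid,
        mode=mode,
        component=component,
        quad_coef=float(coefs[0]),
        n_omitted=n_omitted,
    )
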