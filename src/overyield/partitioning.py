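"""Additive partitioning of net biodiversity effects (Loreau-Hector).

For a mixture plot-year with sown species i = 1..n, observed annual yields
Y_i, sown proportions RY_e,i and monoculture reference yields M_i:

    RY_i   = Y_i / M_i                      (relative yield)
    RYT    = sum_i RY_i                     (relative yield total)
    dRY_i  = RY_i - RY_e,i
    NBE    = sum_i Y_i - sum_i RY_e,i * M_i (net biodiversity effect)
    CE     = n * mean(M) * mean(dRY)        (complementarity effect)
    SE     = n * cov_pop(M, dRY)            (selection effect)

with cov_pop the population covariance (divisor n) across the sown
species, the "corrected covariance" variant for which NBE = CE + SE is an
exact algebraic identity.  A small constant ``c`` (default 1 g/m2/yr) is
added to every monoculture yield so that relative yields stay finite when
a species fails in monoculture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import schema as S

__all__ = [
    "MixtureObservation",
    "PartitionResult",
    "aggregate_annual_yield",
    "monoculture_reference",
    "partition",
    "batch_partition",
]

# monoculture matching policies: columns that define the reference group.
# the treatment arm is identified by the experimental N rate, so studies
# with several nonzero rates keep separate monoculture references per arm
MATCHING_POLICIES = {
    "study_year_treatment": [S.STUDY, S.YEAR, S.N_RATE],
    "study_treatment": [S.STUDY, S.N_RATE],
    "study_year": [S.STUDY, S.YEAR],
}


@dataclass(frozen=True)
class MixtureObservation:
    """One mixture plot-year: sown composition with observed annual yields.

    ``composition`` maps species_id -> (sown_proportion RY_e,i, annual
    yield Y_i in g/m2/yr).  Richness ``n`` must equal the number of sown
    species; sown proportions must sum to 1.
    """

    study_id: str
    plot_id: str
    year: int
    composition: Mapping[str, tuple[float, float]]
    n_rate: float = 0.0
    n_treatment: int = 0

    @property
    def n(self) -> int:
        return len(self.composition)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(
                f"partition undefined for monocultures (plot {self.plot_id}, "
                f"richness {self.n})"
            )
        props = [p for p, _ in self.composition.values()]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(
                f"sown proportions must sum to 1, got {sum(props)!r} "
                f"(plot {self.plot_id}, year {self.year})"
            )
        if any(y < 0 for _, y in self.composition.values()):
            raise ValueError(f"negative yield in plot {self.plot_id}")


@dataclass
class PartitionResult:
    """NBE, CE, SE, RYT and per-species diagnostics for one plot-year."""

    study_id: str
    plot_id: str
    year: int
    richness: int
    nbe: float
    ce: float
    se: float
    ryt: float
    per_species: dict[str, tuple[float, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def aggregate_annual_yield(records: pd.DataFrame) -> pd.DataFrame:
    """Sum biomass over within-year harvests: one row per plot-year-species.

    Input rows carry ``harvest_index`` (>= 1); the output biomass is annual
    productivity in g/m2/yr.  All non-harvest fields must be constant
    within a (plot, year, species) group and are carried through.

    Raises
    ------
    ValueError
        on negative biomass or duplicated (plot, year, species, harvest)
        keys, naming the offending rows.
    """
    df = records.copy()
    neg = df[S.BIOMASS] < 0
    if neg.any():
        bad = df.loc[neg, [S.PLOT, S.YEAR, S.SPECIES]].iloc[0]
        raise ValueError(
            f"negative biomass for species {bad[S.SPECIES]} in plot "
            f"{bad[S.PLOT]}, year {bad[S.YEAR]}"
        )
    key = [S.STUDY, S.PLOT, S.YEAR, S.SPECIES, S.HARVEST]
    dup = df.duplicated(key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0]
        raise ValueError(
            "duplicate harvest row for key "
            + "/".join(str(first[k]) for k in key)
        )
    group = [S.STUDY, S.PLOT, S.YEAR, S.SPECIES]
    carried = [
        c for c in df.columns if c not in group + [S.HARVEST, S.BIOMASS]
    ]
    agg = {S.BIOMASS: "sum", **{c: "first" for c in carried}}
    out = df.groupby(group, as_index=False, sort=False).agg(agg)
    out[S.HARVEST] = 1
    return out[[c for c in df.columns]]


def monoculture_reference(
    records: pd.DataFrame,
    adjustment_c: float = 1.0,
    matching_policy: str = "study_year_treatment",
) -> pd.DataFrame:
    """Build the monoculture reference table M_i from annual records.

    Monoculture plots are those whose plot-year contains exactly one sown
    species.  Within each matching group (default study x year x
    N-treatment) replicate monocultures of a species are averaged and the
    adjustment constant ``c`` is added, so every entry satisfies M >= c.

    Returns a table with the group columns, ``species_id``, ``M`` and the
    replicate count ``n_reps``.
    """
    if adjustment_c < 0:
        raise ValueError("adjustment_c must be >= 0")
    try:
        group_cols = MATCHING_POLICIES[matching_policy]
    except KeyError:
        raise ValueError(
            f"unknown matching policy {matching_policy!r}; "
            f"choose from {sorted(MATCHING_POLICIES)}"
        ) from None
    sown = records[records[S.SOWN].astype(int) == 1]
    richness = sown.groupby([S.STUDY, S.PLOT, S.YEAR])[S.SPECIES].transform(
        "nunique"
    )
    monos = sown[richness == 1]
    table = (
        monos.groupby(group_cols + [S.SPECIES], as_index=False)
        .agg(M=(S.BIOMASS, "mean"), n_reps=(S.BIOMASS, "size"))
    )
    table["M"] = table["M"] + adjustment_c
    return table


def _effects(
    M: np.ndarray, ry_e: np.ndarray, Y: np.ndarray
) -> tuple[float, float, float, float, np.ndarray, np.ndarray]:
    """Core algebra shared by the scalar and batch entry points."""
    n = len(M)
    ry = Y / M
    d_ry = ry - ry_e
    nbe = float(Y.sum() - (ry_e * M).sum())
    ce = float(n * M.mean() * d_ry.mean())
    # population covariance (divisor n): the variant that preserves
    # NBE = CE + SE exactly
    se = float(n * ((M * d_ry).mean() - M.mean() * d_ry.mean()))
    ryt = float(ry.sum())
    return nbe, ce, se, ryt, ry, d_ry


def partition(
    obs: MixtureObservation,
    monos: pd.DataFrame,
    matching_policy: str = "study_year_treatment",
) -> PartitionResult:
    """Partition one mixture observation into NBE = CE + SE.

    ``monos`` is the table from :func:`monoculture_reference` built with
    the same matching policy.  Sums, means and the covariance run over the
    sown species only.

    Raises
    ------
    KeyError
        if any sown species lacks a monoculture reference in the
        observation's matching group (flag ``missing_monoculture``).
    """
    group_cols = MATCHING_POLICIES[matching_policy]
    key_vals = {
        S.STUDY: obs.study_id,
        S.YEAR: obs.year,
        S.N_RATE: obs.n_rate,
    }
    mask = np.ones(len(monos), dtype=bool)
    for col in group_cols:
        mask &= monos[col].to_numpy() == key_vals[col]
    sub = monos[mask].set_index(S.SPECIES)["M"]
    species = list(obs.composition)
    missing = [sp for sp in species if sp not in sub.index]
    if missing:
        raise KeyError(
            f"missing_monoculture: no reference for species {missing} in "
            f"group {[key_vals[c] for c in group_cols]}"
        )
    M = sub.loc[species].to_numpy(dtype=float)
    ry_e = np.array([obs.composition[sp][0] for sp in species], dtype=float)
    Y = np.array([obs.composition[sp][1] for sp in species], dtype=float)
    nbe, ce, se, ryt, ry, d_ry = _effects(M, ry_e, Y)
    return PartitionResult(
        study_id=obs.study_id,
        plot_id=obs.plot_id,
        year=obs.year,
        richness=obs.n,
        nbe=nbe,
        ce=ce,
        se=se,
        ryt=ryt,
        per_species={sp: (float(r), float(d)) for sp, r, d in zip(species, ry, d_ry)},
    )


def batch_partition(
    dataset: pd.DataFrame,
    monos: pd.DataFrame,
    matching_policy: str = "study_year_treatment",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition every qualifying mixture plot-year of an annual dataset.

    Vectorised over plot-years.  Unsown species found in a mixture are
    excluded from the algebra and flagged ``unsown_invader``; plot-years
    with a sown species lacking a monoculture reference are dropped with
    reason ``missing_monoculture`` rather than imputed.

    Returns
    -------
    results : DataFrame
        one row per mixture plot-year with columns
        study_id, plot_id, year, richness, nbe, ce, se, ryt, flags.
    drops : DataFrame
        dropped plot-years with a ``reason`` column.
    """
    group_cols = MATCHING_POLICIES[matching_policy]
    df = dataset.copy()
    if S.STUDY in df.columns:
        meta = df.groupby(S.PLOT)[S.STUDY].nunique()
        if (meta > 1).any():
            bad = meta[meta > 1].index[0]
            raise ValueError(f"plot {bad!r} appears under multiple studies")
    empty_results = pd.DataFrame(columns=S.PARTITION_COLUMNS)
    empty_drops = pd.DataFrame(columns=[S.STUDY, S.PLOT, S.YEAR, "reason"])
    if df.empty:
        return empty_results, empty_drops

    sown_flag = df[S.SOWN].astype(int) == 1
    key = [S.STUDY, S.PLOT, S.YEAR]
    df["_richness"] = df[sown_flag].groupby(key)[S.SPECIES].transform("nunique")
    df["_richness"] = df.groupby(key)["_richness"].transform("max")
    mix = df[df["_richness"] >= 2].copy()
    if mix.empty:
        return empty_results, empty_drops

    invaded = (
        mix[~sown_flag.loc[mix.index]]
        .groupby(key)
        .size()
        .rename("n_invaders")
    )
    mix = mix[sown_flag.loc[mix.index]]

    merged = mix.merge(monos, on=group_cols + [S.SPECIES], how="left")
    merged["_missing"] = merged["M"].isna()
    miss_by_plot = merged.groupby(key)["_missing"].transform("any")
    drops = (
        merged.loc[miss_by_plot, key]
        .drop_duplicates()
        .assign(reason="missing_monoculture")
    )
    ok = merged[~miss_by_plot].copy()
    if ok.empty:
        return empty_results, drops.reset_index(drop=True)

    ok["_rye_m"] = ok[S.SOWN_PROP] * ok["M"]
    ok["_ry"] = ok[S.BIOMASS] / ok["M"]
    ok["_dry"] = ok["_ry"] - ok[S.SOWN_PROP]
    ok["_m_dry"] = ok["M"] * ok["_dry"]
    g = ok.groupby(key, sort=False)
    res = g.agg(
        richness=(S.SPECIES, "nunique"),
        sum_y=(S.BIOMASS, "sum"),
        sum_rye_m=("_rye_m", "sum"),
        mean_m=("M", "mean"),
        mean_dry=("_dry", "mean"),
        mean_m_dry=("_m_dry", "mean"),
        ryt=("_ry", "sum"),
        prop_sum=(S.SOWN_PROP, "sum"),
    ).reset_index()
    bad_props = (res["prop_sum"] - 1.0).abs() > 1e-9
    if bad_props.any():
        extra = res.loc[bad_props, key].assign(reason="proportions_not_normalized")
        drops = pd.concat([drops, extra], ignore_index=True)
        res = res[~bad_props]
    n = res["richness"].to_numpy(dtype=float)
    res["nbe"] = res["sum_y"] - res["sum_rye_m"]
    res["ce"] = n * res["mean_m"] * res["mean_dry"]
    res["se"] = n * (res["mean_m_dry"] - res["mean_m"] * res["mean_dry"])
    res = res.merge(invaded, left_on=key, right_index=True, how="left")
    res["flags"] = np.where(res["n_invaders"].notna(), "unsown_invader", "")
    out = res[S.PARTITION_COLUMNS].reset_index(drop=True)
    return out, drops.reset_index(drop=True)


def partition_to_csv(results: pd.DataFrame, path) -> None:
    """Write a partition-result table in the canonical output schema."""
    results[S.PARTITION_COLUMNS].to_csv(path, index=False)
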