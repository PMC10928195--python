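"""Relative-yield algebra and the additive partition NBE = CE + SE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from overyield import schema as S
from overyield.partitioning import (
    MixtureObservation,
    aggregate_annual_yield,
    batch_partition,
    monoculture_reference,
    partition,
)
from conftest import brute_force_partition, make_mono_table


def records_df(rows):
    cols = [S.STUDY, S.PLOT, S.YEAR, S.HARVEST, S.SPECIES, S.BIOMASS,
            S.SOWN, S.SOWN_PROP, S.N_RATE, S.N_TREATMENT]
    return pd.DataFrame(rows, columns=cols)


class TestAggregateAnnualYield:
    @pytest.mark.parametrize(
        "harvest_biomass, expected",
        [([120.0, 80.0], 200.0), ([42.0], 42.0), ([10.0, 0.0, 5.0], 15.0)],
    )
    def test_sums_within_year_harvests(self, harvest_biomass, expected):
        rows = [
            ("A", "p1", 2, h + 1, "sp1", b, 1, 1.0, 0.0, 0)
            for h, b in enumerate(harvest_biomass)
        ]
        out = aggregate_annual_yield(records_df(rows))
        assert len(out) == 1
        assert out[S.BIOMASS].iloc[0] == pytest.approx(expected)

    def test_negative_biomass_rejected(self):
        rows = [("A", "p1", 2, 1, "sp1", -1.0, 1, 1.0, 0.0, 0)]
        with pytest.raises(ValueError, match="negative biomass"):
            aggregate_annual_yield(records_df(rows))

    def test_duplicate_harvest_key_named(self):
        rows = [("A", "p1", 2, 1, "sp1", 5.0, 1, 1.0, 0.0, 0)] * 2
        with pytest.raises(ValueError, match="duplicate harvest"):
            aggregate_annual_yield(records_df(rows))


class TestMonocultureReference:
    @pytest.mark.parametrize(
        "yields, c, expected",
        [([90.0, 110.0], 1.0, 101.0), ([0.0], 1.0, 1.0), ([100.0, 200.0], 0.0, 150.0)],
    )
    def test_mean_plus_adjustment(self, yields, c, expected):
        rows = [
            ("A", f"p{i}", 2, 1, "sp1", y, 1, 1.0, 0.0, 0)
            for i, y in enumerate(yields)
        ]
        table = monoculture_reference(records_df(rows), adjustment_c=c)
        assert table["M"].iloc[0] == pytest.approx(expected)
        assert table["n_reps"].iloc[0] == len(yields)

    def test_negative_adjustment_rejected(self):
        with pytest.raises(ValueError, match="adjustment_c"):
            monoculture_reference(records_df([]), adjustment_c=-1.0)

    def test_mixtures_do_not_enter_reference(self):
        rows = [
            ("A", "p1", 2, 1, "sp1", 100.0, 1, 1.0, 0.0, 0),
            ("A", "p2", 2, 1, "sp1", 999.0, 1, 0.5, 0.0, 0),
            ("A", "p2", 2, 1, "sp2", 999.0, 1, 0.5, 0.0, 0),
        ]
        table = monoculture_reference(records_df(rows), adjustment_c=0.0)
        assert table["M"].tolist() == [100.0]


class TestPartition:
    def test_worked_two_species_example(self):
        # M = (100, 200), even sowing, Y = (80, 90), c = 0
        monos = make_mono_table("A", 2, 0.0, {"sp1": 100.0, "sp2": 200.0})
        obs = MixtureObservation("A", "p1", 2, {"sp1": (0.5, 80.0), "sp2": (0.5, 90.0)})
        res = partition(obs, monos)
        assert res.nbe == pytest.approx(20.0, abs=1e-12)
        assert res.ce == pytest.approx(37.5, abs=1e-12)
        assert res.se == pytest.approx(-17.5, abs=1e-12)
        assert res.ryt == pytest.approx(1.25, abs=1e-12)
        assert res.per_species["sp1"] == pytest.approx((0.80, 0.30))
        assert res.per_species["sp2"] == pytest.approx((0.45, -0.05))
        # independent term-by-term oracle agrees
        oracle = brute_force_partition([100.0, 200.0], [0.5, 0.5], [80.0, 90.0])
        assert (res.nbe, res.ce, res.se, res.ryt) == pytest.approx(oracle)

    def test_mixture_at_expectation_has_null_effects(self):
        monos = make_mono_table("A", 2, 0.0, {"sp1": 120.0, "sp2": 80.0})
        obs = MixtureObservation("A", "p1", 2, {"sp1": (0.25, 30.0), "sp2": (0.75, 60.0)})
        res = partition(obs, monos)
        assert res.nbe == pytest.approx(0.0, abs=1e-12)
        assert res.ce == pytest.approx(0.0, abs=1e-12)
        assert res.se == pytest.approx(0.0, abs=1e-12)
        assert all(d == pytest.approx(0.0, abs=1e-12)
                   for _, d in res.per_species.values())

    def test_constant_delta_ry_zeroes_selection(self):
        # dRY = 0.1 for both species: CE = 30, SE = 0
        monos = make_mono_table("A", 2, 0.0, {"sp1": 100.0, "sp2": 200.0})
        obs = MixtureObservation("A", "p1", 2, {"sp1": (0.5, 60.0), "sp2": (0.5, 120.0)})
        res = partition(obs, monos)
        assert res.nbe == pytest.approx(30.0)
        assert res.ce == pytest.approx(30.0)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_monoculture_rejected(self):
        with pytest.raises(ValueError, match="monoculture"):
            MixtureObservation("A", "p1", 2, {"sp1": (1.0, 50.0)})

    def test_unnormalised_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureObservation("A", "p1", 2, {"sp1": (0.5, 1.0), "sp2": (0.3, 1.0)})

    def test_missing_monoculture_raises(self):
        monos = make_mono_table("A", 2, 0.0, {"sp1": 100.0})
        obs = MixtureObservation("A", "p1", 2, {"sp1": (0.5, 1.0), "sp2": (0.5, 1.0)})
        with pytest.raises(KeyError, match="missing_monoculture"):
            partition(obs, monos)


def _three_plot_dataset(include_orphan=False, invader_biomass=None):
    rows = []
    for sp, m in (("sp1", 100.0), ("sp2", 200.0), ("sp3", 50.0)):
        rows.append(("A", f"mono-{sp}", 2, 1, sp, m, 1, 1.0, 0.0, 0))
    for i in range(3):
        species = ("sp1", "sp2") if not (include_orphan and i == 2) else ("sp1", "spX")
        for sp in species:
            rows.append(("A", f"mix{i}", 2, 1, sp, 40.0 + 10 * i, 1, 0.5, 0.0, 0))
    if invader_biomass is not None:
        rows.append(("A", "mix0", 2, 1, "weed", invader_biomass, 0, 0.0, 0.0, 0))
    return records_df(rows)


class TestBatchPartition:
    def test_pass_through_counts(self):
        data = _three_plot_dataset()
        monos = monoculture_reference(data, 0.0)
        results, drops = batch_partition(data, monos)
        assert len(results) == 3 and len(drops) == 0

    def test_missing_monoculture_dropped_with_flag(self):
        data = _three_plot_dataset(include_orphan=True)
        monos = monoculture_reference(data, 0.0)
        results, drops = batch_partition(data, monos)
        assert len(results) == 2
        assert drops["reason"].tolist() == ["missing_monoculture"]

    def test_unsown_invader_excluded_and_flagged(self):
        data = _three_plot_dataset(invader_biomass=5.0)
        monos = monoculture_reference(data, 0.0)
        results, _ = batch_partition(data, monos)
        flagged = results[results[S.PLOT] == "mix0"]
        assert flagged["flags"].iloc[0] == "unsown_invader"
        # oracle: recompute after deleting the invader row
        clean = _three_plot_dataset()
        expected, _ = batch_partition(clean, monos)
        for col in ("nbe", "ce", "se", "ryt"):
            assert flagged[col].iloc[0] == pytest.approx(
                expected[expected[S.PLOT] == "mix0"][col].iloc[0]
            )

    def test_empty_dataset_gives_empty_table(self):
        data = records_df([])
        monos = monoculture_reference(data, 0.0)
        results, drops = batch_partition(data, monos)
        assert results.empty and drops.empty


# ---------------------------------------------------------------------------
# properties

community = st.integers(min_value=2, max_value=12).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(1.0, 1000.0), min_size=n, max_size=n),
        st.lists(st.floats(0.01, 1.0), min_size=n, max_size=n),
        st.lists(st.floats(0.0, 1000.0), min_size=n, max_size=n),
    )
)


def _obs_from(M, weights, Y):
    props = np.array(weights) / np.sum(weights)
    species = {f"s{i}": (float(props[i]), float(Y[i])) for i in range(len(M))}
    # renormalise exactly: the last proportion absorbs rounding
    total = sum(p for p, _ in species.values())
    k = f"s{len(M) - 1}"
    species[k] = (species[k][0] + (1.0 - total), species[k][1])
    monos = make_mono_table("A", 2, 0.0, {f"s{i}": float(M[i]) for i in range(len(M))})
    return MixtureObservation("A", "p", 2, species), monos


@settings(max_examples=200, derandomize=True)
@given(community)
def test_additivity_and_covariance_identity(c):
    """NBE - (CE + SE) vanishes and SE matches the covariance formula."""
    M, w, Y = c
    obs, monos = _obs_from(M, w, Y)
    res = partition(obs, monos)
    assert abs(res.nbe - (res.ce + res.se)) <= 1e-9 * max(1.0, abs(res.nbe))
    props = [obs.composition[s][0] for s in obs.composition]
    ys = [obs.composition[s][1] for s in obs.composition]
    nbe_o, ce_o, se_o, ryt_o = brute_force_partition(list(M), props, ys)
    assert res.se == pytest.approx(se_o, rel=1e-9, abs=1e-9)
    assert res.se == pytest.approx(res.nbe - res.ce, rel=1e-9, abs=1e-9)
    assert res.ryt == pytest.approx(ryt_o, rel=1e-12, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(community, st.floats(0.1, 50.0))
def test_scale_equivariance(c, k):
    """Scaling all yields and references by k scales NBE, CE, SE by k."""
    M, w, Y = c
    obs, monos = _obs_from(M, w, Y)
    base = partition(obs, monos)
    obs2, monos2 = _obs_from([m * k for m in M], w, [y * k for y in Y])
    scaled = partition(obs2, monos2)
    assert scaled.nbe == pytest.approx(k * base.nbe, rel=1e-9, abs=1e-6)
    assert scaled.ce == pytest.approx(k * base.ce, rel=1e-9, abs=1e-6)
    assert scaled.se == pytest.approx(k * base.se, rel=1e-9, abs=1e-6)


@settings(max_examples=100, derandomize=True)
@given(community, st.randoms(use_true_random=False))
def test_permutation_invariance(c, rnd):
    """Species order never changes NBE, CE, SE or RYT."""
    M, w, Y = c
    idx = list(range(len(M)))
    rnd.shuffle(idx)
    obs, monos = _obs_from(M, w, Y)
    obs2, monos2 = _obs_from([M[i] for i in idx], [w[i] for i in idx],
                             [Y[i] for i in idx])
    a, b = partition(obs, monos), partition(obs2, monos2)
    for attr in ("nbe", "ce", "se", "ryt"):
        assert getattr(a, attr) == pytest.approx(getattr(b, attr), rel=1e-9, abs=1e-9)


@settings(max_examples=50, derandomize=True)
@given(community, st.floats(0.0, 10.0), st.floats(0.1, 10.0))
def test_adjustment_weakly_shrinks_relative_yields(c, c1, dc):
    """Raising the monoculture adjustment shrinks |RY| for fixed yields."""
    M, w, Y = c
    obs, _ = _obs_from(M, w, Y)
    m1 = make_mono_table("A", 2, 0.0, {f"s{i}": M[i] + c1 for i in range(len(M))})
    m2 = make_mono_table("A", 2, 0.0, {f"s{i}": M[i] + c1 + dc for i in range(len(M))})
    r1, r2 = partition(obs, m1), partition(obs, m2)
    for sp in r1.per_species:
        assert abs(r2.per_species[sp][0]) <= abs(r1.per_species[sp][0]) + 1e-12
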