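"""Synthetic generator: determinism, planted anomalies, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from treesilience import (GroundTruthLedger, SyntheticConfig, generate_bundle,
                          generate_dataset)
from treesilience.exceptions import ConfigError
from treesilience.spei import aggregate, water_balance
from treesilience.synthetic import generate_climate, generate_soil_table


def test_seeded_determinism_in_memory_and_on_disk(small_config, tmp_path):
    s1, m1, c1, so1, l1 = generate_bundle(small_config)
    s2, m2, c2, so2, l2 = generate_bundle(small_config)
    pd.testing.assert_frame_equal(m1, m2)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(so1, so2)
    for a, b in zip(s1, s2):
        np.testing.assert_array_equal(a.trw, b.trw)
    p1 = generate_dataset(small_config, tmp_path / "a")
    p2 = generate_dataset(small_config, tmp_path / "b")
    for key in ("metadata", "climate", "soil", "ledger"):
        assert p1[key].read_bytes() == p2[key].read_bytes()
    for f1, f2 in zip(p1["rwl"], p2["rwl"]):
        assert f1.read_bytes() == f2.read_bytes()


def test_tree_counts_statuses_and_ledger(small_bundle, small_config):
    series, meta, _, _, ledger = small_bundle
    cfg = small_config
    n = cfg.n_sites * (cfg.trees_per_site_surviving + cfg.trees_per_site_dead)
    assert len(series) == n == len(ledger.trees)
    assert len(ledger.sites) == cfg.n_sites
    counts = meta.groupby(["site", "status"]).size().unstack()
    assert (counts["surviving"] == cfg.trees_per_site_surviving).all()
    assert (counts["now-dead"] == cfg.trees_per_site_dead).all()
    # dead trees die before surviving trees' sampling year, >= 10 y after event
    for site, info in ledger.sites.items():
        sub = meta[meta.site == site]
        dead_last = sub.loc[sub.status == "now-dead", "last_year"]
        surv_last = sub.loc[sub.status == "surviving", "last_year"]
        assert dead_last.max() < surv_last.min()
        assert (dead_last >= info["event_year"] + 10).all()
        assert (dead_last <= info["event_year"] + 40).all()


def test_all_widths_positive(small_bundle):
    for s in small_bundle[0]:
        assert (s.trw > 0).all()


def test_planted_event_is_argmin_of_aggregated_balance():
    cfg = SyntheticConfig(n_sites=2, seed=9)
    rng = np.random.default_rng(10)
    for i in range(2):
        clim = generate_climate(cfg, i, rng)
        d = water_balance(clim["prcp_mm"].to_numpy(), clim["pet_mm"].to_numpy())
        month, scale = cfg.true_window[i]
        agg = aggregate(d, cfg.years, scale, month, cfg.hemisphere)
        assert int(agg.idxmin()) == cfg.event_year[i]


def test_zero_interannual_noise_gives_identical_nonevent_years():
    cfg = SyntheticConfig(n_sites=1, climate_noise_sd=0.0, seed=0)
    clim = generate_climate(cfg, 0, np.random.default_rng(0))
    d = water_balance(clim["prcp_mm"].to_numpy(), clim["pet_mm"].to_numpy())
    month, scale = cfg.true_window[0]
    agg = aggregate(d, cfg.years, scale, month, cfg.hemisphere)
    others = agg.drop(index=cfg.event_year[0]).to_numpy()
    assert np.ptp(others) < 1e-9
    assert agg.loc[cfg.event_year[0]] < others.min()


def test_soil_table_texture_and_fertility_axis():
    rng = np.random.default_rng(11)
    soil = generate_soil_table(40, rng)
    np.testing.assert_allclose(
        soil[["clay", "silt", "sand"]].sum(axis=1), 100.0, atol=1e-6)
    # latent factor loads positively and jointly on N, OC, AWC
    sub = soil[["total_nitrogen", "organic_carbon", "awc"]]
    corr = sub.corr().to_numpy()
    assert (corr[np.triu_indices(3, 1)] > 0.3).all()
    rng2 = np.random.default_rng(11)
    pd.testing.assert_frame_equal(soil, generate_soil_table(40, rng2))


def _one_site_series(cfg, seed=0):
    from treesilience.synthetic import generate_tree_series
    rng = np.random.default_rng(seed)
    clim = generate_climate(cfg, 0, rng)
    return generate_tree_series(cfg, 0, clim, rng)


def _event_year_ratio(series, event_year):
    dead = [s.to_series().get(event_year) for s in series
            if s.status == "now-dead"]
    surv = [s.to_series().get(event_year) for s in series
            if s.status == "surviving"]
    return np.mean(dead) / np.mean(surv)


def test_angiosperm_resistance_deficit_planted_at_event_year():
    # one angiosperm site, many trees: mean event-year TRW of dead trees
    # should be ~0.7x the surviving mean
    cfg = SyntheticConfig(n_sites=1, trees_per_site_surviving=100,
                          trees_per_site_dead=100,
                          taxon_per_site=["angiosperm"],
                          resist_deficit_dead={"angiosperm": 0.7,
                                               "gymnosperm": 0.9},
                          seed=21)
    series = _one_site_series(cfg, seed=21)
    assert _event_year_ratio(series, cfg.event_year[0]) == \
        pytest.approx(0.7, abs=0.06)


def test_deficit_monotonicity():
    ratios = {}
    for deficit in (0.5, 0.9):
        cfg = SyntheticConfig(n_sites=1, trees_per_site_surviving=80,
                              trees_per_site_dead=80,
                              taxon_per_site=["angiosperm"],
                              resist_deficit_dead={"angiosperm": deficit,
                                                   "gymnosperm": 0.9},
                              seed=22)
        series = _one_site_series(cfg, seed=22)
        ratios[deficit] = _event_year_ratio(series, cfg.event_year[0])
    assert ratios[0.5] < ratios[0.9]


def test_null_configuration_statuses_exchangeable():
    cfg = SyntheticConfig(n_sites=1, trees_per_site_surviving=80,
                          trees_per_site_dead=80, beta_climate=0.0,
                          resist_deficit_dead={"angiosperm": 1.0,
                                               "gymnosperm": 1.0},
                          recov_deficit_dead={"angiosperm": 1.0,
                                              "gymnosperm": 1.0},
                          seed=23)
    series = _one_site_series(cfg, seed=23)
    ey = cfg.event_year[0]
    dead = [np.log(s.to_series().get(ey)) for s in series
            if s.status == "now-dead"]
    surv = [np.log(s.to_series().get(ey)) for s in series
            if s.status == "surviving"]
    assert stats.ks_2samp(dead, surv).pvalue > 0.01


def test_ledger_round_trip(bundle_dir):
    ledger = GroundTruthLedger.from_json(bundle_dir["ledger"])
    assert set(ledger.sites) == {"S001", "S002", "S003"}
    for info in ledger.sites.values():
        m, k = info["true_window"]
        assert 1 <= k <= 24


@pytest.mark.parametrize("kwargs,match", [
    (dict(n_sites=0), "counts"),
    (dict(span=(1990, 2013)), "50 years"),
    (dict(event_year=[2012] * 5), "margin|room"),
    (dict(resist_deficit_dead={"angiosperm": 1.4, "gymnosperm": 0.9}),
     "deficit"),
    (dict(true_window=[(6, 30)] * 5), "scale"),
    (dict(ar_coef=1.0), "ar_coef"),
])
def test_config_validation(kwargs, match):
    with pytest.raises(ConfigError, match=match):
        SyntheticConfig(**kwargs)
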