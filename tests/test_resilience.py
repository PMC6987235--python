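"""BAI reconstruction, Lloret indices, SPEI covariates, trajectories."""

import numpy as np
import pandas as pd
import pytest

from treesilience import (build_records, compute_bai, dbh_at_year,
                          growth_pattern_bootstrap, lloret_indices,
                          spei_covariates)
from treesilience.drought import DroughtEvent
from treesilience.ring_io import RingSeries


def _series(widths, first_year=1990, dbh=None, **kw):
    widths = np.asarray(widths, float)
    if dbh is None:
        dbh = 2 * widths.sum() / 10 + 0.2
    years = np.arange(first_year, first_year + widths.size)
    return RingSeries("t1", years, widths, dbh_cm=dbh, **kw)


class TestBai:
    def test_single_ring_disc_area(self):
        s = _series([1.0], dbh=0.2)          # radius 1 mm, no prior wood
        bai = compute_bai(s)
        assert bai.iloc[0] == pytest.approx(np.pi)

    def test_telescoping_identity(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.5, 3.0, 40)
        s = _series(w, dbh=2 * (w.sum() + 5) / 10)   # 5 mm pith core
        bai = compute_bai(s)
        r_last = s.dbh_cm * 10 / 2
        r_first = r_last - w.sum()
        assert bai.sum() == pytest.approx(np.pi * (r_last**2 - r_first**2))

    def test_constant_width_gives_increasing_bai(self):
        s = _series(np.full(30, 1.5))
        assert (np.diff(compute_bai(s).to_numpy()) > 0).all()

    def test_inconsistent_dbh_truncates_with_warning(self):
        s = _series(np.full(30, 2.0), dbh=4.0)   # 60 mm of rings, 20 mm radius
        with pytest.warns(UserWarning, match="truncated"):
            bai = compute_bai(s)
        assert len(bai) < 30 and (bai > 0).all()


class TestDbhAtYear:
    def test_subtracts_later_rings(self):
        s = _series(np.full(25, 1.0), first_year=1976, dbh=30.0)
        # 24 one-mm rings follow 1976: DBH_i = 30 - 2*24/10 = 25.2 cm
        assert dbh_at_year(s, 1976) == pytest.approx(25.2)

    def test_last_year_returns_sampling_dbh(self):
        s = _series(np.full(20, 1.2), dbh=28.0)
        assert dbh_at_year(s, s.last_year) == pytest.approx(28.0)

    def test_monotone_in_year(self):
        s = _series(np.linspace(0.5, 2.5, 30))
        vals = [dbh_at_year(s, y) for y in s.years]
        assert (np.diff(vals) >= 0).all()

    def test_out_of_range_errors(self):
        s = _series(np.full(20, 1.0))
        with pytest.raises(ValueError):
            dbh_at_year(s, 1900)


class TestLloret:
    def test_direct_ratios(self):
        years = np.arange(1990, 2001)
        g = pd.Series([2.0] * 4 + [1.0] + [1.5] * 4 + [9, 9], index=years[:11])
        idx = lloret_indices(g, 1994, 4)
        assert (idx.resistance, idx.recovery, idx.resilience) == \
            pytest.approx((0.5, 1.5, 0.75))

    def test_flat_series_all_ones(self):
        g = pd.Series(3.3, index=np.arange(1990, 2010))
        idx = lloret_indices(g, 2000, 4)
        assert (idx.resistance, idx.recovery, idx.resilience) == \
            pytest.approx((1.0, 1.0, 1.0))

    def test_multiplicative_identity_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            g = pd.Series(rng.lognormal(0, 0.5, 11),
                          index=np.arange(1990, 2001))
            a = lloret_indices(g, 1995, 4)
            assert abs(a.resilience - a.resistance * a.recovery) < 1e-12
            b = lloret_indices(g * 17.3, 1995, 4)
            assert b.resistance == pytest.approx(a.resistance)
            assert b.resilience == pytest.approx(a.resilience)

    def test_insufficient_coverage_raises(self):
        g = pd.Series(1.0, index=np.arange(1990, 1997))   # dies 2 y post event
        with pytest.raises(ValueError, match="missing"):
            lloret_indices(g, 1994, 4)
        idx = lloret_indices(g, 1994, 1)                   # m = 1 still works
        assert idx.resilience == pytest.approx(1.0)


def test_spei_covariates_and_identity():
    years = np.arange(1990, 2001)
    s = pd.Series(0.0, index=years)
    s.loc[1995] = -2.0
    cov = spei_covariates(s, 1995, 4)
    assert (cov["speidiff_resist"], cov["speidiff_recov"],
            cov["speidiff_resil"]) == pytest.approx((-2.0, 2.0, 0.0))
    flat = spei_covariates(pd.Series(0.7, index=years), 1995, 4)
    assert flat["speidiff_resil"] == flat["speidiff_resist"] == \
        flat["speidiff_recov"] == 0.0
    rng = np.random.default_rng(2)
    r = spei_covariates(pd.Series(rng.normal(0, 1, 11), index=years), 1995, 4)
    assert r["speidiff_resil"] == pytest.approx(
        r["speidiff_resist"] + r["speidiff_recov"], abs=1e-12)


def _mini_events(dataset, ledger):
    events, spei = {}, {}
    for site, info in ledger.sites.items():
        y = info["event_year"]
        events[site] = DroughtEvent(site, y, -2.5, -1.2, 0.2, 0,
                                    (y - 10, y + 10))
        yrs = np.arange(1901, 2014)
        spei[site] = pd.Series(0.0, index=yrs)
        spei[site].loc[y] = -2.5
    return events, spei


def test_build_records_counts_and_skips(small_dataset, bundle_dir):
    from treesilience import GroundTruthLedger
    ledger = GroundTruthLedger.from_json(bundle_dir["ledger"])
    events, spei = _mini_events(small_dataset, ledger)
    rec, skipped = build_records(small_dataset, events, spei, window_m=4,
                                 metrics=("TRW", "BAI"))
    # every tree spans event +/- 4 (deaths are >= 10 y post event)
    assert len(rec) == 2 * len(small_dataset.series)
    assert not skipped
    assert ((rec["resilience"] - rec["resistance"] * rec["recovery"]).abs()
            < 1e-12).all()
    assert (rec["delta_time"] >= 0).all()


def test_tree_dying_right_after_event_skipped_at_wide_window(small_dataset,
                                                             bundle_dir):
    from treesilience import GroundTruthLedger
    ledger = GroundTruthLedger.from_json(bundle_dir["ledger"])
    events, spei = _mini_events(small_dataset, ledger)
    # shift one site's event so a dead tree has only 2 post-event years
    site = list(events)[0]
    dead_last = min(s.last_year for s in small_dataset.site_series(site)
                    if s.status == "now-dead")
    y = dead_last - 2
    events[site] = DroughtEvent(site, y, -2.5, -1.2, 0.2, 0, (y - 5, y + 5))
    rec4, skipped4 = build_records(small_dataset, events, spei, window_m=4,
                                   metrics=("TRW",))
    rec1, skipped1 = build_records(small_dataset, events, spei, window_m=1,
                                   metrics=("TRW",))
    assert len(skipped4) > 0
    assert len(rec1) > len(rec4)


def test_growth_bootstrap_properties(small_dataset, bundle_dir):
    from treesilience import GroundTruthLedger
    ledger = GroundTruthLedger.from_json(bundle_dir["ledger"])
    events, _ = _mini_events(small_dataset, ledger)
    a = growth_pattern_bootstrap(small_dataset, events, half_window=6,
                                 n_boot=200, seed=3)
    b = growth_pattern_bootstrap(small_dataset, events, half_window=6,
                                 n_boot=200, seed=3)
    pd.testing.assert_frame_equal(a, b)           # seeded reproducibility
    assert set(a["rel_year"]) == set(range(-4, 7))
    assert (a["ci_lo"] <= a["mean_log_ratio"]).all()
    assert (a["mean_log_ratio"] <= a["ci_hi"]).all()


def test_plot_growth_patterns_smoke(small_dataset, bundle_dir, tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    from treesilience import GroundTruthLedger, plot_growth_patterns
    ledger = GroundTruthLedger.from_json(bundle_dir["ledger"])
    events, _ = _mini_events(small_dataset, ledger)
    curves = growth_pattern_bootstrap(small_dataset, events, half_window=4,
                                      n_boot=100, seed=0)
    axes = plot_growth_patterns(curves)
    axes[0].figure.savefig(tmp_path / "patterns.png")


def test_bootstrap_ci_shrinks_with_more_trees():
    rng = np.random.default_rng(4)

    def make_dataset(n_trees):
        series = []
        for i in range(n_trees):
            w = rng.lognormal(0, 0.3, 30)
            series.append(RingSeries(f"t{i}", np.arange(1980, 2010), w,
                                     site_id="s", group="angiosperm",
                                     status="surviving", dbh_cm=20))
        class _DS:
            def site_series(self, site):
                return series
        return _DS()

    ev = {"s": DroughtEvent("s", 1995, -2.0, -1.0, 0.2, 0, (1990, 2000))}
    widths = {}
    for n in (20, 80):
        curves = growth_pattern_bootstrap(make_dataset(n), ev, half_window=4,
                                          n_boot=400, seed=5)
        w = (curves["ci_hi"] - curves["ci_lo"]).mean()
        widths[n] = w
    ratio = widths[80] / widths[20]
    assert 0.3 < ratio < 0.75                      # ~ 1/sqrt(4) = 0.5
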