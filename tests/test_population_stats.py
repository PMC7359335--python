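"""DRPs, field entropy, direction selectivity, cluster matching, group test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from retinachrome import population_stats as ps
from retinachrome import synthetic_data as sd


class TestDensityRecoveryProfile:
    def test_single_point_zero_profile(self):
        with pytest.warns(UserWarning):
            prof, edges = ps.density_recovery_profile(np.array([[1.0, 2.0]]))
        assert np.all(prof == 0)

    def test_csr_profile_flat_at_density(self):
        rng = np.random.default_rng(3)
        lam = 600 / 300.0**2
        pts = rng.uniform(0, 300, (600, 2))
        prof, edges = ps.density_recovery_profile(pts, 2.0, 20.0)
        # each bin within 3 standard errors of the homogeneous density
        areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        n_ref = ((pts > 20).all(1) & (pts < 280).all(1)).sum()
        se = np.sqrt(lam / (areas * n_ref))
        assert np.all(np.abs(prof - lam) < 3 * se)

    def test_exclusion_mosaic_depletes_short_range(self):
        cells = sd.make_population(50, "OPL", seed=1)
        geom = sd.FieldGeometry(shape=(100, 100), um_per_px=1.2, terminal_diam_um=5.0)
        prot = sd.make_flash_protocol(n_repeats=1)
        m = sd.simulate_scan_field(cells, geom, prot, seed=2, rate_hz=3.9)
        pts = m.truth_centers_px * geom.um_per_px
        prof, _ = ps.density_recovery_profile(pts, 2.0, 16.0, guard_um=0.0)
        assert prof[0] == 0 and prof[1] == 0  # bins below 4 µm empty

    def test_csr_flat_chi2(self):
        rng = np.random.default_rng(11)
        pvals = []
        for k in range(10):
            pts = rng.uniform(0, 250, (400, 2))
            prof, edges = ps.density_recovery_profile(pts, 2.0, 16.0)
            areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
            n_ref = ((pts > 16).all(1) & (pts < 234).all(1)).sum()
            counts = prof * areas * n_ref
            expected = counts.sum() * areas / areas.sum()  # flat density
            pvals.append(stats.chisquare(counts, expected).pvalue)
        assert np.mean(pvals) > 0.01


class TestFieldEntropy:
    def test_single_bin_zero(self):
        assert ps.field_entropy(np.full(50, 0.1)) == 0.0

    def test_two_equal_bins_one_bit(self):
        assert ps.field_entropy([0.1] * 25 + [0.3] * 25) == pytest.approx(1.0)

    def test_four_equal_bins_two_bits(self):
        sc = [0.1] * 10 + [0.3] * 10 + [0.5] * 10 + [0.7] * 10
        assert ps.field_entropy(sc) == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ps.field_entropy([])

    @given(st.lists(st.floats(-2, 3), min_size=1, max_size=60))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_entropy_bounds(self, sc):
        s = ps.field_entropy(sc)
        occupied = len(np.unique(np.floor(np.asarray(sc) / 0.2).astype(int)))
        assert 0.0 <= s <= np.log2(occupied) + 1e-9

    def test_invariant_under_bin_preserving_shift(self):
        sc = np.array([0.05, 0.15, 0.25, 0.31])
        assert ps.field_entropy(sc) == ps.field_entropy(sc + 0.02)


class TestDirectionSelectivity:
    def test_untuned_response_zero_dsi(self):
        R = np.ones((3, 30, 8)) * np.sin(np.linspace(0, 6, 30))[None, :, None]
        dsi, p, info = ps.direction_selectivity(R, n_perm=20, seed=0)
        assert dsi == pytest.approx(0.0, abs=1e-9)

    def test_single_direction_dsi_one(self):
        R = np.zeros((3, 30, 8))
        R[:, :, 2] = np.sin(np.linspace(0, 6, 30))[None, :]
        dsi, p, info = ps.direction_selectivity(R, n_perm=50, seed=0)
        assert dsi == pytest.approx(1.0)
        assert p < 0.05

    def test_all_zero_undefined(self):
        dsi, p, _ = ps.direction_selectivity(np.zeros((3, 10, 8)), n_perm=10, seed=0)
        assert np.isnan(dsi)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(5)
        rej = 0
        n = 400
        for i in range(n):
            R = rng.normal(0, 1, (4, 15, 8))
            _, p, _ = ps.direction_selectivity(R, n_perm=99, seed=i)
            rej += p <= 0.05
        assert rej / n == pytest.approx(0.05, abs=0.015)


@pytest.fixture(scope="module")
def templates():
    return sd.make_group_templates(8, seed=1)


class TestAssignCluster:

    def test_exact_template_match(self, templates):
        g = 1
        t = templates[g]
        m = ps.assign_cluster(t["chirp"], t["bar"], 0.5, 0.5, templates,
                              rate_hz=t["rate_hz"], shift_s=0.0, boxcar_points=1)
        assert m.assigned_group == g
        assert m.mi[g] == pytest.approx(1.0, abs=0.05)

    def test_match_index_weighting(self):
        # equal qualities with r_chirp ≈ 0.4 and r_bar ≈ 0.8 combine to Mi ≈ 0.6
        rng = np.random.default_rng(4)

        def with_corr(template, r, m):
            noise = rng.normal(size=m)
            noise -= noise @ template / (template @ template) * template
            return r * template / template.std() + np.sqrt(1 - r**2) * noise / noise.std()

        a = rng.normal(size=4000)
        b = rng.normal(size=1000)
        templates = {1: {"chirp": a, "bar": b, "is_ds": False, "is_alpha": False}}
        m = ps.assign_cluster(with_corr(a, 0.4, 4000), with_corr(b, 0.8, 1000),
                              0.5, 0.5, templates, shift_s=0.0, boxcar_points=1)
        assert m.mi[1] == pytest.approx(0.6, abs=0.03)
        assert m.assigned_group == 1

    def test_recovery_at_snr5(self, templates):
        rng = np.random.default_rng(0)
        ok = n = 0
        for g, t in templates.items():
            for rep in range(4):
                chirp = t["chirp"] + rng.normal(0, 0.2, t["chirp"].size)
                bar = t["bar"] + rng.normal(0, 0.2, t["bar"].size)
                m = ps.assign_cluster(chirp, bar, 0.6, 0.6, templates,
                                      is_ds=t["is_ds"], is_alpha=t["is_alpha"],
                                      rate_hz=t["rate_hz"])
                n += 1
                ok += m.assigned_group == g
        assert ok / n >= 0.9

    def test_class_restriction(self, templates):
        # a DS cell is only compared against DS templates
        ds_groups = {g for g, t in templates.items() if t["is_ds"]}
        t = templates[sorted(ds_groups)[0]]
        m = ps.assign_cluster(t["chirp"], t["bar"], 0.5, 0.5, templates,
                              is_ds=True, rate_hz=t["rate_hz"], shift_s=0.0,
                              boxcar_points=1)
        assert set(m.mi) == ds_groups

    def test_no_candidates_unassigned(self):
        templates = {1: {"chirp": np.sin(np.arange(100.0)), "bar": np.ones(50),
                         "is_ds": True, "is_alpha": False}}
        m = ps.assign_cluster(np.ones(100), np.ones(50), 0.5, 0.5, templates,
                              is_ds=False)
        assert m.assigned_group is None and "no candidate" in m.reason

    def test_weak_match_unassigned(self, templates):
        rng = np.random.default_rng(9)
        m = ps.assign_cluster(rng.normal(0, 1, 1000), rng.normal(0, 1, 125),
                              0.5, 0.5, templates, rate_hz=31.25)
        assert m.assigned_group is None


def _grouped_records(rng, n_groups=36, n_per=20, enrich=None, effect=3.0,
                     enrich_n=60):
    rows = []
    for g in range(1, n_groups + 1):
        n = enrich_n if enrich == g else n_per
        sc_c = rng.normal(-0.3, 0.4, n)
        sc_d = rng.normal(0.6, 0.5, n)
        logit = -1.2 + 1.5 * sc_d + 0.5 * sc_c
        if enrich == g:
            logit = logit + np.log(effect)
        opp = rng.random(n) < 1 / (1 + np.exp(-logit))
        rows += [(g, c, d, o) for c, d, o in zip(sc_c, sc_d, opp)]
    return pd.DataFrame(rows, columns=["group_id", "sc_center", "sc_diff", "is_opponent"])


class TestGroupOpponencyTest:
    def test_null_percentiles_uniform(self):
        rng = np.random.default_rng(42)
        pcts = []
        for k in range(120):
            df = _grouped_records(rng)
            res = ps.group_opponency_test(df, n_iter=300, seed=k, group_ids=[1])
            pcts.append(res[0].percentile)
        assert stats.kstest(pcts, "uniform").pvalue > 0.01

    def test_strata_determined_opponency_not_flagged(self):
        # opponency fully determined by (SC_center, SC_Diff) strata: the
        # observed percentage sits inside the null 95% interval
        rng = np.random.default_rng(0)
        inside = 0
        for k in range(20):
            df = _grouped_records(rng)
            df["is_opponent"] = df["sc_diff"] > 0.8  # deterministic in the stratum
            res = ps.group_opponency_test(df, n_iter=400, seed=k, group_ids=[2])[0]
            inside += 0.025 < res.percentile < 0.975
        assert inside >= 17

    def test_enriched_group_detected(self):
        rng = np.random.default_rng(1)
        detected = 0
        n = 30
        for k in range(n):
            df = _grouped_records(rng, enrich=3, effect=3.0)
            res = ps.group_opponency_test(df, n_iter=400, seed=100 + k, group_ids=[3])[0]
            detected += res.p_two_sided < 0.05 and res.direction == "enriched"
        assert detected / n >= 0.9

    def test_small_group_skipped(self):
        rng = np.random.default_rng(2)
        df = _grouped_records(rng, n_groups=2, n_per=10)
        res = ps.group_opponency_test(df, n_iter=50, seed=0)
        assert all(r.skipped for r in res)

    def test_missing_columns_rejected(self):
        with pytest.raises(KeyError):
            ps.group_opponency_test(pd.DataFrame({"group_id": [1]}))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        df = _grouped_records(rng)
        a = ps.group_opponency_test(df, n_iter=200, seed=5, group_ids=[1])[0]
        b = ps.group_opponency_test(df, n_iter=200, seed=5, group_ids=[1])[0]
        assert a.percentile == b.percentile
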