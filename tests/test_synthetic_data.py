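"""Generator guarantees: balance, determinism, LN structure, mosaic geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinachrome import synthetic_data as sd
from retinachrome.chromatic_analysis import spectral_contrast
from scipy.stats import spearmanr


class TestFlickerProtocol:
    @pytest.mark.parametrize("rate,dur,n_expected", [
        (10.0, 180.0, 1800),   # inner-retina protocol
        (5.0, 300.0, 1500),    # ganglion-cell-layer protocol
        (10.0, 0.2, 2),        # minimal balanced sequence
    ])
    def test_step_count_and_balance(self, rate, dur, n_expected):
        p = sd.make_flicker_protocol(4, rate, dur, seed=1)
        assert p.channels.shape == (4, n_expected)
        assert set(np.unique(p.channels)) == {-1.0, 1.0}
        # exactly balanced: mean of each ±1 sequence is 0
        assert np.all(p.channels.sum(axis=1) == 0)

    def test_odd_step_count_rejected(self):
        with pytest.raises(ValueError):
            sd.make_flicker_protocol(4, 10.0, 180.05, seed=0)

    def test_conditions_uncorrelated(self):
        p = sd.make_flicker_protocol(4, 10.0, 600.0, seed=2)
        c = np.corrcoef(p.channels)
        off = c[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_seed_determinism(self):
        a = sd.make_flicker_protocol(4, 10.0, 180.0, seed=3)
        b = sd.make_flicker_protocol(4, 10.0, 180.0, seed=3)
        c = sd.make_flicker_protocol(4, 10.0, 180.0, seed=4)
        assert np.array_equal(a.channels, b.channels)
        assert not np.array_equal(a.channels, c.channels)


class TestFlashProtocol:
    def test_repetitions_and_metadata(self):
        p = sd.make_flash_protocol(150, 700, n_repeats=25)
        tbl = p.metadata["trial_table"]
        per_cond = {}
        for cond, _, _ in tbl:
            per_cond[cond] = per_cond.get(cond, 0) + 1
        assert all(v == 25 for v in per_cond.values())
        assert p.metadata["center_diam_um"] == 150

    def test_single_trial_and_custom_geometry(self):
        p = sd.make_flash_protocol(100, 700, n_repeats=1)
        assert p.metadata["center_diam_um"] == 100
        assert len(p.metadata["trial_table"]) == len(p.condition_names)

    def test_triggers_strictly_increasing(self):
        p = sd.make_flash_protocol(n_repeats=3)
        assert np.all(np.diff(p.trigger_times_s) > 0)
        assert p.trigger_times_s[-1] < p.duration_s


class TestCellResponse:
    def test_zero_weights_zero_noise_constant(self):
        cell = sd.GroundTruthCell(0.0, "IPL", 0, 0, polarity="On")
        p = sd.make_flicker_protocol(4, 10.0, 2.0, seed=0)
        tr = sd.simulate_cell_response(cell, p, noise_sd=0, nonlinearity="identity")
        assert np.allclose(tr, 0)

    def test_single_pathway_flash_polarity(self):
        # glutamate-decrease center: UV flash drives a negative deflection only
        cell = sd.GroundTruthCell(-1.0, "OPL", w_center_uv=-1.0, w_center_green=0.0)
        p = sd.make_flash_protocol(n_repeats=1)
        tr = sd.simulate_cell_response(cell, p, noise_sd=0, nonlinearity="identity")
        t = np.arange(tr.size) / 500.0
        uv_on = [row[1] for row in p.metadata["trial_table"] if row[0] == "uv_center"][0]
        during = (t > uv_on + 0.2) & (t < uv_on + 1.0)
        far = t < uv_on - 0.1
        assert tr[during].max() < -0.5
        assert np.allclose(tr[far], 0, atol=1e-9)

    def test_ln_linearity_doubling_weights(self):
        cell = sd.GroundTruthCell(-1.0, "OPL", -0.5, -0.2, 0.1, 0.3)
        cell2 = sd.GroundTruthCell(-1.0, "OPL", -1.0, -0.4, 0.2, 0.6,
                                   kinetics_tau_s=cell.kinetics_tau_s)
        p = sd.make_flicker_protocol(4, 10.0, 10.0, seed=1)
        a = sd.simulate_cell_response(cell, p, 0, nonlinearity="identity")
        b = sd.simulate_cell_response(cell2, p, 0, nonlinearity="identity")
        assert np.allclose(b, 2 * a, atol=1e-10)

    def test_noise_determinism(self):
        cell = sd.GroundTruthCell(-1.0, "OPL", -1, 0)
        p = sd.make_flicker_protocol(4, 10.0, 2.0, seed=0)
        a = sd.simulate_cell_response(cell, p, noise_sd=0.5, seed=9)
        b = sd.simulate_cell_response(cell, p, noise_sd=0.5, seed=9)
        assert np.array_equal(a, b)

    def test_invalid_args(self):
        cell = sd.GroundTruthCell(-1.0, "OPL", -1, 0)
        p = sd.make_flicker_protocol(4, 10.0, 2.0, seed=0)
        with pytest.raises(ValueError):
            sd.simulate_cell_response(cell, p, noise_sd=-1)
        with pytest.raises(ValueError):
            sd.GroundTruthCell(0, "OPL", np.inf, 0)
        with pytest.raises(ValueError):
            sd.GroundTruthCell(0, "OPL", 0, 0, kinetics_tau_s=0)


class TestWeightInversion:
    @given(st.floats(-2.5, 3.0), st.sampled_from([-1.0, 1.0]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_sc_weight_roundtrip(self, sc, sign):
        wg, wu = sd.weights_from_sc(sc, sign)
        assert abs(abs(wg) + abs(wu) - 1.0) < 1e-12
        assert sd.truth_spectral_contrast(wg, wu, sign) == pytest.approx(sc, abs=1e-9)


class TestPopulation:
    def test_flat_gradient_same_expected_sc(self):
        cells = sd.make_population(50, "OPL", gradient_params=dict(
            sc_ventral=-0.5, sc_dorsal=-0.5, sc_jitter=0.0), seed=0)
        scs = [sd.truth_spectral_contrast(c.w_center_green, c.w_center_uv, -1)
               for c in cells]
        assert np.ptp(scs) < 1e-9

    def test_ventral_population_uv_dominant(self):
        cells = sd.make_population(200, "OPL", dorsoventral_range_mm=(-2.0, -0.5), seed=1)
        scs = [sd.truth_spectral_contrast(c.w_center_green, c.w_center_uv, -1)
               for c in cells]
        assert np.mean(scs) < 0

    def test_gradient_monotone_with_position(self):
        cells = sd.make_population(1000, "OPL", dorsoventral_range_mm=(-2, 2), seed=2)
        pos = [c.position_mm for c in cells]
        scs = [sd.truth_spectral_contrast(c.w_center_green, c.w_center_uv, -1)
               for c in cells]
        rho, _ = spearmanr(pos, scs)
        assert rho > 0.9

    def test_gcl_needs_templates(self):
        with pytest.raises(ValueError):
            sd.make_population(10, "GCL", seed=0)

    def test_pinned_population_moments(self):
        cells = sd.make_population_from_sc(2000, "IPL", -0.44, 0.24, seed=3)
        scs = [sd.truth_spectral_contrast(c.w_center_green, c.w_center_uv, +1)
               for c in cells]
        assert np.mean(scs) == pytest.approx(-0.44, abs=0.02)
        assert np.std(scs) == pytest.approx(0.24, abs=0.02)


class TestScanField:
    def test_single_cell_no_noise_perfect_correlation(self):
        cell = sd.GroundTruthCell(-1.0, "OPL", -1, 0)
        p = sd.make_flash_protocol(n_repeats=2)
        geom = sd.FieldGeometry(shape=(20, 20), pixel_noise_sd=0.0, terminal_diam_um=5)
        m = sd.simulate_scan_field([cell], geom, p, seed=0, rate_hz=7.8)
        assert len(np.unique(m.truth_mask)) == 2  # background + one unit
        sel = m.truth_mask == 1
        traces = m.pixels[sel]
        c = np.corrcoef(traces)
        assert np.all(c > 0.999)

    def test_mosaic_exclusion_radius(self):
        cells = sd.make_population(40, "OPL", seed=1)
        p = sd.make_flash_protocol(n_repeats=1)
        geom = sd.FieldGeometry(shape=(80, 80), um_per_px=1.3, terminal_diam_um=6.0)
        m = sd.simulate_scan_field(cells, geom, p, seed=2, rate_hz=3.9)
        centers = m.truth_centers_px * geom.um_per_px
        d = np.sqrt(((centers[:, None] - centers[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 6.0

    def test_overcrowded_field_raises(self):
        cells = sd.make_population(200, "OPL", seed=1)
        geom = sd.FieldGeometry(shape=(20, 20), um_per_px=1.0, terminal_diam_um=6.0,
                                max_placement_tries=2000)
        p = sd.make_flash_protocol(n_repeats=1)
        with pytest.raises(RuntimeError):
            sd.simulate_scan_field(cells, geom, p, seed=0, rate_hz=3.9)

    def test_frame_count_matches_duration(self):
        cell = sd.GroundTruthCell(-1.0, "OPL", -1, 0)
        p = sd.make_flash_protocol(n_repeats=1)
        geom = sd.FieldGeometry(shape=(16, 16))
        m = sd.simulate_scan_field([cell], geom, p, seed=0, rate_hz=7.8125)
        assert abs(m.n_frames - p.duration_s * 7.8125) <= 1
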