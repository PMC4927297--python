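"""Generator behaviour: capacitance kinetics, reporter bookkeeping,
neighbor ROI, acid puffs, and seeding."""

import numpy as np
import pytest

import calyxcycle as cc
from calyxcycle import EndocytosisParams, PuffEvent, ReacidificationParams, preset


class TestCapacitance:
    def test_jump_amplitude_at_stimulus_end(self, rat_clean):
        """Ten pulses add 1.52 pF on top of the 18.87 pF baseline."""
        cm = rat_clean["cm"]
        assert cm.interp(0.0) - 18.87 == pytest.approx(1.52, abs=1e-9)

    def test_closed_form_endpoint(self, rat_clean):
        """Normalized recovery at 60 s matches the closed-form mixture
        0.12 + 0.88*(0.37 exp(-60/5.2) + 0.63 exp(-60/66.5)) = 0.345."""
        expected = 0.12 + 0.88 * (0.37 * np.exp(-60 / 5.2) + 0.63 * np.exp(-60 / 66.5))
        got = cc.endpoint_metric(rat_clean["cm_norm"], 60.0)
        assert got == pytest.approx(expected, abs=2e-3)
        assert expected == pytest.approx(0.345, abs=5e-4)

    def test_no_endocytosis_limit_is_flat(self):
        scn = preset("rat_control", noise_sd=0.0,
                     endo=EndocytosisParams(0.0, ((1.0, 1e9),)))
        cm = cc.simulate_capacitance(scn)
        post = cm.v[cm.t >= 0]
        np.testing.assert_allclose(post, post[0], rtol=1e-6)

    def test_noise_scale(self):
        scn = preset("rat_control", noise_sd=0.03, seed=5)
        clean = cc.simulate_capacitance(preset("rat_control", noise_sd=0.0))
        noisy = cc.simulate_capacitance(scn)
        resid = noisy.v - clean.v
        assert np.std(resid) == pytest.approx(0.03 * 1.52, rel=0.1)

    def test_per_pulse_superposition_differs(self):
        a = cc.simulate_capacitance(preset("rat_control", noise_sd=0.0))
        b = cc.simulate_capacitance(preset("rat_control", noise_sd=0.0,
                                           endo_onset="per_pulse"))
        assert a.interp(30.0) != pytest.approx(b.interp(30.0), abs=1e-4)

    def test_identical_seeds_bitwise(self):
        x = cc.simulate_capacitance(preset("rat_control", seed=42))
        y = cc.simulate_capacitance(preset("rat_control", seed=42))
        assert np.array_equal(x.v, y.v)
        z = cc.simulate_capacitance(preset("rat_control", seed=43))
        assert not np.array_equal(x.v, z.v)


class TestReporter:
    def test_reacid_block_freezes_quench(self):
        scn = preset("bafilomycin", noise_sd=0.0)
        fl, _ = cc.simulate_reporter(scn)
        q = cc.normalize_invert(fl)
        np.testing.assert_allclose(q.v[q.t >= 0], 1.0, atol=1e-9)

    def test_full_stranding_freezes_quench(self):
        scn = preset("rat_control", noise_sd=0.0, stranding_frac=1.0)
        fl, _ = cc.simulate_reporter(scn)
        q = cc.normalize_invert(fl)
        np.testing.assert_allclose(q.v[q.t >= 0], 1.0, atol=1e-9)

    def test_infinite_delay_equals_block(self):
        blocked = preset("rat_control", noise_sd=0.0, reacid_blocked=True)
        delayed = preset("rat_control", noise_sd=0.0,
                         reacid=ReacidificationParams(delay_s=1e9, tau_acid_s=38.7))
        fa, _ = cc.simulate_reporter(blocked)
        fb, _ = cc.simulate_reporter(delayed)
        np.testing.assert_array_equal(fa.v, fb.v)

    def test_reporter_conservation(self, rat_clean):
        """Surface + endocytosed-unacidified + acidified = exposed pool."""
        log = rat_clean["state_log"]
        post = log[log.time_s >= 0]
        total = post.surface + post.endocytosed + post.acidified
        np.testing.assert_allclose(total, post.exposed, atol=1e-9)
        np.testing.assert_allclose(post.exposed, 1.0, atol=1e-9)

    @pytest.mark.parametrize("name", ["rat_control", "mouse_wt", "bulk_2s", "cam_peptide"])
    def test_quench_non_increasing_after_stimulus(self, name):
        scn = preset(name, noise_sd=0.0)
        fl, _ = cc.simulate_reporter(scn)
        q = cc.normalize_invert(fl)
        assert np.all(np.diff(q.v[q.t >= 0]) <= 1e-12)

    def test_provenance_mismatch_rejected(self, rat_clean):
        other = preset("rat_control", noise_sd=0.0, seed=99)
        with pytest.raises(ValueError, match="provenance"):
            cc.simulate_reporter(other, rat_clean["cm"])


class TestMonteCarloOracle:
    @pytest.mark.parametrize("name", ["rat_control", "mouse_wt"])
    def test_convolution_matches_event_oracle(self, name):
        """The deterministic forward model agrees with 1e5 discrete
        organelles drawn from the same retrieval/re-acidification laws."""
        from conftest import mc_quench_oracle

        scn = preset(name, noise_sd=0.0)
        fl, _ = cc.simulate_reporter(scn)
        q = cc.normalize_invert(fl)
        t_mc, mu, se = mc_quench_oracle(scn)
        conv = np.interp(t_mc, q.t, q.v)
        z = np.abs(conv - mu) / np.maximum(se, 1e-12)
        assert z.max() < 3.0


class TestNeighborRoi:
    def test_no_bleach_is_constant(self):
        scn = preset("rat_control", noise_sd=0.0)
        nb = cc.simulate_neighbor_roi(scn)
        np.testing.assert_allclose(nb.v, nb.v[0])

    def test_linear_bleach_slope_recoverable(self):
        scn = preset("rat_control", noise_sd=0.0, bleach=("linear", 1e-3))
        nb = cc.simulate_neighbor_roi(scn)
        slope = np.polyfit(nb.t - nb.t[0], nb.v, 1)[0]
        assert slope == pytest.approx(-1e-3, rel=1e-6)

    def test_exponential_bleach_log_linear(self):
        scn = preset("rat_control", noise_sd=0.0, bleach=("exponential", 2e-3))
        nb = cc.simulate_neighbor_roi(scn)
        coeffs = np.polyfit(nb.t - nb.t[0], np.log(nb.v), 2)
        assert coeffs[0] == pytest.approx(0.0, abs=1e-12)  # no curvature in log
        assert coeffs[1] == pytest.approx(-2e-3, rel=1e-6)


class TestAcidPuff:
    def test_no_surface_reporter_no_response(self, rat_clean):
        scn = rat_clean["scn"].replace(surface_stranded_density=0.0)
        puff = PuffEvent(onset_s=-15.0)
        out = cc.simulate_acid_puff(scn, rat_clean["fluor"], rat_clean["state_log"], [puff])
        assert out.meta["puff_dF"][0] == pytest.approx(0.0, abs=1e-12)

    def test_prestimulus_puff_reads_stranded_density(self, rat_clean):
        """A pH 5.5 puff before stimulation de-quenches exactly the
        pre-existing stranded surface pool (0.48 of stimulus deltaF)."""
        scn = rat_clean["scn"]
        out = cc.simulate_acid_puff(scn, rat_clean["fluor"], rat_clean["state_log"],
                                    [PuffEvent(onset_s=-15.0, pH=5.5)])
        assert out.meta["puff_dF"][0] == pytest.approx(0.48, abs=1e-9)

    def test_bulk_preset_surface_pool_internalized(self):
        """After a 2-s pulse, membrane retrieval is essentially complete by
        +40 s, so pre- and post-stimulus puffs see the same surface pool."""
        scn = preset("bulk_2s", noise_sd=0.0)
        fl, log = cc.simulate_reporter(scn)
        puffs = [PuffEvent(onset_s=-15.0), PuffEvent(onset_s=40.0)]
        out = cc.simulate_acid_puff(scn, fl, log, puffs)
        pre, post = out.meta["puff_dF"]
        assert post / pre == pytest.approx(1.0, abs=1e-4)
        surf40 = np.interp(40.0, log.time_s, log.surface)
        assert post - pre == pytest.approx(surf40, abs=1e-9)

    def test_overlapping_puffs_rejected(self, rat_clean):
        with pytest.raises(ValueError, match="overlap"):
            cc.simulate_acid_puff(rat_clean["scn"], rat_clean["fluor"],
                                  rat_clean["state_log"],
                                  [PuffEvent(onset_s=0.0), PuffEvent(onset_s=2.0)])
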