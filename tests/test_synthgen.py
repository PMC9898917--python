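"""Tests for the synthetic-data generators: determinism, planted ground
truth, and forward/inverse consistency with the analysis modules."""

import numpy as np
import pytest
from scipy import stats

from thaggfip import cleavage, foldfit, synthgen
from thaggfip.foldfit import StabilityParams
from thaggfip.synthgen import (
    SynthConfig,
    gen_cleavage_dataset,
    gen_dls_trace,
    gen_melt_curves,
    gen_tht_trace,
)


class TestSynthConfig:
    def test_background_validated(self):
        with pytest.raises(ValueError):
            SynthConfig(background=np.full(20, 0.06))  # sums to 1.2

    def test_invalid_motif_position_rejected(self):
        with pytest.raises(ValueError, match="position"):
            SynthConfig(motif={"p": {9: {"K": 1.0}}})

    def test_motif_probability_overflow_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(motif={"p": {3: {"K": 0.7, "R": 0.5}}})


class TestCleavageDataset:
    def test_degenerate_motif_forces_residue(self):
        cfg = SynthConfig(seed=1, n_substrates=50, motif={"p": {3: {"K": 1.0}}})
        ds = gen_cleavage_dataset(cfg, n_fragments=0)
        assert all(w.residues[3] == "K" for w in ds.windows["p"])

    def test_no_fragments_still_returns_sequence(self):
        cfg = SynthConfig(seed=2)
        ds = gen_cleavage_dataset(cfg, seq_len=100, n_fragments=0)
        assert len(ds.sequence) == 100
        assert ds.fragments == []

    def test_planted_p1_frequency_within_binomial_bounds(self):
        p_true = 0.8
        cfg = SynthConfig(
            seed=3,
            n_substrates=200,
            motif={"p": {3: {"K": p_true}}},
            background=np.full(20, 0.05),
        )
        ds = gen_cleavage_dataset(cfg, n_fragments=0)
        count = sum(w.residues[3] == "K" for w in ds.windows["p"])
        # 99% binomial bounds; background adds 0.2 * 0.05 K mass
        p_eff = p_true + (1 - p_true) * 0.05
        lo = stats.binom.ppf(0.005, 200, p_eff)
        hi = stats.binom.ppf(0.995, 200, p_eff)
        assert lo <= count <= hi

    def test_fragment_edges_lie_on_recorded_cut_sites(self):
        cfg = SynthConfig(seed=4)
        ds = gen_cleavage_dataset(cfg, seq_len=214, n_fragments=6)
        cuts = set(ds.true_cut_sites)
        for f in ds.fragments:
            for cut in (f.start - 1, f.end):
                if 4 <= cut <= len(ds.sequence) - 4:
                    assert cut in cuts

    def test_determinism(self):
        a = gen_cleavage_dataset(SynthConfig(seed=7))
        b = gen_cleavage_dataset(SynthConfig(seed=7))
        assert a.sequence == b.sequence
        assert a.fragments == b.fragments
        assert [w.residues for w in a.windows["cathepsin_B"]] == [
            w.residues for w in b.windows["cathepsin_B"]
        ]

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            gen_cleavage_dataset(SynthConfig(seed=0), seq_len=10)


class TestMeltCurves:
    def test_noiseless_equals_signal_model(self, stability_truth):
        curves = gen_melt_curves(stability_truth, urea_grid=[1.34], noise_sd=0.0)
        (c,) = curves
        np.testing.assert_allclose(
            c.i330, foldfit.signal_model(stability_truth, c.T, 1.34, 330)
        )

    def test_paper_urea_protocol_yields_nine_families(self, stability_truth):
        curves = gen_melt_curves(stability_truth, noise_sd=0.0, n_capillaries=2)
        assert len({c.urea_M for c in curves}) == 9
        assert len(curves) == 18

    def test_ratio_midpoint_at_tm(self):
        truth = StabilityParams(
            tm_C=50.0, dHm=500.0, dCp=8.0, m_value=7.1,
            baselines={330: (1.0, 0.0, 0.6, 0.0), 350: (0.6, 0.0, 1.0, 0.0)},
        )
        T = np.arange(30.0, 70.0 + 1e-9, 0.1)
        (c,) = gen_melt_curves(truth, urea_grid=[0.0], T_grid=T, noise_sd=0.0)
        # invert the 330 nm channel to the unfolded fraction and locate 0.5
        fu = (c.i330 - 1.0) / (0.6 - 1.0)
        mid = np.interp(0.5, fu, c.T)
        assert mid == pytest.approx(50.0, abs=0.05)

    def test_determinism_and_noise_sd_convergence(self, stability_truth):
        T = np.arange(20.0, 70.0, 0.02)  # large grid for tight SD estimate
        a = gen_melt_curves(stability_truth, urea_grid=[2.01], T_grid=T, noise_sd=0.01, seed=5)
        b = gen_melt_curves(stability_truth, urea_grid=[2.01], T_grid=T, noise_sd=0.01, seed=5)
        np.testing.assert_array_equal(a[0].i350, b[0].i350)
        clean = foldfit.signal_model(stability_truth, T, 2.01, 350)
        resid_sd = np.std(a[0].i350 - clean)
        assert resid_sd == pytest.approx(0.01, rel=0.05)


class TestDlsAndThtTraces:
    T = np.arange(25.0, 70.0 + 1e-9, 0.5)

    def test_zero_growth_flat_at_baseline(self):
        tr = gen_dls_trace(self.T, baseline_radius=3.0, growth_amplitude=0.0, noise_sd=0.0)
        np.testing.assert_allclose(tr.radius, 3.0)

    def test_large_growth_reaches_micron_scale(self):
        tr = gen_dls_trace(
            self.T, baseline_radius=3.0, Tagg_true=50.0,
            growth_amplitude=1000.0, growth_width=1.0, noise_sd=0.0,
        )
        assert tr.radius[-1] == pytest.approx(1003.0, rel=0.01)

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            gen_dls_trace(self.T, baseline_radius=-1.0)

    def test_tht_noiseless_identity(self):
        from thaggfip.aggkin import SigmoidalFit, sigmoid_model

        truth = SigmoidalFit(y_i=1.0, m_i=0.0, y_f=9.0, m_f=0.0, t50=10.0, k=2.0)
        t = np.linspace(0, 30, 100)
        tr = gen_tht_trace(truth, t, noise_sd=0.0)
        np.testing.assert_allclose(
            tr.intensity, sigmoid_model(t, 1.0, 0.0, 9.0, 0.0, 10.0, 2.0)
        )
        assert tr.intensity[np.argmin(np.abs(t - 10.0))] == pytest.approx(5.5, abs=0.05)


class TestSerialisation:
    def test_melt_curve_csv_round_trip(self, tmp_path, stability_truth):
        curves = gen_melt_curves(
            stability_truth, urea_grid=[0.0, 0.67], noise_sd=0.002,
            n_capillaries=2, seed=1,
        )
        path = tmp_path / "curves.csv"
        synthgen.write_melt_curves_csv(path, curves)
        back = synthgen.read_melt_curves_csv(path)
        assert len(back) == len(curves)
        orig = {(c.capillary_id, c.urea_M): c for c in curves}
        for c in back:
            o = orig[(c.capillary_id, c.urea_M)]
            np.testing.assert_allclose(c.i330, o.i330, rtol=1e-12)
            np.testing.assert_allclose(c.i350, o.i350, rtol=1e-12)

    def test_fasta_and_tsv_round_trip(self, tmp_path):
        cfg = SynthConfig(seed=11)
        ds = gen_cleavage_dataset(cfg, seq_len=120, n_fragments=3)
        synthgen.write_fasta(tmp_path / "s.fasta", {ds.parent_id: ds.sequence})
        synthgen.write_windows_tsv(tmp_path / "w.tsv", ds.windows)
        synthgen.write_fragments_tsv(tmp_path / "f.tsv", ds.fragments)
        assert synthgen.read_fasta(tmp_path / "s.fasta")[ds.parent_id] == ds.sequence
        back_w = synthgen.read_windows_tsv(tmp_path / "w.tsv")
        assert [w.residues for w in back_w["cathepsin_D"]] == [
            w.residues for w in ds.windows["cathepsin_D"]
        ]
        assert synthgen.read_fragments_tsv(tmp_path / "f.tsv") == ds.fragments

    def test_truth_json_sidecar(self, tmp_path, stability_truth):
        import json

        path = tmp_path / "truth.json"
        synthgen.write_truth_json(path, {"stability": stability_truth, "seed": 3})
        loaded = json.loads(path.read_text())
        assert loaded["stability"]["tm_C"] == 52.0
        assert loaded["seed"] == 3
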