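"""Quality-control reports: MA flatness, replicate concordance, peak
convergence across replicates, TSS-distance histograms."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_peak, make_track
from minichip.experiments import normalized_average_track
from minichip.normalize import (average_replicates, ma_transform,
                                quantile_normalize, within_array_normalize)
from minichip.peaks import PeakCallerConfig, PeakSet, call_peaks
from minichip.qc import (histogram_similarity, ma_plot_report,
                         peak_convergence_report, replicate_concordance,
                         tss_distance_histogram)
from minichip.simulate import (MarkSpec, SimulationConfig,
                               build_promoter_model, simulate_array)
from minichip.annotate import assign_peaks_to_tss, call_promoter_state


def _null_config(**kw):
    defaults = dict(
        n_genes=60, n_replicates=2,
        marks=[MarkSpec("H3K4me3", "activating", "tss_double_peak", 2.5, 0.0)],
        rng_seed=31)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestMaPlotReport:
    def test_injected_bias_fails_before_and_passes_after(self):
        cfg = _null_config(dye_bias_amplitude=0.5, array_scale_shifts=(0.0,),
                           n_replicates=1)
        model = build_promoter_model(cfg)
        raw = ma_transform(simulate_array(model, "H3K4me3", 0), "a",
                           "H3K4me3", "stem")
        fixed = within_array_normalize(raw)
        report = ma_plot_report(raw, fixed)
        assert report.verdicts["max_abs_decile_median_before"] == "warn"
        assert report.verdicts["max_abs_decile_median_after"] == "pass"
        assert report.passed

    def test_bias_free_track_passes_both_sides(self):
        cfg = _null_config(dye_bias_amplitude=0.0, array_scale_shifts=(0.0,),
                           n_replicates=1)
        model = build_promoter_model(cfg)
        raw = ma_transform(simulate_array(model, "H3K4me3", 0), "a",
                           "H3K4me3", "stem")
        report = ma_plot_report(raw, within_array_normalize(raw))
        assert report.verdicts["max_abs_decile_median_before"] == "pass"

    def test_constant_track_decile_medians_are_the_constant(self):
        rng = np.random.default_rng(0)
        t = make_track(np.full(1000, 0.7), a=rng.normal(10, 1, 1000),
                       state="raw")
        report = ma_plot_report(t, t)
        assert np.allclose(report.metrics["decile_medians_before"], 0.7)

    def test_report_is_deterministic(self):
        rng = np.random.default_rng(1)
        t = make_track(rng.normal(0, 0.3, 500), a=rng.normal(10, 1, 500),
                       state="raw")
        r1 = ma_plot_report(t, t)
        r2 = ma_plot_report(t, t)
        assert r1.metrics == r2.metrics and r1.verdicts == r2.verdicts


class TestReplicateConcordance:
    def test_identical_tracks_correlate_perfectly(self):
        m = np.random.default_rng(2).normal(0, 1, 300)
        tracks = [make_track(m, array_id=f"r{i}") for i in range(2)]
        report = replicate_concordance(tracks)
        assert report.metrics["min_pairwise_pearson_r"] == pytest.approx(1.0)

    def test_independent_noise_tracks_near_zero(self):
        rng = np.random.default_rng(3)
        tracks = [make_track(rng.normal(0, 1, 5000), array_id=f"r{i}",
                             state="within_array") for i in range(2)]
        report = replicate_concordance(tracks)
        assert abs(report.metrics["min_pairwise_pearson_r"]) < 0.1

    def test_post_quantile_summaries_identical(self):
        rng = np.random.default_rng(4)
        tracks = [make_track(rng.normal(i, 1 + i, 400), array_id=f"r{i}",
                             state="within_array") for i in range(2)]
        qn = quantile_normalize(tracks)
        report = replicate_concordance(qn, min_pearson=-1.0)
        assert report.verdicts["five_number_summaries_identical"] == "pass"


class TestPeakConvergence:
    def _peakset(self, n, tier="strict"):
        return PeakSet([make_peak(i * 2000, i * 2000 + 500, tier=tier)
                        for i in range(n)])

    def test_concordant_replicates_unflagged(self):
        report = peak_convergence_report({
            "rep0": self._peakset(10), "rep1": self._peakset(11),
            "rep2": self._peakset(9)})
        assert report.passed
        assert report.metrics["outlier_labels"] == []

    def test_dead_replicate_flagged(self):
        report = peak_convergence_report({
            "rep0": self._peakset(10), "rep1": self._peakset(10),
            "rep2": self._peakset(0)})
        assert not report.passed
        assert report.metrics["outlier_labels"] == ["rep2"]

    def test_failed_chip_detected_end_to_end(self):
        # one replicate simulated without spike signal: its single-array
        # peak calls collapse relative to the healthy replicates
        mark = MarkSpec("H3K4me3", "activating", "tss_double_peak", 2.5, 0.5)
        cfg = SimulationConfig(n_genes=40, n_replicates=3, marks=[mark],
                               rng_seed=37)
        dead_cfg = SimulationConfig(
            n_genes=40, n_replicates=3,
            marks=[MarkSpec("H3K4me3", "activating", "tss_double_peak",
                            2.5, 0.0)], rng_seed=37)
        model = build_promoter_model(cfg)
        dead_model = build_promoter_model(dead_cfg)
        peaksets = {}
        for rep in range(3):
            src_model, src_cfg = ((dead_model, dead_cfg) if rep == 2
                                  else (model, cfg))
            raw = ma_transform(simulate_array(src_model, "H3K4me3", rep,
                                              src_cfg),
                               f"rep{rep}", "H3K4me3", "stem")
            single = within_array_normalize(raw).advance(
                "quantile", within_array_normalize(raw).m)
            track = single.advance("averaged", single.m)
            peaksets[f"rep{rep}"] = call_peaks(
                track, PeakCallerConfig(rng_seed=37))
        report = peak_convergence_report(peaksets)
        assert report.metrics["outlier_labels"] == ["rep2"]


class TestTssHistogram:
    def _annotated(self, cfg_seed=41, profile="tss_double_peak"):
        cfg = SimulationConfig(
            n_genes=40, n_replicates=3,
            marks=[MarkSpec("mark", "activating", profile, 2.5, 0.6)],
            rng_seed=cfg_seed)
        model = build_promoter_model(cfg)
        track = normalized_average_track(model, "mark", cfg)
        ps = call_peaks(track, PeakCallerConfig(rng_seed=cfg_seed))
        calls, _ = assign_peaks_to_tss(ps, model.genes)
        return call_promoter_state(calls), model

    def test_tss_mark_mass_concentrates_at_the_tss(self):
        calls, model = self._annotated()
        report = tss_distance_histogram(calls, model.genes)
        counts = np.array(report.metrics["counts"])
        edges = np.array(report.metrics["bin_edges"])
        centers = (edges[:-1] + edges[1:]) / 2
        near = np.abs(centers) <= 1000
        assert counts[near].sum() >= 0.8 * counts.sum() > 0

    def test_gene_body_mark_mass_is_downstream(self):
        calls, model = self._annotated(profile="gene_body")
        report = tss_distance_histogram(calls, model.genes)
        counts = np.array(report.metrics["counts"])
        edges = np.array(report.metrics["bin_edges"])
        centers = (edges[:-1] + edges[1:]) / 2
        assert counts[centers > 0].sum() > counts[centers < 0].sum()

    def test_empty_calls_give_all_zero_histogram(self):
        genes = pd.DataFrame({"gene_id": ["g1"], "chromosome": ["chr1"],
                              "tss": [20000], "strand": ["+"]})
        from minichip.annotate import PromoterCall
        calls = {"g1": PromoterCall("g1", "m", "ct")}
        report = tss_distance_histogram(calls, genes)
        assert sum(report.metrics["counts"]) == 0

    def test_replicate_histograms_similar(self):
        calls, model = self._annotated()
        r1 = tss_distance_histogram(calls, model.genes)
        r2 = tss_distance_histogram(calls, model.genes)
        assert histogram_similarity(r1, r2) == pytest.approx(1.0)


class TestFailureModeDetection:
    """The QC battery must catch each injected failure mode almost always."""

    N_SIMS = 50

    def test_dye_bias_detected(self):
        detected = 0
        for seed in range(self.N_SIMS):
            cfg = _null_config(n_genes=20, n_replicates=1,
                               dye_bias_amplitude=0.5,
                               array_scale_shifts=(0.0,), rng_seed=seed)
            model = build_promoter_model(cfg)
            raw = ma_transform(simulate_array(model, "H3K4me3", 0), "a",
                               "H3K4me3", "stem")
            report = ma_plot_report(raw, within_array_normalize(raw))
            detected += report.verdicts["max_abs_decile_median_before"] == "warn"
        assert detected / self.N_SIMS >= 0.95

    def test_between_array_scale_shift_detected(self):
        detected = 0
        for seed in range(self.N_SIMS):
            cfg = _null_config(n_genes=20, n_replicates=2,
                               dye_bias_amplitude=0.0,
                               array_scale_shifts=(0.0, 0.8), rng_seed=seed)
            model = build_promoter_model(cfg)
            tracks = [ma_transform(simulate_array(model, "H3K4me3", r),
                                   f"r{r}", "H3K4me3", "stem")
                      for r in range(2)]
            report = replicate_concordance(tracks, min_pearson=-1.0)
            medians = [s[2] for s in report.metrics["five_number_summaries"]]
            detected += abs(medians[1] - medians[0]) > 0.3
        assert detected / self.N_SIMS >= 0.95

    def test_dead_replicate_detected(self):
        mark = MarkSpec("H3K4me3", "activating", "tss_double_peak", 2.5, 0.5)
        detected = 0
        for seed in range(self.N_SIMS):
            cfg = SimulationConfig(n_genes=20, n_replicates=3, marks=[mark],
                                   rng_seed=seed)
            dead_cfg = SimulationConfig(
                n_genes=20, n_replicates=3,
                marks=[MarkSpec("H3K4me3", "activating", "tss_double_peak",
                                2.5, 0.0)], rng_seed=seed)
            model = build_promoter_model(cfg)
            dead_model = build_promoter_model(dead_cfg)
            peaksets = {}
            for rep in range(3):
                src_model, src_cfg = ((dead_model, dead_cfg) if rep == 2
                                      else (model, cfg))
                raw = ma_transform(
                    simulate_array(src_model, "H3K4me3", rep, src_cfg),
                    f"rep{rep}", "H3K4me3", "stem")
                single = within_array_normalize(raw)
                track = single.advance("quantile", single.m).advance(
                    "averaged", single.m)
                peaksets[f"rep{rep}"] = call_peaks(
                    track, PeakCallerConfig(rng_seed=seed))
            report = peak_convergence_report(peaksets)
            detected += "rep2" in report.metrics["outlier_labels"]
        assert detected / self.N_SIMS >= 0.95
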