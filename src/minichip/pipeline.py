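"""End-to-end orchestration: simulate -> normalize -> peaks -> annotate ->
integrate -> qc, with on-disk intermediates, stage resume and provenance.

Each stage writes its outputs (plus the resolved configuration) into a run
directory; a stage is skipped on re-run when its sentinel outputs already
exist, so deleting one stage's outputs resumes the pipeline from there.
Fixed seeds give byte-identical run directories.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import integrate as integ
from . import io as mio
from . import qc as qcmod
from .normalize import (RatioTrack, average_replicates, ma_transform,
                        quantile_normalize, within_array_normalize)
from .peaks import PeakCallerConfig, call_peaks
from .simulate import (SimulationConfig, config_from_dict, config_to_dict,
                       simulate_study)

log = logging.getLogger("minichip")

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("simulate", "normalize", "callpeaks", "annotate", "integrate", "qc")


@dataclasses.dataclass
class PipelineConfig:
    simulation: SimulationConfig = dataclasses.field(
        default_factory=SimulationConfig)
    peaks: PeakCallerConfig = dataclasses.field(
        default_factory=PeakCallerConfig)
    polarity: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(integ.DEFAULT_POLARITY))
    within_array_method: str = "a_lowess"
    bin_size: int = 100
    stages: tuple[str, ...] = STAGES
    qc_hard_fail: bool = False  # abort downstream stages on a QC failure
    rng_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = config_to_dict(self.simulation)
        d["peaks"] = dataclasses.asdict(self.peaks)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = config_from_dict(d["simulation"])
        if "peaks" in d:
            d["peaks"] = PeakCallerConfig(**d["peaks"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _array_path(outdir: Path, ct: str, mark: str, rep: int) -> Path:
    return outdir / "arrays" / f"{ct}_{mark}_rep{rep}.tsv"


def run_pipeline(config: PipelineConfig, outdir: Path | str) -> Path:
    """Execute the configured stages, resuming from existing outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    cfg_dict = config.to_dict()
    cfg_hash = mio.config_hash(cfg_dict)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)

    sim = config.simulation
    try:
        _run_stages(config, outdir, cfg_hash)
    except Exception:
        log.removeHandler(handler)
        handler.close()
        raise
    log.removeHandler(handler)
    handler.close()
    return outdir


def _run_stages(config: PipelineConfig, outdir: Path, cfg_hash: str) -> None:
    sim = config.simulation
    sentinel_ok = lambda p: Path(p).exists()

    # ---- simulate ---------------------------------------------------------
    promoter_path = outdir / "promoters.tsv"
    if "simulate" in config.stages and not sentinel_ok(promoter_path):
        log.info("stage simulate")
        model, arrays = simulate_study(sim)
        for (ct, mark, rep), signals in arrays.items():
            mio.write_probe_file(signals, _array_path(outdir, ct, mark, rep))
        mio.write_promoter_table(model.genes, model.expression, promoter_path)
        truth = pd.concat(
            {ct: t for ct, t in model.truth.items()}, names=["cell_type"])
        # ground-truth sidecar: written for auditing, never read back
        truth.to_csv(outdir / "truth_sidecar.tsv", sep="\t")
    genes, expression = mio.read_promoter_table(promoter_path)

    # ---- normalize --------------------------------------------------------
    avg_dir = outdir / "tracks"
    marks = [m.name for m in sim.marks]
    combos = [(ct, mark) for ct in sim.cell_types for mark in marks]
    if "normalize" in config.stages and not all(
            sentinel_ok(avg_dir / f"{ct}_{mark}_averaged.tsv")
            for ct, mark in combos):
        log.info("stage normalize")
        for ct, mark in combos:
            reps = []
            for rep in range(sim.n_replicates):
                signals = mio.read_probe_file(
                    _array_path(outdir, ct, mark, rep))
                raw = ma_transform(signals, f"{ct}_{mark}_rep{rep}", mark, ct)
                reps.append(within_array_normalize(
                    raw, method=config.within_array_method))
            qn = quantile_normalize(reps)
            for t in qn:
                mio.write_track(t, avg_dir / f"{t.array_id}_quantile.tsv",
                                cfg_hash)
            avg = average_replicates(qn)
            mio.write_track(avg, avg_dir / f"{ct}_{mark}_averaged.tsv",
                            cfg_hash)

    # ---- callpeaks --------------------------------------------------------
    peak_dir = outdir / "peaks"
    if "callpeaks" in config.stages and not all(
            sentinel_ok(peak_dir / f"{ct}_{mark}.bed") for ct, mark in combos):
        log.info("stage callpeaks")
        for ct, mark in combos:
            avg = mio.read_track(avg_dir / f"{ct}_{mark}_averaged.tsv")
            ps = call_peaks(avg, config.peaks)
            mio.write_peaks_bed(ps, peak_dir / f"{ct}_{mark}.bed")
            mio.write_table(ps.to_dataframe(),
                            peak_dir / f"{ct}_{mark}_peaks.tsv",
                            "callpeaks", cfg_hash)

    # ---- annotate ---------------------------------------------------------
    call_dir = outdir / "calls"
    if "annotate" in config.stages and not all(
            sentinel_ok(call_dir / f"{ct}_{mark}_calls.tsv")
            for ct, mark in combos):
        log.info("stage annotate")
        for ct, mark in combos:
            ps = _read_peaks_table(peak_dir / f"{ct}_{mark}_peaks.tsv",
                                   mark, ct)
            calls, unassigned = ann.assign_peaks_to_tss(
                ps, genes, sim.window_upstream, sim.window_downstream)
            calls = ann.call_promoter_state(calls, tier="strict")
            mio.write_table(ann.calls_to_dataframe(calls),
                            call_dir / f"{ct}_{mark}_calls.tsv",
                            "annotate", cfg_hash)
            mio.write_assigned_gff(calls, call_dir / f"{ct}_{mark}.gff")
            log.info("%s/%s: %d peaks unassigned", ct, mark, len(unassigned))

    # ---- integrate --------------------------------------------------------
    net_path = outdir / "net_enrichment.tsv"
    if "integrate" in config.stages and not sentinel_ok(net_path):
        log.info("stage integrate")
        per_ct_calls = {}
        for ct in sim.cell_types:
            calls_by_mark = {
                mark: _reload_calls(peak_dir, call_dir, ct, mark, genes, sim)
                for mark in marks}
            per_ct_calls[ct] = calls_by_mark
            records = integ.net_enrichment(
                calls_by_mark, config.polarity, expression[ct])
            mio.write_table(records, outdir / f"net_enrichment_{ct}.tsv",
                            "integrate", cfg_hash)
            if len(records) >= 2 * config.bin_size:
                table, rho = integ.correlate_net_with_expression(
                    records, config.bin_size)
                table["spearman_rho"] = rho
                mio.write_table(table, outdir / f"expression_bins_{ct}.tsv",
                                "integrate", cfg_hash)
        if len(sim.cell_types) >= 2:
            ct_a, ct_b = sim.cell_types[:2]
            fc = integ.fold_change_score_analysis(
                per_ct_calls[ct_a], per_ct_calls[ct_b],
                expression[ct_a], expression[ct_b])
            mio.write_table(fc, outdir / "fold_change_scores.tsv",
                            "integrate", cfg_hash)
        mio.write_table(pd.DataFrame({"done": [1]}), net_path,
                        "integrate", cfg_hash)

    # ---- qc ---------------------------------------------------------------
    qc_path = outdir / "qc_report.tsv"
    if "qc" in config.stages and not sentinel_ok(qc_path):
        log.info("stage qc")
        reports = []
        for ct, mark in combos:
            tracks = [mio.read_track(
                avg_dir / f"{ct}_{mark}_rep{r}_quantile.tsv")
                for r in range(sim.n_replicates)]
            if len(tracks) >= 2:
                reports.append(qcmod.replicate_concordance(tracks))
        frames = [r.to_dataframe() for r in reports]
        table = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame())
        mio.write_table(table, qc_path, "qc", cfg_hash)
        if config.qc_hard_fail and any(not r.passed for r in reports):
            raise RuntimeError("stage qc: hard QC failure")


def _read_peaks_table(path: Path, mark: str, ct: str):
    from .peaks import Peak, PeakSet
    df = mio.read_table(path)
    peaks = [Peak(chromosome=r.chromosome, start=int(r.start), end=int(r.end),
                  n_probes=int(r.n_probes), score_pct=float(r.score_pct),
                  score_log2=float(r.score_log2), mean_m=float(r.mean_m),
                  fdr=float(r.fdr), tier=r.tier, mark=mark, cell_type=ct)
             for r in df.itertuples()]
    return PeakSet(peaks, mark=mark, cell_type=ct)


def _reload_calls(peak_dir: Path, call_dir: Path, ct: str, mark: str,
                  genes: pd.DataFrame, sim: SimulationConfig):
    ps = _read_peaks_table(peak_dir / f"{ct}_{mark}_peaks.tsv", mark, ct)
    calls, _ = ann.assign_peaks_to_tss(
        ps, genes, sim.window_upstream, sim.window_downstream)
    return ann.call_promoter_state(calls, tier="strict")
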