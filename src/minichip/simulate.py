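"""Synthetic two-color promoter tiling-array data.

Emulates the statistical structure of a miniaturized ChIP-chip experiment on
promoter tiling arrays: ~100 bp-spaced probes tiling a strand-oriented
-8.2 kb/+3 kb window around each TSS, two-channel intensities (R = ChIP,
G = input) distorted by an intensity-dependent dye bias, per-replicate scale
shifts and log2 probe noise, with mark-specific spatial enrichment profiles
spiked into a configurable fraction of promoters:

* ``tss_double_peak`` -- two maxima flanking the TSS with a local trough at
  the TSS itself (the canonical H3K4me3 promoter shape);
* ``gene_body``       -- enrichment downstream of the TSS (H3K36me3/H3K79me2);
* ``broad_domain``    -- a wide plateau across the tiled window
  (H3K27me3/H3K9me3 heterochromatic domains).

Expression is coupled to the ground-truth marks (log-normal base, additive
log2-scale effects: activating marks raise expression, silencing marks lower
it), so downstream chromatin/expression integration has a known signal to
recover.  All randomness flows from ``SimulationConfig.rng_seed`` through
:class:`numpy.random.SeedSequence`; identical seeds give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkSpec",
    "SimulationConfig",
    "PromoterModel",
    "default_marks",
    "build_promoter_model",
    "simulate_array",
    "simulate_study",
    "simulate_qpcr",
    "true_percent_input",
]

ACTIVATING = "activating"
SILENCING = "silencing"
_PROFILES = ("tss_double_peak", "gene_body", "broad_domain")


@dataclass(frozen=True)
class MarkSpec:
    """One chromatin mark (or PolII) tracked by the simulated study."""

    name: str
    polarity: str  # activating | silencing
    profile: str  # tss_double_peak | gene_body | broad_domain
    effect_size: float  # peak log2 enrichment at truly enriched genes
    fraction_enriched: float  # fraction of genes carrying the mark

    def __post_init__(self) -> None:
        if self.polarity not in (ACTIVATING, SILENCING):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown spatial profile {self.profile!r}")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0 for enriched genes")
        if not 0 <= self.fraction_enriched <= 1:
            raise ValueError("fraction_enriched must be in [0, 1]")


def default_marks() -> list[MarkSpec]:
    """Five histone marks with field-typical shapes and polarities."""
    return [
        MarkSpec("H3K4me3", ACTIVATING, "tss_double_peak", 2.5, 0.40),
        MarkSpec("H3ac", ACTIVATING, "tss_double_peak", 2.0, 0.35),
        MarkSpec("H3K79me2", ACTIVATING, "gene_body", 2.0, 0.30),
        MarkSpec("H3K27me3", SILENCING, "broad_domain", 1.5, 0.25),
        MarkSpec("H3K9me3", SILENCING, "broad_domain", 1.5, 0.15),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic tiling-array experiment.

    Defaults describe a desk-scale version of a promoter-array study:
    100 bp probe spacing across an 11.2 kb (-8.2 kb / +3 kb) window,
    triplicate arrays, 0.35 log2 probe noise, a quadratic dye-bias of
    amplitude 0.5 log2 and small per-replicate scale shifts.
    """

    n_genes: int = 200
    probe_spacing: int = 100
    window_upstream: int = 8200
    window_downstream: int = 3000
    marks: list[MarkSpec] = field(default_factory=default_marks)
    cell_types: tuple[str, ...] = ("stem",)
    n_replicates: int = 3
    dye_bias_amplitude: float = 0.5
    array_scale_shifts: tuple[float, ...] | None = None
    noise_sd: float = 0.35
    expression_effect: float = 1.5  # log2 expression shift per truth mark
    truth_flip_prob: float = 0.2  # per-gene/mark flip for extra cell types
    overlap_fraction: float = 0.0  # fraction of genes tiled overlapping the previous
    n_chromosomes: int = 5
    baseline_log2_intensity: float = 10.0
    baseline_sd: float = 1.0
    rng_seed: int = 0

    @property
    def window_span(self) -> int:
        return self.window_upstream + self.window_downstream

    @property
    def probes_per_gene(self) -> int:
        return self.window_span // self.probe_spacing

    def scale_shift(self, replicate_index: int) -> float:
        if self.array_scale_shifts is None:
            # small alternating between-array offsets
            pattern = (0.0, 0.3, -0.2, 0.15, -0.1, 0.25)
            return pattern[replicate_index % len(pattern)]
        return self.array_scale_shifts[replicate_index]

    def mark_by_name(self, name: str) -> MarkSpec:
        for m in self.marks:
            if m.name == name:
                return m
        raise KeyError(f"mark {name!r} not in configuration "
                       f"(known: {[m.name for m in self.marks]})")

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be positive")
        if self.window_span < 4 * self.probe_spacing:
            raise ValueError(
                "tiled window shorter than 4 probe spacings cannot contain "
                "a minimal peak")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0 or self.dye_bias_amplitude < 0:
            raise ValueError("noise_sd and dye_bias_amplitude must be >= 0")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if len({m.name for m in self.marks}) != len(self.marks):
            raise ValueError("mark names must be unique")
        if (self.array_scale_shifts is not None
                and len(self.array_scale_shifts) < self.n_replicates):
            raise ValueError("need one scale shift per replicate")


@dataclass
class PromoterModel:
    """Promoter layout, probe layout, expression and simulation ground truth.

    ``genes``:      gene_id, chromosome, tss (0-based bp), strand.
    ``probes``:     probe_id, chromosome, position (0-based probe start),
                    gc_fraction, baseline_a (probe-intrinsic log2 intensity).
    ``expression``: one column per cell type, indexed by gene_id.
    ``truth``:      per cell type, a boolean gene x mark DataFrame -- which
                    genes truly carry which marks (never read by the pipeline).
    """

    genes: pd.DataFrame
    probes: pd.DataFrame
    expression: pd.DataFrame
    truth: dict[str, pd.DataFrame]
    config: SimulationConfig

    def truth_marks(self, gene_id: str, cell_type: str | None = None) -> set[str]:
        ct = cell_type or self.config.cell_types[0]
        row = self.truth[ct].loc[gene_id]
        return set(row.index[row])

    def window(self, gene_id: str) -> tuple[str, int, int]:
        """Genomic (chrom, start, end) of the gene's tiled window."""
        g = self.genes.set_index("gene_id").loc[gene_id]
        cfg = self.config
        if g["strand"] == "+":
            return g["chromosome"], g["tss"] - cfg.window_upstream, g["tss"] + cfg.window_downstream
        return g["chromosome"], g["tss"] - cfg.window_downstream, g["tss"] + cfg.window_upstream


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.rng_seed, spawn_key=tuple(key)))


def build_promoter_model(config: SimulationConfig) -> PromoterModel:
    """Lay out promoters and probes, draw ground truth and expression.

    Genes are placed sequentially along ``n_chromosomes`` chromosomes with
    random inter-window gaps (non-overlapping) unless ``overlap_fraction``
    asks for overlapping tiled regions, which exercises unique peak-to-TSS
    assignment downstream.  Probes tile each window at ``probe_spacing`` and
    are deduplicated by genomic position where windows overlap.
    """
    config.validate()
    cfg = config
    rng = _rng(cfg, 0)

    n_digits = max(4, len(str(cfg.n_genes)))
    rows = []
    cursors = {f"chr{c + 1}": 0 for c in range(cfg.n_chromosomes)}
    chrom_names = list(cursors)
    prev: dict[str, tuple[int, int]] = {}  # chrom -> previous window (start, end)
    for i in range(cfg.n_genes):
        chrom = chrom_names[i % cfg.n_chromosomes]
        strand = "+" if rng.random() < 0.5 else "-"
        up = cfg.window_upstream if strand == "+" else cfg.window_downstream
        overlap = (chrom in prev) and (rng.random() < cfg.overlap_fraction)
        if overlap:
            pstart, pend = prev[chrom]
            wstart = pstart + cfg.window_span // 2  # share ~half the tiled span
        else:
            gap = int(rng.integers(1000, 3001))
            wstart = cursors[chrom] + gap
        tss = wstart + up
        wend = wstart + cfg.window_span
        rows.append((f"gene{i:0{n_digits}d}", chrom, tss, strand, wstart, wend))
        cursors[chrom] = max(cursors[chrom], wend)
        prev[chrom] = (wstart, wend)

    genes = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "tss", "strand", "_wstart", "_wend"])

    # genome-wide probe layout: union of tiled windows, deduplicated
    probe_frames = []
    for chrom, sub in genes.groupby("chromosome", sort=True):
        positions = np.unique(np.concatenate([
            np.arange(ws, we, cfg.probe_spacing)
            for ws, we in zip(sub["_wstart"], sub["_wend"])]))
        probe_frames.append(pd.DataFrame({
            "chromosome": chrom, "position": positions.astype(np.int64)}))
    probes = pd.concat(probe_frames, ignore_index=True)
    probes = probes.sort_values(["chromosome", "position"], kind="mergesort",
                                ignore_index=True)
    probes.insert(0, "probe_id", [
        f"{c}P{p:09d}" for c, p in zip(probes["chromosome"], probes["position"])])
    # probe-intrinsic baseline intensity (hybridization affinity) and GC,
    # correlated so that GC bins approximate A bins
    base = rng.normal(cfg.baseline_log2_intensity, cfg.baseline_sd, len(probes))
    probes["baseline_a"] = base
    gc = 0.5 + 0.1 * (base - cfg.baseline_log2_intensity) / max(cfg.baseline_sd, 1e-9)
    probes["gc_fraction"] = np.clip(gc + rng.normal(0, 0.005, len(probes)), 0.05, 0.95)

    # ground truth marks per cell type; extra cell types re-flip marks so that
    # expression fold changes between cell types track chromatin changes
    mark_names = [m.name for m in cfg.marks]
    fracs = np.array([m.fraction_enriched for m in cfg.marks])
    truth: dict[str, pd.DataFrame] = {}
    base_truth = rng.random((cfg.n_genes, len(mark_names))) < fracs
    truth[cfg.cell_types[0]] = pd.DataFrame(
        base_truth, index=genes["gene_id"], columns=mark_names)
    for k, ct in enumerate(cfg.cell_types[1:], start=1):
        flip = _rng(cfg, 1, k).random(base_truth.shape) < cfg.truth_flip_prob
        resample = _rng(cfg, 2, k).random(base_truth.shape) < fracs
        truth[ct] = pd.DataFrame(
            np.where(flip, resample, base_truth),
            index=genes["gene_id"], columns=mark_names)

    # expression: shared log-normal base per gene + additive log2 mark effects
    polarity_sign = np.array(
        [1.0 if m.polarity == ACTIVATING else -1.0 for m in cfg.marks])
    log2_base = rng.normal(5.0, 1.0, cfg.n_genes)
    expr = {}
    for ct in cfg.cell_types:
        shift = truth[ct].to_numpy() @ (polarity_sign * cfg.expression_effect)
        expr[ct] = np.exp2(log2_base + shift)
    expression = pd.DataFrame(expr, index=genes["gene_id"])

    genes = genes.drop(columns=["_wstart", "_wend"])
    return PromoterModel(genes=genes, probes=probes, expression=expression,
                         truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# spatial enrichment profiles (generator-private shapes; only the qualitative
# contracts -- TSS trough, gene-body maxima, broad plateau -- are public)

def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _profile(kind: str, offset: np.ndarray) -> np.ndarray:
    """Unit-peak profile as a function of strand-oriented bp offset from TSS."""
    if kind == "tss_double_peak":
        v = _gauss(offset, -450.0, 220.0) + _gauss(offset, 450.0, 220.0)
    elif kind == "gene_body":
        v = 0.8 * _gauss(offset, 1000.0, 500.0) + _gauss(offset, 2000.0, 600.0)
    elif kind == "broad_domain":
        centers = np.arange(-4000.0, 2000.1, 700.0)
        v = _gauss(offset[:, None], centers[None, :], 600.0).sum(axis=1)
    else:  # pragma: no cover - guarded by MarkSpec
        raise ValueError(f"unknown profile {kind!r}")
    return v / v.max() if v.max() > 0 else v


def true_ratio_track(model: PromoterModel, mark_name: str,
                     cell_type: str | None = None) -> np.ndarray:
    """Noise-free true log2 ChIP/input ratio at every probe, in probe order."""
    cfg = model.config
    mark = cfg.mark_by_name(mark_name)
    ct = cell_type or cfg.cell_types[0]
    if ct not in model.truth:
        raise KeyError(f"cell type {ct!r} not simulated")
    truth = model.truth[ct][mark.name]
    m = np.zeros(len(model.probes))
    pos_by_chrom = {c: sub for c, sub in model.probes.groupby("chromosome")}
    for gene_id, chrom, tss, strand in model.genes[
            ["gene_id", "chromosome", "tss", "strand"]].itertuples(index=False):
        if not truth[gene_id]:
            continue
        sub = pos_by_chrom[chrom]
        _, wstart, wend = model.window(gene_id)
        inside = sub[(sub["position"] >= wstart) & (sub["position"] < wend)]
        offset = inside["position"].to_numpy() - tss
        if strand == "-":
            offset = -offset
        contrib = mark.effect_size * _profile(mark.profile, offset.astype(float))
        m[inside.index] = np.maximum(m[inside.index], contrib)
    return m


def simulate_array(model: PromoterModel, mark: str, replicate_index: int,
                   config: SimulationConfig | None = None,
                   cell_type: str | None = None) -> pd.DataFrame:
    """Simulate one two-color array: probe table with R and G intensities.

    The observed log2 ratio is the true ratio plus a quadratic-in-A dye-bias
    curve (amplitude ``dye_bias_amplitude``), the replicate's scale shift and
    Gaussian log2 noise; channels are back-computed as
    R = 2^(A + M/2), G = 2^(A - M/2) so that with all distortions at zero
    log2(R/G) recovers the true ratio exactly.
    """
    cfg = config or model.config
    mark_spec = cfg.mark_by_name(mark)  # raises for unknown mark
    ct = cell_type or cfg.cell_types[0]
    ct_idx = cfg.cell_types.index(ct)
    mark_idx = [m.name for m in cfg.marks].index(mark_spec.name)
    if replicate_index < 0 or replicate_index >= cfg.n_replicates:
        raise ValueError(f"replicate_index {replicate_index} out of range")

    rng = _rng(cfg, 3, ct_idx, mark_idx, replicate_index)
    a = model.probes["baseline_a"].to_numpy()
    m_true = true_ratio_track(model, mark, ct)

    z = (a - a.mean()) / max(a.std(), 1e-12)
    bias = cfg.dye_bias_amplitude * (z ** 2 - 1.0)  # banana-shaped, mean ~0
    m_obs = (m_true + bias + cfg.scale_shift(replicate_index)
             + rng.normal(0.0, cfg.noise_sd, len(a)))

    out = model.probes[["probe_id", "chromosome", "position", "gc_fraction"]].copy()
    out["signal_r"] = np.exp2(a + m_obs / 2.0)
    out["signal_g"] = np.exp2(a - m_obs / 2.0)
    if not (np.all(out["signal_r"] > 0) and np.all(out["signal_g"] > 0)):
        raise AssertionError("generator produced nonpositive intensities")
    return out


def simulate_study(config: SimulationConfig) -> tuple[
        PromoterModel, dict[tuple[str, str, int], pd.DataFrame]]:
    """Build a model and simulate every (cell type, mark, replicate) array."""
    model = build_promoter_model(config)
    arrays = {
        (ct, mark.name, rep): simulate_array(model, mark.name, rep, config, ct)
        for ct in config.cell_types
        for mark in config.marks
        for rep in range(config.n_replicates)
    }
    return model, arrays


# ---------------------------------------------------------------------------
# qPCR fixture generator

def true_percent_input(model: PromoterModel, mark: str, gene_id: str,
                       offset_bp: float, input_fraction: float = 0.1,
                       cell_type: str | None = None) -> float:
    """Ground-truth percent input at a strand-oriented offset from a TSS.

    Background (no enrichment) sits at ``100 * input_fraction`` percent; a
    truly enriched gene multiplies that by 2^(profile x effect size).
    """
    cfg = model.config
    spec = cfg.mark_by_name(mark)
    m = 0.0
    if spec.name in model.truth_marks(gene_id, cell_type):
        m = spec.effect_size * float(
            _profile(spec.profile, np.asarray([float(offset_bp)]))[0])
    return 100.0 * input_fraction * float(np.exp2(m))


def simulate_qpcr(model: PromoterModel | None, mark: str | None,
                  regions: dict[str, float], input_fraction: float = 0.1,
                  config: SimulationConfig | None = None, *,
                  n_replicates: int = 3, jitter_sd: float = 0.0,
                  base_ct: float = 26.0, seed: int = 0) -> pd.DataFrame:
    """Generate a Ct table whose true percent input equals ``regions`` values.

    ``regions`` maps region_id -> true percent-input enrichment (use
    :func:`true_percent_input` to derive these from the model).  With zero
    jitter the percent-input formula recovers the configured enrichment
    exactly: Ct(chip) = Ct(input) - log2(1/input_fraction) - log2(pct/100).
    """
    if not 0 < input_fraction < 1:
        raise ValueError("input_fraction must be in (0, 1)")
    if model is not None and mark is not None:
        (config or model.config).mark_by_name(mark)  # validate mark name
    rng = np.random.default_rng(seed)
    sample = mark or "chip"
    rows = []
    for region_id, pct in regions.items():
        if pct <= 0:
            raise ValueError(f"region {region_id!r}: percent input must be > 0")
        ct_input = base_ct
        ct_chip = ct_input - np.log2(1.0 / input_fraction) - np.log2(pct / 100.0)
        for rep in range(1, n_replicates + 1):
            rows.append((sample, region_id, "chip",
                         ct_chip + rng.normal(0.0, jitter_sd), rep))
            rows.append((sample, region_id, "input",
                         ct_input + rng.normal(0.0, jitter_sd), rep))
    return pd.DataFrame(
        rows, columns=["sample_id", "region_id", "role", "ct", "replicate"])


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["marks"] = [dataclasses.asdict(m) for m in config.marks]
    d["cell_types"] = list(config.cell_types)
    if config.array_scale_shifts is not None:
        d["array_scale_shifts"] = list(config.array_scale_shifts)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "marks" in d:
        d["marks"] = [MarkSpec(**m) for m in d["marks"]]
    if "cell_types" in d:
        d["cell_types"] = tuple(d["cell_types"])
    if d.get("array_scale_shifts") is not None:
        d["array_scale_shifts"] = tuple(d["array_scale_shifts"])
    return SimulationConfig(**d)
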