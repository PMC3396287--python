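"""Sliding-window peak calling with permutation false-discovery rates.

A region is called enriched when at least ``min_probes`` adjacent probes
(consecutive on the array layout, inter-probe gap bounded by a multiple of
the probe spacing) exceed a log2-ratio cutoff and fit inside a sliding
window of ``window_bp``.  Cutoffs sweep from ``cutoff_high_pct`` down to
``cutoff_low_pct`` percent of a *theoretical maximum enrichment value*
(default mean(M) + 6 sd(M)); a peak's score is the highest cutoff percentage
at which it is still detected, stored alongside the corresponding log2
threshold.

FDR is estimated by permuting the probe ratio data (within chromosomes by
default, which preserves per-chromosome probe counts and, because permuting
is distribution-preserving, the theoretical maximum), re-running the full
cutoff sweep, and comparing permuted to observed peak counts at each score
level.  Peaks are tiered: strict (FDR <= 0.05) peaks drive present/absent
promoter calls; relaxed (0.05 < FDR <= 0.2) peaks serve quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .normalize import RatioTrack

__all__ = [
    "PeakCallerConfig",
    "Peak",
    "PeakSet",
    "theoretical_max",
    "call_peaks_at_cutoff",
    "call_peaks",
    "permutation_fdr",
    "merge_fragmented_peaks",
]

STRICT_FDR = 0.05
RELAXED_FDR = 0.20


@dataclass(frozen=True)
class PeakCallerConfig:
    window_bp: int = 500
    min_probes: int = 4
    cutoff_high_pct: float = 90.0
    cutoff_low_pct: float = 15.0
    cutoff_step_pct: float = 5.0
    theoretical_max_rule: str = "mean_plus_6sd"
    n_permutations: int = 20
    permutation_scope: str = "within_chromosome"  # or genome_wide
    max_gap_factor: float = 2.0  # gaps > factor * spacing break adjacency
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff_low_pct >= self.cutoff_high_pct:
            raise ValueError("cutoff_low_pct must be < cutoff_high_pct")
        if self.min_probes < 1 or self.window_bp <= 0:
            raise ValueError("min_probes >= 1 and window_bp > 0 required")
        if self.cutoff_step_pct <= 0:
            raise ValueError("cutoff_step_pct must be positive")
        if self.permutation_scope not in ("within_chromosome", "genome_wide"):
            raise ValueError(f"unknown permutation scope "
                             f"{self.permutation_scope!r}")

    @property
    def cutoff_levels(self) -> np.ndarray:
        """Cutoff percentages swept, highest first (default 90, 85, ..., 15)."""
        return np.arange(self.cutoff_high_pct,
                         self.cutoff_low_pct - 1e-9, -self.cutoff_step_pct)


@dataclass
class Peak:
    chromosome: str
    start: int  # 0-based, half-open
    end: int
    n_probes: int
    score_pct: float  # highest cutoff (% of theoretical max) still detected
    score_log2: float  # the corresponding log2-ratio threshold
    mean_m: float
    fdr: float = 1.0
    tier: str = "discarded"  # strict | relaxed | discarded
    mark: str = ""
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("peak end must exceed start")

    @property
    def bound_area(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)
    mark: str = ""
    cell_type: str = ""
    theoretical_max: float = float("nan")

    def __post_init__(self) -> None:
        self.peaks.sort(key=lambda p: (p.chromosome, p.start))
        prev_end: dict[str, int] = {}
        for p in self.peaks:
            if p.start < prev_end.get(p.chromosome, -1):
                raise ValueError("peaks overlap within one track")
            prev_end[p.chromosome] = p.end

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def tier(self, tier: str) -> list[Peak]:
        return [p for p in self.peaks if p.tier == tier]

    @property
    def strict(self) -> list[Peak]:
        return self.tier("strict")

    def total_bound_bp(self, tier: str | None = "strict") -> int:
        peaks = self.peaks if tier is None else self.tier(tier)
        return sum(p.bound_area for p in peaks)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "chromosome": p.chromosome, "start": p.start, "end": p.end,
            "n_probes": p.n_probes, "score_pct": p.score_pct,
            "score_log2": p.score_log2, "mean_m": p.mean_m,
            "bound_area": p.bound_area, "fdr": p.fdr, "tier": p.tier,
            "mark": p.mark, "cell_type": p.cell_type,
        } for p in self.peaks])


def theoretical_max(track: RatioTrack, rule: str = "mean_plus_6sd") -> float:
    """Ceiling against which detection cutoffs are expressed.

    ``mean_plus_6sd``: mean(M) + 6 sd(M) -- a robust proxy for the strongest
    enrichment the array could register.  ``max_observed``: max(M).
    """
    if track.state != "averaged":
        raise ValueError("peak calling expects a replicate-averaged track")
    m = track.m
    if len(m) < 10:
        raise ValueError("need at least 10 probes to estimate the "
                         "theoretical maximum")
    if rule == "mean_plus_6sd":
        return float(m.mean() + 6.0 * m.std())
    if rule == "max_observed":
        return float(m.max())
    raise ValueError(f"unknown theoretical-max rule {rule!r}")


def _infer_spacing(pos: np.ndarray) -> float:
    gaps = np.diff(pos)
    gaps = gaps[gaps > 0]
    return float(np.median(gaps)) if len(gaps) else 100.0


def _regions_one_chromosome(pos: np.ndarray, m: np.ndarray, cutoff: float,
                            config: PeakCallerConfig, spacing: float
                            ) -> list[tuple[int, int, int, float]]:
    """Regions (start, end, n_probes, mean_m) on one sorted chromosome.

    Semantics: a 500 bp window is *hit* when it contains >= min_probes
    adjacent above-cutoff probes; overlapping hit windows are merged and the
    region runs between the outermost above-cutoff probes covered by the
    merged windows (end = last probe start + probe spacing).
    """
    if np.any(np.diff(pos) < 0):
        raise ValueError("track positions are not sorted")
    above = m > cutoff
    if not above.any():
        return []
    max_gap = config.max_gap_factor * spacing
    w = config.window_bp
    k = config.min_probes
    idx = np.flatnonzero(above)
    # adjacency runs: consecutive above-cutoff probes with bounded gaps
    breaks = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(pos[idx]) > max_gap))
    runs = np.split(idx, breaks + 1)
    # a window placed at w0 is hit when it holds >= k adjacent above-cutoff
    # probes; the union of hit-window extents for a qualifying k-tuple
    # starting at run offset j is the open interval
    # (p[j+k-1] - window, p[j] + window)
    intervals: list[tuple[float, float]] = []
    for run in runs:
        if len(run) < k:
            continue
        p = pos[run]
        span = p[k - 1:] - p[: len(p) - k + 1]
        for j in np.flatnonzero(span < w):
            intervals.append((p[j + k - 1] - w, p[j] + w))
    if not intervals:
        return []
    intervals.sort()
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    # region = outermost above-cutoff probes inside each merged hit span
    apos = pos[idx]
    regions: list[tuple[int, int, int, float]] = []
    for lo, hi in merged:
        sel = idx[(apos > lo) & (apos < hi)]
        if len(sel) == 0:
            continue
        start = int(pos[sel[0]])
        end = int(pos[sel[-1]] + spacing)
        if regions and start < regions[-1][1]:  # defensive overlap merge
            pstart, _, pn, pm = regions[-1]
            n = pn + len(sel)
            regions[-1] = (pstart, end, n,
                           (pm * pn + float(m[sel].sum())) / n)
        else:
            regions.append((start, end, len(sel), float(m[sel].mean())))
    return regions


def call_peaks_at_cutoff(track: RatioTrack, cutoff: float,
                         config: PeakCallerConfig | None = None
                         ) -> pd.DataFrame:
    """Candidate enriched regions at a single log2-ratio cutoff."""
    config = config or PeakCallerConfig()
    rows = []
    for chrom, sub in track.probes.groupby("chromosome", sort=True):
        pos = sub["position"].to_numpy(dtype=float)
        m = sub["m"].to_numpy(dtype=float)
        spacing = _infer_spacing(pos)
        for start, end, n, mean_m in _regions_one_chromosome(
                pos, m, cutoff, config, spacing):
            rows.append((chrom, start, end, n, mean_m))
    return pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "n_probes", "mean_m"])


def _sweep(track_by_chrom: list[tuple[str, np.ndarray, np.ndarray, float]],
           tmax: float, config: PeakCallerConfig) -> list[Peak]:
    """Full cutoff sweep; peaks scored by the highest detecting cutoff."""
    levels = config.cutoff_levels
    thresholds = levels / 100.0 * tmax
    peaks: list[Peak] = []
    for chrom, pos, m, spacing in track_by_chrom:
        base = _regions_one_chromosome(pos, m, thresholds[-1], config, spacing)
        if not base:
            continue
        # score: highest level whose regions intersect the base region
        higher = [
            _regions_one_chromosome(pos, m, thr, config, spacing)
            for thr in thresholds[:-1]
        ]
        for start, end, n, mean_m in base:
            score_pct = levels[-1]
            for lev, regs in zip(levels[:-1], higher):
                if any(s < end and e > start for s, e, _, _ in regs):
                    score_pct = lev
                    break
            peaks.append(Peak(
                chromosome=chrom, start=start, end=end, n_probes=n,
                score_pct=float(score_pct),
                score_log2=float(score_pct / 100.0 * tmax), mean_m=mean_m))
    return peaks


def _track_arrays(track: RatioTrack
                  ) -> list[tuple[str, np.ndarray, np.ndarray, float]]:
    out = []
    for chrom, sub in track.probes.groupby("chromosome", sort=True):
        pos = sub["position"].to_numpy(dtype=float)
        out.append((chrom, pos, sub["m"].to_numpy(dtype=float),
                    _infer_spacing(pos)))
    return out


def call_peaks(track: RatioTrack, config: PeakCallerConfig | None = None
               ) -> PeakSet:
    """Cutoff-sweep peak calling with permutation FDR and tier assignment."""
    config = config or PeakCallerConfig()
    if len(track.probes) == 0:
        return PeakSet([], mark=track.mark, cell_type=track.cell_type)
    tmax = theoretical_max(track, config.theoretical_max_rule)
    arrays = _track_arrays(track)
    peaks = _sweep(arrays, tmax, config)
    fdr_by_level = permutation_fdr(track, peaks, config, tmax=tmax,
                                   _arrays=arrays)
    for p in peaks:
        p.fdr = fdr_by_level.get(p.score_pct, 1.0)
        p.tier = ("strict" if p.fdr <= STRICT_FDR
                  else "relaxed" if p.fdr <= RELAXED_FDR
                  else "discarded")
        p.mark, p.cell_type = track.mark, track.cell_type
    return PeakSet(peaks, mark=track.mark, cell_type=track.cell_type,
                   theoretical_max=tmax)


def permutation_fdr(track: RatioTrack, observed_peaks: list[Peak],
                    config: PeakCallerConfig | None = None, *,
                    tmax: float | None = None, _arrays=None
                    ) -> dict[float, float]:
    """FDR per score level from cutoff sweeps over permuted ratio tracks.

    For each score level s: FDR(s) = (mean permuted count of peaks with
    score >= s) / (observed count with score >= s), clipped to [0, 1] and
    made monotone non-increasing in s.  Permutation preserves the M value
    distribution, so the theoretical maximum is unchanged by construction.
    """
    config = config or PeakCallerConfig()
    if not observed_peaks:
        return {}
    if tmax is None:
        tmax = theoretical_max(track, config.theoretical_max_rule)
    arrays = _arrays if _arrays is not None else _track_arrays(track)
    rng = np.random.default_rng(config.rng_seed)

    levels = config.cutoff_levels  # descending
    obs_scores = np.array([p.score_pct for p in observed_peaks])
    perm_scores: list[float] = []
    for _ in range(config.n_permutations):
        if config.permutation_scope == "within_chromosome":
            permuted = [(c, pos, rng.permutation(m), sp)
                        for c, pos, m, sp in arrays]
        else:
            all_m = np.concatenate([m for _, _, m, _ in arrays])
            shuffled = rng.permutation(all_m)
            permuted, start = [], 0
            for c, pos, m, sp in arrays:
                permuted.append((c, pos, shuffled[start:start + len(m)], sp))
                start += len(m)
        perm_scores.extend(p.score_pct for p in _sweep(permuted, tmax, config))
    perm_scores_arr = np.array(perm_scores)

    # ascending score levels with a running minimum: FDR(s) becomes monotone
    # non-increasing in s (a higher-scoring peak is never less significant)
    fdr_by_level: dict[float, float] = {}
    running = 1.0
    for lev in levels[::-1]:
        n_obs = int((obs_scores >= lev - 1e-9).sum())
        if n_obs > 0:
            n_perm = float((perm_scores_arr >= lev - 1e-9).sum()
                           ) / config.n_permutations
            running = min(running, min(max(n_perm / n_obs, 0.0), 1.0))
        fdr_by_level[float(lev)] = running
    return fdr_by_level


def merge_fragmented_peaks(peakset: PeakSet, gap_bp: int) -> PeakSet:
    """Diagnostic merge of nearby peaks (hybridization artifacts fragment
    single enriched regions); original peaks are retained by the caller.

    Peaks separated by <= ``gap_bp`` merge into one region whose bound area
    is the combined span, scored by the best (max) constituent score and
    most significant (min) FDR.
    """
    merged: list[Peak] = []
    for chrom in sorted({p.chromosome for p in peakset.peaks}):
        group: list[Peak] = []
        for p in [q for q in peakset.peaks if q.chromosome == chrom]:
            if group and p.start - group[-1].end <= gap_bp:
                group.append(p)
            else:
                if group:
                    merged.append(_merge_group(group))
                group = [p]
        if group:
            merged.append(_merge_group(group))
    return PeakSet(merged, mark=peakset.mark, cell_type=peakset.cell_type,
                   theoretical_max=peakset.theoretical_max)


def _merge_group(group: list[Peak]) -> Peak:
    if len(group) == 1:
        return replace(group[0])
    best = max(group, key=lambda p: p.score_pct)
    return Peak(
        chromosome=group[0].chromosome,
        start=min(p.start for p in group), end=max(p.end for p in group),
        n_probes=sum(p.n_probes for p in group),
        score_pct=best.score_pct, score_log2=best.score_log2,
        mean_m=float(np.mean([p.mean_m for p in group])),
        fdr=min(p.fdr for p in group),
        tier=min((p.tier for p in group),
                 key=lambda t: ("strict", "relaxed", "discarded").index(t)),
        mark=group[0].mark, cell_type=group[0].cell_type)
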