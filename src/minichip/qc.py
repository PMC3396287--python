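"""Quality-control battery for each stage of the array pipeline.

Every report is a pure function of its inputs and thresholds: MA-plot
flatness before/after within-array normalization, replicate concordance
(pairwise Pearson r and five-number summaries) around quantile
normalization, convergence of the total strict-tier bound base pairs across
replicates and normalization stages (an outlier replicate suggests a failed
ChIP), and the distribution of assigned peaks over TSS distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .annotate import PromoterCall
from .normalize import RatioTrack, a_decile_medians
from .peaks import PeakSet

__all__ = [
    "QcReport",
    "ma_plot_report",
    "replicate_concordance",
    "peak_convergence_report",
    "tss_distance_histogram",
]


@dataclass
class QcReport:
    stage: str
    metrics: dict[str, float | int | list] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    verdicts: dict[str, str] = field(default_factory=dict)  # pass|warn|fail

    @property
    def passed(self) -> bool:
        return all(v != "fail" for v in self.verdicts.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(self.stage, k, repr(self.metrics.get(k)),
                 self.thresholds.get(k, np.nan), v)
                for k, v in self.verdicts.items()]
        return pd.DataFrame(rows, columns=[
            "stage", "metric", "value", "threshold", "verdict"])


def ma_plot_report(track_before: RatioTrack, track_after: RatioTrack,
                   tolerance: float = 0.05, n_deciles: int = 10) -> QcReport:
    """MA flatness: median M per A-decile must sit near 0 after correction."""
    if not track_before.probes["probe_id"].equals(
            track_after.probes["probe_id"]):
        raise ValueError("before/after tracks must share the probe set")
    med_before = a_decile_medians(track_before, n_deciles)
    med_after = a_decile_medians(track_after, n_deciles)
    worst_before = float(np.abs(med_before).max())
    worst_after = float(np.abs(med_after).max())
    report = QcReport(stage="within_array")
    report.metrics = {
        "decile_medians_before": med_before.tolist(),
        "decile_medians_after": med_after.tolist(),
        "max_abs_decile_median_before": worst_before,
        "max_abs_decile_median_after": worst_after,
    }
    report.thresholds["max_abs_decile_median_after"] = tolerance
    report.verdicts["max_abs_decile_median_after"] = (
        "pass" if worst_after <= tolerance else "fail")
    # before-normalization flatness is informational, not a failure
    report.thresholds["max_abs_decile_median_before"] = tolerance
    report.verdicts["max_abs_decile_median_before"] = (
        "pass" if worst_before <= tolerance else "warn")
    return report


def _five_number(x: np.ndarray) -> list[float]:
    return np.percentile(x, [0, 25, 50, 75, 100]).tolist()


def replicate_concordance(tracks: list[RatioTrack], min_pearson: float = 0.4,
                          subsample: int = 10_000, seed: int = 0) -> QcReport:
    """Pairwise Pearson r on M plus box-and-whisker five-number summaries.

    With more than ``subsample`` probes the correlation uses a seeded random
    probe subsample (a sufficiently sized set; keeps large arrays cheap).
    After quantile normalization the five-number summaries of replicates
    must agree.
    """
    if len(tracks) < 2:
        raise ValueError("replicate concordance needs >= 2 tracks")
    n = len(tracks[0].probes)
    idx = np.arange(n)
    if n > subsample:
        idx = np.random.default_rng(seed).choice(n, subsample, replace=False)
    report = QcReport(stage=tracks[0].state)
    worst = 1.0
    for (i, a), (j, b) in combinations(enumerate(tracks), 2):
        r = float(np.corrcoef(a.m[idx], b.m[idx])[0, 1])
        report.metrics[f"pearson_r_{a.array_id}_{b.array_id}"] = r
        worst = min(worst, r)
    report.metrics["min_pairwise_pearson_r"] = worst
    report.thresholds["min_pairwise_pearson_r"] = min_pearson
    report.verdicts["min_pairwise_pearson_r"] = (
        "pass" if worst >= min_pearson else "fail")
    summaries = [_five_number(t.m) for t in tracks]
    report.metrics["five_number_summaries"] = summaries
    if tracks[0].state in ("quantile", "averaged"):
        agree = all(np.allclose(summaries[0], s) for s in summaries[1:])
        report.thresholds["five_number_summaries_identical"] = 1.0
        report.verdicts["five_number_summaries_identical"] = (
            "pass" if agree else "fail")
    return report


def peak_convergence_report(peaksets: dict[str, PeakSet],
                            outlier_factor: float = 2.0) -> QcReport:
    """Compare strict-tier bound bp across replicates/normalization stages.

    A replicate whose total strict-tier bound base pairs deviates from the
    median of its peers by more than ``outlier_factor`` (in either
    direction) is flagged -- the signature of a failed ChIP or array.
    """
    report = QcReport(stage="peaks")
    bound = {label: ps.total_bound_bp("strict") for label, ps in peaksets.items()}
    counts = {label: len(ps.tier("strict")) for label, ps in peaksets.items()}
    report.metrics["strict_bound_bp"] = bound
    report.metrics["strict_peak_count"] = counts
    median = float(np.median(list(bound.values())))
    outliers = []
    for label, bp in bound.items():
        if median > 0:
            deviant = bp > outlier_factor * median or bp < median / outlier_factor
        else:
            deviant = bp > 0
        if deviant:
            outliers.append(label)
    report.metrics["median_strict_bound_bp"] = median
    report.metrics["outlier_labels"] = outliers
    report.thresholds["n_outliers"] = 0.0
    report.verdicts["n_outliers"] = "pass" if not outliers else "fail"
    return report


def tss_distance_histogram(calls: dict[str, PromoterCall],
                           genes: pd.DataFrame, bin_bp: int = 500,
                           upstream_bp: int = 8200, downstream_bp: int = 3000
                           ) -> QcReport:
    """Histogram of assigned peak midpoints by signed distance from the TSS.

    Distances are strand-oriented (negative = upstream of transcription);
    bins of ``bin_bp`` span the tiled -8.2 kb ... +3 kb window.
    """
    gene_info = genes.set_index("gene_id")
    edges = np.arange(-upstream_bp, downstream_bp + bin_bp, bin_bp)
    distances = []
    for call in calls.values():
        if not call.peaks:
            continue
        tss = int(gene_info.loc[call.gene_id, "tss"])
        strand = gene_info.loc[call.gene_id, "strand"]
        for p in call.peaks:
            d = p.midpoint - tss
            distances.append(-d if strand == "-" else d)
    hist, _ = np.histogram(distances, bins=edges)
    report = QcReport(stage="annotation")
    report.metrics["bin_edges"] = edges.tolist()
    report.metrics["counts"] = hist.tolist()
    report.metrics["n_assigned_peaks"] = int(hist.sum())
    report.thresholds["n_assigned_peaks"] = 0.0
    report.verdicts["n_assigned_peaks"] = "pass"
    return report


def histogram_similarity(report_a: QcReport, report_b: QcReport) -> float:
    """Pearson correlation between two TSS-distance histograms."""
    a = np.asarray(report_a.metrics["counts"], dtype=float)
    b = np.asarray(report_b.metrics["counts"], dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float(np.allclose(a, b))
    return float(np.corrcoef(a, b)[0, 1])
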