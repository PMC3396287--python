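"""Unique peak-to-promoter assignment and present/absent promoter calls.

Promoter tiling windows (-8.2 kb / +3 kb around each TSS, strand-oriented)
overlap for nearby genes, so a naive overlap join would link one peak to
several promoters.  Each peak is instead assigned to exactly one gene: the
candidate whose TSS is closest to the peak midpoint among all genes whose
window contains that midpoint.  A promoter is called enriched for a mark
when at least one strict-tier (FDR <= 0.05) peak is assigned to it --
present/absent semantics; peak *number* is never used quantitatively
because hybridization artifacts fragment single enriched regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import Peak, PeakSet

__all__ = [
    "PromoterCall",
    "assign_peaks_to_tss",
    "call_promoter_state",
    "occupancy_summary",
    "promoter_window",
]

_TIER_RANK = {"strict": 0, "relaxed": 1, "discarded": 2}


@dataclass
class PromoterCall:
    gene_id: str
    mark: str
    cell_type: str
    peaks: list[Peak] = field(default_factory=list)
    enriched: bool = False
    total_bound_area: int = 0
    max_score: float = 0.0  # max log2 peak score among qualifying peaks
    n_peaks: int = 0


def promoter_window(tss: int, strand: str, upstream_bp: int = 8200,
                    downstream_bp: int = 3000) -> tuple[int, int]:
    """Genomic (start, end) of the strand-oriented promoter window."""
    if strand == "+":
        return tss - upstream_bp, tss + downstream_bp
    if strand == "-":
        return tss - downstream_bp, tss + upstream_bp
    raise ValueError(f"unknown strand {strand!r}")


def assign_peaks_to_tss(peakset: PeakSet, genes: pd.DataFrame,
                        upstream_bp: int = 8200, downstream_bp: int = 3000,
                        reference: str = "midpoint"
                        ) -> tuple[dict[str, PromoterCall], list[Peak]]:
    """Partition peaks among promoters by the most-proximate-TSS rule.

    ``genes`` columns: gene_id, chromosome, tss, strand.  A peak's candidate
    genes are those whose window contains the peak's reference point
    (midpoint by default; ``reference="any_overlap"`` admits any window
    overlapping the peak span); the peak goes to the candidate with the
    smallest |reference - tss|, distance ties resolved toward the gene
    earlier in coordinate order.  Returns per-gene calls (every gene gets
    one, possibly empty) and the list of unassigned peaks.
    """
    if len(genes) == 0:
        raise ValueError("empty promoter model")
    calls = {
        g.gene_id: PromoterCall(g.gene_id, peakset.mark, peakset.cell_type)
        for g in genes.itertuples()
    }
    by_chrom = {
        chrom: sub.sort_values(["tss", "gene_id"], kind="mergesort")
        for chrom, sub in genes.groupby("chromosome")
    }
    unassigned: list[Peak] = []
    for peak in peakset:
        sub = by_chrom.get(peak.chromosome)
        if sub is None:
            unassigned.append(peak)
            continue
        tss = sub["tss"].to_numpy()
        starts, ends = np.array([
            promoter_window(t, s, upstream_bp, downstream_bp)
            for t, s in zip(tss, sub["strand"])]).T
        mid = peak.midpoint
        if reference == "midpoint":
            inside = (starts <= mid) & (mid < ends)
        elif reference == "any_overlap":
            inside = (starts < peak.end) & (peak.start < ends)
        else:
            raise ValueError(f"unknown reference {reference!r}")
        if not inside.any():
            unassigned.append(peak)
            continue
        cand = np.flatnonzero(inside)
        dist = np.abs(mid - tss[cand])
        # ties: earliest in coordinate order (sub already sorted by tss)
        winner = sub.iloc[cand[np.argmin(dist)]]["gene_id"]
        calls[winner].peaks.append(peak)
    return calls, unassigned


def call_promoter_state(calls: dict[str, PromoterCall], tier: str = "strict"
                        ) -> dict[str, PromoterCall]:
    """Flag promoters enriched when >= 1 peak reaches the requested tier.

    ``tier="strict"`` counts FDR <= 0.05 peaks only; ``tier="relaxed"``
    additionally admits 0.05 < FDR <= 0.2 peaks.  Summary features
    (total bound area, max log2 score) are computed over qualifying peaks.
    """
    if tier not in ("strict", "relaxed"):
        raise ValueError(f"unknown tier {tier!r}")
    max_rank = _TIER_RANK[tier]
    for call in calls.values():
        qualifying = [p for p in call.peaks
                      if _TIER_RANK[p.tier] <= max_rank]
        call.n_peaks = len(qualifying)
        call.enriched = call.n_peaks >= 1
        call.total_bound_area = sum(p.bound_area for p in qualifying)
        call.max_score = max((p.score_log2 for p in qualifying), default=0.0)
    return calls


def occupancy_summary(calls_by_mark: dict[str, dict[str, PromoterCall]]
                      ) -> pd.DataFrame:
    """Fraction of genes enriched per mark (and cell type)."""
    rows = []
    for mark, calls in calls_by_mark.items():
        n = len(calls)
        enriched = sum(c.enriched for c in calls.values())
        cell_type = next(iter(calls.values())).cell_type if calls else ""
        rows.append((mark, cell_type, n, enriched,
                     enriched / n if n else 0.0))
    return pd.DataFrame(rows, columns=[
        "mark", "cell_type", "n_genes", "n_enriched", "fraction_enriched"])


def calls_to_dataframe(calls: dict[str, PromoterCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": c.gene_id, "mark": c.mark, "cell_type": c.cell_type,
        "enriched": c.enriched, "n_peaks": c.n_peaks,
        "total_bound_area": c.total_bound_area, "max_score": c.max_score,
    } for c in calls.values()])
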