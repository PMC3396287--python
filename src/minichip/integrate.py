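"""Chromatin/expression integration: the net-enrichment statistic.

Net enrichment condenses a promoter's chromatin state into one signed
number.  For every strict-tier peak the product bound_area x peak score
(log2 scale) is summed per mark; activating marks (H3K4me3, H3ac, H3K79me2,
PolII) contribute positively and silencing marks (H3K27me3, H3K9me3)
negatively, each polarity's sum divided by the number of marks of that
polarity present (>= 1 strict peak) at the promoter:

    net = S_act / max(1, n_act_present) - S_sil / max(1, n_sil_present)

Area x score is used rather than peak count because a single enriched
region is often fragmented into many small peaks by hybridization
artifacts: splitting a peak in two with the same total area x score leaves
net enrichment unchanged.  Downstream analyses relate net enrichment to
expression (genes sorted by expression, binned 100 at a time) and track the
change in per-mark peak scores across expression fold-change categories
between two cell types.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import PromoterCall

__all__ = [
    "DEFAULT_POLARITY",
    "DEFAULT_FOLD_CHANGE_THRESHOLDS",
    "net_enrichment",
    "correlate_net_with_expression",
    "fold_change_score_analysis",
]

DEFAULT_POLARITY: dict[str, str] = {
    "H3K4me3": "activating",
    "H3ac": "activating",
    "H3K79me2": "activating",
    "PolII": "activating",
    "H3K27me3": "silencing",
    "H3K9me3": "silencing",
}

DEFAULT_FOLD_CHANGE_THRESHOLDS = (
    1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0)


def _mark_sum(call: PromoterCall) -> float:
    """Sum of bound_area x log2 score over this mark's strict peaks."""
    return sum(p.bound_area * p.score_log2 for p in call.peaks
               if p.tier == "strict")


def net_enrichment(calls_by_mark: dict[str, dict[str, PromoterCall]],
                   polarity: dict[str, str] | None = None,
                   expression: pd.Series | None = None,
                   normalize_by_mark_count: bool = True) -> pd.DataFrame:
    """Per-gene net enrichment across marks.

    ``calls_by_mark`` maps mark name -> per-gene PromoterCall dict (all marks
    on the same gene set, strict tier already assigned).  Returns a DataFrame
    with gene_id, net_enrichment, the per-polarity sums and present-mark
    counts, and expression when provided.
    """
    polarity = polarity if polarity is not None else DEFAULT_POLARITY
    unknown = [m for m in calls_by_mark if m not in polarity]
    if unknown:
        raise ValueError(f"marks with unknown polarity: {sorted(unknown)}; "
                         f"provide a polarity mapping for them")
    gene_sets = [set(calls) for calls in calls_by_mark.values()]
    if any(g != gene_sets[0] for g in gene_sets[1:]):
        raise ValueError("all marks must be called on the same gene set")

    rows = []
    for gene_id in sorted(gene_sets[0]):
        s_act = s_sil = 0.0
        n_act = n_sil = 0
        for mark, calls in calls_by_mark.items():
            call = calls[gene_id]
            total = _mark_sum(call)
            present = any(p.tier == "strict" for p in call.peaks)
            if polarity[mark] == "activating":
                s_act += total
                n_act += present
            else:
                s_sil += total
                n_sil += present
        if normalize_by_mark_count:
            net = s_act / max(1, n_act) - s_sil / max(1, n_sil)
        else:
            net = s_act - s_sil
        rows.append((gene_id, net, s_act, s_sil, n_act, n_sil))
    out = pd.DataFrame(rows, columns=[
        "gene_id", "net_enrichment", "activating_sum", "silencing_sum",
        "n_activating_present", "n_silencing_present"])
    if expression is not None:
        out = out.merge(expression.rename("expression"), left_on="gene_id",
                        right_index=True, how="left")
    return out


def correlate_net_with_expression(records: pd.DataFrame, bin_size: int = 100
                                  ) -> tuple[pd.DataFrame, float]:
    """Bin genes by expression and relate bin means of net enrichment.

    Genes are sorted by expression and grouped into consecutive bins of
    ``bin_size`` (the last bin may be short and is flagged).  Returns the
    per-bin table (mean expression, mean net enrichment) and the Spearman
    rank correlation across bins.
    """
    if "expression" not in records.columns:
        raise ValueError("records must carry an 'expression' column")
    if len(records) < 2 * bin_size:
        raise ValueError(f"need at least {2 * bin_size} genes for binning")
    missing = records["expression"].isna()
    if missing.mean() > 0.10:
        warnings.warn(f"{missing.sum()} genes ({missing.mean():.0%}) lack "
                      f"expression and are excluded")
    recs = records[~missing].sort_values(
        "expression", kind="mergesort", ignore_index=True)
    bins = np.arange(len(recs)) // bin_size
    table = recs.groupby(bins).agg(
        n_genes=("gene_id", "size"),
        mean_expression=("expression", "mean"),
        mean_net_enrichment=("net_enrichment", "mean"),
    ).reset_index(names="bin")
    table["short_bin"] = table["n_genes"] < bin_size
    rho = stats.spearmanr(table["mean_expression"],
                          table["mean_net_enrichment"]).statistic
    return table, float(rho)


def _max_strict_score(call: PromoterCall) -> float:
    return max((p.score_log2 for p in call.peaks if p.tier == "strict"),
               default=0.0)


def fold_change_score_analysis(
        calls_a: dict[str, dict[str, PromoterCall]],
        calls_b: dict[str, dict[str, PromoterCall]],
        expression_a: pd.Series, expression_b: pd.Series,
        thresholds: tuple[float, ...] = DEFAULT_FOLD_CHANGE_THRESHOLDS,
        pseudocount: float = 1.0) -> pd.DataFrame:
    """Mean change in per-mark peak score across expression fold-change bands.

    For each fold-change threshold t and direction, genes with
    (expr_b + pc) / (expr_a + pc) >= t (up) or <= 1/t (down) are selected
    and, per mark, the mean difference in max strict-tier log2 peak score
    (condition b minus a; 0 where a mark has no strict peak) is reported.
    Empty categories are recorded with NaN, not raised.
    """
    marks = sorted(calls_a)
    if sorted(calls_b) != marks:
        raise ValueError("both conditions must be called for the same marks")
    genes = sorted(set(calls_a[marks[0]]) & set(expression_a.index)
                   & set(expression_b.index))
    fc = ((expression_b.loc[genes] + pseudocount)
          / (expression_a.loc[genes] + pseudocount)).to_numpy()
    delta = {
        mark: np.array([_max_strict_score(calls_b[mark][g])
                        - _max_strict_score(calls_a[mark][g])
                        for g in genes])
        for mark in marks
    }
    rows = []
    for direction in ("up", "down"):
        for t in thresholds:
            sel = fc >= t if direction == "up" else fc <= 1.0 / t
            for mark in marks:
                mean_d = float(delta[mark][sel].mean()) if sel.any() else np.nan
                rows.append((direction, t, mark, int(sel.sum()), mean_d))
    return pd.DataFrame(rows, columns=[
        "direction", "threshold", "mark", "n_genes", "mean_delta_score"])
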