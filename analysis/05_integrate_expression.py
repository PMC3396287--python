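#!/usr/bin/env python
"""Net enrichment vs expression, and fold-change score analysis.

Computes the signed per-gene net-enrichment statistic (area x score summed
over strict peaks, activating minus silencing, normalized by the number of
present marks of each polarity), bins genes by expression (100 per bin) and
reports the Spearman correlation of bin means; then contrasts the two cell
types across 12 expression fold-change categories per direction.
"""

from pathlib import Path

from minichip import io as mio
from minichip.annotate import assign_peaks_to_tss, call_promoter_state
from minichip.integrate import (correlate_net_with_expression,
                                fold_change_score_analysis, net_enrichment)
from minichip.simulate import default_marks

STUDY = Path(__file__).resolve().parents[1] / "scratch" / "study"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def _load_calls(genes, ct):
    from minichip.peaks import Peak, PeakSet
    out = {}
    for mark in [m.name for m in default_marks()]:
        df = mio.read_table(STUDY / "peaks" / f"{ct}_{mark}_peaks.tsv")
        ps = PeakSet([Peak(chromosome=r.chromosome, start=int(r.start),
                           end=int(r.end), n_probes=int(r.n_probes),
                           score_pct=float(r.score_pct),
                           score_log2=float(r.score_log2),
                           mean_m=float(r.mean_m), fdr=float(r.fdr),
                           tier=r.tier, mark=mark, cell_type=ct)
                      for r in df.itertuples()], mark=mark, cell_type=ct)
        calls, _ = assign_peaks_to_tss(ps, genes)
        out[mark] = call_promoter_state(calls)
    return out


def main() -> None:
    genes, expression = mio.read_promoter_table(STUDY / "promoters.tsv")
    calls = {ct: _load_calls(genes, ct) for ct in ("stem", "tcell")}
    for ct in ("stem", "tcell"):
        records = net_enrichment(calls[ct], expression=expression[ct])
        mio.write_table(records, STUDY / f"net_enrichment_{ct}.tsv",
                        "integrate")
        table, rho = correlate_net_with_expression(records, bin_size=100)
        table["spearman_rho"] = rho
        mio.write_table(table, STUDY / f"expression_bins_{ct}.tsv",
                        "integrate")
        mio.write_table(table, RESULTS / f"expression_bins_{ct}.tsv",
                        "integrate")
        print(f"{ct}: Spearman(bin mean net enrichment, bin mean "
              f"expression) = {rho:.3f} over {len(table)} bins of 100")
    fc = fold_change_score_analysis(calls["stem"], calls["tcell"],
                                    expression["stem"], expression["tcell"])
    mio.write_table(fc, STUDY / "fold_change_scores.tsv", "integrate")
    mio.write_table(fc, RESULTS / "fold_change_scores.tsv", "integrate")
    up = fc[(fc["direction"] == "up") & fc["mean_delta_score"].notna()]
    print("upregulated stem->tcell: mean activating-mark score change by "
          "fold-change threshold:")
    act = up[up["mark"].isin(["H3K4me3", "H3ac", "H3K79me2"])]
    print(act.groupby("threshold")["mean_delta_score"].mean().round(3)
          .to_string())


if __name__ == "__main__":
    main()
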