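"""Readers and writers for the pipeline's plain-text formats.

Probe files are a pair-file-like tab-separated dialect (one file per array)
with header columns PROBE_ID, CHROMOSOME, POSITION, SIGNAL_R, SIGNAL_G and
optional GC.  Coordinates are 0-based half-open internally and in BED
output; GFF output is 1-based inclusive.  Tables written by pipeline stages
carry '#'-prefixed provenance header lines (tool version, stage, config
hash) which all readers here skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .annotate import PromoterCall
from .normalize import RatioTrack
from .peaks import Peak, PeakSet

__version__ = "0.1.0"

PROBE_COLUMNS = {"PROBE_ID": "probe_id", "CHROMOSOME": "chromosome",
                 "POSITION": "position", "SIGNAL_R": "signal_r",
                 "SIGNAL_G": "signal_g", "GC": "gc_fraction"}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _provenance(stage: str, cfg_hash: str) -> str:
    return (f"# minichip {__version__}\n# stage: {stage}\n"
            f"# config: {cfg_hash}\n")


def write_table(df: pd.DataFrame, path: Path | str, stage: str,
                cfg_hash: str = "unconfigured") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(stage, cfg_hash))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: Path | str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# -- probe files ------------------------------------------------------------

def write_probe_file(signals: pd.DataFrame, path: Path | str) -> None:
    out = signals.rename(columns={v: k for k, v in PROBE_COLUMNS.items()})
    cols = ["PROBE_ID", "CHROMOSOME", "POSITION", "SIGNAL_R", "SIGNAL_G"]
    if "GC" in out.columns:
        cols.append("GC")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out[cols].to_csv(path, sep="\t", index=False)


def read_probe_file(path: Path | str) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", comment="#")
    missing = {"PROBE_ID", "CHROMOSOME", "POSITION", "SIGNAL_R",
               "SIGNAL_G"} - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing probe columns {sorted(missing)}")
    df = raw.rename(columns=PROBE_COLUMNS)
    return df.sort_values(["chromosome", "position"], kind="mergesort",
                          ignore_index=True)


# -- promoter model ---------------------------------------------------------

def write_promoter_table(genes: pd.DataFrame, expression: pd.DataFrame,
                         path: Path | str) -> None:
    out = genes.merge(expression, left_on="gene_id", right_index=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)


def read_promoter_table(path: Path | str
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", comment="#")
    gene_cols = ["gene_id", "chromosome", "tss", "strand"]
    expr_cols = [c for c in df.columns if c not in gene_cols]
    return df[gene_cols], df.set_index("gene_id")[expr_cols]


# -- ratio tracks -----------------------------------------------------------

def write_track(track: RatioTrack, path: Path | str,
                cfg_hash: str = "unconfigured") -> None:
    df = track.probes[["probe_id", "chromosome", "position", "m", "a"]].copy()
    df["state"] = track.state
    df["array_id"] = track.array_id
    df["mark"] = track.mark
    df["cell_type"] = track.cell_type
    write_table(df, path, stage=f"normalize:{track.state}", cfg_hash=cfg_hash)


def read_track(path: Path | str) -> RatioTrack:
    df = read_table(path)
    meta = df[["state", "array_id", "mark", "cell_type"]].iloc[0]
    probes = df[["probe_id", "chromosome", "position", "m", "a"]].copy()
    return RatioTrack(array_id=meta["array_id"], mark=meta["mark"],
                      cell_type=meta["cell_type"], probes=probes,
                      state=meta["state"])


def write_wiggle(track: RatioTrack, path: Path | str) -> None:
    """Wiggle-style export of M values for genome browsers."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track.array_id}"\n')
        for chrom, sub in track.probes.groupby("chromosome", sort=True):
            fh.write(f"variableStep chrom={chrom}\n")
            for pos, m in zip(sub["position"], sub["m"]):
                fh.write(f"{pos + 1}\t{m:.4f}\n")  # wiggle is 1-based


# -- peaks ------------------------------------------------------------------

def write_peaks_bed(peakset: PeakSet, path: Path | str) -> None:
    """BED6+3: chrom start end name score strand n_probes fdr tier."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for p in peakset:
            name = f"{p.mark or 'peak'}:{p.cell_type or 'NA'}"
            fh.write(f"{p.chromosome}\t{p.start}\t{p.end}\t{name}\t"
                     f"{p.score_pct:g}\t.\t{p.n_probes}\t{p.fdr:.4f}\t"
                     f"{p.tier}\n")


def read_peaks_bed(path: Path | str, mark: str = "", cell_type: str = ""
                   ) -> PeakSet:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else ":"
            score_pct = float(f[4]) if len(f) > 4 else 0.0
            n_probes = int(f[6]) if len(f) > 6 else 0
            fdr = float(f[7]) if len(f) > 7 else 1.0
            tier = f[8] if len(f) > 8 else "discarded"
            pk_mark, _, pk_ct = name.partition(":")
            peaks.append(Peak(
                chromosome=chrom, start=start, end=end, n_probes=n_probes,
                score_pct=score_pct, score_log2=0.0, mean_m=0.0, fdr=fdr,
                tier=tier, mark=mark or pk_mark,
                cell_type=cell_type or pk_ct))
    return PeakSet(peaks, mark=mark, cell_type=cell_type)


def write_assigned_gff(calls: dict[str, PromoterCall], path: Path | str
                       ) -> None:
    """GFF3 of peaks with their assigned gene; 1-based inclusive coords."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for call in calls.values():
            for p in call.peaks:
                attrs = (f"ID={p.mark}_{p.chromosome}_{p.start};"
                         f"gene_id={call.gene_id};tier={p.tier};"
                         f"fdr={p.fdr:.4f}")
                fh.write(f"{p.chromosome}\tminichip\tpeak\t{p.start + 1}\t"
                         f"{p.end}\t{p.score_pct:g}\t.\t.\t{attrs}\n")
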