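"""Two-stage normalization of two-color tiling arrays.

Stage 1, *within-array*: each array's probe ratios are put on the MA scale
(M = log2(R/G), A = (1/2) log2(R*G)) and the intensity-dependent dye bias is
removed, either by subtracting a lowess trend of M on A or by robust
standardization of M within probe-GC bins.  Correctness is judged by the MA
plot contract: after normalization the median M within every A-decile sits
near zero.

Stage 2, *between-array*: quantile normalization across replicate arrays of
one mark in one cell type (never across cell types -- biological differences
between cell types must survive), replacing each rank's values with the
cross-array mean at that rank, followed by per-probe averaging of replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "RatioTrack",
    "NORMALIZATION_STATES",
    "ma_transform",
    "within_array_normalize",
    "quantile_normalize",
    "average_replicates",
    "a_decile_medians",
]

NORMALIZATION_STATES = ("raw", "within_array", "quantile", "averaged")


@dataclass
class RatioTrack:
    """Per-array (or replicate-averaged) log2 ratio track.

    ``probes`` columns: probe_id, chromosome, position, m, a
    [, gc_fraction]; sorted by (chromosome, position), one row per probe.
    ``state`` only moves forward through ``NORMALIZATION_STATES``.
    """

    array_id: str
    mark: str
    cell_type: str
    probes: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in NORMALIZATION_STATES:
            raise ValueError(f"unknown normalization state {self.state!r}")
        required = {"probe_id", "chromosome", "position", "m", "a"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"track missing columns: {sorted(missing)}")
        if not np.isfinite(self.probes["m"]).all() or not np.isfinite(
                self.probes["a"]).all():
            raise ValueError("m and a values must be finite")
        key = self.probes[["chromosome", "position"]]
        if not key.equals(key.sort_values(["chromosome", "position"],
                                          kind="mergesort")):
            raise ValueError("probes must be sorted by (chromosome, position)")

    @property
    def m(self) -> np.ndarray:
        return self.probes["m"].to_numpy()

    @property
    def a(self) -> np.ndarray:
        return self.probes["a"].to_numpy()

    def advance(self, new_state: str, m: np.ndarray,
                a: np.ndarray | None = None, array_id: str | None = None
                ) -> "RatioTrack":
        """Copy with updated values in a forward normalization state."""
        order = NORMALIZATION_STATES
        if order.index(new_state) < order.index(self.state):
            raise ValueError(
                f"normalization state may only move forward "
                f"({self.state} -> {new_state})")
        probes = self.probes.copy()
        probes["m"] = np.asarray(m, dtype=float)
        if a is not None:
            probes["a"] = np.asarray(a, dtype=float)
        return replace(self, probes=probes, state=new_state,
                       array_id=array_id or self.array_id)


def ma_transform(signals: pd.DataFrame, array_id: str, mark: str,
                 cell_type: str, max_reject_fraction: float = 0.05
                 ) -> RatioTrack:
    """MA transform of a two-channel probe table into a raw RatioTrack.

    Probes with a nonpositive channel intensity (failed spots) are rejected
    with a logged count; more than ``max_reject_fraction`` rejected is a
    hard error.
    """
    required = {"probe_id", "chromosome", "position", "signal_r", "signal_g"}
    missing = required - set(signals.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    ok = (signals["signal_r"] > 0) & (signals["signal_g"] > 0)
    n_rejected = int((~ok).sum())
    if n_rejected:
        if n_rejected > max_reject_fraction * len(signals):
            raise ValueError(
                f"{array_id}: {n_rejected}/{len(signals)} probes with "
                f"nonpositive intensity exceeds the "
                f"{max_reject_fraction:.0%} rejection limit")
        warnings.warn(f"{array_id}: rejected {n_rejected} probes with "
                      f"nonpositive intensity")
    sig = signals[ok].sort_values(["chromosome", "position"],
                                  kind="mergesort", ignore_index=True)
    r = sig["signal_r"].to_numpy(dtype=float)
    g = sig["signal_g"].to_numpy(dtype=float)
    probes = sig[["probe_id", "chromosome", "position"]].copy()
    probes["m"] = np.log2(r / g)
    probes["a"] = 0.5 * np.log2(r * g)
    if "gc_fraction" in sig.columns:
        probes["gc_fraction"] = sig["gc_fraction"].to_numpy()
    return RatioTrack(array_id=array_id, mark=mark, cell_type=cell_type,
                      probes=probes, state="raw")


def a_decile_medians(track: RatioTrack, n_deciles: int = 10) -> np.ndarray:
    """Median M within each A-decile -- the MA-plot flatness diagnostic."""
    deciles = pd.qcut(track.probes["a"], n_deciles, labels=False,
                      duplicates="drop")
    return track.probes.groupby(deciles, observed=True)["m"].median().to_numpy()


def within_array_normalize(track: RatioTrack, method: str = "a_lowess",
                           lowess_frac: float = 0.3, n_gc_bins: int = 20
                           ) -> RatioTrack:
    """Remove intensity-dependent dye bias from one array.

    ``a_lowess``: subtract a local-regression trend of M on A.
    ``gc_bins``: robustly standardize M within probe-GC bins (subtract the
    bin median, divide by the bin MAD-scale, restore the global MAD-scale);
    requires a ``gc_fraction`` column.
    """
    if track.state != "raw":
        raise ValueError(f"within-array normalization expects a raw track, "
                         f"got state {track.state!r}")
    m, a = track.m, track.a
    if method == "a_lowess":
        # delta: interpolate over close-by A values (linear-time lowess)
        delta = 0.01 * (a.max() - a.min())
        trend = lowess(m, a, frac=lowess_frac, delta=delta,
                       return_sorted=False)
        new_m = m - trend
    elif method == "gc_bins":
        if "gc_fraction" not in track.probes.columns:
            raise ValueError("gc_bins normalization requires probe "
                             "gc_fraction annotations")
        gc = track.probes["gc_fraction"]
        bins = pd.qcut(gc, n_gc_bins, labels=False, duplicates="drop")
        df = pd.DataFrame({"m": m, "bin": bins})
        med = df.groupby("bin")["m"].transform("median").to_numpy()
        mad = df.groupby("bin")["m"].transform(
            lambda x: (x - x.median()).abs().median()).to_numpy()
        global_scale = float(np.median(np.abs(m - np.median(m)))) or 1.0
        mad = np.where(mad > 0, mad, global_scale)
        new_m = (m - med) / mad * global_scale
    else:
        raise ValueError(f"unknown within-array method {method!r}")
    return track.advance("within_array", new_m)


def _check_replicate_group(tracks: list[RatioTrack],
                           states: tuple[str, ...]) -> None:
    cell_types = {t.cell_type for t in tracks}
    if len(cell_types) > 1:
        raise ValueError(
            f"refusing to normalize across cell types {sorted(cell_types)}: "
            f"between-array quantile normalization is restricted to "
            f"replicates of one mark in one cell type, because it would "
            f"erase biological differences between cell types")
    if len({t.mark for t in tracks}) > 1:
        raise ValueError("tracks must all measure the same mark")
    ref = tracks[0].probes["probe_id"]
    for t in tracks[1:]:
        if not ref.equals(t.probes["probe_id"]):
            raise ValueError("tracks must share an identical probe set")
    for t in tracks:
        if t.state not in states:
            raise ValueError(f"expected state in {states!r}, "
                             f"got {t.state!r} for {t.array_id}")


def quantile_normalize(tracks: list[RatioTrack]) -> list[RatioTrack]:
    """Quantile-normalize replicate tracks: rank values get the rank's mean.

    After normalization the sorted M vectors of all replicates are identical;
    ties receive the mean of the quantile means across the tied ranks, which
    keeps the transform deterministic and permutation-invariant.  Preserves
    within-track rank order and the grand mean of M.
    """
    if not tracks:
        raise ValueError("no tracks to normalize")
    # re-application on already-quantile tracks is an allowed fixed point
    _check_replicate_group(tracks, ("within_array", "quantile"))
    X = np.column_stack([t.m for t in tracks])
    n = X.shape[0]
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = []
    for j, t in enumerate(tracks):
        ranks = rankdata(X[:, j], method="average")  # 1..n, ties averaged
        new_m = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
        out.append(t.advance("quantile", new_m))
    return out


def average_replicates(tracks: list[RatioTrack]) -> RatioTrack:
    """Per-probe arithmetic mean of replicate M (and A) values."""
    if not tracks:
        raise ValueError("no tracks to average")
    _check_replicate_group(tracks, ("quantile",))
    if len(tracks) == 1:
        warnings.warn("averaging a single track is a pass-through")
    m = np.mean([t.m for t in tracks], axis=0)
    a = np.mean([t.a for t in tracks], axis=0)
    array_id = "avg(" + "+".join(t.array_id for t in tracks) + ")"
    return tracks[0].advance("averaged", m, a=a, array_id=array_id)
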