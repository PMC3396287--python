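"""ChIP-qPCR percent-input quantification and primer qualification.

Enrichment at a genomic region is expressed as percent of total input
chromatin.  With a fraction ``f`` of the chromatin reserved as the input
control (1/10 volume by default), the input Ct is first corrected by the
log2 dilution factor DF = 1/f, and one PCR cycle corresponds to an exact
factor of two:

    % input = 100 * 2^[(Ct_input - log2(1/f)) - Ct_chip]

A ``formula="literal"`` switch evaluates the uncorrected expression
``100 * 2^(Ct_chip - Ct_input * DF)`` for comparison; it is not recommended
(multiplying a cycle number by the dilution factor inside the exponent
produces absurd magnitudes) and exists only to document the difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "PrimerQualification",
    "percent_input",
    "percent_input_table",
    "qualify_primers",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """A (possibly replicate-averaged) Ct observation for one region."""

    sample_id: str
    region_id: str
    role: str  # chip | input
    ct: float
    input_fraction: float = 0.1
    ct_sd: float = 0.0  # replicate SD on the Ct scale, propagated alongside

    def __post_init__(self) -> None:
        if self.role not in ("chip", "input"):
            raise ValueError(f"role must be 'chip' or 'input', got {self.role!r}")
        if not np.isfinite(self.ct):
            raise ValueError("ct must be finite")
        if not 0 < self.input_fraction < 1:
            raise ValueError("input_fraction must be in (0, 1)")


def percent_input(chip: QpcrMeasurement, input_: QpcrMeasurement,
                  formula: str = "dilution_corrected") -> float:
    """Percent of total input recovered in the ChIP, from paired Ct values.

    Strictly decreasing in the ChIP Ct and increasing in the input Ct; a
    one-cycle change is exactly a factor of two.
    """
    if chip.region_id != input_.region_id:
        raise ValueError(
            f"cannot pair measurements from different regions "
            f"({chip.region_id!r} vs {input_.region_id!r})")
    if chip.role != "chip" or input_.role != "input":
        raise ValueError("expected one 'chip' and one 'input' measurement")
    f = chip.input_fraction
    if formula == "dilution_corrected":
        ct_input_adjusted = input_.ct - np.log2(1.0 / f)
        return float(100.0 * 2.0 ** (ct_input_adjusted - chip.ct))
    if formula == "literal":
        # the expression as printed, with DF = 1/f multiplying the input Ct
        return float(100.0 * 2.0 ** (chip.ct - input_.ct * (1.0 / f)))
    raise ValueError(f"unknown formula {formula!r}")


def percent_input_table(ct_table: pd.DataFrame, input_fraction: float = 0.1,
                        formula: str = "dilution_corrected") -> pd.DataFrame:
    """Replicate-averaged percent input per (sample, region).

    ``ct_table`` columns: sample_id, region_id, role, ct[, replicate].
    Triplicate Ct values are averaged on the Ct scale before the formula;
    the replicate SD is carried through for error reporting.
    """
    required = {"sample_id", "region_id", "role", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    rows = []
    for (sample, region), sub in ct_table.groupby(
            ["sample_id", "region_id"], sort=True):
        by_role = {role: grp["ct"] for role, grp in sub.groupby("role")}
        if "chip" not in by_role or "input" not in by_role:
            raise ValueError(
                f"sample {sample!r} region {region!r}: need both chip and "
                f"input measurements")
        chip = QpcrMeasurement(sample, region, "chip",
                               float(by_role["chip"].mean()), input_fraction,
                               float(by_role["chip"].std(ddof=1))
                               if len(by_role["chip"]) > 1 else 0.0)
        inp = QpcrMeasurement(sample, region, "input",
                              float(by_role["input"].mean()), input_fraction,
                              float(by_role["input"].std(ddof=1))
                              if len(by_role["input"]) > 1 else 0.0)
        pct = percent_input(chip, inp, formula=formula)
        # first-order error propagation: d(log2 pct) = dCt in quadrature
        log2_sd = float(np.hypot(chip.ct_sd, inp.ct_sd))
        rows.append((sample, region, pct, chip.ct, inp.ct, log2_sd))
    return pd.DataFrame(rows, columns=[
        "sample_id", "region_id", "percent_input",
        "ct_chip_mean", "ct_input_mean", "log2_sd"])


@dataclass
class PrimerQualification:
    """Standard-curve data for one primer pair.

    ``ct_by_mass`` pairs (template mass in ng, mean Ct) spanning the
    qualification range (0.1-20 ng when complete); ``single_amplicon`` comes
    from melt-curve inspection.
    """

    region_id: str
    ct_by_mass: list[tuple[float, float]] = field(default_factory=list)
    single_amplicon: bool = True


def qualify_primers(q: PrimerQualification,
                    ct_spread_tolerance: float = 0.1) -> dict:
    """Pass/fail a primer pair on its standard curve and melt behaviour.

    A perfectly efficient primer pair loses exactly one Ct per doubling of
    template, i.e. slope(Ct vs log2 mass) = -1.  Efficiency is reported as
    2^(-1/slope) - 1 (1.0 for the perfect doubling).  Fails when the slope
    deviates from -1 beyond ``ct_spread_tolerance`` or when the melt curve
    shows more than one amplicon.
    """
    if len(q.ct_by_mass) < 3:
        raise ValueError(
            f"primer qualification for {q.region_id!r} needs >= 3 standard-"
            f"curve points, got {len(q.ct_by_mass)}")
    mass = np.array([m for m, _ in q.ct_by_mass], dtype=float)
    ct = np.array([c for _, c in q.ct_by_mass], dtype=float)
    if np.any(mass <= 0):
        raise ValueError("template masses must be positive")
    fit = stats.linregress(np.log2(mass), ct)
    slope = float(fit.slope)
    efficiency = float(2.0 ** (-1.0 / slope) - 1.0) if slope != 0 else np.inf
    slope_ok = abs(slope - (-1.0)) <= ct_spread_tolerance
    passed = bool(slope_ok and q.single_amplicon)
    return {
        "region_id": q.region_id,
        "slope": slope,
        "efficiency": efficiency,
        "single_amplicon": q.single_amplicon,
        "slope_within_tolerance": bool(slope_ok),
        "passed": passed,
    }
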