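"""qPCR and substrate-consumption quantification helpers.

Covers the small calculations used to quantify silencing: standard-curve fitting
with amplification-efficiency estimation, ddCt relative expression (target vs.
housekeeping reference, normalised to a control construct), vector copies per
chromosome from two standard curves, and relative substrate consumption per
chromosome.  The amplification base defaults to 2 (efficiency 1.0), with the
option to supply a fitted efficiency instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import QuantError


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    primer_pair: str
    ct: float
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise QuantError(f"Ct must be positive, got {self.ct}")


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares fit of Ct against log10(template copies)."""

    points: tuple[tuple[float, float], ...]  # (log10_copies, ct)
    slope: float
    intercept: float
    efficiency: float  # amplification factor = 1 + efficiency
    r_squared: float

    def copies(self, ct: float) -> float:
        """Back-calculate template copies from a Ct."""
        return float(10.0 ** ((ct - self.intercept) / self.slope))


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit a qPCR standard curve; efficiency = 10^(-1/slope) - 1.

    Requires >= 3 points spanning >= 2 log10 units of template.
    """
    if len(points) < 3:
        raise QuantError(f"standard curve needs >= 3 points, got {len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if x.max() - x.min() < 2.0:
        raise QuantError(
            f"standard curve x-range spans {x.max() - x.min():.2f} log10 units (< 2)"
        )
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise QuantError("standard curve slope must be negative (Ct falls with copies)")
    efficiency = float(10.0 ** (-1.0 / fit.slope) - 1.0)
    return StandardCurve(
        points=tuple((float(a), float(b)) for a, b in points),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=efficiency,
        r_squared=float(fit.rvalue**2),
    )


def relative_expression_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
    efficiency: float = 1.0,
) -> float:
    """Relative expression (percent of control) by the ddCt method.

    ddCt = (Ct_target,sample - Ct_ref,sample) - (Ct_target,control - Ct_ref,control);
    result = 100 * (1 + efficiency)^(-ddCt).
    """
    for ct in (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control):
        if ct <= 0:
            raise QuantError(f"Ct values must be positive, got {ct}")
    if not 0 < efficiency <= 1:
        raise QuantError(f"efficiency must be in (0, 1], got {efficiency}")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return float(100.0 * (1.0 + efficiency) ** (-ddct))


def copies_per_chromosome(
    viral_ct: float,
    chromosomal_ct: float,
    curve_viral: StandardCurve,
    curve_chrom: StandardCurve,
) -> float:
    """Vector copies per chromosome: ratio of back-calculated copies on one sample."""
    return curve_viral.copies(viral_ct) / curve_chrom.copies(chromosomal_ct)


def relative_consumption(
    sample_abs_t0: float,
    sample_abs_t2: float,
    blank_abs: float,
    sample_chromosomes: float,
    control_triplet: tuple[float, float, float],
) -> float:
    """Substrate consumption per chromosome, as percent of a control culture.

    consumption = ((abs_t0 - blank) - (abs_t2 - blank)) / chromosomes; the blank
    (medium absorbance without cells) cancels in the difference but is accepted
    for interface fidelity.
    """
    if sample_chromosomes <= 0:
        raise QuantError("sample chromosome count must be positive")
    c_t0, c_t2, c_chrom = control_triplet
    if c_chrom <= 0:
        raise QuantError("control chromosome count must be positive")
    sample = ((sample_abs_t0 - blank_abs) - (sample_abs_t2 - blank_abs)) / sample_chromosomes
    control = ((c_t0 - blank_abs) - (c_t2 - blank_abs)) / c_chrom
    if control <= 0:
        raise QuantError(f"control consumption must be positive, got {control}")
    return float(100.0 * sample / control)


def relative_expression_from_table(
    measurements: pd.DataFrame,
    *,
    target_pair: str,
    ref_pair: str,
    control_sample: str,
    efficiency: float = 1.0,
) -> pd.DataFrame:
    """ddCt relative expression from a replicate Ct table.

    *measurements* needs columns sample_id, primer_pair, ct (one row per
    replicate).  Replicate Cts are averaged (arithmetic mean) per sample and
    primer pair before the ddCt; replicate SDs are propagated in quadrature onto
    ddCt and mapped onto the percentage via the log-scale delta method.
    """
    required = {"sample_id", "primer_pair", "ct"}
    if not required <= set(measurements.columns):
        raise QuantError(f"table must have columns {sorted(required)}")
    g = measurements.groupby(["sample_id", "primer_pair"])["ct"].agg(["mean", "std", "count"])
    base = np.log(1.0 + efficiency)

    def _cell(sample: str, pair: str) -> tuple[float, float]:
        try:
            row = g.loc[(sample, pair)]
        except KeyError:
            raise QuantError(f"no measurements for sample {sample!r}, primer pair {pair!r}")
        sd = 0.0 if np.isnan(row["std"]) else float(row["std"])
        return float(row["mean"]), sd

    ct_tc, sd_tc = _cell(control_sample, target_pair)
    ct_rc, sd_rc = _cell(control_sample, ref_pair)
    rows = []
    for sample in measurements["sample_id"].unique():
        ct_ts, sd_ts = _cell(sample, target_pair)
        ct_rs, sd_rs = _cell(sample, ref_pair)
        percent = relative_expression_ddct(ct_ts, ct_rs, ct_tc, ct_rc, efficiency)
        sd_ddct = float(np.sqrt(sd_ts**2 + sd_rs**2 + sd_tc**2 + sd_rc**2))
        rows.append(
            {
                "sample_id": sample,
                "percent_of_control": percent,
                "ddct_sd": sd_ddct,
                "percent_sd": percent * base * sd_ddct,
            }
        )
    return pd.DataFrame(rows)
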