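"""Apparent diffusion coefficient (ADC) maps from multi-b-value DWI.

The mono-exponential signal model S(b) = S0 * exp(-b * ADC) gives, for a pair
of b-values (b0, b),

    ADC = -ln(S / S0) / (b - b0),

which is the two-point estimator. With three or more b-values the log-linear
mode fits an ordinary least-squares line to (b, ln S) per voxel and reports
minus the slope; on exactly two usable points it reduces to the two-point
formula. ADC is reported in 1e-3 mm^2/s (typical soft-tissue values fall in
0.5-3.0 on that scale); a flag emits SI mm^2/s instead.

Nonpositive signals make ln S undefined. Such voxels are flagged invalid and
excluded downstream rather than clamped to an epsilon, which would bias the
estimate low at exactly the voxels where the signal floor matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Grid, ImageVolume

__all__ = ["DwiSeries", "AdcVolume", "compute_adc_two_point", "compute_adc_loglinear"]

ADC_SCALE = 1.0e3  # mm^2/s -> 1e-3 mm^2/s


@dataclass
class DwiSeries:
    """An ordered diffusion-weighted series: ascending b-values, one volume each.

    ``reference_index`` designates which acquisition plays the role of
    (b0, S0); by default the lowest b-value, which need not be b = 0.
    """

    bvalues: np.ndarray
    volumes: list[ImageVolume]
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if self.bvalues.ndim != 1 or self.bvalues.size < 2:
            raise ValueError("a DWI series needs at least two b-values")
        if np.any(np.diff(self.bvalues) <= 0):
            raise ValueError(f"b-values must be strictly increasing, got {self.bvalues}")
        if np.any(self.bvalues < 0):
            raise ValueError("b-values must be nonnegative")
        if len(self.volumes) != self.bvalues.size:
            raise ValueError("need one volume per b-value")
        g = self.volumes[0].grid
        if any(v.grid != g for v in self.volumes[1:]):
            raise ValueError("all DWI volumes must share one grid")
        if not 0 <= self.reference_index < self.bvalues.size:
            raise ValueError("reference_index out of range")

    @property
    def grid(self) -> Grid:
        return self.volumes[0].grid

    def signal_stack(self) -> np.ndarray:
        """(n_b, *shape) stack of signal volumes."""
        return np.stack([v.data for v in self.volumes], axis=0)


@dataclass
class AdcVolume:
    """An ADC map plus a validity mask; ADC is finite wherever valid is True."""

    volume: ImageVolume
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.volume.data.shape:
            raise ValueError("validity mask shape mismatch")
        if not np.all(np.isfinite(self.volume.data[self.valid])):
            raise ValueError("ADC must be finite at every valid voxel")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def grid(self) -> Grid:
        return self.volume.grid


def compute_adc_two_point(
    series: DwiSeries, high_b_index: int = -1, si_units: bool = False
) -> AdcVolume:
    """Two-point ADC: -ln(S/S0)/(b - b0) between the reference and one high-b volume.

    Voxels where either signal is nonpositive are flagged invalid (set to 0 in
    the map, excluded by the mask).
    """
    high_b_index = range(series.bvalues.size)[high_b_index]
    if high_b_index == series.reference_index:
        raise ValueError("high_b_index must differ from the reference index")
    b0 = series.bvalues[series.reference_index]
    b = series.bvalues[high_b_index]
    if b <= b0:
        raise ValueError(f"high b-value ({b}) must exceed the reference b-value ({b0})")
    s0 = np.asarray(series.volumes[series.reference_index].data, dtype=float)
    s = np.asarray(series.volumes[high_b_index].data, dtype=float)

    valid = (s0 > 0) & (s > 0)
    adc = np.zeros_like(s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = -np.log(s[valid] / s0[valid]) / (b - b0)
    if not si_units:
        adc *= ADC_SCALE
    return AdcVolume(ImageVolume(adc, series.grid, modality="ADC"), valid)


def compute_adc_loglinear(series: DwiSeries, si_units: bool = False) -> AdcVolume:
    """Log-linear ADC: minus the OLS slope of ln S against b, per voxel.

    Uses every b-value with positive signal at that voxel; voxels with fewer
    than two positive signals are invalid. With exactly two usable points the
    OLS slope through two points equals the two-point formula.
    """
    sig = series.signal_stack().astype(float)
    pos = sig > 0
    n = pos.sum(axis=0)

    b = series.bvalues.reshape((-1,) + (1,) * (sig.ndim - 1))
    logs = np.where(pos, np.log(np.where(pos, sig, 1.0)), 0.0)
    bm = np.where(pos, b, 0.0)

    # closed-form OLS slope restricted to the usable points of each voxel
    sum_b = bm.sum(axis=0)
    sum_y = logs.sum(axis=0)
    sum_bb = (bm * bm).sum(axis=0)
    sum_by = (bm * logs).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * sum_bb - sum_b**2
        slope = np.where(denom > 0, (n * sum_by - sum_b * sum_y) / np.where(denom > 0, denom, 1.0), 0.0)

    valid = (n >= 2) & (denom > 0)
    adc = np.where(valid, -slope, 0.0)
    if not si_units:
        adc *= ADC_SCALE
    return AdcVolume(ImageVolume(adc, series.grid, modality="ADC"), valid)
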