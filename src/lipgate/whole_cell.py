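"""Whole-cell voltage-ramp analysis.

Ramp sweeps (−130 to +80 mV by convention) are resampled onto a uniform
potential grid, capacitance-normalised current densities are tracked at
fixed potentials (−90 and +70 mV by default) across repeated sweeps,
reversal potentials are read off by zero-crossing interpolation, and
bi-ionic divalent/monovalent permeability ratios are computed from the
reversal-potential shift with the standard GHK-derived relation

    P_X / P_M = [M]_i * xi * (1 + xi) / (4 [X]_o),   xi = exp(E_rev F / RT)

for a divalent external ion X against an internal monovalent M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants, ndimage

from .core import IVCurve, RampSweepSet

__all__ = [
    "ramp_to_iv",
    "current_density_timecourse",
    "reversal_potential",
    "bi_ionic_permeability",
    "erev_from_permeability",
    "CurrentDensityResult",
]

RAMP_RANGE = (-130.0, 80.0)  # mV, protocol convention
ROOM_TEMPERATURE = 295.0  # K
FARADAY = constants.physical_constants["Faraday constant"][0]  # C/mol


def ramp_to_iv(
    voltage: np.ndarray,
    current: np.ndarray,
    grid: np.ndarray | None = None,
    capacitance: float | None = None,
) -> IVCurve:
    """Resample one ramp sweep onto a uniform potential grid.

    Linear interpolation of the current against the (monotonic) command
    potential; the default grid spans the −130..+80 mV protocol range at
    1 mV. When a capacitance (pF) is given the curve is returned in
    pA/pF.
    """
    voltage = np.asarray(voltage, dtype=float)
    current = np.asarray(current, dtype=float)
    dv = np.diff(voltage)
    if np.all(dv < 0):
        voltage, current = voltage[::-1], current[::-1]
    elif not np.all(dv > 0):
        raise ValueError("ramp voltage must be monotonic")
    if grid is None:
        lo = max(RAMP_RANGE[0], voltage[0])
        hi = min(RAMP_RANGE[1], voltage[-1])
        grid = np.arange(lo, hi + 0.5, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid[0] < voltage[0] or grid[-1] > voltage[-1]:
        raise ValueError("grid extends beyond the recorded ramp span")
    iv = np.interp(grid, voltage, current)
    if capacitance is not None:
        if capacitance <= 0:
            raise ValueError("capacitance must be positive")
        return IVCurve(potentials=grid, currents=iv / capacitance, normalised=True)
    return IVCurve(potentials=grid, currents=iv)


@dataclass
class CurrentDensityResult:
    """Capacitance-normalised current density versus time at fixed potentials."""

    times: np.ndarray  # s, sweep timestamps
    potentials: tuple  # mV
    densities: np.ndarray  # (n_potentials, n_sweeps) pA/pF
    net: np.ndarray | None = None  # baseline-subtracted, same shape


def current_density_timecourse(
    sweeps: RampSweepSet,
    potentials: tuple = (-90.0, 70.0),
    baseline_window: tuple[float, float] | None = None,
) -> CurrentDensityResult:
    """Current density (pA/pF) at fixed ramp potentials across sweeps.

    Per sweep, the current at each requested potential is linearly
    interpolated on the ramp and divided by the cell capacitance. When a
    pre-stimulus ``baseline_window`` (start, end in s, on the sweep
    timestamps) is given, the mean over that window is subtracted to
    give the net density.
    """
    v = sweeps.voltage
    lo, hi = min(v[0], v[-1]), max(v[0], v[-1])
    for p in potentials:
        if p < lo or p > hi:
            raise ValueError(f"potential {p} mV outside the ramp span [{lo}, {hi}]")
    dens = np.empty((len(potentials), sweeps.n_sweeps))
    for s in range(sweeps.n_sweeps):
        iv = ramp_to_iv(v, sweeps.currents[s], grid=np.asarray(sorted(potentials), dtype=float))
        order = np.argsort(np.asarray(potentials))
        dens[order, s] = iv.currents / sweeps.capacitance
    net = None
    if baseline_window is not None:
        b0, b1 = baseline_window
        in_base = (sweeps.sweep_times >= b0) & (sweeps.sweep_times <= b1)
        if not np.any(in_base):
            raise ValueError("no sweep falls in the baseline window")
        net = dens - dens[:, in_base].mean(axis=1, keepdims=True)
    return CurrentDensityResult(
        times=sweeps.sweep_times, potentials=tuple(potentials), densities=dens, net=net
    )


def reversal_potential(iv: IVCurve, smooth_bins: float = 0.0) -> float:
    """Reversal potential (mV) as the unique zero crossing of the IV curve.

    The crossing is located by linear interpolation between the bracketing
    grid points; optional Gaussian smoothing (in grid bins) suppresses
    noise-induced spurious crossings. No crossing or multiple crossings
    raise, since the quantity is then ill-defined.
    """
    i = iv.currents
    if smooth_bins > 0:
        i = ndimage.gaussian_filter1d(i, smooth_bins)
    v = iv.potentials
    sign = np.sign(i)
    on_zero = np.flatnonzero(i == 0)
    crossings = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if on_zero.size == 1 and crossings.size == 0:
        return float(v[on_zero[0]])
    if crossings.size != 1 or on_zero.size > 1:
        raise ValueError(
            f"IV curve has {crossings.size + max(0, on_zero.size - 1)} zero crossings; "
            "expected exactly one"
        )
    k = crossings[0]
    return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))


def bi_ionic_permeability(
    erev_mV: float,
    monovalent_internal_mM: float,
    divalent_external_mM: float,
    temperature_K: float = ROOM_TEMPERATURE,
) -> float:
    """Divalent/monovalent permeability ratio from a bi-ionic reversal shift.

    P_X/P_M = [M]_i * xi * (1 + xi) / (4 [X]_o) with
    xi = exp(E_rev F / (R T)), for external divalent X (e.g. Ca2+)
    carried against internal monovalent M (e.g. Cs+). Activity
    coefficients and residual monovalent permeation are neglected.
    """
    if monovalent_internal_mM <= 0 or divalent_external_mM <= 0:
        raise ValueError("concentrations must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    xi = np.exp(erev_mV * 1e-3 * FARADAY / (constants.R * temperature_K))
    return float(monovalent_internal_mM * xi * (1.0 + xi) / (4.0 * divalent_external_mM))


def erev_from_permeability(
    ratio: float,
    monovalent_internal_mM: float,
    divalent_external_mM: float,
    temperature_K: float = ROOM_TEMPERATURE,
) -> float:
    """Invert the bi-ionic relation: reversal potential (mV) for a ratio.

    xi solves xi^2 + xi − 4 [X]_o ratio / [M]_i = 0, taking the positive
    root; E_rev = (RT/F) ln xi.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    c = 4.0 * divalent_external_mM * ratio / monovalent_internal_mM
    xi = (-1.0 + np.sqrt(1.0 + 4.0 * c)) / 2.0
    return float(np.log(xi) * constants.R * temperature_K / FARADAY * 1e3)
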