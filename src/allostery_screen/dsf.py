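"""Differential scanning fluorimetry (thermal shift) analysis.

A hydrophobic dye (e.g. SYPRO Orange) reports protein unfolding as a
sigmoidal rise in fluorescence with temperature; the transition midpoint
is the melting temperature Tm.  A ligand that binds the folded state
raises Tm, and the shift versus the vehicle (DMSO) reference, dTm, ranks
binders in a screen.  Dye curves decay after the fluorescence peak
(dye-protein aggregate dissociation), so fits use the pre-peak region
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MeltCurve",
    "MeltFit",
    "boltzmann",
    "truncate_post_peak",
    "fit_melt_curve",
    "tm_from_derivative",
    "compute_delta_tm",
    "call_stabilizers",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeltCurve:
    """Fluorescence vs temperature for one well."""

    well_id: str
    ligand_id: str  # "DMSO" marks the vehicle reference
    ligand_concentration: float  # molar
    temperatures: np.ndarray  # degC, strictly increasing
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, float)
        f = np.asarray(self.fluorescence, float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("temperature and fluorescence grids must match")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)


@dataclass(frozen=True)
class MeltFit:
    """Boltzmann sigmoid parameters for one melt curve.

    tm is the transition midpoint (degC), slope the transition width
    (degC), f_low/f_high the folded/unfolded fluorescence plateaus.
    """

    well_id: str
    ligand_id: str
    tm: float
    slope: float
    f_low: float
    f_high: float
    r_squared: float
    converged: bool
    message: str = ""


def boltzmann(t: np.ndarray, tm: float, slope: float, f_low: float, f_high: float) -> np.ndarray:
    """Two-state unfolding sigmoid: F(T) = f_low + (f_high - f_low) / (1 + exp((tm - T)/slope))."""
    return f_low + (f_high - f_low) / (1.0 + np.exp((tm - t) / slope))


def truncate_post_peak(curve: MeltCurve) -> MeltCurve:
    """Drop points after the global fluorescence maximum.

    Raises if the maximum sits at the first point (pure decay, no
    transition to fit).
    """
    peak = int(np.argmax(curve.fluorescence))
    if peak == 0:
        raise ValueError(f"well {curve.well_id}: fluorescence maximum at first point, no transition")
    return replace(
        curve,
        temperatures=curve.temperatures[: peak + 1],
        fluorescence=curve.fluorescence[: peak + 1],
    )


def tm_from_derivative(curve: MeltCurve) -> float:
    """Tm as the temperature of maximal dF/dT (model-free cross-check)."""
    dfdt = np.gradient(curve.fluorescence, curve.temperatures)
    return float(curve.temperatures[np.argmax(dfdt)])


def fit_melt_curve(curve: MeltCurve) -> MeltFit:
    """Least-squares Boltzmann fit of a (truncated) melt curve.

    Initialisation: tm at the maximal first derivative, slope 2 degC,
    plateaus from the curve extremes — a robust basin for typical dye
    curves.  Non-convergence is reported in the returned fit, never as a
    silent NaN.
    """
    t, f = curve.temperatures, curve.fluorescence
    if t.size < 8:
        return MeltFit(curve.well_id, curve.ligand_id, np.nan, np.nan, np.nan, np.nan, 0.0,
                       False, "too few points")
    p0 = [tm_from_derivative(curve), 2.0, float(f.min()), float(f.max())]
    span = float(f.max() - f.min())
    try:
        popt, _ = curve_fit(
            boltzmann, t, f, p0=p0,
            bounds=([t.min() - 20.0, 1e-3, -np.inf, -np.inf],
                    [t.max() + 20.0, 50.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return MeltFit(curve.well_id, curve.ligand_id, np.nan, np.nan, np.nan, np.nan, 0.0,
                       False, f"curve_fit failed: {exc}")
    tm, slope, f_low, f_high = map(float, popt)
    resid = f - boltzmann(t, *popt)
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    ok = f_high > f_low and t.min() <= tm <= t.max() and span > 0
    msg = "" if ok else "no valid unfolding transition (f_high <= f_low or tm outside window)"
    return MeltFit(curve.well_id, curve.ligand_id, tm, slope, f_low, f_high, r2, ok, msg)


def compute_delta_tm(sample: MeltFit, reference: MeltFit) -> float:
    """Ligand-induced thermal shift: tm(sample) - tm(reference)."""
    if not (sample.converged and reference.converged):
        raise ValueError("delta-Tm requires converged fits on both sides")
    return sample.tm - reference.tm


def call_stabilizers(deltas: dict[str, float], threshold: float = 2.0) -> list[tuple[str, float]]:
    """Stabilisation hits: ligands with dTm >= threshold, ranked descending.

    The default 2 degC sits well above replicate noise while below the
    weakest genuine stabilisers seen in practice (~3-4 degC).
    """
    hits = [(lig, d) for lig, d in deltas.items() if d >= threshold]
    return sorted(hits, key=lambda kv: -kv[1])
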