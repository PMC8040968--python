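"""Steady-state surface plasmon resonance (SPR) affinity analysis.

At equilibrium the response of a 1:1 interaction follows the Langmuir
isotherm

    Req(C) = Rmax * C / (Kd + C)

where C is the analyte concentration, Rmax the saturating response and
Kd the dissociation constant.  The module fits serial-dilution
equilibrium responses, provides dilution-series design helpers, a
plateau-averaging Req extractor for raw sensorgrams, and replicate
concordance summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SPRSeries",
    "SteadyStateFit",
    "langmuir",
    "make_dilution_series",
    "extract_req",
    "fit_steady_state",
    "replicate_concordance",
    "SaturationWarning",
]

logger = logging.getLogger(__name__)


class SaturationWarning(UserWarning):
    """Tested concentrations do not approach saturation; Kd poorly bounded."""


@dataclass(frozen=True)
class SPRSeries:
    analyte_id: str
    ligand_construct_id: str
    concentrations: np.ndarray  # molar, positive, distinct
    req: np.ndarray  # equilibrium response units
    immobilization_density: float = np.nan  # RU, metadata

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, float)
        r = np.asarray(self.req, float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentration and response arrays must match")
        if np.any(c <= 0) or np.unique(c).size != c.size:
            raise ValueError("concentrations must be positive and distinct")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")
        order = np.argsort(c)
        object.__setattr__(self, "concentrations", c[order])
        object.__setattr__(self, "req", r[order])


@dataclass(frozen=True)
class SteadyStateFit:
    analyte_id: str
    ligand_construct_id: str
    kd: float  # molar
    rmax: float  # RU
    kd_se: float
    rmax_se: float
    r_squared: float
    converged: bool
    message: str = ""


def langmuir(c: np.ndarray, kd: float, rmax: float) -> np.ndarray:
    """1:1 steady-state binding isotherm; Req(kd) = rmax / 2."""
    c = np.asarray(c, float)
    return rmax * c / (kd + c)


def make_dilution_series(top: float, factor: float = 2.0, n: int = 8) -> np.ndarray:
    """Descending geometric dilution series: top, top/factor, ...

    A 1:1 serial dilution is ``factor=2``; e.g. eight points from
    6.25 uM end at ~0.049 uM.
    """
    if top <= 0:
        raise ValueError("top concentration must be positive")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if n < 2:
        raise ValueError("need at least 2 concentrations")
    return top / factor ** np.arange(n, dtype=float)


def extract_req(time: np.ndarray, response: np.ndarray, window: tuple[float, float]) -> float:
    """Equilibrium response as the mean over a late plateau time window."""
    time = np.asarray(time, float)
    response = np.asarray(response, float)
    sel = (time >= window[0]) & (time <= window[1])
    if not sel.any():
        raise ValueError("no sensorgram points inside the averaging window")
    return float(response[sel].mean())


def fit_steady_state(series: SPRSeries) -> SteadyStateFit:
    """Least-squares Langmuir fit for Kd and Rmax.

    Initialisation: Rmax just above the largest response, Kd at the
    concentration closest to half of it.  When the top tested
    concentration is below Kd/2 the isotherm is nearly linear and Kd and
    Rmax are strongly correlated; a :class:`SaturationWarning` is
    emitted.
    """
    c, r = series.concentrations, series.req
    if c.size < 5:
        raise ValueError("need >= 5 concentrations for a steady-state fit")
    rmax0 = float(r.max()) * 1.2 if r.max() > 0 else 1.0
    kd0 = float(c[np.argmin(np.abs(r - rmax0 / 2.0))])
    try:
        popt, pcov = curve_fit(
            langmuir, c, r, p0=[kd0, rmax0],
            bounds=([c.min() / 1e6, 0.0], [c.max() * 1e6, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return SteadyStateFit(series.analyte_id, series.ligand_construct_id,
                              np.nan, np.nan, np.nan, np.nan, 0.0, False,
                              f"curve_fit failed: {exc}")
    kd, rmax = map(float, popt)
    kd_se, rmax_se = map(float, np.sqrt(np.maximum(np.diag(pcov), 0.0)))
    resid = r - langmuir(c, kd, rmax)
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    ok = kd > 0 and rmax > 0
    msg = ""
    if ok and c.max() < kd / 2.0:
        msg = "poor saturation: max concentration < Kd/2"
        warnings.warn(f"{series.analyte_id}: {msg}", SaturationWarning, stacklevel=2)
    return SteadyStateFit(series.analyte_id, series.ligand_construct_id,
                          kd, rmax, kd_se, rmax_se, r2, ok, msg)


def replicate_concordance(fits: list[SteadyStateFit]) -> dict:
    """Geometric-mean Kd and fold-spread across replicate fits.

    Affinities are compared on the log scale, so the geometric mean is
    the natural centre and max/min the natural dispersion.
    """
    kds = np.array([f.kd for f in fits if f.converged])
    if kds.size < 2:
        raise ValueError("replicate concordance needs >= 2 converged fits")
    return {
        "n_replicates": int(kds.size),
        "kd_values": kds.tolist(),
        "kd_geometric_mean": float(np.exp(np.mean(np.log(kds)))),
        "fold_spread": float(kds.max() / kds.min()),
    }
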