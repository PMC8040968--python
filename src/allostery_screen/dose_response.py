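"""Four-parameter logistic dose-response analysis with partial inhibition.

Remaining enzyme activity (percent of the uninhibited control) versus
inhibitor concentration is fitted to

    Y(X) = bottom + (top - bottom) / (1 + (X / ic50)^hill)

The inflection concentration ic50 is reported as the inhibitor constant
Ki, following the convention of inhibitor-vs-response fits; no
Cheng-Prusoff transformation is applied.  A nonzero ``bottom`` plateau
is the signature of partial inhibition — the inhibitor-saturated enzyme
retains a residual activity floor (bottom/top), as seen with allosteric
modulators that only dampen, rather than abolish, turnover.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseCurve",
    "FourPLFit",
    "four_pl",
    "fit_four_pl",
    "estimate_ki",
    "classify_inhibition",
    "competitive_shift_analysis",
    "IdentifiabilityWarning",
]

logger = logging.getLogger(__name__)

MIN_ACTIVITY_SPAN = 30.0  # percentage points; flatter curves carry no dose information
_HILL_BOUNDS = (0.2, 5.0)


class IdentifiabilityWarning(UserWarning):
    """Design does not constrain a parameter (e.g. floor untested at saturation)."""


@dataclass(frozen=True)
class DoseResponseCurve:
    inhibitor_id: str
    concentrations: np.ndarray  # molar, sorted, >= 0
    activities: np.ndarray  # percent of uninhibited control
    replicate: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, float)
        a = np.asarray(self.activities, float)
        if c.shape != a.shape or c.ndim != 1:
            raise ValueError("concentration and activity arrays must match")
        if np.any(c < 0) or not np.all(np.isfinite(a)):
            raise ValueError("concentrations must be >= 0 and activities finite")
        order = np.argsort(c)
        object.__setattr__(self, "concentrations", c[order])
        object.__setattr__(self, "activities", a[order])


@dataclass(frozen=True)
class FourPLFit:
    inhibitor_id: str
    top: float
    bottom: float
    ic50: float  # molar; the inflection concentration
    hill: float
    se: dict  # parameter -> standard error
    cov_top_bottom: float
    r_squared: float
    converged: bool
    message: str = ""

    @property
    def ki(self) -> float:
        """Inhibitor constant, reported as the 4PL inflection (== ic50)."""
        return self.ic50

    @property
    def residual_fraction(self) -> float:
        """Activity floor at saturating inhibitor, as a fraction of top."""
        return self.bottom / self.top

    @property
    def residual_fraction_se(self) -> float:
        """Delta-method SE of bottom/top from the fit covariance."""
        f = self.residual_fraction
        vt, vb = self.se["top"] ** 2, self.se["bottom"] ** 2
        var = (vb + f**2 * vt - 2 * f * self.cov_top_bottom) / self.top**2
        return float(np.sqrt(max(var, 0.0)))


def four_pl(x: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    """Inhibitor-vs-response logistic; Y(0) = top, Y(inf) = bottom for hill > 0."""
    x = np.asarray(x, float)
    out = np.full_like(x, top, dtype=float)
    pos = x > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (x[pos] / ic50) ** hill)
    return out


def fit_four_pl(
    curve: DoseResponseCurve,
    fix_top: float | None = None,
    weights_inv_y2: bool = False,
    log_space: bool = False,
) -> FourPLFit:
    """Least-squares 4PL fit, unweighted by default.

    The default fits in linear concentration, where zero-concentration
    anchors are handled naturally (Y(0) = top exactly).  ``log_space``
    refits the identical model against log10 concentration, replacing
    any zero dose by a pseudo-dose of 0.01 x the smallest nonzero dose;
    the two parameterisations agree on noiseless data.  ``fix_top``
    constrains the upper plateau (e.g. to 100%); ``weights_inv_y2``
    applies 1/Y^2 relative weighting.  Emits
    :class:`IdentifiabilityWarning` when the tested range ends below
    ~10x the fitted ic50, where the floor is poorly constrained.
    """
    x, y = curve.concentrations, curve.activities
    if log_space and np.any(x == 0):
        x = np.where(x > 0, x, 0.01 * x[x > 0].min())
    if np.unique(x).size < 6:
        raise ValueError("need >= 6 distinct concentrations for a 4PL fit")
    span = float(y.max() - y.min())
    if span < MIN_ACTIVITY_SPAN:
        raise ValueError(
            f"activity span {span:.1f} points < {MIN_ACTIVITY_SPAN:.0f}; "
            "curve carries no dose-response information (flat segment)"
        )

    top0 = float(y.max()) if fix_top is None else fix_top
    bot0 = float(max(y.min(), 0.0))
    half = (top0 + bot0) / 2.0
    nz = x[x > 0]
    if nz.size == 0:
        raise ValueError("all concentrations are zero")
    ic0 = float(nz[np.argmin(np.abs(y[x > 0] - half))])
    sigma = np.maximum(np.abs(y), 1.0) if weights_inv_y2 else None

    # the midpoint is optimised either directly or as log10(ic50); the
    # model itself is identical in both parameterisations
    def to_ic50(v: float) -> float:
        return 10.0**v if log_space else v

    ic50_p0 = np.log10(ic0) if log_space else ic0
    ic50_lb = np.log10(nz.min() / 1e4) if log_space else nz.min() / 1e4
    ic50_ub = np.log10(nz.max() * 1e4) if log_space else nz.max() * 1e4

    if fix_top is None:
        def model(xv, top, bottom, mid, hill):
            return four_pl(xv, top, bottom, to_ic50(mid), hill)
        p0 = [top0, bot0, ic50_p0, 1.0]
        lb = [0.0, -50.0, ic50_lb, _HILL_BOUNDS[0]]
        ub = [np.inf, np.inf, ic50_ub, _HILL_BOUNDS[1]]
        names = ["top", "bottom", "ic50", "hill"]
    else:
        def model(xv, bottom, mid, hill):  # top fixed
            return four_pl(xv, fix_top, bottom, to_ic50(mid), hill)
        p0 = [bot0, ic50_p0, 1.0]
        lb = [-50.0, ic50_lb, _HILL_BOUNDS[0]]
        ub = [np.inf, ic50_ub, _HILL_BOUNDS[1]]
        names = ["bottom", "ic50", "hill"]

    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, bounds=(lb, ub), sigma=sigma, maxfev=20000)
    except RuntimeError as exc:
        return FourPLFit(curve.inhibitor_id, np.nan, np.nan, np.nan, np.nan, {}, np.nan, 0.0,
                         False, f"curve_fit failed: {exc}")

    perr = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    if fix_top is None:
        top, bottom, mid, hill = map(float, popt)
        se = dict(zip(names, map(float, perr)))
        cov_tb = float(pcov[0, 1])
    else:
        top = fix_top
        bottom, mid, hill = map(float, popt)
        se = {"top": 0.0, **dict(zip(names, map(float, perr)))}
        cov_tb = 0.0
    ic50 = to_ic50(mid)
    if log_space:
        se["ic50"] = float(np.log(10.0) * ic50 * se["ic50"])  # delta method

    resid = y - four_pl(x, top, bottom, ic50, hill)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0

    ok = np.isfinite(ic50) and nz.min() * 0.01 <= ic50 <= nz.max() * 100.0 and top > bottom
    msg = "" if ok else "ic50 outside tested range x [0.01, 100] or inverted plateaus"
    if ok and nz.max() < 10.0 * ic50:
        warnings.warn(
            f"{curve.inhibitor_id}: max tested concentration {nz.max():.3g} M < 10 x ic50; "
            "residual-activity floor weakly identified",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    return FourPLFit(curve.inhibitor_id, top, bottom, ic50, hill, se, cov_tb, r2, ok, msg)


def estimate_ki(fit: FourPLFit) -> tuple[float, float]:
    """Ki (molar) and its standard error from a converged fit."""
    if not fit.converged:
        raise ValueError(f"{fit.inhibitor_id}: cannot report Ki from an unconverged fit")
    return fit.ic50, fit.se.get("ic50", np.nan)


def classify_inhibition(fit: FourPLFit, full_threshold: float = 0.10) -> str:
    """'partial', 'complete' or 'indeterminate' from the activity floor.

    partial if floor - 2*SE > threshold; complete if floor + 2*SE <
    threshold; indeterminate when the confidence band straddles it.
    """
    if not fit.converged:
        raise ValueError("classification requires a converged fit")
    f, se = fit.residual_fraction, fit.residual_fraction_se
    if f - 2 * se > full_threshold:
        return "partial"
    if f + 2 * se < full_threshold:
        return "complete"
    return "indeterminate"


def competitive_shift_analysis(
    curve_alone: DoseResponseCurve, curve_with_coligand: DoseResponseCurve, **fit_kwargs
) -> dict:
    """Ki with and without a fixed co-ligand, and their ratio.

    Both curves must share the concentration design.  The ratio's
    relative uncertainty combines the two Ki standard errors in
    quadrature (independent fits).
    """
    if not np.allclose(curve_alone.concentrations, curve_with_coligand.concentrations):
        raise ValueError("paired curves must share the concentration design")
    fit_a = fit_four_pl(curve_alone, **fit_kwargs)
    fit_b = fit_four_pl(curve_with_coligand, **fit_kwargs)
    ki_a, se_a = estimate_ki(fit_a)
    ki_b, se_b = estimate_ki(fit_b)
    ratio = ki_b / ki_a
    rel_se = np.sqrt((se_a / ki_a) ** 2 + (se_b / ki_b) ** 2)
    return {
        "ki_alone": ki_a,
        "ki_alone_se": se_a,
        "ki_with_coligand": ki_b,
        "ki_with_coligand_se": se_b,
        "ki_ratio": ratio,
        "ki_ratio_se": ratio * rel_se,
        "delta_ki": ki_b - ki_a,
        "delta_ki_se": float(np.hypot(se_a, se_b)),
    }
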