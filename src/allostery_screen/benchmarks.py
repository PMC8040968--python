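"""Self-benchmarks: error rates and parameter recovery on synthetic truth.

Every function regenerates its inputs from a seed, runs the relevant
analysis stage, and measures performance against the generator's truth
tables.  The study conditions are the module defaults: a 400-metabolite
x 20-protein dialysis screen with 5% true enrichments at |log2 FC| = 2,
a 162-compound thermal-shift screen with four programmed stabilisers,
full- and partial-inhibition dose-response scenarios, and the
eight-point 1:1 SPR dilution design.
"""

from __future__ import annotations

import numpy as np

from .dose_response import classify_inhibition, fit_four_pl, four_pl, DoseResponseCurve
from .dsf import call_stabilizers, fit_melt_curve, truncate_post_peak
from .midas import run_midas
from .simulate import (
    CurveSimConfig,
    MidasSimConfig,
    gen_dose_response,
    gen_dsf_screen,
    gen_melt_curves,
    gen_midas_dataset,
    gen_spr_series,
)
from .spr import SPRSeries, fit_steady_state, langmuir, make_dilution_series

__all__ = [
    "midas_screen_error_rates",
    "melt_noiseless_recovery",
    "melt_noisy_recovery",
    "dsf_screen_hit_rate",
    "fourpl_noiseless_recovery",
    "fourpl_floor_recovery",
    "spr_noiseless_recovery",
    "spr_noisy_recovery",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def midas_screen_error_rates(n_seeds: int = 20, seed: int = 0, **cfg_kwargs) -> dict:
    """Mean empirical FDR and sensitivity of the full interactomics chain."""
    fdrs, sens = [], []
    for s in _child_seeds(seed, n_seeds):
        meas, truth = gen_midas_dataset(MidasSimConfig(seed=s, **cfg_kwargs))
        calls, _ = run_midas(meas)
        sig = calls[calls["significant"]]
        called = set(zip(sig["metabolite_id"], sig["protein_id"]))
        true_pairs = set(zip(truth["metabolite_id"], truth["protein_id"]))
        tp = len(called & true_pairs)
        fdrs.append((len(called) - tp) / max(len(called), 1))
        sens.append(tp / max(len(true_pairs), 1))
    return {
        "n_seeds": n_seeds,
        "mean_fdr": float(np.mean(fdrs)),
        "mean_sensitivity": float(np.mean(sens)),
        "fdr_per_seed": fdrs,
        "sensitivity_per_seed": sens,
    }


def melt_noiseless_recovery(tms=(45.0, 55.0, 65.0, 75.0)) -> dict:
    """Worst-case |Tm error| on noiseless melt curves across the Tm range."""
    errors = []
    for tm in tms:
        cfg = CurveSimConfig("boltzmann", {"tm": tm, "slope": 2.0,
                                           "f_low": 0.0, "f_high": 100.0}, noise_sd=0.0)
        (curve,), _ = gen_melt_curves(cfg)
        fit = fit_melt_curve(curve)
        errors.append(abs(fit.tm - tm))
    return {"max_abs_tm_error_C": float(np.max(errors)), "tms": list(tms)}


def melt_noisy_recovery(n_seeds: int = 100, noise_sd: float = 2.0, seed: int = 0) -> dict:
    """Median |Tm error| at a given fluorescence noise (2% of span default)."""
    errors = []
    for s in _child_seeds(seed, n_seeds):
        cfg = CurveSimConfig("boltzmann", {"tm": 55.0, "slope": 2.0,
                                           "f_low": 0.0, "f_high": 100.0},
                             noise_sd=noise_sd, seed=s)
        (curve,), _ = gen_melt_curves(cfg)
        fit = fit_melt_curve(curve)
        errors.append(abs(fit.tm - 55.0) if fit.converged else np.inf)
    return {"n_seeds": n_seeds, "median_abs_tm_error_C": float(np.median(errors))}


def dsf_screen_hit_rate(n_seeds: int = 20, threshold: float = 2.0, seed: int = 0) -> dict:
    """Fraction of simulated screens calling exactly the programmed hits."""
    exact, n_hits_all = 0, []
    for s in _child_seeds(seed, n_seeds):
        curves, truth = gen_dsf_screen(seed=s)
        fits = [fit_melt_curve(truncate_post_peak(c)) for c in curves]
        ref = np.mean([f.tm for f in fits if f.ligand_id == "DMSO" and f.converged])
        deltas = {f.ligand_id: f.tm - ref for f in fits
                  if f.converged and f.ligand_id != "DMSO"}
        hits = call_stabilizers(deltas, threshold=threshold)
        programmed = set(truth.loc[truth["true_shift"] > 0, "ligand_id"])
        n_hits_all.append(len(hits))
        if {h[0] for h in hits} == programmed:
            exact += 1
    return {
        "n_seeds": n_seeds,
        "n_programmed_stabilizers": len(programmed),
        "frac_seeds_exact_hit_set": exact / n_seeds,
        "mean_hits_called": float(np.mean(n_hits_all)),
    }


def fourpl_noiseless_recovery(top=100.0, bottom=0.0, ic50=5.8e-6, hill=1.0) -> dict:
    """Worst relative parameter error on a noiseless inhibition curve."""
    cfg = CurveSimConfig("four_pl", {"top": top, "bottom": bottom,
                                     "ic50": ic50, "hill": hill}, noise_sd=0.0)
    (curve,), _ = gen_dose_response(cfg)
    fit = fit_four_pl(curve)
    rel = [
        abs(fit.top - top) / top,
        abs(fit.ic50 - ic50) / ic50,
        abs(fit.hill - hill) / hill,
        abs(fit.bottom - bottom) / (top if bottom == 0 else bottom),
    ]
    return {"max_rel_param_error": float(np.max(rel)), "ki_M": fit.ic50}


def fourpl_floor_recovery(
    n_seeds: int = 100, floor_pct: float = 30.0, noise_sd: float = 2.0, seed: int = 0
) -> dict:
    """Partial-inhibition floor recovery and classification rate."""
    floors, partial = [], 0
    for s in _child_seeds(seed, n_seeds):
        cfg = CurveSimConfig("four_pl", {"top": 100.0, "bottom": floor_pct,
                                         "ic50": 0.78e-6, "hill": 1.0},
                             noise_sd=noise_sd, seed=s)
        (curve,), _ = gen_dose_response(cfg)
        fit = fit_four_pl(curve)
        floors.append(100.0 * fit.residual_fraction)
        if fit.converged and classify_inhibition(fit) == "partial":
            partial += 1
    return {
        "n_seeds": n_seeds,
        "true_floor_pct": floor_pct,
        "median_recovered_floor_pct": float(np.median(floors)),
        "max_abs_floor_error_pct": float(np.max(np.abs(np.array(floors) - floor_pct))),
        "frac_classified_partial": partial / n_seeds,
    }


def spr_noiseless_recovery(kds=(0.05e-6, 0.6e-6, 1.5e-6, 4.3e-6)) -> dict:
    """Worst relative Kd/Rmax error on noiseless eight-point isotherms."""
    conc = make_dilution_series(6.25e-6, 2.0, 8)
    errors = []
    for kd in kds:
        fit = fit_steady_state(SPRSeries("a", "c", conc, langmuir(conc, kd, 50.0)))
        errors.append(max(abs(fit.kd - kd) / kd, abs(fit.rmax - 50.0) / 50.0))
    return {"max_rel_error": float(np.max(errors)), "kds_M": list(kds)}


def spr_noisy_recovery(
    n_seeds: int = 100, kd: float = 0.612e-6, noise_sd: float = 0.02, seed: int = 0
) -> dict:
    """Median relative Kd error at 2% relative response noise."""
    errors, fitted = [], []
    for s in _child_seeds(seed, n_seeds):
        cfg = CurveSimConfig("langmuir", {"kd": kd, "rmax": 50.0},
                             noise_sd=noise_sd, seed=s)
        (series,), _ = gen_spr_series(cfg)
        fit = fit_steady_state(series)
        errors.append(abs(fit.kd - kd) / kd)
        fitted.append(fit.kd)
    return {
        "n_seeds": n_seeds,
        "true_kd_M": kd,
        "median_rel_kd_error": float(np.median(errors)),
        "median_fitted_kd_nM": float(np.median(fitted) * 1e9),
    }
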