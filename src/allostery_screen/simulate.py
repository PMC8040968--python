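"""Seeded synthetic-data generators for every analysis stage.

Each generator emits data with the statistical structure its analysis
stage assumes — triplicate dialysis fold changes with sparse true
binders, low-rank systematic variation and rare gross outliers; dye
melt curves with a post-peak decay; partial-inhibition dose-response
curves; 1:1 serial-dilution binding isotherms — together with a truth
table, so parameter recovery and error rates can be measured exactly.

Scenario banks collect parameter sets matching the magnitudes seen in a
regulatory-domain screening campaign (thermal shifts of ~3-10 degC over
a 162-compound library, inhibitor constants in the 0.8-7 uM range with
residual-activity floors of 30-50%, sub-uM to low-uM dissociation
constants) so that the same conditions are exercised everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve, four_pl
from .dsf import MeltCurve, boltzmann
from .spr import SPRSeries, langmuir, make_dilution_series

__all__ = [
    "MidasSimConfig",
    "CurveSimConfig",
    "gen_midas_dataset",
    "gen_melt_curves",
    "gen_dsf_screen",
    "gen_dose_response",
    "gen_spr_series",
    "DSF_SHIFT_SCENARIOS",
    "DOSE_SCENARIOS",
    "SPR_SCENARIOS",
]

# programmed thermal shifts (degC vs vehicle) spanning the weakest to the
# strongest stabiliser classes seen in an AdoMet-mimetic screen
DSF_SHIFT_SCENARIOS: dict[str, float] = {
    "sinefungin_analogue_A": 3.0,
    "sinefungin_analogue_B": 4.0,
    "adohcy_like": 7.0,
    "benzyl_sinefungin_like": 10.0,
}

# (top %, bottom %, Ki molar, Hill); floors of 30-50% mark partial inhibitors
DOSE_SCENARIOS: dict[str, dict] = {
    "allosteric_full_inhibitor": {"top": 100.0, "bottom": 0.0, "ic50": 5.8e-6, "hill": 1.0},
    "partial_inhibitor": {"top": 100.0, "bottom": 30.0, "ic50": 0.78e-6, "hill": 1.0},
    "full_inhibitor_with_coligand": {"top": 100.0, "bottom": 0.0, "ic50": 4.2e-6, "hill": 1.0},
    "lysate_full_inhibitor": {"top": 100.0, "bottom": 0.0, "ic50": 6.8e-6, "hill": 1.0},
    "lysate_partial_inhibitor": {"top": 100.0, "bottom": 50.0, "ic50": 3.0e-6, "hill": 1.0},
}

# replicate Kd pairs (molar) for three construct-analyte pairings
SPR_SCENARIOS: dict[str, tuple[float, float]] = {
    "full_construct_tight_binder": (596e-9, 612e-9),
    "domain_only_tight_binder": (1.47e-6, 1.175e-6),
    "domain_only_native_ligand": (1.057e-6, 4.3e-6),
}


@dataclass(frozen=True)
class MidasSimConfig:
    """Equilibrium-dialysis screen generator settings.

    Defaults mirror a 400-metabolite library screened in four pools
    against a panel of protein samples in technical triplicate, with
    5% of metabolites truly enriched at |log2 fold change| = 2,
    replicate noise of 0.3 log2 units, three low-rank systematic
    factors and a 1% gross-outlier rate.
    """

    n_metabolites: int = 400
    n_proteins: int = 20
    n_replicates: int = 3
    n_pools: int = 4
    frac_enriched: float = 0.05
    frac_depleted: float = 0.0
    effect_size: float = 2.0
    replicate_noise_sd: float = 0.3
    n_systematic_factors: int = 3
    factor_scale: float = 0.5
    outlier_rate: float = 0.01
    outlier_magnitude: float = 5.0
    base_abundance: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_enriched + self.frac_depleted < 1:
            raise ValueError("enriched + depleted fractions must sum below 1")
        for name in ("effect_size", "replicate_noise_sd", "factor_scale", "outlier_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CurveSimConfig:
    """Generic curve generator settings: model family, true parameters,
    sampling grid and Gaussian noise level."""

    model: str  # boltzmann | four_pl | langmuir
    params: dict = field(default_factory=dict)
    grid: np.ndarray | None = None
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("boltzmann", "four_pl", "langmuir"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_midas_dataset(cfg: MidasSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a dialysis screen; returns (measurements, truth).

    The log2 chamber ratio of each pair decomposes as
    ``truth effect + low-rank systematic variation + iid replicate
    noise (+ sparse single-replicate spikes)``.  Each truly interacting
    metabolite is paired with one randomly chosen protein sample, so
    every metabolite's no-signal population stays predominantly null.
    The truth table lists each programmed interaction once.
    """
    rng = np.random.default_rng(cfg.seed)
    n_m, n_p, n_r = cfg.n_metabolites, cfg.n_proteins, cfg.n_replicates

    n_enr = round(cfg.frac_enriched * n_m)
    n_dep = round(cfg.frac_depleted * n_m)
    affected = rng.choice(n_m, n_enr + n_dep, replace=False)
    effect = np.zeros((n_m, n_p))
    truth_rows = []
    for idx, m in enumerate(affected):
        sign = 1.0 if idx < n_enr else -1.0
        p = int(rng.integers(n_p))
        effect[m, p] = sign * cfg.effect_size
        truth_rows.append(
            {
                "metabolite_id": f"M{m:04d}",
                "protein_id": f"P{p:02d}",
                "true_log2fc": sign * cfg.effect_size,
                "direction": "enriched" if sign > 0 else "depleted",
            }
        )
    truth = pd.DataFrame(truth_rows, columns=["metabolite_id", "protein_id", "true_log2fc", "direction"])

    systematic = np.zeros((n_m, n_p))
    for _ in range(cfg.n_systematic_factors):
        systematic += cfg.factor_scale * np.outer(rng.normal(size=n_m), rng.normal(size=n_p))

    noise = rng.normal(0.0, cfg.replicate_noise_sd, size=(n_m, n_p, n_r))
    ratio = effect[:, :, None] + systematic[:, :, None] + noise

    # gross outliers: a single-replicate multiplicative abundance spike,
    # so the "up to one per triplicate" rule has a well-defined target
    outlier_pair = rng.random((n_m, n_p)) < cfg.outlier_rate
    spike_rep = rng.integers(n_r, size=(n_m, n_p))
    spike_sign = rng.choice([-1.0, 1.0], size=(n_m, n_p))
    ii, jj = np.nonzero(outlier_pair)
    ratio[ii, jj, spike_rep[ii, jj]] += spike_sign[ii, jj] * cfg.outlier_magnitude

    # metabolite-chamber abundances: metabolite-specific base intensity
    # with small per-replicate measurement scatter
    base = cfg.base_abundance * rng.lognormal(0.0, 1.0, size=n_m)
    met_ab = base[:, None, None] * rng.lognormal(0.0, 0.05, size=(n_m, n_p, n_r))
    prot_ab = met_ab * 2.0**ratio

    m_ids = np.repeat(np.arange(n_m), n_p * n_r)
    p_ids = np.tile(np.repeat(np.arange(n_p), n_r), n_m)
    r_ids = np.tile(np.arange(1, n_r + 1), n_m * n_p)
    measurements = pd.DataFrame(
        {
            "protein_id": [f"P{j:02d}" for j in p_ids],
            "metabolite_id": [f"M{i:04d}" for i in m_ids],
            "pool_id": [f"pool{i % cfg.n_pools + 1}" for i in m_ids],
            "replicate": r_ids,
            "protein_chamber_abundance": prot_ab.ravel(),
            "metabolite_chamber_abundance": met_ab.ravel(),
        }
    )
    return measurements, truth


def gen_melt_curves(cfg: CurveSimConfig) -> tuple[list[MeltCurve], pd.DataFrame]:
    """Boltzmann melt curves with optional post-peak dye decay.

    params: tm, slope, f_low, f_high, optional decay_rate (fluorescence
    units per degC past the peak) and decay_start_offset.
    """
    if cfg.model != "boltzmann":
        raise ValueError("gen_melt_curves requires model='boltzmann'")
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(25.0, 95.5, 0.5) if cfg.grid is None else np.asarray(cfg.grid, float)
    p = cfg.params
    clean = boltzmann(t, p["tm"], p.get("slope", 2.0), p.get("f_low", 0.0), p.get("f_high", 100.0))
    decay = p.get("decay_rate", 0.0)
    if decay > 0:
        start = p["tm"] + p.get("decay_start_offset", 10.0)
        clean = clean - decay * np.clip(t - start, 0.0, None)
    curves, rows = [], []
    for r in range(cfg.n_replicates):
        f = clean + rng.normal(0.0, cfg.noise_sd, size=t.size)
        wid = f"W{r + 1:02d}"
        curves.append(MeltCurve(wid, p.get("ligand_id", "ligand"), p.get("concentration", 250e-6), t, f))
        rows.append({"well_id": wid, "true_tm": p["tm"], "true_slope": p.get("slope", 2.0)})
    return curves, pd.DataFrame(rows)


def gen_dsf_screen(
    n_compounds: int = 162,
    reference_tm: float = 52.0,
    stabilizer_shifts: dict[str, float] | None = None,
    tm_noise_sd: float = 0.3,
    fluor_noise_sd: float = 2.0,
    n_reference_wells: int = 8,
    seed: int = 0,
) -> tuple[list[MeltCurve], pd.DataFrame]:
    """A full single-plate-logic screen: vehicle wells plus one well per
    compound, a handful of which carry programmed stabilisation shifts.

    Non-binders melt at the reference Tm plus well-to-well jitter of
    ``tm_noise_sd`` degC; stabilisers add their programmed shift on top.
    Returns the curves and a truth table of per-well true Tm and shift.
    """
    shifts = DSF_SHIFT_SCENARIOS if stabilizer_shifts is None else stabilizer_shifts
    if len(shifts) > n_compounds:
        raise ValueError("more programmed stabilizers than compounds")
    rng = np.random.default_rng(seed)
    t = np.arange(25.0, 95.5, 0.5)
    curves, rows = [], []

    def make_well(well_id: str, ligand: str, true_tm: float, true_shift: float):
        clean = boltzmann(t, true_tm, 2.0, 10.0, 110.0)
        start = true_tm + 10.0
        clean = clean - 1.5 * np.clip(t - start, 0.0, None)  # post-peak dye decay
        f = clean + rng.normal(0.0, fluor_noise_sd, size=t.size)
        curves.append(MeltCurve(well_id, ligand, 250e-6, t, f))
        rows.append({"well_id": well_id, "ligand_id": ligand,
                     "true_tm": true_tm, "true_shift": true_shift})

    for r in range(n_reference_wells):
        make_well(f"DMSO{r + 1:02d}", "DMSO", reference_tm + rng.normal(0.0, tm_noise_sd), 0.0)
    ligands = list(shifts) + [f"CPD{i:03d}" for i in range(n_compounds - len(shifts))]
    for i, lig in enumerate(ligands):
        shift = shifts.get(lig, 0.0)
        make_well(f"C{i + 1:03d}", lig, reference_tm + shift + rng.normal(0.0, tm_noise_sd), shift)
    return curves, pd.DataFrame(rows)


def gen_dose_response(cfg: CurveSimConfig) -> tuple[list[DoseResponseCurve], pd.DataFrame]:
    """Inhibitor-vs-activity curves from a 4PL truth.

    params: top, bottom, ic50, hill, optional inhibitor_id and
    include_zero (prepend an uninhibited anchor, default True).
    noise_sd is in percent-of-control activity units.
    """
    if cfg.model != "four_pl":
        raise ValueError("gen_dose_response requires model='four_pl'")
    rng = np.random.default_rng(cfg.seed)
    p = cfg.params
    if cfg.grid is None:
        conc = np.concatenate([[0.0], np.geomspace(5e-8, 1e-4, 10)])
    else:
        conc = np.asarray(cfg.grid, float)
    clean = four_pl(conc, p.get("top", 100.0), p.get("bottom", 0.0), p["ic50"], p.get("hill", 1.0))
    curves, rows = [], []
    for r in range(cfg.n_replicates):
        y = clean + rng.normal(0.0, cfg.noise_sd, size=conc.size)
        curves.append(DoseResponseCurve(p.get("inhibitor_id", "inhibitor"), conc, y, replicate=r + 1))
        rows.append({"replicate": r + 1, "true_ic50": p["ic50"],
                     "true_top": p.get("top", 100.0), "true_bottom": p.get("bottom", 0.0),
                     "true_hill": p.get("hill", 1.0)})
    return curves, pd.DataFrame(rows)


def gen_spr_series(cfg: CurveSimConfig) -> tuple[list[SPRSeries], pd.DataFrame]:
    """Steady-state 1:1 isotherms on a serial-dilution design.

    params: kd, rmax, optional analyte_id/construct_id, top/factor/n for
    the dilution series.  noise_sd is relative (fraction of each clean
    response).
    """
    if cfg.model != "langmuir":
        raise ValueError("gen_spr_series requires model='langmuir'")
    rng = np.random.default_rng(cfg.seed)
    p = cfg.params
    if cfg.grid is None:
        conc = make_dilution_series(p.get("top", 6.25e-6), p.get("factor", 2.0), p.get("n", 8))
    else:
        conc = np.asarray(cfg.grid, float)
    clean = langmuir(conc, p["kd"], p.get("rmax", 50.0))
    series, rows = [], []
    for r in range(cfg.n_replicates):
        req = clean * (1.0 + rng.normal(0.0, cfg.noise_sd, size=conc.size))
        series.append(SPRSeries(p.get("analyte_id", "analyte"), p.get("construct_id", "construct"),
                                conc, req))
        rows.append({"replicate": r + 1, "true_kd": p["kd"], "true_rmax": p.get("rmax", 50.0)})
    return series, pd.DataFrame(rows)
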