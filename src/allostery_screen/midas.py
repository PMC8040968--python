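"""Equilibrium-dialysis protein-metabolite interactomics statistics.

The screen measures, for every protein x metabolite pair, the relative
metabolite abundance in the protein-containing dialysis chamber versus
the protein-free chamber.  A metabolite that binds the protein is
retained (enriched) in the protein chamber; one consumed by an active
enzyme is depleted.  The analysis chain is:

1. per-replicate log2 fold change (protein chamber / metabolite chamber)
2. removal of at most one gross outlier per technical triplicate
3. collapse to one mean fold change per protein-metabolite pair
4. removal of the leading principal components (systematic, pair-
   nonspecific variation such as chamber loading and batch effects)
5. per-metabolite robust "no-signal" model: median centre and a
   quantile-extrapolated standard deviation, insensitive to the true
   binders sitting in the tails
6. z-score and two-sided normal p-value per pair, Storey q-values,
   and significance calls at p < 0.05 and q < 0.1
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qvalue import estimate_pi0, storey_qvalues

__all__ = [
    "DialysisMeasurement",
    "FoldChangeMatrix",
    "NoSignalModel",
    "MidasError",
    "compute_log2_fold_changes",
    "remove_triplicate_outliers",
    "collapse_replicates",
    "remove_principal_components",
    "build_nosignal_model",
    "build_nosignal_models",
    "score_interactions",
    "call_interactions",
    "run_midas",
]

logger = logging.getLogger(__name__)

# Phi^-1(0.75): converts an interquartile range to a normal sigma
NORMAL_IQR_FACTOR = 2.0 * stats.norm.ppf(0.75)  # 1.3489795...

# relative efficiency of the IQR scale estimate vs the sample SD; sets
# the effective degrees of freedom used in variance shrinkage
_IQR_RELATIVE_EFFICIENCY = 0.37


class MidasError(ValueError):
    """Structured failure in the interactomics statistics chain."""


@dataclass(frozen=True)
class DialysisMeasurement:
    """One chamber-pair abundance measurement for one replicate."""

    protein_id: str
    metabolite_id: str
    pool_id: str
    replicate: int
    protein_chamber_abundance: float
    metabolite_chamber_abundance: float


@dataclass
class FoldChangeMatrix:
    """Log2 fold changes, metabolites x protein samples (x replicates).

    ``values`` is 3-D (metabolite, protein, replicate) before replicate
    collapse and 2-D after; NaN marks absent or masked entries.
    ``outlier_mask`` is True where a replicate was removed as an outlier.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    outlier_mask: np.ndarray | None = None

    @property
    def has_replicates(self) -> bool:
        return self.values.ndim == 3


@dataclass(frozen=True)
class NoSignalModel:
    """Robust null model for one metabolite's corrected fold changes."""

    metabolite_id: str
    center: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise MidasError(
                f"degenerate no-signal model for {self.metabolite_id}: sigma={self.sigma}"
            )


def compute_log2_fold_changes(measurements) -> FoldChangeMatrix:
    """Per-replicate log2(protein chamber / metabolite chamber).

    Accepts a list of :class:`DialysisMeasurement` or a tidy DataFrame
    with columns protein_id, metabolite_id, replicate,
    protein_chamber_abundance, metabolite_chamber_abundance.

    Records with a non-positive metabolite-chamber (denominator)
    abundance cannot form a ratio; they are excluded with a logged
    warning rather than propagated as infinities.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:
        df = pd.DataFrame([vars(m) for m in measurements])
    required = {
        "protein_id",
        "metabolite_id",
        "replicate",
        "protein_chamber_abundance",
        "metabolite_chamber_abundance",
    }
    missing = required - set(df.columns)
    if missing:
        raise MidasError(f"measurement table missing columns: {sorted(missing)}")

    num = df["protein_chamber_abundance"].to_numpy(float)
    den = df["metabolite_chamber_abundance"].to_numpy(float)
    if not (np.all(np.isfinite(num)) and np.all(np.isfinite(den))):
        raise MidasError("non-finite chamber abundances")
    bad = (den <= 0) | (num <= 0)
    if bad.any():
        logger.warning(
            "excluding %d measurement(s) with non-positive chamber abundance", int(bad.sum())
        )
        df = df.loc[~bad]
        num, den = num[~bad], den[~bad]

    dup = df.duplicated(subset=["protein_id", "metabolite_id", "replicate"])
    if dup.any():
        raise MidasError(
            "duplicate replicate entries for pairs: "
            + ", ".join(
                map(str, df.loc[dup, ["protein_id", "metabolite_id", "replicate"]].itertuples(index=False))
            )
        )

    df = df.assign(log2fc=np.log2(num / den))
    rows = sorted(df["metabolite_id"].unique())
    cols = sorted(df["protein_id"].unique())
    reps = sorted(df["replicate"].unique())
    r_ix = {m: i for i, m in enumerate(rows)}
    c_ix = {p: j for j, p in enumerate(cols)}
    k_ix = {r: k for k, r in enumerate(reps)}
    values = np.full((len(rows), len(cols), len(reps)), np.nan)
    values[
        df["metabolite_id"].map(r_ix),
        df["protein_id"].map(c_ix),
        df["replicate"].map(k_ix),
    ] = df["log2fc"].to_numpy()

    n_per_pair = np.sum(~np.isnan(values), axis=2)
    if np.any(n_per_pair < 2):
        n_bad = int(np.sum(n_per_pair < 2))
        raise MidasError(f"{n_bad} protein-metabolite pair(s) have fewer than 2 replicates")
    return FoldChangeMatrix(values, rows, cols, np.zeros_like(values, dtype=bool))


def remove_triplicate_outliers(fc: FoldChangeMatrix, cutoff: float = 5.0) -> FoldChangeMatrix:
    """Mask at most one gross outlier per technical triplicate.

    Within a 3-point group the sample z-score is bounded at 1.15, so the
    cutoff is referenced to a dataset-wide replicate-noise scale: the
    median of all triplicate standard deviations.  For each triplicate,
    the single most extreme point with |value - mean| / global_sigma
    above ``cutoff`` is masked.
    """
    if not fc.has_replicates:
        raise MidasError("replicate axis already collapsed; cannot remove outliers")
    if cutoff <= 0:
        raise MidasError("outlier cutoff must be positive")
    vals = fc.values.copy()
    with np.errstate(invalid="ignore"):
        trip_sd = np.nanstd(vals, axis=2, ddof=1)
    global_sigma = float(np.nanmedian(trip_sd))
    if global_sigma == 0:
        logger.warning("zero global replicate noise; no outliers removable")
        return FoldChangeMatrix(vals, fc.row_ids, fc.col_ids, np.zeros_like(vals, dtype=bool))

    mean = np.nanmean(vals, axis=2, keepdims=True)
    z = np.abs(vals - mean) / global_sigma
    z = np.where(np.isnan(z), -np.inf, z)
    worst = np.argmax(z, axis=2)
    worst_z = np.take_along_axis(z, worst[..., None], axis=2)[..., 0]
    remove = worst_z > cutoff

    n_retained = np.sum(~np.isnan(vals), axis=2)
    impossible = remove & (n_retained <= 2)
    if impossible.any():
        i, j = np.argwhere(impossible)[0]
        raise MidasError(
            f"outlier removal would leave <2 replicates for pair "
            f"({fc.row_ids[i]}, {fc.col_ids[j]})"
        )

    mask = np.zeros_like(vals, dtype=bool)
    ii, jj = np.nonzero(remove)
    mask[ii, jj, worst[ii, jj]] = True
    vals[mask] = np.nan
    frac = mask.sum() / max(np.isfinite(fc.values).sum(), 1)
    logger.info("removed %d outlier replicate(s) (%.3g%% of observations)", mask.sum(), 100 * frac)
    return FoldChangeMatrix(vals, fc.row_ids, fc.col_ids, mask)


def collapse_replicates(fc: FoldChangeMatrix) -> FoldChangeMatrix:
    """Arithmetic mean of retained replicates per protein-metabolite pair."""
    if not fc.has_replicates:
        raise MidasError("replicate axis already collapsed")
    n = np.sum(~np.isnan(fc.values), axis=2)
    if np.any(n < 2):
        raise MidasError("some pairs have fewer than 2 retained replicates")
    return FoldChangeMatrix(
        np.nanmean(fc.values, axis=2), fc.row_ids, fc.col_ids, fc.outlier_mask
    )


def remove_principal_components(
    fc: FoldChangeMatrix, k: int = 3
) -> tuple[FoldChangeMatrix, dict]:
    """Subtract the rank-``k`` principal-component reconstruction.

    Captures pair-nonspecific systematic variation (loading, batch and
    chamber effects) that is shared across metabolites within a protein
    sample.  The matrix is column-centred, the top-k SVD reconstruction
    of the centred matrix is subtracted, and the centres are added back.
    Missing entries are mean-imputed for the SVD and re-masked after.

    Returns the corrected matrix and a report with the fraction of
    (centred) variance removed.
    """
    if fc.has_replicates:
        raise MidasError("collapse replicates before principal-component removal")
    X = fc.values.copy()
    n_rows, n_cols = X.shape
    if not 0 <= k < min(n_rows, n_cols):
        raise MidasError(f"k={k} out of range for a {n_rows}x{n_cols} matrix")
    nan_mask = np.isnan(X)
    if nan_mask.any():
        col_means = np.nanmean(X, axis=0)
        X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])

    center = X.mean(axis=0)
    Xc = X - center
    if k == 0:
        out = fc.values.copy()
        report = {"k": 0, "variance_removed": 0.0, "singular_values": []}
        return FoldChangeMatrix(out, fc.row_ids, fc.col_ids, fc.outlier_mask), report

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n_rows, n_cols) * np.finfo(float).eps))
    if k > rank:
        raise MidasError(f"k={k} exceeds matrix rank {rank}")
    low_rank = (U[:, :k] * s[:k]) @ Vt[:k]
    corrected = Xc - low_rank + center
    corrected[nan_mask] = np.nan
    total_var = float(np.sum(s**2))
    report = {
        "k": k,
        "variance_removed": float(np.sum(s[:k] ** 2) / total_var),
        "singular_values": s.tolist(),
    }
    return FoldChangeMatrix(corrected, fc.row_ids, fc.col_ids, fc.outlier_mask), report


def build_nosignal_model(
    population: np.ndarray, metabolite_id: str = "", sigma_override: float | None = None
) -> NoSignalModel:
    """Robust null model from one metabolite's corrected fold changes.

    centre = median; sigma = IQR / (2 * Phi^-1(0.75)), the normal-
    consistent interquartile extrapolation.  Both are insensitive to the
    (sparse) true binders in the tails of the population.  Quantiles use
    the normal-unbiased plotting positions so the scale is unbiased at
    small population sizes.
    """
    pop = np.asarray(population, dtype=float)
    pop = pop[np.isfinite(pop)]
    if pop.size < 4:
        raise MidasError(f"no-signal population too small (n={pop.size}) for {metabolite_id!r}")
    q25, q75 = np.percentile(pop, [25, 75], method="normal_unbiased")
    if q75 == q25:
        raise MidasError(f"degenerate no-signal population for {metabolite_id!r} (q25 == q75)")
    sigma = (q75 - q25) / NORMAL_IQR_FACTOR if sigma_override is None else sigma_override
    return NoSignalModel(metabolite_id, float(np.median(pop)), float(sigma))


def build_nosignal_models(
    fc: FoldChangeMatrix, prior_df: float = 20.0
) -> list[NoSignalModel]:
    """Per-metabolite no-signal models with empirical-Bayes scale shrinkage.

    The raw quantile-extrapolated sigma has few effective degrees of
    freedom when the screen contains a modest number of protein samples,
    which fattens the null z tails and destroys FDR control.  Each
    metabolite's variance is therefore shrunk toward the pooled variance
    across metabolites, weighting the raw estimate by its effective df
    (0.37 per sample, the IQR estimator's efficiency) against
    ``prior_df`` pseudo-observations of the pooled value.  ``prior_df=0``
    disables shrinkage.
    """
    if fc.has_replicates:
        raise MidasError("collapse replicates before building no-signal models")
    raw = [build_nosignal_model(fc.values[i], mid) for i, mid in enumerate(fc.row_ids)]
    if prior_df <= 0:
        return raw
    n_samples = fc.values.shape[1]
    eff_df = _IQR_RELATIVE_EFFICIENCY * (n_samples - 1)
    pooled_var = float(np.mean([m.sigma**2 for m in raw]))
    out = []
    for m in raw:
        var = (prior_df * pooled_var + eff_df * m.sigma**2) / (prior_df + eff_df)
        out.append(NoSignalModel(m.metabolite_id, m.center, float(np.sqrt(var))))
    return out


def score_interactions(fc_value, model: NoSignalModel):
    """z-score and two-sided normal p-value against a no-signal model.

    Both enrichment (positive z) and depletion (negative z) are real
    signals, hence the two-sided tail.
    """
    z = (np.asarray(fc_value, dtype=float) - model.center) / model.sigma
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(np.maximum(p, np.finfo(float).tiny), 1.0)
    if np.ndim(fc_value) == 0:
        return float(z), float(p)
    return z, p


def call_interactions(
    calls: pd.DataFrame, p_threshold: float = 0.05, q_threshold: float = 0.1
) -> tuple[pd.DataFrame, dict]:
    """Annotate significance and direction; strict-inequality thresholds.

    A pair is significant iff p < p_threshold and q < q_threshold;
    direction is enriched for positive corrected fold change, depleted
    for negative.
    """
    out = calls.copy()
    out["direction"] = np.where(out["corrected_log2fc"] > 0, "enriched", "depleted")
    out["significant"] = (out["p"] < p_threshold) & (out["q"] < q_threshold)
    sig = out[out["significant"]]
    summary = {
        "n_pairs": int(len(out)),
        "n_significant": int(len(sig)),
        "n_enriched": int((sig["direction"] == "enriched").sum()),
        "n_depleted": int((sig["direction"] == "depleted").sum()),
        "p_threshold": p_threshold,
        "q_threshold": q_threshold,
    }
    return out, summary


def run_midas(
    measurements,
    n_pcs: int = 3,
    outlier_cutoff: float = 5.0,
    p_threshold: float = 0.05,
    q_threshold: float = 0.1,
    prior_df: float = 20.0,
) -> tuple[pd.DataFrame, dict]:
    """Full chain: chamber abundances -> significant interaction calls.

    Returns the per-pair call table (corrected_log2fc, z, p, q,
    direction, significant) and a run summary (outlier fraction,
    variance removed, pi0, call counts).
    """
    fc = compute_log2_fold_changes(measurements)
    fc = remove_triplicate_outliers(fc, cutoff=outlier_cutoff)
    n_outliers = int(fc.outlier_mask.sum())
    fc2 = collapse_replicates(fc)
    corrected, pca_report = remove_principal_components(fc2, k=n_pcs)
    models = build_nosignal_models(corrected, prior_df=prior_df)

    records = []
    for i, model in enumerate(models):
        z_row, p_row = score_interactions(corrected.values[i], model)
        for j, protein in enumerate(corrected.col_ids):
            if np.isnan(corrected.values[i, j]):
                continue
            records.append(
                {
                    "protein_id": protein,
                    "metabolite_id": model.metabolite_id,
                    "corrected_log2fc": corrected.values[i, j],
                    "z": z_row[j],
                    "p": p_row[j],
                }
            )
    calls = pd.DataFrame.from_records(records)
    pi0 = estimate_pi0(calls["p"].to_numpy())
    calls["q"] = storey_qvalues(calls["p"].to_numpy(), pi0=pi0)
    calls, summary = call_interactions(calls, p_threshold, q_threshold)
    summary.update(
        {
            "n_outliers_removed": n_outliers,
            "variance_removed": pca_report["variance_removed"],
            "n_pcs_removed": n_pcs,
            "pi0": pi0,
            "prior_df": prior_df,
        }
    )
    return calls, summary
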