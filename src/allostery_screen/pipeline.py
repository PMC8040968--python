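"""Stage orchestration, run manifests and the cross-assay campaign summary.

Every stage reads TSV, writes TSV/JSON, and records its inputs,
parameters and output hashes in a machine-readable manifest; a rerun
from the same inputs and parameters reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as asio
from .dose_response import classify_inhibition, estimate_ki, fit_four_pl
from .dsf import call_stabilizers, compute_delta_tm, fit_melt_curve, truncate_post_peak
from .midas import run_midas
from .spr import fit_steady_state, replicate_concordance

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "midas_stage",
    "dsf_stage",
    "dose_stage",
    "spr_stage",
    "summarize_campaign",
]

logger = logging.getLogger(__name__)

MANIFEST_SCHEMA_VERSION = 1
KNOWN_STAGES = ("midas", "dsf", "dose", "spr")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    stages: list[str] = dc_field(default_factory=list)
    inputs: dict = dc_field(default_factory=dict)  # stage -> TSV path
    output_dir: str = "results"
    p_threshold: float = 0.05
    q_threshold: float = 0.1
    n_pcs: int = 3
    delta_tm_threshold: float = 2.0
    full_inhibition_threshold: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
        for stage in self.stages:
            path = self.inputs.get(stage)
            if path is None or not Path(path).exists():
                raise PipelineError(f"stage '{stage}': input path missing or not found: {path}")
        if not 0 < self.p_threshold < 1 or not 0 < self.q_threshold <= 1:
            raise PipelineError("thresholds out of range")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def midas_stage(input_path: str | Path, outdir: Path, cfg: RunConfig) -> dict:
    df = asio.read_midas_measurements(input_path)
    calls, summary = run_midas(
        df, n_pcs=cfg.n_pcs, p_threshold=cfg.p_threshold, q_threshold=cfg.q_threshold
    )
    out_tsv = asio.write_table(calls, outdir / "midas_calls.tsv")
    out_json = asio.write_json(summary, outdir / "midas_summary.json")
    return {"outputs": [out_tsv, out_json], "summary": summary}


def dsf_stage(input_path: str | Path, outdir: Path, cfg: RunConfig) -> dict:
    curves = asio.table_to_melt_curves(asio.read_table(input_path))
    fits = [fit_melt_curve(truncate_post_peak(c)) for c in curves]
    fit_df = pd.DataFrame(
        [
            {
                "well_id": f.well_id, "ligand_id": f.ligand_id, "tm_C": f.tm,
                "slope_C": f.slope, "f_low": f.f_low, "f_high": f.f_high,
                "r_squared": f.r_squared, "converged": f.converged,
            }
            for f in fits
        ]
    )
    ref_fits = [f for f in fits if f.ligand_id == "DMSO" and f.converged]
    if not ref_fits:
        raise PipelineError("dsf: no converged DMSO reference wells")
    ref_tm = float(np.mean([f.tm for f in ref_fits]))
    deltas = {
        f.ligand_id: f.tm - ref_tm for f in fits if f.converged and f.ligand_id != "DMSO"
    }
    hits = call_stabilizers(deltas, threshold=cfg.delta_tm_threshold)
    delta_df = pd.DataFrame(
        sorted(deltas.items(), key=lambda kv: -kv[1]), columns=["ligand_id", "delta_tm_C"]
    )
    delta_df["hit"] = delta_df["delta_tm_C"] >= cfg.delta_tm_threshold
    out1 = asio.write_table(fit_df, outdir / "dsf_melt_fits.tsv")
    out2 = asio.write_table(delta_df, outdir / "dsf_delta_tm.tsv")
    summary = {
        "n_wells": len(fits),
        "n_converged": int(sum(f.converged for f in fits)),
        "reference_tm_C": ref_tm,
        "n_hits": len(hits),
        "hits": [{"ligand_id": k, "delta_tm_C": v} for k, v in hits],
        "delta_tm_threshold_C": cfg.delta_tm_threshold,
    }
    out3 = asio.write_json(summary, outdir / "dsf_summary.json")
    return {"outputs": [out1, out2, out3], "summary": summary}


def dose_stage(input_path: str | Path, outdir: Path, cfg: RunConfig) -> dict:
    curves = asio.table_to_dose_curves(asio.read_table(input_path))
    rows = []
    for curve in curves:
        fit = fit_four_pl(curve)
        if fit.converged:
            ki, ki_se = estimate_ki(fit)
            cls = classify_inhibition(fit, cfg.full_inhibition_threshold)
        else:
            ki = ki_se = np.nan
            cls = "unconverged"
        rows.append(
            {
                "inhibitor_id": curve.inhibitor_id, "replicate": curve.replicate,
                "ki_M": ki, "ki_se_M": ki_se, "top": fit.top, "bottom": fit.bottom,
                "hill": fit.hill, "residual_fraction": fit.residual_fraction if fit.converged else np.nan,
                "classification": cls, "r_squared": fit.r_squared, "converged": fit.converged,
            }
        )
    fit_df = pd.DataFrame(rows)
    out1 = asio.write_table(fit_df, outdir / "dose_fits.tsv")
    summary = {
        "n_curves": len(curves),
        "n_converged": int(fit_df["converged"].sum()),
        "classifications": fit_df.groupby("inhibitor_id")["classification"].first().to_dict(),
    }
    out2 = asio.write_json(summary, outdir / "dose_summary.json")
    return {"outputs": [out1, out2], "summary": summary}


def spr_stage(input_path: str | Path, outdir: Path, cfg: RunConfig) -> dict:
    series = asio.table_to_spr_series(asio.read_table(input_path))
    rows, by_pair = [], {}
    for rep, s in series:
        fit = fit_steady_state(s)
        rows.append(
            {
                "analyte_id": s.analyte_id, "construct_id": s.ligand_construct_id,
                "replicate": rep, "kd_M": fit.kd, "kd_se_M": fit.kd_se,
                "rmax_RU": fit.rmax, "rmax_se_RU": fit.rmax_se,
                "r_squared": fit.r_squared, "converged": fit.converged,
            }
        )
        by_pair.setdefault((s.analyte_id, s.ligand_construct_id), []).append(fit)
    fit_df = pd.DataFrame(rows)
    conc_rows = []
    for (analyte, construct), fits in by_pair.items():
        if sum(f.converged for f in fits) >= 2:
            cc = replicate_concordance(fits)
            conc_rows.append(
                {
                    "analyte_id": analyte, "construct_id": construct,
                    "n_replicates": cc["n_replicates"],
                    "kd_geometric_mean_M": cc["kd_geometric_mean"],
                    "fold_spread": cc["fold_spread"],
                }
            )
    out1 = asio.write_table(fit_df, outdir / "spr_fits.tsv")
    outputs = [out1]
    summary = {"n_series": len(series), "n_converged": int(fit_df["converged"].sum())}
    if conc_rows:
        out2 = asio.write_table(pd.DataFrame(conc_rows), outdir / "spr_concordance.tsv")
        outputs.append(out2)
    outputs.append(asio.write_json(summary, outdir / "spr_summary.json"))
    return {"outputs": outputs, "summary": summary}


_STAGE_FUNCS = {"midas": midas_stage, "dsf": dsf_stage, "dose": dose_stage, "spr": spr_stage}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a run manifest.

    The manifest records schema version, every input path with its
    sha256, every user-visible parameter, the seed, and every output
    path with its sha256 — sufficient to verify a rerun bit-for-bit.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "stages": list(config.stages),
        "seed": config.seed,
        "parameters": {
            "p_threshold": config.p_threshold,
            "q_threshold": config.q_threshold,
            "n_pcs": config.n_pcs,
            "delta_tm_threshold": config.delta_tm_threshold,
            "full_inhibition_threshold": config.full_inhibition_threshold,
        },
        "inputs": {}, "outputs": {}, "summaries": {},
    }
    for stage in config.stages:
        path = config.inputs[stage]
        manifest["inputs"][stage] = {"path": str(path), "sha256": _sha256(path)}
        logger.info("running stage %s on %s", stage, path)
        try:
            result = _STAGE_FUNCS[stage](path, outdir, config)
        except Exception as exc:
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        manifest["outputs"][stage] = [
            {"path": str(p), "sha256": _sha256(p)} for p in result["outputs"]
        ]
        manifest["summaries"][stage] = result["summary"]
    asio.write_json(manifest, outdir / "run_manifest.json")
    return manifest


def summarize_campaign(
    midas_calls: pd.DataFrame | None = None,
    dsf_deltas: pd.DataFrame | None = None,
    dose_fits: pd.DataFrame | None = None,
    spr_fits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per compound across all assays that saw it.

    Joins thermal shift, Kd, Ki, residual-activity floor and screen
    significance on the shared compound identifier; assays that did not
    test a compound contribute missing values, never a crash.
    """
    pieces = []
    if dsf_deltas is not None:
        d = dsf_deltas.rename(columns={"ligand_id": "compound_id"})
        _check_unique(d, "dsf")
        pieces.append(d.set_index("compound_id")[["delta_tm_C"] + (["hit"] if "hit" in d else [])])
    if spr_fits is not None:
        s = spr_fits.rename(columns={"analyte_id": "compound_id"})
        s = s.groupby("compound_id", as_index=True).agg(
            kd_M=("kd_M", lambda v: float(np.exp(np.mean(np.log(v))))),
        )
        pieces.append(s)
    if dose_fits is not None:
        d = dose_fits.rename(columns={"inhibitor_id": "compound_id"})
        d = d.groupby("compound_id", as_index=True).agg(
            ki_M=("ki_M", "mean"),
            residual_fraction=("residual_fraction", "mean"),
            classification=("classification", "first"),
        )
        pieces.append(d)
    if midas_calls is not None:
        m = midas_calls.rename(columns={"metabolite_id": "compound_id"})
        m = m.sort_values("p").groupby("compound_id", as_index=True).agg(
            midas_significant=("significant", "any"),
            midas_best_q=("q", "min"),
        )
        pieces.append(m)
    if not pieces:
        return pd.DataFrame()
    out = pd.concat(pieces, axis=1, join="outer")
    out.index.name = "compound_id"
    return out.reset_index().sort_values("compound_id", ignore_index=True)


def _check_unique(df: pd.DataFrame, source: str) -> None:
    dup = df["compound_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{source}: duplicate compound identifiers: {sorted(df.loc[dup, 'compound_id'].unique())}"
        )
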