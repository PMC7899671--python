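"""End-to-end orchestration: simulate -> process -> Hill -> linkage -> MWC.

One configured, seeded run produces a synthetic cohort mirroring the study's
constructs, normalizes and summarizes every recording, fits pooled Hill
curves, computes gating energies and the common DZ offset, globally fits the
MWC model on estimated-Po curves, and emits potentiation predictions plus a
human-readable report. All outputs are deterministic for a given
(config, seed) and embed the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import reference_data as ref
from .exceptions import ConfigError
from .hill import PooledHillResults, pooled_fit
from .linkage import fit_common_offset, per_oocyte_energies, sensitivity_table
from .mwc import (MWCGlobalResults, MWCGlobalModel, MWCParams,
                  build_estimated_po_curve, decompose_potentiation,
                  predict_potentiation, standard_scheme)
from .simulate import (Cohort, CohortConfig, ConstructSpec, generate_cohort,
                       write_cohort)
from .traces import process_trace, peaks_frame, summaries_frame

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "default_cohort_config"]

log = logging.getLogger("chanlink.pipeline")

#: Constructs whose estimated-Po curves enter the global MWC fit.
MWC_FIT_CONSTRUCTS = ("L9'T", "L9'T/V279A", "WT")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 1
    constructs: List[str] = field(default_factory=lambda: [
        "L9'T", "L9'T/K278A", "L9'T/V279A", "L9'T/T283A", "WT"])
    n_oocytes: int = 3
    kT: float = ref.KT_ROOM
    po_gaba_max: List[float] = field(default_factory=lambda: [1.0, 0.5])
    offset_exclude: List[str] = field(default_factory=lambda: ["L9'T/V279A"])
    exclude_conc: Dict[str, List[float]] = field(default_factory=dict)
    scheme: str = "standard"
    n_starts: int = 8
    noise_sd: float = 2.0
    rundown_fraction: float = 0.15
    drift_rate_sd: float = 0.02
    amplitude_scale: float = 500.0
    amplitude_cv: float = 0.3
    sample_rate: float = 100.0
    dz_test_conc: float = 1e-6

    def __post_init__(self) -> None:
        unknown = [c for c in self.constructs if c not in ref.KNOWN_CONSTRUCTS]
        if unknown:
            raise ConfigError(f"unknown construct labels: {unknown}")
        if self.scheme != "standard":
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        for c in MWC_FIT_CONSTRUCTS:
            if c not in self.constructs:
                raise ConfigError(
                    f"construct {c!r} is required for the global MWC fit")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - valid
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _conc_grid(ec50: float, n_points: int = 7, decades: float = 2.0):
    return tuple(ec50 * np.logspace(-decades, decades, n_points))


def default_cohort_config(config: RunConfig) -> CohortConfig:
    """Cohort mirroring the study's constructs: MWC ground truth per
    construct, concentration series spanning two decades around each
    reported EC50 (GABA for all; DZ for the spontaneously active L9'T
    background only, where DZ evokes measurable current)."""
    specs = []
    for cid in config.constructs:
        gaba = _conc_grid(ref.HILL_GABA[cid][0]) if cid in ref.HILL_GABA else ()
        dz = _conc_grid(ref.HILL_DZ[cid][0]) if cid in ref.HILL_DZ else ()
        specs.append(ConstructSpec(
            construct_id=cid, mwc=ref.ground_truth_mwc(cid),
            n_oocytes=config.n_oocytes, gaba_concs=gaba, dz_concs=dz))
    return CohortConfig(
        constructs=specs, amplitude_scale=config.amplitude_scale,
        amplitude_cv=config.amplitude_cv, noise_sd=config.noise_sd,
        drift_rate_sd=config.drift_rate_sd,
        rundown_fraction=config.rundown_fraction,
        sample_rate=config.sample_rate)


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    config: RunConfig
    cohort: Cohort
    peaks: pd.DataFrame
    summaries: pd.DataFrame
    construct_means: pd.DataFrame
    hill_fits: Dict[tuple, PooledHillResults]
    hill_table: pd.DataFrame
    energies: pd.DataFrame
    per_oocyte_ddg: pd.DataFrame
    offset: float
    mwc: MWCGlobalResults
    predictions: pd.DataFrame
    report: str

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(self.cohort, outdir / "traces")
        fmt = dict(index=False, float_format="%.10g")
        self.peaks.to_csv(outdir / "peaks.csv", **fmt)
        self.summaries.to_csv(outdir / "summaries.csv", **fmt)
        self.construct_means.to_csv(outdir / "construct_means.csv", **fmt)
        self.hill_table.to_csv(outdir / "hill_fits.csv", **fmt)
        self.energies.to_csv(outdir / "energies.csv", **fmt)
        self.per_oocyte_ddg.to_csv(outdir / "per_oocyte_ddg.csv", **fmt)
        self.predictions.to_csv(outdir / "predictions.csv", **fmt)
        (outdir / "offset.json").write_text(json.dumps(
            {"ddg_common_kcal_mol": self.offset,
             "excluded": list(self.config.offset_exclude)}, indent=1))
        params = {k: v for k, v in self.mwc.params.items()}
        (outdir / "mwc_params.json").write_text(json.dumps(
            {"params": params, "ssr": self.mwc.ssr, "seed": self.mwc.seed,
             "n_starts": self.mwc.n_starts, "scheme": self.config.scheme},
            indent=1, sort_keys=True))
        (outdir / "report.txt").write_text(self.report)
        return outdir


def _fit_all_hill(peaks: pd.DataFrame, exclude_conc: Dict[str, List[float]]):
    fits: Dict[tuple, PooledHillResults] = {}
    rows = []
    for (cid, ligand), grp in peaks[peaks.ligand.isin(["GABA", "DZ"])].groupby(
            ["construct_id", "ligand"], sort=False):
        datasets = []
        for _, sub in grp.groupby("oocyte_id", sort=False):
            datasets.append((sub["concentration_M"].to_numpy(),
                             np.abs(sub["corrected_peak_nA"].to_numpy())))
        res = pooled_fit(datasets, exclude_conc=exclude_conc.get(ligand, ()))
        fits[(cid, ligand)] = res
        rows.append(dict(construct_id=cid, ligand=ligand,
                         EC50_M=res.pooled.ec50, hill_n=res.pooled.n,
                         rss=res.pooled.rss, n_oocytes=len(datasets),
                         n_points=res.pooled.n_points))
    return fits, pd.DataFrame(rows)


def _estimated_curves(hill_fits, means: pd.DataFrame):
    curves = []
    by_construct = means.set_index("construct_id")
    for cid in MWC_FIT_CONSTRUCTS:
        r_pg = float(by_construct.loc[cid, "r_ptx_gaba"])
        po_max = ref.PO_GABA_MAX_WT if cid == "WT" else 1.0
        if (cid, "GABA") in hill_fits:
            curves.append(build_estimated_po_curve(
                hill_fits[(cid, "GABA")].pooled, "GABA", r_pg,
                po_max=po_max, construct_id=cid))
        if (cid, "DZ") in hill_fits:
            r_dp = float(by_construct.loc[cid, "r_dz_ptx"])
            curves.append(build_estimated_po_curve(
                hill_fits[(cid, "DZ")].pooled, "DZ", r_pg, r_dz_ptx=r_dp,
                po_max=po_max, construct_id=cid))
    return curves


def _predictions(mwc: MWCGlobalResults, hill_fits, config: RunConfig) -> pd.DataFrame:
    """Model potentiation of WT and V279A GABA responses by DZ; V279A-in-WT
    L follows from the independence of the two mutations' effects."""
    p_wt = mwc.params_for("WT")
    L_v279a = p_wt.L * mwc.params["L[L9'T/V279A]"] / mwc.params["L[L9'T]"]
    p_v279a = MWCParams(L=L_v279a, K_G=p_wt.K_G, K_D=p_wt.K_D, c=p_wt.c,
                        d=mwc.params["d_V279A"])
    dz = config.dz_test_conc
    rows = []
    for cid, p in (("WT", p_wt), ("V279A", p_v279a)):
        hill = hill_fits.get(("WT", "GABA"))
        ec25 = hill.pooled.ec50 * 3.0 ** (-1.0 / hill.pooled.n) if hill else None
        if ec25 is not None:
            rows.append(dict(construct_id=cid, gaba_M=ec25, dz_M=dz,
                             condition="EC25",
                             potentiation_pct=predict_potentiation(p, ec25, dz)))
        rows.append(dict(construct_id=cid, gaba_M=math.inf, dz_M=dz,
                         condition="saturating",
                         potentiation_pct=predict_potentiation(p, math.inf, dz)))
    frac = decompose_potentiation(p_v279a, p_wt, dz=dz)
    rows.append(dict(construct_id="V279A", gaba_M=math.inf, dz_M=dz,
                     condition="fraction_from_gating_pct", potentiation_pct=frac))
    return pd.DataFrame(rows)


def _report(config, means, hill_table, energies, per_oocyte, offset, mwc,
            predictions) -> str:
    lines = [
        "chanlink pipeline report",
        "========================",
        f"seed: {config.seed}   config hash: {config.hash}",
        "",
        "Per-construct current ratios and DZ gating energy",
        "(mean +/- SD across oocytes; energies in kcal/mol, Po-GABA-max = 1)",
        "",
        f"{'construct':<14s} {'I_PTX/I_GABA-max':>17s} {'I_DZ-max/I_PTX':>15s} {'ddG_DZ':>14s}",
    ]
    poo = per_oocyte.groupby("construct_id", sort=False)["ddG_dz"].agg(["mean", "std", "count"])
    for _, r in means.iterrows():
        cid = r["construct_id"]
        dd = poo.loc[cid] if cid in poo.index else None
        ddg = (f"{dd['mean']:.2f} +/- {dd['std']:.2f}" if dd is not None
               and np.isfinite(dd["std"]) else
               (f"{dd['mean']:.2f}" if dd is not None else "--"))
        r2 = f"{r['r_dz_ptx']:.2f}" if np.isfinite(r.get("r_dz_ptx", np.nan)) else "--"
        lines.append(f"{cid:<14s} {r['r_ptx_gaba']:>17.2f} {r2:>15s} {ddg:>14s}")
    lines += [
        "",
        f"Common DZ offset (unit-slope fit, excluding {config.offset_exclude}): "
        f"{offset:.2f} kcal/mol",
        "",
        "Pooled Hill fits",
        f"{'construct':<14s} {'ligand':<6s} {'EC50':>12s} {'slope':>7s} {'oocytes':>8s}",
    ]
    for _, r in hill_table.iterrows():
        lines.append(f"{r['construct_id']:<14s} {r['ligand']:<6s} "
                     f"{r['EC50_M']:>12.3g} {r['hill_n']:>7.2f} {r['n_oocytes']:>8d}")
    lines += ["", mwc.summary(), "", "Model potentiation predictions (1 uM DZ unless noted)"]
    for _, r in predictions.iterrows():
        g = "sat" if math.isinf(r["gaba_M"]) else f"{r['gaba_M']:.3g} M"
        lines.append(f"  {r['construct_id']:<8s} GABA {g:<10s} {r['condition']:<26s} "
                     f"{r['potentiation_pct']:.1f}%")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig, outdir: Optional[Path] = None) -> PipelineResult:
    """Execute every stage on a synthetic cohort; see the module docstring."""
    log.info("simulating cohort (seed %d)", config.seed)
    cohort_cfg = default_cohort_config(config)
    cohort = generate_cohort(cohort_cfg, config.seed)

    log.info("processing %d traces", len(cohort.traces))
    all_peaks, summaries = [], []
    for trace in cohort.traces:
        ligand = "DZ" if any(e.ligand == "DZ" for e in trace.protocol) else "GABA"
        peaks, summary = process_trace(
            trace, exclude_conc=config.exclude_conc.get(ligand, ()),
            on_rundown_error="identity")
        all_peaks.append(peaks_frame(trace.oocyte_id, trace.construct_id, peaks))
        summaries.append(summary)
    peaks_df = pd.concat(all_peaks, ignore_index=True)
    summaries_df = summaries_frame(summaries)
    means = (summaries_df.groupby("construct_id", sort=False)
             [["r_ptx_gaba", "r_dz_ptx"]].mean().reset_index())

    log.info("fitting Hill curves")
    hill_fits, hill_table = _fit_all_hill(peaks_df, config.exclude_conc)

    log.info("linkage analysis")
    ratio_rows = [(r["construct_id"], r["r_ptx_gaba"], r["r_dz_ptx"])
                  for _, r in means.iterrows()
                  if np.isfinite(r["r_ptx_gaba"]) and np.isfinite(r["r_dz_ptx"])]
    energies = sensitivity_table(ratio_rows, config.po_gaba_max, config.kT)
    per_oocyte = per_oocyte_energies(summaries_df, po_gaba_max=1.0, kT=config.kT)
    base = energies[energies.po_gaba_max == config.po_gaba_max[0]]
    from .linkage import GatingEnergies
    glist = [GatingEnergies(r["construct_id"], r["dG0"], r["dG1"], r["ddG_dz"],
                            r["po_gaba_max"], r["kT"]) for _, r in base.iterrows()]
    offset = fit_common_offset(glist, exclude=config.offset_exclude).offset

    log.info("global MWC fit")
    curves = _estimated_curves(hill_fits, means)
    model = MWCGlobalModel(curves, standard_scheme(MWC_FIT_CONSTRUCTS))
    mwc = model.fit(n_starts=config.n_starts, seed=config.seed)

    predictions = _predictions(mwc, hill_fits, config)
    report = _report(config, means, hill_table, energies, per_oocyte, offset,
                     mwc, predictions)
    result = PipelineResult(
        config=config, cohort=cohort, peaks=peaks_df, summaries=summaries_df,
        construct_means=means, hill_fits=hill_fits, hill_table=hill_table,
        energies=energies, per_oocyte_ddg=per_oocyte, offset=offset, mwc=mwc,
        predictions=predictions, report=report)
    if outdir is not None:
        result.write(outdir)
    return result
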