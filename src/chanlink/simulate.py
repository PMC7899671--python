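"""Synthetic TEVC trace and cohort generation with known ground truth.

Emulates whole-oocyte voltage-clamp recordings of spontaneously active
GABA-A receptors: a PTX-blockable standing current, concentration-dependent
GABA- or DZ-evoked responses governed by an MWC (or Hill-curve) ground
truth, linear baseline drift, linear amplitude rundown across the
recording, mono-exponential pulse kinetics, and additive Gaussian noise.
Every sampled parameter is recorded in a manifest so downstream estimates
can be compared against truth, and identical (config, seed) pairs reproduce
a cohort bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ConfigError, UnknownLigandError
from .mwc import MWCParams, po_mwc
from .hill import hill_response
from .protocol import LIGANDS, PulseEvent, bookended_protocol, validate_protocol
from .traces import Trace, write_trace

__all__ = [
    "HillTruth", "GroundTruth", "ideal_peak", "simulate_trace",
    "ConstructSpec", "CohortConfig", "Cohort", "generate_cohort",
    "regenerate", "corruption_free_twin", "write_cohort",
]


@dataclass(frozen=True)
class HillTruth:
    """Hill-curve generating mechanism for one ligand: the open probability
    runs from ``po0`` (spontaneous) to ``po_max`` along a Hill curve with
    the given EC50 (molar) and slope."""

    ligand: str
    ec50: float
    n: float
    po0: float
    po_max: float

    def po(self, conc: float) -> float:
        return self.po0 + (self.po_max - self.po0) * float(hill_response(conc, self.ec50, self.n))


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for one simulated oocyte.

    Exactly one of ``mwc`` (MWC parameter set) or ``hill`` (per-ligand Hill
    curves sharing a common spontaneous Po) defines the open-probability
    ground truth. ``amplitude_scale`` converts open probability to current
    (nA per unit Po); drift is linear in time, rundown linear between the
    first and last pulse onsets, noise additive Gaussian per sample.
    """

    construct_id: str
    mwc: Optional[MWCParams] = None
    hill: Tuple[HillTruth, ...] = ()
    amplitude_scale: float = 500.0
    drift_rate: float = 0.0
    rundown_fraction: float = 0.0
    noise_sd: float = 0.0
    rise_tau: float = 0.5
    decay_tau: float = 2.0
    desens_tau: Optional[float] = None
    desens_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.mwc is None) == (not self.hill):
            raise ConfigError("exactly one of mwc or hill ground truth is required")
        if not self.amplitude_scale > 0:
            raise ConfigError("amplitude_scale must be > 0")
        if not 0 <= self.rundown_fraction < 1:
            raise ConfigError("rundown_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (self.rise_tau > 0 and self.decay_tau > 0):
            raise ConfigError("rise_tau and decay_tau must be > 0")
        if self.hill:
            po0s = {h.po0 for h in self.hill}
            if len(po0s) > 1:
                raise ConfigError("all HillTruth entries must share the same po0")

    @property
    def po_spont(self) -> float:
        return self.mwc.po0 if self.mwc is not None else self.hill[0].po0

    def po(self, ligand: str, conc: float) -> float:
        if self.mwc is not None:
            if ligand == "GABA":
                return float(po_mwc(self.mwc, conc, 0.0))
            if ligand == "DZ":
                return float(po_mwc(self.mwc, 0.0, conc))
            raise UnknownLigandError(f"no evoked response defined for {ligand!r}")
        for h in self.hill:
            if h.ligand == ligand:
                return h.po(conc)
        raise UnknownLigandError(f"no Hill ground truth for ligand {ligand!r}")


def ideal_peak(truth: GroundTruth, pulse: PulseEvent) -> float:
    """Noise-free peak deflection (nA) a pulse would evoke with no rundown.

    GABA/DZ pulses deflect by amplitude_scale * (Po(conc) - Po(0));
    a PTX pulse blocks the spontaneous current, a deflection of opposite
    sign with magnitude amplitude_scale * Po(0); buffer evokes nothing.
    """
    if pulse.ligand not in LIGANDS:
        raise UnknownLigandError(f"unknown ligand {pulse.ligand!r}")
    if pulse.ligand == "buffer":
        return 0.0
    if pulse.ligand == "PTX":
        return -truth.amplitude_scale * truth.po_spont
    return truth.amplitude_scale * (truth.po(pulse.ligand, pulse.concentration)
                                    - truth.po_spont)


def simulate_trace(
    truth: GroundTruth,
    protocol: Sequence[PulseEvent],
    sample_rate: float = 100.0,
    oocyte_id: Optional[str] = None,
    tail: float = 30.0,
) -> Trace:
    """Synthesize one recording.

    Each pulse contributes a mono-exponential rise toward its plateau
    (optionally with slow mono-exponential desensitization) during the
    application and a mono-exponential decay after washout; the plateau
    amplitude is the ideal peak scaled by the rundown factor at pulse onset
    (1 at the first onset, 1 - rundown_fraction at the last). Linear drift
    and Gaussian noise are added on top.
    """
    if sample_rate < 10:
        raise ConfigError("sample_rate must be >= 10 Hz")
    protocol = list(protocol)
    validate_protocol(protocol)
    t_end = protocol[-1].t_end + tail
    t = np.arange(0.0, t_end, 1.0 / sample_rate)
    y = truth.drift_rate * t

    t_first = protocol[0].t_start
    t_last = protocol[-1].t_start

    def rundown(onset: float) -> float:
        if t_last == t_first:
            return 1.0
        return 1.0 - truth.rundown_fraction * (onset - t_first) / (t_last - t_first)

    for ev in protocol:
        amp = ideal_peak(truth, ev) * rundown(ev.t_start)
        if amp == 0.0:
            continue
        on = (t >= ev.t_start) & (t < ev.t_end)
        dt_on = t[on] - ev.t_start
        resp_on = amp * (1.0 - np.exp(-dt_on / truth.rise_tau))
        if truth.desens_tau is not None and truth.desens_frac > 0:
            resp_on = resp_on * (1.0 - truth.desens_frac
                                 * (1.0 - np.exp(-dt_on / truth.desens_tau)))
        y[on] += resp_on
        end_val = amp * (1.0 - np.exp(-ev.duration / truth.rise_tau))
        if truth.desens_tau is not None and truth.desens_frac > 0:
            end_val *= (1.0 - truth.desens_frac
                        * (1.0 - np.exp(-ev.duration / truth.desens_tau)))
        off = t >= ev.t_end
        y[off] += end_val * np.exp(-(t[off] - ev.t_end) / truth.decay_tau)

    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=t.size)
    oid = oocyte_id if oocyte_id is not None else f"{truth.construct_id}-0"
    return Trace(oid, truth.construct_id, t, y, protocol)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class ConstructSpec:
    """One construct's generating mechanism and recording plan."""

    construct_id: str
    mwc: Optional[MWCParams] = None
    hill: Tuple[HillTruth, ...] = ()
    n_oocytes: int = 3
    gaba_concs: Tuple[float, ...] = ()
    dz_concs: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_oocytes < 1:
            raise ConfigError("n_oocytes must be >= 1")


@dataclass
class CohortConfig:
    """Cohort-level generating conditions.

    Per-oocyte amplitude is log-normal around ``amplitude_scale`` with
    coefficient of variation ``amplitude_cv``; rundown is jittered uniformly
    by ``±rundown_jitter`` (fractional) around ``rundown_fraction``; drift
    rate is drawn Normal(0, ``drift_rate_sd``). Each (construct, ligand
    series) gets ``n_oocytes`` independent recordings.
    """

    constructs: List[ConstructSpec]
    amplitude_scale: float = 500.0
    amplitude_cv: float = 0.3
    noise_sd: float = 2.0
    drift_rate_sd: float = 0.02
    rundown_fraction: float = 0.15
    rundown_jitter: float = 0.5
    rise_tau: float = 0.5
    decay_tau: float = 2.0
    pulse_duration: float = 10.0
    gap: float = 60.0
    ptx_conc: float = 1e-3
    sample_rate: float = 100.0


@dataclass
class Cohort:
    """Simulated traces plus a manifest of every sampled parameter."""

    traces: List[Trace]
    manifest: Dict[str, dict]
    seed: int


def _truth_record(truth: GroundTruth, ligand: str, concs: Sequence[float]) -> dict:
    rec = dataclasses.asdict(truth)
    if truth.mwc is not None:
        rec["mwc"] = {k: v for k, v in dataclasses.asdict(truth.mwc).items()
                      if k != "allow_inverse"}
    rec["series_ligand"] = ligand
    rec["series_concentrations_M"] = list(concs)
    return rec


def generate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Generate one trace per (construct, ligand series, oocyte).

    The master seed is fanned out deterministically: one stream samples the
    per-oocyte parameters, and every oocyte receives its own child seed for
    the trace noise, so regeneration with the same (config, seed) is
    bit-for-bit identical.
    """
    ss = np.random.SeedSequence(seed)
    plan = []
    for spec in config.constructs:
        for ligand, concs in (("GABA", spec.gaba_concs), ("DZ", spec.dz_concs)):
            if not concs:
                continue
            for k in range(spec.n_oocytes):
                plan.append((spec, ligand, tuple(concs), k))
    children = ss.spawn(len(plan) + 1)
    sampler = np.random.default_rng(children[0])
    traces: List[Trace] = []
    manifest: Dict[str, dict] = {}
    log_sd = np.sqrt(np.log1p(config.amplitude_cv ** 2))
    for (spec, ligand, concs, k), child in zip(plan, children[1:]):
        amp = config.amplitude_scale * np.exp(
            sampler.normal(-0.5 * log_sd ** 2, log_sd))
        jit = sampler.uniform(-config.rundown_jitter, config.rundown_jitter)
        rundown = float(np.clip(config.rundown_fraction * (1.0 + jit), 0.0, 0.95))
        drift = float(sampler.normal(0.0, config.drift_rate_sd)) if config.drift_rate_sd > 0 else 0.0
        oocyte_seed = int(child.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
        truth = GroundTruth(
            construct_id=spec.construct_id, mwc=spec.mwc, hill=spec.hill,
            amplitude_scale=float(amp), drift_rate=drift,
            rundown_fraction=rundown, noise_sd=config.noise_sd,
            rise_tau=config.rise_tau, decay_tau=config.decay_tau,
            seed=oocyte_seed,
        )
        protocol = bookended_protocol(ligand, concs, ptx_conc=config.ptx_conc,
                                      duration=config.pulse_duration, gap=config.gap)
        oid = f"{spec.construct_id.replace('/', '_').replace(chr(39), '')}-{ligand}-{k:02d}"
        traces.append(simulate_trace(truth, protocol, config.sample_rate, oocyte_id=oid))
        manifest[oid] = _truth_record(truth, ligand, concs)
    return Cohort(traces, manifest, seed)


def regenerate(cohort: Cohort, config: CohortConfig, **overrides) -> Cohort:
    """Re-simulate every oocyte of a cohort from its manifest, optionally
    overriding GroundTruth fields (e.g. ``drift_rate=0``)."""
    traces = []
    manifest = {}
    for oid, rec in cohort.manifest.items():
        kwargs = {k: v for k, v in rec.items()
                  if k not in ("series_ligand", "series_concentrations_M")}
        if kwargs.get("mwc") is not None:
            kwargs["mwc"] = MWCParams(**kwargs["mwc"])
        kwargs["hill"] = tuple(HillTruth(**h) if isinstance(h, dict) else h
                               for h in kwargs.get("hill", ()))
        kwargs.update(overrides)
        truth = GroundTruth(**kwargs)
        protocol = bookended_protocol(
            rec["series_ligand"], rec["series_concentrations_M"],
            ptx_conc=config.ptx_conc, duration=config.pulse_duration, gap=config.gap)
        traces.append(simulate_trace(truth, protocol, config.sample_rate, oocyte_id=oid))
        manifest[oid] = _truth_record(truth, rec["series_ligand"],
                                      rec["series_concentrations_M"])
    return Cohort(traces, manifest, cohort.seed)


def corruption_free_twin(cohort: Cohort, config: CohortConfig) -> Cohort:
    """The same cohort (same seeds, hence the same noise realizations) with
    drift and rundown switched off — the oracle for normalization tests."""
    return regenerate(cohort, config, drift_rate=0.0, rundown_fraction=0.0)


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write trace CSVs, protocol sidecars and the ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for trace in cohort.traces:
        write_trace(trace, outdir)
    (outdir / "manifest.json").write_text(
        json.dumps({"seed": cohort.seed, "oocytes": cohort.manifest},
                   indent=1, sort_keys=True))
    return outdir
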