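"""Shared builders for synthetic fixtures used across the test suite."""

from __future__ import annotations

import numpy as np

import chanlink as cl

ref = cl.reference_data

#: The fitted global MWC parameter values keyed by global-fit parameter name.
TRUTH_PARAMS = {
    "L[L9'T]": ref.MWC_FITTED["L_L9T"],
    "L[L9'T/V279A]": ref.MWC_FITTED["L_L9T_V279A"],
    "L[WT]": ref.MWC_FITTED["L_WT"],
    "K_G": ref.MWC_FITTED["K_G"],
    "K_D": ref.MWC_FITTED["K_D"],
    "c": ref.MWC_FITTED["c"],
    "d": ref.MWC_FITTED["d"],
    "d_V279A": ref.MWC_FITTED["d_V279A"],
}

CURVE_GRIDS = {
    ("L9'T", "GABA"): (1e-8, 1e-4),
    ("L9'T", "DZ"): (1e-9, 1e-5),
    ("L9'T/V279A", "GABA"): (1e-8, 1e-4),
    ("L9'T/V279A", "DZ"): (1e-9, 1e-5),
    ("WT", "GABA"): (1e-6, 1e-2),
}


def exact_po_curves(noise_frac: float = 0.0, seed: int = 0, n_points: int = 40):
    """Estimated-Po curves computed exactly from the fitted MWC parameters,
    optionally with multiplicative noise (clipped into (0, 1])."""
    rng = np.random.default_rng(seed)
    curves = []
    for (cid, ligand), (lo, hi) in CURVE_GRIDS.items():
        x = np.logspace(np.log10(lo), np.log10(hi), n_points)
        p = ref.fitted_mwc_params(cid)
        po = cl.po_mwc(p, x, 0.0) if ligand == "GABA" else cl.po_mwc(p, 0.0, x)
        if noise_frac > 0:
            po = np.clip(po * (1.0 + rng.normal(0.0, noise_frac, po.shape)),
                         1e-9, 1.0)
        curves.append(cl.EstimatedPoCurve(cid, ligand, x, po))
    return curves


def hill_truth_cohort_config(
    ligand: str,
    ec50: float,
    slope: float,
    n_oocytes: int,
    noise_frac: float,
    po0: float = 0.36,
    po_max: float | None = None,
    sample_rate: float = 50.0,
    **cohort_kwargs,
) -> cl.CohortConfig:
    """Cohort whose evoked responses follow an exact Hill generating curve."""
    if po_max is None:
        po_max = 1.0 if ligand == "GABA" else po0 * 1.35
    truth = (cl.HillTruth(ligand, ec50, slope, po0, po_max),)
    concs = tuple(ec50 * np.logspace(-2, 2, 7))
    spec = cl.ConstructSpec(
        construct_id="L9'T", hill=truth, n_oocytes=n_oocytes,
        gaba_concs=concs if ligand == "GABA" else (),
        dz_concs=concs if ligand == "DZ" else ())
    defaults = dict(amplitude_scale=500.0, noise_sd=noise_frac * 500.0,
                    sample_rate=sample_rate)
    defaults.update(cohort_kwargs)
    return cl.CohortConfig(constructs=[spec], **defaults)


def pooled_ec50_from_cohort(config: cl.CohortConfig, seed: int, ligand: str) -> float:
    """Run the trace pipeline on a cohort and return the pooled Hill EC50."""
    cohort = cl.generate_cohort(config, seed)
    datasets = []
    for trace in cohort.traces:
        peaks, _ = cl.process_trace(trace)
        pts = [(p.concentration, abs(p.corrected_peak))
               for p in peaks if p.ligand == ligand]
        datasets.append(([c for c, _ in pts], [a for _, a in pts]))
    return cl.pooled_fit(datasets).pooled.ec50
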