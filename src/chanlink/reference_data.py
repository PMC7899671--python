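"""Tabulated reference inputs for the diazepam/GABA-A gating analysis.

These are the construct-level measurements and fitted model parameters from
the original two-electrode voltage-clamp study of diazepam (DZ) modulation
in the spontaneously active alpha1-L9'T background: mean current-amplitude
ratios per construct, Hill fit parameters of the pooled concentration-response
relationships, and the globally fitted MWC parameters. They serve three roles:

* inputs to the linkage analysis (the ratio table is the published data);
* ground-truth settings for the synthetic-data generator, so that simulated
  cohorts reproduce the study's conditions;
* defaults for efficiency/potentiation calculations.

All concentrations are in molar, energies in kcal/mol, currents in nA.
"""

from __future__ import annotations

from .mwc import MWCParams

#: kT at 298.15 K, kcal/mol (room-temperature thermodynamic convention).
KT_ROOM = 0.5925

#: Open probability in saturating GABA for wild-type receptors.
PO_GABA_MAX_WT = 0.85

#: Mean current-amplitude ratios per construct (L9'T background):
#: (I_PTX/I_GABA-max, sd, n) and (I_DZ-max/I_PTX, sd, n), plus the
#: reported per-oocyte DZ gating energy (ddG, sd, n) in kcal/mol.
CURRENT_RATIOS: dict[str, dict[str, float | int]] = {
    "L9'T": dict(r_ptx_gaba=0.36, r_ptx_gaba_sd=0.04, n_gaba=5,
                 r_dz_ptx=1.35, r_dz_ptx_sd=0.05, n_dz=5,
                 ddg=-0.31, ddg_sd=0.04, n_ddg=5),
    "L9'T/L276A": dict(r_ptx_gaba=0.22, r_ptx_gaba_sd=0.09, n_gaba=4,
                       r_dz_ptx=1.62, r_dz_ptx_sd=0.07, n_dz=5,
                       ddg=-0.45, ddg_sd=0.04, n_ddg=5),
    "L9'T/P277A": dict(r_ptx_gaba=0.45, r_ptx_gaba_sd=0.03, n_gaba=3,
                       r_dz_ptx=1.41, r_dz_ptx_sd=0.17, n_dz=5,
                       ddg=-0.46, ddg_sd=0.20, n_ddg=5),
    "L9'T/K278A": dict(r_ptx_gaba=0.20, r_ptx_gaba_sd=0.06, n_gaba=5,
                       r_dz_ptx=1.67, r_dz_ptx_sd=0.15, n_dz=4,
                       ddg=-0.44, ddg_sd=0.08, n_ddg=4),
    "L9'T/V279A": dict(r_ptx_gaba=0.17, r_ptx_gaba_sd=0.04, n_gaba=4,
                       r_dz_ptx=3.30, r_dz_ptx_sd=0.70, n_dz=5,
                       ddg=-1.11, ddg_sd=0.30, n_ddg=5),
    "L9'T/V279D": dict(r_ptx_gaba=0.02, r_ptx_gaba_sd=0.005, n_gaba=3,
                       r_dz_ptx=2.31, r_dz_ptx_sd=0.08, n_dz=3,
                       ddg=-0.52, ddg_sd=0.02, n_ddg=3),
    "L9'T/V279W": dict(r_ptx_gaba=0.16, r_ptx_gaba_sd=0.05, n_gaba=2,
                       r_dz_ptx=1.96, r_dz_ptx_sd=0.23, n_dz=3,
                       ddg=-0.53, ddg_sd=0.10, n_ddg=3),
    "L9'T/Y281A": dict(r_ptx_gaba=0.25, r_ptx_gaba_sd=0.07, n_gaba=5,
                       r_dz_ptx=1.59, r_dz_ptx_sd=0.11, n_dz=4,
                       ddg=-0.42, ddg_sd=0.07, n_ddg=4),
    "L9'T/T283A": dict(r_ptx_gaba=0.11, r_ptx_gaba_sd=0.03, n_gaba=5,
                       r_dz_ptx=1.71, r_dz_ptx_sd=0.10, n_dz=6,
                       ddg=-0.38, ddg_sd=0.04, n_ddg=6),
}

#: Reported common DZ gating energy of the unit-slope line through all
#: constructs except the L9'T/V279A outlier, kcal/mol.
DDG_COMMON = -0.4

#: Pooled Hill fit parameters for GABA-evoked currents: (EC50 [M], slope, n oocytes).
HILL_GABA: dict[str, tuple[float, float, int]] = {
    "L9'T": (0.25e-6, 0.83, 7),
    "L9'T/L276A": (1.53e-6, 1.51, 4),
    "L9'T/P277A": (1.48e-6, 0.80, 3),
    "L9'T/K278A": (0.99e-6, 0.79, 5),
    "L9'T/V279A": (0.23e-6, 1.44, 4),
    "L9'T/Y281A": (0.42e-6, 1.23, 5),
    "L9'T/T283A": (1.08e-6, 0.67, 5),
    "L9'T/V279D": (13e-6, 0.68, 3),
    "L9'T/V279W": (1.4e-6, 0.65, 2),
    "WT": (28e-6, 1.2, 3),
    "V279A": (222e-6, 0.7, 4),
}

#: Pooled Hill fit parameters for DZ-evoked currents (L9'T background).
HILL_DZ: dict[str, tuple[float, float, int]] = {
    "L9'T": (85e-9, 1.10, 5),
    "L9'T/L276A": (380e-9, 0.61, 8),
    "L9'T/P277A": (67e-9, 1.24, 5),
    "L9'T/K278A": (72e-9, 0.97, 4),
    "L9'T/V279A": (110e-9, 0.98, 5),
    "L9'T/Y281A": (56e-9, 1.14, 4),
    "L9'T/T283A": (60e-9, 1.42, 6),
    "L9'T/V279D": (0.88e-6, 0.58, 3),
    "L9'T/V279W": (0.23e-6, 0.90, 3),
}

#: Globally fitted MWC parameters (shared K_G, K_D, c; per-construct L;
#: d shared between WT and L9'T, separate with the V279A mutation).
MWC_FITTED: dict[str, float] = {
    "L_L9T": 1.8,
    "L_L9T_V279A": 4.4,
    "L_WT": 18000.0,
    "K_G": 53e-6,
    "K_D": 180e-9,
    "c": 0.0031,
    "d": 0.59,
    "d_V279A": 0.20,
}

KNOWN_CONSTRUCTS: tuple[str, ...] = tuple(CURRENT_RATIOS) + ("WT", "V279A")


def fitted_mwc_params(construct: str) -> MWCParams:
    """Return the globally fitted MWC parameter set for one construct.

    ``"V279A"`` (the single mutant in a wild-type background) uses the
    independence assumption for L: L_V279A = L_WT * (L_L9'T/V279A / L_L9'T).
    """
    f = MWC_FITTED
    shared = dict(K_G=f["K_G"], K_D=f["K_D"], c=f["c"])
    if construct == "L9'T":
        return MWCParams(L=f["L_L9T"], d=f["d"], **shared)
    if construct == "L9'T/V279A":
        return MWCParams(L=f["L_L9T_V279A"], d=f["d_V279A"], **shared)
    if construct == "WT":
        return MWCParams(L=f["L_WT"], d=f["d"], **shared)
    if construct == "V279A":
        L = f["L_WT"] * f["L_L9T_V279A"] / f["L_L9T"]
        return MWCParams(L=L, d=f["d_V279A"], **shared)
    raise KeyError(f"no fitted MWC parameters for construct {construct!r}")


def ground_truth_mwc(construct: str) -> MWCParams:
    """MWC parameter set used as simulation ground truth for a construct.

    The three constructs of the global fit use the fitted parameters directly.
    For the remaining L9'T-background linker mutants, L and d are derived from
    their mean current ratios (L = (1-Po0)/Po0 with Po0 = I_PTX/I_GABA-max;
    d = (1/Po1 - 1)/L with Po1 = Po0 * I_DZ-max/I_PTX) under shared K_G, K_D
    and c, i.e. mutations perturb the gating equilibrium only.
    """
    try:
        return fitted_mwc_params(construct)
    except KeyError:
        pass
    row = CURRENT_RATIOS[construct]
    po0 = float(row["r_ptx_gaba"])
    po1 = po0 * float(row["r_dz_ptx"])
    L = (1.0 - po0) / po0
    d = (1.0 / po1 - 1.0) / L
    f = MWC_FITTED
    return MWCParams(L=L, K_G=f["K_G"], K_D=f["K_D"], c=f["c"], d=min(d, 1.0))
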