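"""Two-state Monod-Wyman-Changeux (MWC) allosteric model of GABA-A receptor gating.

The receptor equilibrates between a closed (C) and an open (O) pore
conformation. Two equivalent GABA sites and one benzodiazepine (diazepam, DZ)
site bind independently. ``L`` is the closed/open probability ratio with no
ligand bound; each bound GABA multiplies the gating equilibrium by ``c`` and
a bound DZ multiplies it by ``d`` (both in (0, 1] for positive modulators,
equivalently the open state binds with the higher affinities ``c*K_G`` and
``d*K_D``). The open probability at GABA concentration G and DZ concentration
D is

    Po = 1 / (1 + L * [(1 + G/K_G) / (1 + G/(c K_G))]^2
                    * [(1 + D/K_D) / (1 + D/(d K_D))])

This module provides the closed form (`po_mwc`), a 12-state partition-function
enumeration used as an independent oracle (`po_enumerate`), estimated-Po curve
construction from Hill fits and current ratios, a global multi-construct
fitter with parameter sharing (`MWCGlobalModel`), ligand efficiency, and
potentiation prediction/decomposition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .exceptions import CurveScalingError, IdentifiabilityWarning

__all__ = [
    "MWCParams", "EstimatedPoCurve", "po_mwc", "po_enumerate",
    "ligand_efficiency", "wt_L_from_ec50", "build_estimated_po_curve",
    "ConstructParamNames", "FitScheme", "standard_scheme", "front_face_scheme",
    "MWCGlobalModel", "MWCGlobalResults",
    "predict_potentiation", "decompose_potentiation",
]

N_GABA_SITES = 2
N_DZ_SITES = 1


@dataclass(frozen=True)
class MWCParams:
    """Parameter set of the two-state MWC scheme for one construct.

    Parameters
    ----------
    L : unliganded closed/open probability ratio (> 0).
    K_G, K_D : closed-state dissociation constants for GABA and DZ, molar.
    c, d : factors by which each bound GABA / DZ multiplies the gating
        equilibrium; (0, 1] in the positive-modulator regime. Pass
        ``allow_inverse=True`` to permit d > 1 (inverse agonists).
    """

    L: float
    K_G: float
    K_D: float
    c: float
    d: float
    allow_inverse: bool = False

    def __post_init__(self) -> None:
        for name in ("L", "K_G", "K_D", "c", "d"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"MWCParams.{name} must be finite and > 0, got {v!r}")
        if not self.allow_inverse:
            if self.c > 1 or self.d > 1:
                raise ValueError(
                    "c and d must be <= 1 for positive modulators "
                    "(set allow_inverse=True for inverse agonists)"
                )

    @property
    def po0(self) -> float:
        """Unliganded open probability, 1/(1+L)."""
        return 1.0 / (1.0 + self.L)


def _site_factor(x, K: float, f: float):
    """Closed/open weight ratio contributed by one site class at concentration x.

    (1 + x/K) / (1 + x/(f K)); the x -> inf limit is f.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be >= 0")
    inf = np.isinf(x)
    xf = np.where(inf, 0.0, x)
    ratio = (1.0 + xf / K) / (1.0 + xf / (f * K))
    out = np.where(inf, f, ratio)
    return out if out.ndim else float(out)


def po_mwc(params: MWCParams, gaba=0.0, dz=0.0):
    """Open probability of the MWC scheme (closed form).

    ``gaba`` and ``dz`` are molar concentrations (scalars or arrays,
    broadcast together); ``np.inf`` takes the analytic saturating limit.
    """
    fG = _site_factor(gaba, params.K_G, params.c)
    fD = _site_factor(dz, params.K_D, params.d)
    out = 1.0 / (1.0 + params.L * np.asarray(fG) ** N_GABA_SITES * np.asarray(fD) ** N_DZ_SITES)
    return out if out.ndim else float(out)


def po_enumerate(params: MWCParams, gaba: float = 0.0, dz: float = 0.0) -> float:
    """Open probability by brute-force enumeration of all 12 states.

    States are (conformation in {C, O}) x (GABA occupancy 0..2, binomial
    degeneracy) x (DZ occupancy 0..1). Open-state weights use the higher
    affinities c*K_G and d*K_D; closed-state weights carry the factor L.
    Independent oracle for :func:`po_mwc`; scalar, finite concentrations only.
    """
    g, z = float(gaba), float(dz)
    if g < 0 or z < 0:
        raise ValueError("concentrations must be >= 0")
    if math.isinf(g) or math.isinf(z):
        raise ValueError("enumeration requires finite concentrations")
    z_open = 0.0
    z_closed = 0.0
    for i in range(N_GABA_SITES + 1):
        for j in range(N_DZ_SITES + 1):
            deg = math.comb(N_GABA_SITES, i) * math.comb(N_DZ_SITES, j)
            z_open += deg * (g / (params.c * params.K_G)) ** i * (z / (params.d * params.K_D)) ** j
            z_closed += params.L * deg * (g / params.K_G) ** i * (z / params.K_D) ** j
    return z_open / (z_open + z_closed)


def ligand_efficiency(K: float, factor: float) -> float:
    """Ligand efficiency in percent: [1 - log(K) / log(factor*K)] * 100.

    The fraction of a ligand's binding energy converted into gating energy.
    ``K`` must be in molar (the logs are of molar-valued quantities, so the
    result is unit-convention dependent); ``factor`` is the gating factor
    (c or d). factor = 1 gives 0%.
    """
    if not (K > 0 and factor > 0):
        raise ValueError("K and factor must be > 0")
    denom = math.log10(factor * K)
    if abs(denom) < 1e-12:
        raise ValueError("factor*K = 1 M: efficiency undefined (log(factor*K) = 0)")
    return (1.0 - math.log10(K) / denom) * 100.0


def wt_L_from_ec50(L_l9t: float, ec50_wt: float, ec50_l9t: float) -> float:
    """Map the L9'T gating equilibrium to wild-type via the approximate
    relation L_WT = L_L9'T * (EC50_WT / EC50_L9'T)**2."""
    if not (L_l9t > 0 and ec50_wt > 0 and ec50_l9t > 0):
        raise ValueError("all inputs must be > 0")
    return L_l9t * (ec50_wt / ec50_l9t) ** 2


# ---------------------------------------------------------------------------
# Estimated-Po curves
# ---------------------------------------------------------------------------

@dataclass
class EstimatedPoCurve:
    """Open-probability estimate versus concentration for one construct/ligand.

    Built by rescaling a normalized Hill concentration-response fit so that
    its endpoints match the spontaneous and maximal open probabilities implied
    by the measured current-amplitude ratios.
    """

    construct_id: str
    ligand: str  # "GABA" or "DZ"
    concentrations: np.ndarray
    po: np.ndarray
    po_max_free: bool = False

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.po = np.asarray(self.po, dtype=float)
        if self.ligand not in ("GABA", "DZ"):
            raise ValueError("ligand must be 'GABA' or 'DZ'")
        if self.concentrations.shape != self.po.shape:
            raise ValueError("concentrations and po must have the same shape")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.po = self.po[order]
        if np.any(self.po < -1e-9) or np.any(self.po > 1 + 1e-9):
            raise CurveScalingError("estimated Po outside [0, 1]")


def build_estimated_po_curve(
    hill,
    ligand: str,
    r_ptx_gaba: float,
    r_dz_ptx: float | None = None,
    po_max: float = 1.0,
    concentrations: Sequence[float] | np.ndarray | None = None,
    construct_id: str = "",
    n_points: int = 40,
    po_max_free: bool = False,
) -> EstimatedPoCurve:
    """Scale a Hill fit into an estimated open-probability curve.

    GABA curves run from the spontaneous level Po_spont = po_max * r_ptx_gaba
    up to ``po_max``. DZ curves run from Po_spont up to
    Po_spont * r_dz_ptx (rejected if that exceeds 1).

    ``hill`` is a :class:`~chanlink.hill.HillResults`; ``concentrations``
    defaults to ``n_points`` log-spaced values over the fit's data range.
    """
    if not 0 < po_max <= 1:
        raise ValueError("po_max must be in (0, 1]")
    po_spont = po_max * r_ptx_gaba
    if not 0 <= po_spont <= 1:
        raise CurveScalingError(f"po_max * r_ptx_gaba = {po_spont:.3g} outside [0, 1]")
    if concentrations is None:
        lo, hi = hill.conc_range
        concentrations = np.logspace(np.log10(lo), np.log10(hi), n_points)
    x = np.asarray(concentrations, dtype=float)
    frac = hill.fraction(x)
    if ligand == "GABA":
        top = po_max
    elif ligand == "DZ":
        if r_dz_ptx is None:
            raise ValueError("r_dz_ptx is required for a DZ curve")
        top = po_spont * r_dz_ptx
        if top > 1 + 1e-9:
            raise CurveScalingError(
                f"implied maximal DZ-evoked Po = {top:.3g} > 1 "
                f"(po_max={po_max}, r_ptx_gaba={r_ptx_gaba}, r_dz_ptx={r_dz_ptx})"
            )
    else:
        raise ValueError("ligand must be 'GABA' or 'DZ'")
    po = po_spont + (top - po_spont) * frac
    return EstimatedPoCurve(construct_id, ligand, x, po, po_max_free=po_max_free)


# ---------------------------------------------------------------------------
# Global fitting with parameter sharing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstructParamNames:
    """Names of the global-fit parameters a construct's curves draw from."""

    L: str
    K_G: str = "K_G"
    c: str = "c"
    K_D: str = "K_D"
    d: str = "d"


@dataclass
class FitScheme:
    """Parameter-sharing scheme of a global MWC fit.

    ``mapping`` assigns each construct the parameter names for its L, K_G, c,
    K_D and d; constructs sharing a name share that parameter. ``fixed`` pins
    named parameters to constants (removed from the free set).
    """

    mapping: Dict[str, ConstructParamNames]
    fixed: Dict[str, float] = field(default_factory=dict)


def standard_scheme(constructs: Iterable[str] = ("L9'T", "L9'T/V279A", "WT")) -> FitScheme:
    """The study's sharing scheme: shared K_G, K_D, c; per-construct L;
    d shared across constructs except those carrying the V279A mutation,
    which get a separate ``d_V279A``."""
    mapping = {}
    for cid in constructs:
        dname = "d_V279A" if "V279A" in cid else "d"
        mapping[cid] = ConstructParamNames(L=f"L[{cid}]", d=dname)
    return FitScheme(mapping)


def front_face_scheme(
    constructs: Iterable[str],
    *,
    per_construct_K_G: bool = False,
    per_construct_c: bool = False,
    fixed: Mapping[str, float] | None = None,
) -> FitScheme:
    """GABA-only ("front face", no DZ) scheme variants.

    With both flags False all constructs share K_G and c and differ only in
    L; the flags give each construct its own K_G and/or c. ``fixed`` can pin
    e.g. per-construct L values derived from unliganded Po.
    """
    mapping = {}
    for cid in constructs:
        mapping[cid] = ConstructParamNames(
            L=f"L[{cid}]",
            K_G=f"K_G[{cid}]" if per_construct_K_G else "K_G",
            c=f"c[{cid}]" if per_construct_c else "c",
        )
    return FitScheme(mapping, dict(fixed or {}))


_ROLE_BOUNDS_LOG10 = {  # search bounds per parameter role, log10 units
    "L": (-6.0, 9.0),
    "K": (-12.0, 0.0),
    "factor": (-8.0, 0.0),
}


class MWCGlobalModel:
    """Global fit of the MWC scheme to a set of estimated-Po curves.

    Minimizes the summed squared residual between the closed-form open
    probability and every curve point, with parameters shared across
    constructs according to ``scheme`` (default: :func:`standard_scheme`
    over the constructs present). Positive parameters are optimized in
    log10 space by bounded least squares from a data-driven initial guess
    plus Latin-hypercube multi-starts.
    """

    def __init__(self, curves: Sequence[EstimatedPoCurve], scheme: FitScheme | None = None):
        if not curves:
            raise ValueError("at least one curve is required")
        self.curves = list(curves)
        constructs = list(dict.fromkeys(c.construct_id for c in self.curves))
        self.scheme = scheme if scheme is not None else standard_scheme(constructs)
        for cid in constructs:
            if cid not in self.scheme.mapping:
                raise ValueError(f"scheme has no parameter mapping for construct {cid!r}")
        self._compile()

    # -- parameter bookkeeping ------------------------------------------------
    def _compile(self) -> None:
        roles: Dict[str, str] = {}
        used: list[str] = []
        for curve in self.curves:
            names = self.scheme.mapping[curve.construct_id]
            touched = [("L", names.L)]
            if curve.ligand == "GABA":
                touched += [("K", names.K_G), ("factor", names.c)]
            else:
                touched += [("K", names.K_D), ("factor", names.d)]
            for role, name in touched:
                if name not in roles:
                    roles[name] = role
                    used.append(name)
                elif roles[name] != role:
                    raise ValueError(f"parameter {name!r} used in conflicting roles")
        self.param_roles = roles
        self.free_names = [n for n in used if n not in self.scheme.fixed]
        n_free, n_curves = len(self.free_names), len(self.curves)
        if n_free > 3 * n_curves:
            warnings.warn(
                f"{n_free} free parameters for {n_curves} curves: "
                "the scheme is likely non-identifiable",
                IdentifiabilityWarning,
                stacklevel=3,
            )

    def _values(self, theta: np.ndarray) -> Dict[str, float]:
        values = {name: 10.0 ** t for name, t in zip(self.free_names, theta)}
        values.update(self.scheme.fixed)
        return values

    def params_from_values(self, values: Mapping[str, float], construct: str) -> MWCParams:
        names = self.scheme.mapping[construct]
        def get(name: str, default: float) -> float:
            return float(values.get(name, default))
        # Parameters untouched by any curve (e.g. K_D/d in a GABA-only fit)
        # fall back to inert defaults.
        return MWCParams(
            L=get(names.L, 1.0),
            K_G=get(names.K_G, 1e-6),
            c=get(names.c, 1.0),
            K_D=get(names.K_D, 1e-6),
            d=get(names.d, 1.0),
        )

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        values = self._values(theta)
        res = []
        for curve in self.curves:
            p = self.params_from_values(values, curve.construct_id)
            if curve.ligand == "GABA":
                model = po_mwc(p, curve.concentrations, 0.0)
            else:
                model = po_mwc(p, 0.0, curve.concentrations)
            res.append(model - curve.po)
        return np.concatenate(res)

    # -- initialisation -------------------------------------------------------
    @staticmethod
    def _half_point(conc: np.ndarray, po: np.ndarray) -> float:
        mid = 0.5 * (po[0] + po[-1])
        if po[-1] <= po[0]:
            return float(np.sqrt(conc[0] * conc[-1]))
        return float(np.interp(mid, po, conc))

    def initial_guess(self) -> Dict[str, float]:
        """Moment-style starting values read off the curves themselves:
        L from the spontaneous level, c/d from the asymptote, K from the
        half-activation concentration."""
        from collections import defaultdict

        ests: Dict[str, list] = defaultdict(list)
        L_by_construct: Dict[str, float] = {}
        for curve in self.curves:  # L first: needed for factor/K estimates
            po_min = max(float(np.min(curve.po)), 1e-9)
            L_est = (1.0 - po_min) / po_min
            names = self.scheme.mapping[curve.construct_id]
            ests[names.L].append(L_est)
            L_by_construct.setdefault(curve.construct_id, L_est)
        for curve in self.curves:
            names = self.scheme.mapping[curve.construct_id]
            L_est = L_by_construct[curve.construct_id]
            po_max = min(float(np.max(curve.po)), 1.0 - 1e-12)
            n_sites = N_GABA_SITES if curve.ligand == "GABA" else N_DZ_SITES
            f_name = names.c if curve.ligand == "GABA" else names.d
            K_name = names.K_G if curve.ligand == "GABA" else names.K_D
            B_sat = max((1.0 / po_max - 1.0) / L_est, 1e-16)
            f_est = float(np.clip(B_sat ** (1.0 / n_sites), 1e-8, 1.0))
            ests[f_name].append(f_est)
            x_half = self._half_point(curve.concentrations, curve.po)
            po_mid = 0.5 * (float(curve.po[0]) + po_max)
            B_mid = max((1.0 / po_mid - 1.0) / L_est, 1e-16)
            s = B_mid ** (1.0 / n_sites)
            if f_est < s < 1.0:
                K_est = x_half * (1.0 - s / f_est) / (s - 1.0)
            else:
                K_est = x_half
            ests[K_name].append(float(np.clip(K_est, 1e-12, 1.0)))
        init = {}
        for name in self.free_names:
            vals = ests.get(name)
            if vals:
                init[name] = float(10 ** np.mean(np.log10(vals)))
            else:
                lo, hi = _ROLE_BOUNDS_LOG10[self.param_roles[name]]
                init[name] = 10.0 ** (0.5 * (lo + hi))
        return init

    # -- fitting --------------------------------------------------------------
    def fit(self, n_starts: int = 8, seed: int = 0, spread: float = 1.5) -> "MWCGlobalResults":
        """Run the global fit.

        ``n_starts`` optimizations: one from the data-driven initial guess,
        the rest from a seeded Latin hypercube of width ``2*spread`` decades
        around it (clipped to the role bounds). Returns the best by SSR.
        """
        lo = np.array([_ROLE_BOUNDS_LOG10[self.param_roles[n]][0] for n in self.free_names])
        hi = np.array([_ROLE_BOUNDS_LOG10[self.param_roles[n]][1] for n in self.free_names])
        init = self.initial_guess()
        theta0 = np.clip([np.log10(init[n]) for n in self.free_names], lo + 1e-9, hi - 1e-9)
        starts = [theta0]
        if n_starts > 1:
            sampler = qmc.LatinHypercube(d=len(self.free_names), seed=seed)
            unit = sampler.random(n_starts - 1)
            starts += list(np.clip(theta0 + (2 * unit - 1) * spread, lo + 1e-9, hi - 1e-9))
        best = None
        costs = []
        for x0 in starts:
            sol = least_squares(self._residuals, x0, bounds=(lo, hi), method="trf")
            costs.append(2.0 * sol.cost)
            if best is None or sol.cost < best.cost:
                best = sol
        assert best is not None
        values = self._values(best.x)
        per_curve = {}
        offset = 0
        for curve in self.curves:
            n = curve.po.size
            r = best.fun[offset:offset + n]
            per_curve[(curve.construct_id, curve.ligand)] = float(np.sum(r ** 2))
            offset += n
        try:
            cond = float(np.linalg.cond(best.jac))
        except np.linalg.LinAlgError:  # pragma: no cover
            cond = float("inf")
        if not np.isfinite(cond) or cond > 1e10:
            warnings.warn(
                f"ill-conditioned global fit (condition number {cond:.2g})",
                IdentifiabilityWarning,
                stacklevel=2,
            )
        return MWCGlobalResults(
            model=self,
            params=values,
            ssr=float(2.0 * best.cost),
            per_curve_ssr=per_curve,
            n_starts=len(starts),
            start_ssrs=costs,
            seed=seed,
            condition_number=cond,
            success=bool(best.success),
        )


@dataclass
class MWCGlobalResults:
    """Fitted global MWC parameters with residual diagnostics."""

    model: MWCGlobalModel
    params: Dict[str, float]
    ssr: float
    per_curve_ssr: Dict[tuple, float]
    n_starts: int
    start_ssrs: list
    seed: int
    condition_number: float
    success: bool

    def params_for(self, construct: str) -> MWCParams:
        """Assemble the per-construct MWCParams from the shared parameter set."""
        return self.model.params_from_values(self.params, construct)

    def predict_po(self, construct: str, gaba=0.0, dz=0.0):
        return po_mwc(self.params_for(construct), gaba, dz)

    def summary(self) -> str:
        lines = [
            "Global MWC fit",
            "==============",
            f"curves: {len(self.model.curves)}   free parameters: {len(self.model.free_names)}",
            f"SSR: {self.ssr:.6g}   multi-starts: {self.n_starts} (seed {self.seed})",
            f"condition number: {self.condition_number:.3g}   converged: {self.success}",
            "",
            "parameter        value",
        ]
        for name in self.model.free_names:
            lines.append(f"{name:<16s} {self.params[name]:.6g}")
        for name, v in self.model.scheme.fixed.items():
            lines.append(f"{name:<16s} {v:.6g}  (fixed)")
        lines.append("")
        lines.append("per-curve SSR:")
        for (cid, ligand), s in self.per_curve_ssr.items():
            lines.append(f"  {cid:<14s} {ligand:<5s} {s:.3g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Potentiation
# ---------------------------------------------------------------------------

def predict_potentiation(params: MWCParams, gaba, dz) -> float:
    """Percent increase of the GABA-evoked response caused by co-applied DZ:
    100 * (Po(gaba, dz) - Po(gaba, 0)) / Po(gaba, 0).

    ``gaba`` may be ``np.inf`` for the saturating limit.
    """
    base = po_mwc(params, gaba, 0.0)
    if base == 0:
        raise ZeroDivisionError("Po(gaba, 0) = 0: potentiation undefined")
    return 100.0 * (po_mwc(params, gaba, dz) - base) / base


def decompose_potentiation(
    mutant: MWCParams,
    reference: MWCParams,
    dz: float = 1e-6,
    gaba: float = math.inf,
) -> float:
    """Fraction (percent) of a mutant's predicted potentiation accounted for
    purely by its altered gating equilibrium (lower maximal Po), rather than
    by its change in DZ gating (d).

    Computed as potentiation with the mutant's L but the reference's d,
    divided by potentiation with the mutant's own d, at saturating GABA by
    default. Requires the two parameter sets to share K_D.
    """
    if not math.isclose(mutant.K_D, reference.K_D, rel_tol=1e-9):
        raise ValueError("mutant and reference must share K_D")
    hybrid = replace(mutant, d=reference.d)
    denom = predict_potentiation(mutant, gaba, dz)
    if denom == 0:
        raise ZeroDivisionError("mutant potentiation is 0: decomposition undefined")
    return 100.0 * predict_potentiation(hybrid, gaba, dz) / denom
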