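"""Closed<->open gating free energies and DZ linkage analysis.

A two-state (closed C, open O) approximation assigns each liganded condition
a gating free energy dG = -kT ln(Po/(1-Po)). From whole-oocyte current
ratios, the unliganded open probability is Po0 = Po_GABA_max * I_PTX/I_GABA-max
and the DZ-bound open probability is Po1 = Po0 * I_DZ-max/I_PTX, where
Po_GABA_max is the assumed open probability in saturating GABA (~1 for the
gain-of-function L9'T background). The drug's energetic contribution to pore
opening is ddG_DZ = dG1 - dG0; negative values favour opening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import LinkageError

__all__ = [
    "GatingEnergies", "gating_free_energy", "energies_from_ratios", "ddg_dz",
    "CommonOffsetFit", "fit_common_offset", "sensitivity_table",
    "per_oocyte_energies",
]

from .reference_data import KT_ROOM


@dataclass(frozen=True)
class GatingEnergies:
    """Gating free energies of one construct under stated assumptions.

    dG0/dG1 are the closed->open free energies unliganded and DZ-bound
    (kcal/mol); ddG_dz = dG1 - dG0 is DZ's contribution to pore opening.
    """

    construct_id: str
    dG0: float
    dG1: float
    ddG_dz: float
    po_gaba_max: float
    kT: float


def gating_free_energy(po: float, kT: float = KT_ROOM) -> float:
    """Closed->open gating free energy -kT ln(Po/(1-Po)), kcal/mol.

    Zero at Po = 0.5; negative when the open state is favoured.
    """
    if not 0.0 < po < 1.0:
        raise LinkageError(f"open probability must be in (0, 1), got {po!r}")
    return -kT * math.log(po / (1.0 - po))


def energies_from_ratios(
    construct_id: str,
    r_ptx_gaba: float,
    r_dz_ptx: float,
    po_gaba_max: float = 1.0,
    kT: float = KT_ROOM,
) -> GatingEnergies:
    """Gating energies from the two current-amplitude ratios.

    Po0 = po_gaba_max * r_ptx_gaba, Po1 = Po0 * r_dz_ptx; both must land in
    (0, 1) or the offending ratio is reported in the error.
    """
    if not 0 < po_gaba_max <= 1:
        raise LinkageError("po_gaba_max must be in (0, 1]")
    po0 = po_gaba_max * r_ptx_gaba
    if not 0 < po0 < 1:
        raise LinkageError(
            f"implied unliganded Po = po_gaba_max*r_ptx_gaba = {po0:.4g} "
            f"outside (0, 1) (r_ptx_gaba = {r_ptx_gaba})"
        )
    po1 = po0 * r_dz_ptx
    if not 0 < po1 < 1:
        raise LinkageError(
            f"implied DZ-bound Po = {po1:.4g} outside (0, 1) "
            f"(r_dz_ptx = {r_dz_ptx} is the offending ratio)"
        )
    dG0 = gating_free_energy(po0, kT)
    dG1 = gating_free_energy(po1, kT)
    return GatingEnergies(construct_id, dG0, dG1, dG1 - dG0, po_gaba_max, kT)


def ddg_dz(summary, po_gaba_max: float = 1.0, kT: float = KT_ROOM) -> GatingEnergies:
    """Gating energies from an :class:`~chanlink.traces.OocyteSummary`
    (or any object with construct_id / r_ptx_gaba / r_dz_ptx attributes)."""
    if summary.r_ptx_gaba is None or summary.r_dz_ptx is None:
        raise LinkageError(
            f"summary for {summary.construct_id!r} lacks a required ratio "
            "(r_ptx_gaba and r_dz_ptx must both be defined)"
        )
    return energies_from_ratios(
        summary.construct_id, summary.r_ptx_gaba, summary.r_dz_ptx, po_gaba_max, kT
    )


@dataclass(frozen=True)
class CommonOffsetFit:
    """Least-squares offset of the unit-slope line dG1 = dG0 + ddG through
    a set of constructs; equals the mean of (dG1 - dG0)."""

    offset: float
    included: tuple
    residuals: dict

    @property
    def n_constructs(self) -> int:
        return len(self.included)


def fit_common_offset(
    energies: Iterable[GatingEnergies],
    exclude: Sequence[str] = (),
) -> CommonOffsetFit:
    """Fit the common DZ offset dG1 = dG0 + ddG over included constructs.

    The least-squares solution for a unit-slope line is the mean of
    per-construct (dG1 - dG0). ``exclude`` drops outliers by construct id.
    """
    kept = [e for e in energies if e.construct_id not in set(exclude)]
    if not kept:
        raise LinkageError("no constructs left after exclusion")
    offset = float(np.mean([e.dG1 - e.dG0 for e in kept]))
    residuals = {e.construct_id: (e.dG1 - e.dG0) - offset for e in kept}
    return CommonOffsetFit(offset, tuple(e.construct_id for e in kept), residuals)


def sensitivity_table(
    ratios: Iterable[tuple],
    po_values: Sequence[float],
    kT: float = KT_ROOM,
) -> pd.DataFrame:
    """Recompute gating energies under several Po-GABA-max assumptions.

    ``ratios`` yields (construct_id, r_ptx_gaba, r_dz_ptx) triples; one row
    per (construct, po_gaba_max) combination. The ``ddg_shift`` column gives
    each row's ddG_dz minus that of the first po value for the same
    construct, quantifying how sensitive the linkage estimate is to the
    assumed maximal open probability.
    """
    po_values = list(po_values)
    for po in po_values:
        if not 0 < po <= 1:
            raise LinkageError(f"po_gaba_max must be in (0, 1], got {po!r}")
    rows = []
    for construct_id, r1, r2 in ratios:
        base = None
        for po in po_values:
            e = energies_from_ratios(construct_id, r1, r2, po, kT)
            if base is None:
                base = e.ddG_dz
            rows.append(dict(
                construct_id=construct_id, po_gaba_max=po, dG0=e.dG0, dG1=e.dG1,
                ddG_dz=e.ddG_dz, ddg_shift=e.ddG_dz - base, kT=kT,
            ))
    return pd.DataFrame(rows)


def per_oocyte_energies(
    summaries: pd.DataFrame,
    po_gaba_max: float = 1.0,
    kT: float = KT_ROOM,
    pairing: str = "dz_with_mean_gaba",
) -> pd.DataFrame:
    """Per-oocyte ddG_DZ values mirroring a per-animal summary table.

    ``summaries`` is the per-oocyte summary frame (columns construct_id,
    oocyte_id, r_ptx_gaba, r_dz_ptx). Because GABA- and DZ-series recordings
    come from different oocytes, two pairing schemes are offered:

    - ``"dz_with_mean_gaba"`` (default): each DZ-series oocyte's r_dz_ptx is
      combined with its construct's mean r_ptx_gaba;
    - ``"per_oocyte"``: only oocytes carrying both ratios are used.
    """
    if pairing not in ("dz_with_mean_gaba", "per_oocyte"):
        raise ValueError(f"unknown pairing {pairing!r}")
    rows = []
    for cid, grp in summaries.groupby("construct_id", sort=False):
        mean_gaba = grp["r_ptx_gaba"].dropna().mean()
        for _, rec in grp.iterrows():
            r2 = rec["r_dz_ptx"]
            r1 = rec["r_ptx_gaba"] if pairing == "per_oocyte" else mean_gaba
            if pd.isna(r1) or pd.isna(r2):
                continue
            e = energies_from_ratios(cid, float(r1), float(r2), po_gaba_max, kT)
            rows.append(dict(
                construct_id=cid, oocyte_id=rec["oocyte_id"], dG0=e.dG0,
                dG1=e.dG1, ddG_dz=e.ddG_dz, po_gaba_max=po_gaba_max, kT=kT,
            ))
    return pd.DataFrame(rows)
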