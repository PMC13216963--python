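"""Unified pH from pKa values via proton solvation Gibbs energies.

The unified acidity scale (pH_abs) references the proton to the ideal gas
phase, so solvent scales become comparable once the solvation Gibbs energy
of the proton in each medium is known.  For an equimolar buffer of an acid
and its salt, the solvent-scale pH equals the acid's pKa (ideal-solution
assumption, no activity or homoconjugation corrections), and the
aqueous-aligned value follows from the transfer term between the solvent
and water:

    pH_abs^H2O = pKa_s + (dG_solv_w(H+) - dG_solv_s(H+)) / (R T ln 10)

With the defaults for 1,2-difluorobenzene (-899 kJ/mol) and water
(-1105 kJ/mol) at 298.15 K the shift is -206/5.708 = -36.09 units.  The
conversion is affine with unit slope, so pKa differences carry over to
pH_abs^H2O differences unchanged, and an uncertainty u_G on either
solvation energy maps to u_G / (R T ln 10) pH units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ProtonTransferConstants",
    "PhabsComparison",
    "pka_to_phabs_h2o",
    "solvation_uncertainty_ph",
    "compare_scales",
    "R_KJ_MOL_K",
]

#: molar gas constant, kJ mol^-1 K^-1
R_KJ_MOL_K = 8.31446e-3


@dataclass(frozen=True)
class ProtonTransferConstants:
    """Proton solvation Gibbs energies (kJ/mol) and the temperature used to
    form R T ln 10; defaults describe 1,2-difluorobenzene against water."""

    dG_solv_s: float = -899.0
    dG_solv_w: float = -1105.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.dG_solv_s >= 0 or self.dG_solv_w >= 0:
            raise ValueError("proton solvation Gibbs energies must be negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt_ln10(self) -> float:
        """R T ln 10 in kJ/mol (5.708 at 298.15 K)."""
        return R_KJ_MOL_K * self.temperature * math.log(10.0)

    @property
    def shift(self) -> float:
        """Constant additive conversion term (dG_w - dG_s)/(R T ln 10)."""
        return (self.dG_solv_w - self.dG_solv_s) / self.rt_ln10


def pka_to_phabs_h2o(
    pka_s: float, constants: ProtonTransferConstants = ProtonTransferConstants()
) -> float:
    """Aqueous-aligned unified pH of an equimolar buffer from the acid's
    solvent-scale pKa (equimolar buffer => solvent pH = pKa)."""
    if not np.isfinite(pka_s):
        raise ValueError("pKa must be finite")
    return pka_s + constants.shift


def solvation_uncertainty_ph(
    u_g_kj_mol: float, constants: ProtonTransferConstants = ProtonTransferConstants()
) -> float:
    """Map a standard uncertainty on a proton solvation energy (kJ/mol) to
    pH units: u_G / (R T ln 10); 10 kJ/mol -> 1.75 at 298.15 K."""
    if u_g_kj_mol < 0:
        raise ValueError("uncertainty must be nonnegative")
    return u_g_kj_mol / constants.rt_ln10


@dataclass
class PhabsComparison:
    """Per-buffer differences between pKa-derived and potentiometric
    aqueous-aligned unified pH values (pKa-derived minus potentiometric)."""

    table: pd.DataFrame  # buffer, phabs_from_pka, phabs_potentiometric, diff
    rms: float
    mean: float


def compare_scales(
    pairs: Iterable[tuple[str, float, float]]
) -> PhabsComparison:
    """Compare pKa-derived against potentiometric pH_abs^H2O values.

    ``pairs`` yields (buffer id, pKa-derived value, potentiometric value);
    returns per-buffer differences (pKa-derived - potentiometric), their
    mean, and the root-mean-square difference.
    """
    rows = [
        {"buffer": b, "phabs_from_pka": u, "phabs_potentiometric": p, "diff": u - p}
        for b, u, p in pairs
        if u is not None and p is not None
    ]
    if not rows:
        raise ValueError("no buffer has both a pKa-derived and a potentiometric value")
    df = pd.DataFrame(rows)
    diffs = df["diff"].to_numpy()
    return PhabsComparison(
        table=df,
        rms=float(np.sqrt((diffs**2).mean())),
        mean=float(diffs.mean()),
    )
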