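"""UV-vis spectral unmixing of two-acid titrations.

A mixture of two acids is titrated stepwise with a strong neutral base and
a UV-vis spectrum is recorded after every addition.  Under Beer-Lambert
additivity each mixture spectrum is a nonnegative combination of four basis
spectra - the fully protonated (HA) and fully deprotonated (A-) forms of
both acids, recorded beforehand in separate single-acid titrations.  An
ordinary multilinear (least-squares) regression of each mixture spectrum on
the four basis spectra yields component coefficients from which the
dissociation degree of each acid follows:

    alpha_i = [A_i-] / ([A_i-] + [HA_i])

Because alpha is a ratio of coefficients of the same acid, titrant dilution
cancels.  Each mixture spectrum in which both acids are partially
deprotonated gives one estimate of the ion-pair acidity difference

    Delta pK_ip = log10( alpha_1 (1 - alpha_2) / (alpha_2 (1 - alpha_1)) )

and the per-pair estimate is the mean (or median) over the usable spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SpectrumMatrix",
    "PureFormBasis",
    "DissociationPoint",
    "PairResult",
    "SpectralUnmixer",
    "unmix_spectra",
    "delta_pkip_from_alphas",
    "aggregate_pair",
]

#: alpha inclusion window: endpoint spectra carry unbounded variance in the
#: log-ratio, so only well-buffered points enter the estimate by default.
DEFAULT_ALPHA_WINDOW = (0.05, 0.95)
#: denominator below this fraction of the larger acid's total signal means
#: "this acid is absent from the mixture" -> alpha undefined.
ABSENT_TOL = 1e-6


@dataclass
class SpectrumMatrix:
    """Wavelength grid plus one absorbance column per titration step."""

    wavelengths: np.ndarray
    absorbance: np.ndarray  # shape (n_wavelengths, n_steps)
    step_labels: list[str]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[0] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[0]} rows for "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.absorbance.shape[1] != len(self.step_labels):
            raise ValueError(
                f"{self.absorbance.shape[1]} spectra but {len(self.step_labels)} step labels"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance matrix contains non-finite values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectrumMatrix":
        """Build from the CSV layout: first column ``wavelength_nm``, one
        column per titration step."""
        wl = df.iloc[:, 0].to_numpy(float)
        return cls(wl, df.iloc[:, 1:].to_numpy(float), list(df.columns[1:]))


@dataclass
class PureFormBasis:
    """Pure-form spectra (HA and A-) of both acids on a common grid.

    Each basis spectrum was recorded at a known reference concentration
    (mol L^-1); regression coefficients are therefore expressed as
    concentration fractions of that reference.
    """

    wavelengths: np.ndarray
    acid1: str
    acid2: str
    spectra: dict  # keys "HA1","A1","HA2","A2" -> absorbance arrays
    ref_conc: dict = field(default_factory=dict)  # same keys -> mol/L

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        missing = {"HA1", "A1", "HA2", "A2"} - set(self.spectra)
        if missing:
            raise ValueError(f"basis is missing components {sorted(missing)}")
        for k, v in self.spectra.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.wavelengths.shape:
                raise ValueError(f"basis spectrum {k} not on the common wavelength grid")
            self.spectra[k] = v
        for k in self.spectra:
            self.ref_conc.setdefault(k, 1.0)

    def design_matrix(self, baseline: bool = False) -> np.ndarray:
        """Columns: per-unit-reference spectra of HA1, A1, HA2, A2
        (+ optional flat baseline column)."""
        cols = [self.spectra[k] / self.ref_conc[k] for k in ("HA1", "A1", "HA2", "A2")]
        if baseline:
            cols.append(np.ones_like(self.wavelengths))
        return np.column_stack(cols)


@dataclass
class DissociationPoint:
    """Per-spectrum dissociation degrees of the two acids."""

    step_label: str
    alpha1: Optional[float]
    alpha2: Optional[float]
    usable: bool
    reason: str = ""


@dataclass
class PairResult:
    """Aggregated Delta pK_ip for one acid pair."""

    acid1: str
    acid2: str
    delta_pkip: float
    n_points: int
    spread: float

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("a pair result needs at least one usable point")
        if not math.isfinite(self.delta_pkip):
            raise ValueError("delta_pkip must be finite")


class SpectralUnmixer(BaseEstimator, TransformerMixin):
    """Least-squares unmixing of mixture spectra on a 4-component basis.

    Parameters
    ----------
    baseline : bool
        Add a flat constant regressor (turbidity / baseline drift); off by
        default.
    nonnegative : bool
        Solve with nonnegativity constraints (NNLS) instead of plain least
        squares.
    alpha_window : (float, float)
        Inclusion window on both alphas; points outside are flagged
        unusable.
    cond_max : float
        Maximum allowed condition number of the basis design matrix.
    neg_tol : float
        With plain least squares, coefficients below ``-neg_tol`` (relative
        to the acid's total) flag the point rather than being clipped
        silently.

    Attributes
    ----------
    design_ : ndarray
        The (scaled) basis design matrix.
    condition_number_ : float
    """

    def __init__(
        self,
        baseline: bool = False,
        nonnegative: bool = False,
        alpha_window: tuple[float, float] = DEFAULT_ALPHA_WINDOW,
        cond_max: float = 1e8,
        neg_tol: float = 0.05,
    ):
        self.baseline = baseline
        self.nonnegative = nonnegative
        self.alpha_window = alpha_window
        self.cond_max = cond_max
        self.neg_tol = neg_tol

    def fit(self, basis: PureFormBasis, y=None) -> "SpectralUnmixer":
        design = basis.design_matrix(baseline=self.baseline)
        cond = float(np.linalg.cond(design))
        if not np.isfinite(cond) or cond > self.cond_max:
            raise ValueError(
                f"basis of pair ({basis.acid1}, {basis.acid2}) is ill-conditioned "
                f"(condition number {cond:.3g} > {self.cond_max:.3g}); the four "
                "pure-form spectra are not linearly independent enough"
            )
        self.basis_ = basis
        self.design_ = design
        self.condition_number_ = cond
        return self

    def transform(self, mixtures: SpectrumMatrix) -> list[DissociationPoint]:
        if not np.array_equal(mixtures.wavelengths, self.basis_.wavelengths):
            raise ValueError("mixtures and basis are not on a common wavelength grid")
        lo, hi = self.alpha_window
        points: list[DissociationPoint] = []
        for j, label in enumerate(mixtures.step_labels):
            yvec = mixtures.absorbance[:, j]
            if self.nonnegative:
                ncols = self.design_.shape[1]
                coef, _ = nnls(self.design_, yvec)
                coef = coef[:ncols]
            else:
                coef, *_ = np.linalg.lstsq(self.design_, yvec, rcond=None)
            c_ha1, c_a1, c_ha2, c_a2 = coef[:4]
            # signal-based absence test: dilution-invariant per-acid totals
            tot1 = abs(c_ha1) + abs(c_a1)
            tot2 = abs(c_ha2) + abs(c_a2)
            ref = max(tot1, tot2, ABSENT_TOL)

            reason = ""
            alpha1 = alpha2 = None
            if tot1 / ref < ABSENT_TOL or (c_ha1 + c_a1) <= 0:
                reason = "acid 1 absent"
            else:
                alpha1 = float(c_a1 / (c_ha1 + c_a1))
            if tot2 / ref < ABSENT_TOL or (c_ha2 + c_a2) <= 0:
                reason = (reason + "; " if reason else "") + "acid 2 absent"
            else:
                alpha2 = float(c_a2 / (c_ha2 + c_a2))

            usable = alpha1 is not None and alpha2 is not None and not reason
            if usable and not self.nonnegative:
                if min(c_ha1, c_a1) < -self.neg_tol * tot1 or min(c_ha2, c_a2) < -self.neg_tol * tot2:
                    usable = False
                    reason = "negative component coefficient beyond tolerance"
            if usable:
                if not (lo <= alpha1 <= hi and lo <= alpha2 <= hi):
                    usable = False
                    reason = f"alpha outside inclusion window [{lo}, {hi}]"
            points.append(DissociationPoint(label, alpha1, alpha2, usable, reason))
        return points


def unmix_spectra(
    mixtures: SpectrumMatrix,
    basis: PureFormBasis,
    baseline: bool = False,
    nonnegative: bool = False,
    alpha_window: tuple[float, float] = DEFAULT_ALPHA_WINDOW,
) -> list[DissociationPoint]:
    """Functional wrapper over :class:`SpectralUnmixer`."""
    est = SpectralUnmixer(
        baseline=baseline, nonnegative=nonnegative, alpha_window=alpha_window
    )
    return est.fit(basis).transform(mixtures)


def delta_pkip_from_alphas(alpha1: float, alpha2: float) -> float:
    """Delta pK_ip = log10(alpha1 (1-alpha2) / (alpha2 (1-alpha1))).

    Both dissociation degrees must lie strictly inside (0, 1); endpoints
    give an infinite estimate and are rejected.
    """
    if not (0.0 < alpha1 < 1.0 and 0.0 < alpha2 < 1.0):
        raise ValueError(
            f"dissociation degrees must be strictly inside (0,1); got "
            f"alpha1={alpha1}, alpha2={alpha2}"
        )
    return math.log10(alpha1 * (1.0 - alpha2) / (alpha2 * (1.0 - alpha1)))


def aggregate_pair(
    points: Sequence[DissociationPoint],
    acid1: str,
    acid2: str,
    statistic: Literal["mean", "median"] = "mean",
    spread_n1: float = 0.0,
) -> PairResult:
    """Combine per-spectrum Delta pK_ip estimates into one pair value.

    Uses the usable points only; ``spread`` is the sample standard deviation
    of the per-point estimates (``spread_n1`` for a single point).
    """
    estimates = []
    reasons = []
    for p in points:
        if p.usable:
            estimates.append(delta_pkip_from_alphas(p.alpha1, p.alpha2))
        else:
            reasons.append(f"{p.step_label}: {p.reason or 'unusable'}")
    if not estimates:
        raise ValueError(
            "no usable titration points for pair "
            f"({acid1}, {acid2}); exclusions: " + "; ".join(reasons)
        )
    arr = np.asarray(estimates)
    value = float(np.median(arr) if statistic == "median" else arr.mean())
    spread = float(arr.std(ddof=1)) if arr.size > 1 else spread_n1
    return PairResult(acid1, acid2, value, len(estimates), spread)
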