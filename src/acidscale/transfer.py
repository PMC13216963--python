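"""Cross-solvent pKa transfer: regression, prediction, recommended values.

pKa values of the same acids in two solvents correlate linearly, so an
ordinary least-squares line fitted on compounds measured in both solvents
predicts pKa in the target solvent (here 1,2-difluorobenzene) from values
in acetonitrile (MeCN) or 1,2-dichloroethane (1,2-DCE).  When estimates
from both source solvents exist, the recommended value is their average
and its standard uncertainty is

    u = max(baseline, |difference| / 2 + 0.1)

where the 0.1 covers systematic effects and the baseline (default 0.5,
recomputable as the RMS of the individual dual-source uncertainties)
floors the optimistic cases.  Single-source estimates get a conservative
u = 1.0.  A literature scale anchored elsewhere is aligned by adding the
offset between the pKa of a reference compound on both scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import round_half_away

__all__ = [
    "TransferRegression",
    "RecommendedValue",
    "Prediction",
    "fit_transfer",
    "predict",
    "recommend",
    "compute_baseline",
    "offset_correct",
    "SINGLE_SOURCE_U",
    "DEFAULT_BASELINE_U",
]

#: standard uncertainty assigned when only one source solvent is available
SINGLE_SOURCE_U = 1.0
#: baseline standard uncertainty for dual-source recommendations
DEFAULT_BASELINE_U = 0.5
#: systematic-effect allowance added to half the inter-solvent difference
SYSTEMATIC_U = 0.1


class TransferRegression(RegressorMixin, BaseEstimator):
    """Unweighted OLS of target-solvent pKa on source-solvent pKa.

    Parameters
    ----------
    source, target : str
        Solvent labels, bookkeeping only.
    subset : str
        Tag of the compound-class subset the fit used ("all" or a class
        label such as "arylmalononitrile").
    sigma_dof : {"n-2", "n"}
        Residual-scatter convention: residual standard deviation with n-2
        degrees of freedom (default) or plain RMSE.

    Attributes
    ----------
    slope_, intercept_ : float
    slope_se_, intercept_se_ : float
    sigma_ : float
        Residual standard deviation.
    r2_ : float
        Squared Pearson correlation.
    n_ : int
    x_range_ : (float, float)
        Fitted abscissa range, used to flag extrapolation.
    """

    def __init__(
        self,
        source: str = "MeCN",
        target: str = "1,2-DFB",
        subset: str = "all",
        sigma_dof: Literal["n-2", "n"] = "n-2",
    ):
        self.source = source
        self.target = target
        self.subset = subset
        self.sigma_dof = sigma_dof

    def fit(self, X, y) -> "TransferRegression":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("x and y differ in length")
        if x.size < 3:
            raise ValueError(f"at least 3 compound pairs are required, got {x.size}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("pKa pairs must be finite")
        if np.ptp(x) == 0:
            raise ValueError("degenerate regression: source pKa values are constant")
        res = stats.linregress(x, y)
        resid = y - (res.slope * x + res.intercept)
        dof = x.size - 2 if self.sigma_dof == "n-2" else x.size
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.slope_se_ = float(res.stderr)
        self.intercept_se_ = float(res.intercept_stderr)
        self.sigma_ = float(np.sqrt((resid**2).sum() / dof))
        self.r2_ = float(res.rvalue**2)
        self.n_ = int(x.size)
        self.x_range_ = (float(x.min()), float(x.max()))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * x + self.intercept_

    def summary(self) -> dict:
        check_is_fitted(self, "slope_")
        return {
            "source": self.source,
            "target": self.target,
            "subset": self.subset,
            "n": self.n_,
            "slope": self.slope_,
            "slope_se": self.slope_se_,
            "intercept": self.intercept_,
            "intercept_se": self.intercept_se_,
            "sigma": self.sigma_,
            "r2": self.r2_,
        }


def fit_transfer(
    pairs: Iterable[tuple[float, float]],
    source: str = "MeCN",
    target: str = "1,2-DFB",
    subset: str = "all",
) -> TransferRegression:
    """Fit a cross-solvent regression on (source pKa, target pKa) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    return TransferRegression(source=source, target=target, subset=subset).fit(
        arr[:, 0], arr[:, 1]
    )


@dataclass(frozen=True)
class Prediction:
    """A single transferred pKa estimate, reported at table precision."""

    value: float
    extrapolated: bool


def predict(reg: TransferRegression, x: float) -> Prediction:
    """Transfer one source-solvent pKa; value reported to 1 decimal, with an
    extrapolation flag when x lies outside the fitted range."""
    raw = float(reg.predict([x])[0])
    lo, hi = reg.x_range_
    return Prediction(round_half_away(raw, 1), not (lo <= x <= hi))


@dataclass(frozen=True)
class RecommendedValue:
    """Recommended target-solvent pKa with its assigned uncertainty."""

    compound: str
    est_mecn: Optional[float]
    est_dce: Optional[float]
    recommended: float
    u_assigned: float
    rule_applied: Literal["dual", "single"]


def recommend(
    est_mecn: Optional[float],
    est_dce: Optional[float],
    baseline: float = DEFAULT_BASELINE_U,
    compound: str = "",
) -> RecommendedValue:
    """Apply the recommended-value and uncertainty-assignment rules.

    Dual-source: recommended = average of the two estimates; u = the larger
    of the baseline and |difference|/2 + 0.1.  Single-source: the lone
    estimate with u = 1.0.
    """
    if baseline <= 0:
        raise ValueError("baseline uncertainty must be positive")
    have = [v for v in (est_mecn, est_dce) if v is not None and np.isfinite(v)]
    if not have:
        raise ValueError(f"no estimate available for {compound or 'compound'}")
    if len(have) == 2:
        value = round_half_away((have[0] + have[1]) / 2.0, 1)
        u_ind = abs(have[0] - have[1]) / 2.0 + SYSTEMATIC_U
        u = round_half_away(max(baseline, u_ind), 1)
        return RecommendedValue(compound, est_mecn, est_dce, value, u, "dual")
    return RecommendedValue(
        compound, est_mecn, est_dce, round_half_away(have[0], 1), SINGLE_SOURCE_U, "single"
    )


def compute_baseline(dual_rows: Iterable[tuple[float, float]]) -> float:
    """Root-mean-square of the individual dual-source uncertainties
    (|difference|/2 + 0.1), rounded to 1 decimal for reporting."""
    pairs = np.asarray(list(dual_rows), dtype=float)
    if pairs.size == 0:
        raise ValueError("at least one dual-source row is required")
    u = np.abs(pairs[:, 0] - pairs[:, 1]) / 2.0 + SYSTEMATIC_U
    return round_half_away(float(np.sqrt((u**2).mean())), 1)


def recommend_table(
    table: pd.DataFrame,
    baseline: Optional[float] = None,
    mecn_col: str = "est_mecn",
    dce_col: str = "est_dce",
    compound_col: str = "compound",
) -> pd.DataFrame:
    """Apply :func:`recommend` to every row of an estimates table.

    When ``baseline`` is None it is recomputed from the table's dual-source
    rows; pass ``baseline=0.5`` to reproduce the published convention
    regardless of the table contents.
    """
    dual = table[[mecn_col, dce_col]].dropna()
    if baseline is None:
        baseline = compute_baseline(dual.to_numpy())
    rows = []
    for _, row in table.iterrows():
        m = None if pd.isna(row[mecn_col]) else float(row[mecn_col])
        d = None if pd.isna(row[dce_col]) else float(row[dce_col])
        rec = recommend(m, d, baseline=baseline, compound=str(row[compound_col]))
        rows.append(
            {
                "compound": rec.compound,
                "est_mecn": rec.est_mecn,
                "est_dce": rec.est_dce,
                "recommended": rec.recommended,
                "u_assigned": rec.u_assigned,
                "rule_applied": rec.rule_applied,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["baseline"] = baseline
    return out


def offset_correct(
    values: dict,
    reference: str,
    reference_this_work: float,
    reference_literature: float,
) -> tuple[float, dict]:
    """Align a literature scale by the offset of a shared reference compound.

    offset = (this work - literature) rounded to 1 decimal; every literature
    value is shifted by it and reported to 1 decimal.  Pairwise differences
    are preserved before the final rounding.
    """
    if reference not in values:
        raise ValueError(f"reference compound {reference!r} not in the literature set")
    offset = round_half_away(reference_this_work - reference_literature, 1)
    corrected = {k: round_half_away(v + offset, 1) for k, v in values.items()}
    return offset, corrected
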