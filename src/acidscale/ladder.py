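"""Least-squares assembly of an acidity scale from pairwise measurements.

Many overlapping pairwise differences (Delta pK_ip, Delta pK_a or
Delta pH_abs) form a directed measurement graph over compounds or
solutions.  Scale values x are assigned by minimizing

    SS = sum_i ( delta_i - (x_{b_i} - x_{a_i}) )^2

with one or more nodes held fixed (anchored).  The internal scatter of the
scale is summarized by the consistency standard deviation

    s = sqrt( SS / (n_m - n_c) )

where n_m is the number of included measurements and n_c the number of
fitted parameters.  Anchoring modes:

``fixed_single``
    one node pinned to a reference value (e.g. picric acid at 0 for a
    relative scale);
``offset_multi``
    the scale is fitted relative to an arbitrary gauge and then shifted by
    the offset minimizing the squared differences to several external
    (computational) anchor values;
``bridging``
    identical machinery, with the anchors being bridging solutions of known
    aqueous-aligned unified pH.

Measurement series that disagree with the rest of the graph by more than a
threshold (default 0.75 units) can be excluded iteratively, worst residual
first, mirroring the practice of flagging "red arrows" on published ladders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

__all__ = [
    "LadderMeasurement",
    "AnchorSet",
    "ScaleFit",
    "LadderScale",
    "fit_ladder",
    "consistency_s",
    "anchor_offset",
    "exclude_inconsistent",
    "scale_report",
]

AnchorMode = Literal["fixed_single", "offset_multi", "bridging"]


@dataclass
class LadderMeasurement:
    """One directed pairwise measurement: value(node_b) - value(node_a)."""

    node_a: str
    node_b: str
    delta: float
    kind: str = "pK_ip"  # pK_ip | pK_a | pH_abs
    source: str = ""
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError(f"self-loop measurement on node {self.node_a!r}")
        if not np.isfinite(self.delta):
            raise ValueError(f"non-finite delta for {self.node_a}->{self.node_b}")


@dataclass(frozen=True)
class AnchorSet:
    """External reference values pinning or shifting the relative scale."""

    mode: AnchorMode
    entries: dict  # node id -> reference value

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("anchor set needs at least one entry")
        if self.mode == "fixed_single" and len(self.entries) != 1:
            raise ValueError(
                f"fixed_single anchoring requires exactly one pinned node, got {len(self.entries)}"
            )
        if self.mode not in ("fixed_single", "offset_multi", "bridging"):
            raise ValueError(f"unknown anchor mode {self.mode!r}")


@dataclass
class ScaleFit:
    """Result of a ladder fit."""

    values: dict
    residuals: pd.DataFrame  # node_a, node_b, delta, fitted_delta, residual, excluded
    s: Optional[float]
    n_m: int
    n_c: int
    ss: float
    anchor_mode: str
    offset: Optional[float] = None
    excluded_edges: list = field(default_factory=list)
    link_counts: dict = field(default_factory=dict)

    @property
    def span(self) -> float:
        vals = list(self.values.values())
        return max(vals) - min(vals)


def _check_connected(
    measurements: Sequence[LadderMeasurement], nodes: list[str]
) -> None:
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols = [], []
    for m in measurements:
        rows.append(index[m.node_a])
        cols.append(index[m.node_b])
    n = len(nodes)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comps: dict[int, list[str]] = {}
        for node, lab in zip(nodes, labels):
            comps.setdefault(int(lab), []).append(node)
        raise ValueError(
            "measurement graph is disconnected; components: "
            + "; ".join(",".join(c) for c in comps.values())
        )


class LadderScale(BaseEstimator):
    """Scale-assignment estimator over a pairwise measurement graph.

    Parameters
    ----------
    anchors : AnchorSet or None
        Anchoring specification. ``None`` pins the first node at 0 (pure
        relative scale).
    nc_counts_anchors : bool
        If True, n_c counts every assigned node value (the alternative
        reading of the degrees-of-freedom convention); default counts only
        the freely fitted parameters.
    exclusion_threshold : float or None
        If set, iteratively exclude measurements whose absolute residual
        reaches the threshold (worst first), refitting after each removal.
    precision : int
        Decimals used by :meth:`report` for displayed scale values; full
        precision is kept internally.

    Attributes
    ----------
    values_ : dict
        Assigned value per node.
    s_ : float or None
        Consistency standard deviation (None if n_m <= n_c).
    residuals_ : DataFrame
        Per-measurement residual table, exclusions flagged.
    offset_ : float or None
        Fitted anchoring offset in offset/bridging mode.
    """

    def __init__(
        self,
        anchors: Optional[AnchorSet] = None,
        nc_counts_anchors: bool = False,
        exclusion_threshold: Optional[float] = None,
        precision: int = 1,
    ):
        self.anchors = anchors
        self.nc_counts_anchors = nc_counts_anchors
        self.exclusion_threshold = exclusion_threshold
        self.precision = precision

    # -- internals ---------------------------------------------------------

    def _solve(
        self, measurements: list[LadderMeasurement], anchors: AnchorSet
    ) -> ScaleFit:
        nodes = sorted(
            {m.node_a for m in measurements}
            | {m.node_b for m in measurements}
            | set(anchors.entries if anchors.mode == "fixed_single" else ())
        )
        for a in anchors.entries:
            if a not in nodes:
                raise ValueError(f"anchor node {a!r} absent from the measurement graph")
        _check_connected(measurements, nodes)

        if anchors.mode == "fixed_single":
            (pin_node, pin_value), = anchors.entries.items()
        else:
            # arbitrary gauge; the offset step below fixes the origin
            pin_node, pin_value = nodes[0], 0.0

        free = [n for n in nodes if n != pin_node]
        index = {n: i for i, n in enumerate(free)}
        n_m = len(measurements)
        design = np.zeros((n_m, len(free)))
        rhs = np.empty(n_m)
        for i, m in enumerate(measurements):
            rhs[i] = m.delta
            if m.node_b != pin_node:
                design[i, index[m.node_b]] = 1.0
            else:
                rhs[i] -= pin_value
            if m.node_a != pin_node:
                design[i, index[m.node_a]] = -1.0
            else:
                rhs[i] += pin_value
        # normal-equation solve on the incidence structure; lstsq (SVD) acts
        # as the pseudo-inverse fallback for rank-deficient corner cases
        sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
        values = {pin_node: pin_value}
        values.update({n: float(sol[i]) for n, i in index.items()})

        offset = None
        if anchors.mode in ("offset_multi", "bridging"):
            offset = anchor_offset(values, anchors.entries)
            values = {n: v + offset for n, v in values.items()}

        resid_rows = []
        ss = 0.0
        for m in measurements:
            fitted = values[m.node_b] - values[m.node_a]
            r = m.delta - fitted
            ss += r * r
            resid_rows.append(
                dict(
                    node_a=m.node_a,
                    node_b=m.node_b,
                    delta=m.delta,
                    fitted_delta=fitted,
                    residual=r,
                    kind=m.kind,
                    source=m.source,
                    excluded=False,
                )
            )

        n_free = len(free) + (1 if anchors.mode in ("offset_multi", "bridging") else 0)
        n_c = len(nodes) if self.nc_counts_anchors else n_free
        s = float(np.sqrt(ss / (n_m - n_c))) if n_m > n_c else None

        link_counts: dict[str, int] = {n: 0 for n in nodes}
        for m in measurements:
            link_counts[m.node_a] += 1
            link_counts[m.node_b] += 1
        weak = [n for n, c in link_counts.items() if c < 2]
        if weak:
            warnings.warn(
                f"nodes linked by fewer than two independent measurements: {weak}",
                stacklevel=2,
            )

        return ScaleFit(
            values=values,
            residuals=pd.DataFrame(resid_rows),
            s=s,
            n_m=n_m,
            n_c=n_c,
            ss=float(ss),
            anchor_mode=anchors.mode,
            offset=offset,
            link_counts=link_counts,
        )

    # -- sklearn-style surface --------------------------------------------

    def fit(self, measurements: Iterable[LadderMeasurement], y=None) -> "LadderScale":
        measurements = [m for m in measurements]
        if not measurements:
            raise ValueError("no measurements")
        anchors = self.anchors
        if anchors is None:
            first = measurements[0].node_a
            anchors = AnchorSet("fixed_single", {first: 0.0})

        included = [m for m in measurements if not m.excluded]
        excluded_edges: list[tuple[str, str, float, float]] = []
        fit = self._solve(included, anchors)

        if self.exclusion_threshold is not None:
            threshold = self.exclusion_threshold
            if threshold <= 0:
                raise ValueError("exclusion threshold must be positive")
            while True:
                resid = fit.residuals
                abs_resid = resid["residual"].abs().to_numpy()
                worst = int(np.argmax(abs_resid))  # ties -> input order
                if abs_resid[worst] < threshold:
                    break
                candidate = included[worst]
                trial = [m for j, m in enumerate(included) if j != worst]
                try:
                    new_fit = self._solve(trial, anchors)
                except ValueError:
                    warnings.warn(
                        f"excluding {candidate.node_a}->{candidate.node_b} would "
                        "disconnect the graph; stopping exclusion",
                        stacklevel=2,
                    )
                    break
                excluded_edges.append(
                    (
                        candidate.node_a,
                        candidate.node_b,
                        candidate.delta,
                        float(resid.loc[worst, "residual"]),
                    )
                )
                included = trial
                fit = new_fit

        if excluded_edges:
            extra = []
            for (na, nb, delta, resid_at_excl) in excluded_edges:
                fitted = fit.values[nb] - fit.values[na]
                extra.append(
                    dict(
                        node_a=na,
                        node_b=nb,
                        delta=delta,
                        fitted_delta=fitted,
                        residual=delta - fitted,
                        kind="",
                        source="",
                        excluded=True,
                    )
                )
            fit.residuals = pd.concat(
                [fit.residuals, pd.DataFrame(extra)], ignore_index=True
            )
        fit.excluded_edges = [(na, nb) for na, nb, *_ in excluded_edges]

        self.values_ = fit.values
        self.residuals_ = fit.residuals
        self.s_ = fit.s
        self.offset_ = fit.offset
        self.fit_result_ = fit
        return self

    def transform(self, nodes: Iterable[str]) -> np.ndarray:
        """Look up assigned scale values for ``nodes``."""
        return np.array([self.values_[n] for n in nodes])

    def report(self) -> pd.DataFrame:
        return scale_report(self.fit_result_)


# -- functional wrappers ----------------------------------------------------


def fit_ladder(
    measurements: Iterable[LadderMeasurement],
    anchors: Optional[AnchorSet] = None,
    nc_counts_anchors: bool = False,
) -> ScaleFit:
    """Least-squares scale assignment; see :class:`LadderScale`."""
    est = LadderScale(anchors=anchors, nc_counts_anchors=nc_counts_anchors)
    return est.fit(measurements).fit_result_


def consistency_s(ss: float, n_m: int, n_c: int) -> Optional[float]:
    """s = sqrt(SS/(n_m - n_c)); None when the degrees of freedom are
    exhausted (n_m <= n_c), never 0 by convention."""
    if n_m <= n_c:
        return None
    return float(np.sqrt(ss / (n_m - n_c)))


def anchor_offset(relative_values: dict, calc_anchors: dict) -> float:
    """Offset minimizing sum of squared (calc - (relative + offset)) over the
    anchors: the mean of the per-anchor differences."""
    common = [n for n in calc_anchors if n in relative_values]
    if not common:
        raise ValueError("no anchor overlaps the fitted scale")
    diffs = [calc_anchors[n] - relative_values[n] for n in common]
    return float(np.mean(diffs))


def exclude_inconsistent(
    measurements: Iterable[LadderMeasurement],
    anchors: Optional[AnchorSet] = None,
    threshold: float = 0.75,
) -> ScaleFit:
    """Iteratively drop measurements whose |residual| reaches ``threshold``
    (worst first, ties by input order), refitting after each removal."""
    est = LadderScale(anchors=anchors, exclusion_threshold=threshold)
    return est.fit(measurements).fit_result_


def scale_report(fit: ScaleFit, precision: int = 1) -> pd.DataFrame:
    """Nodes sorted by assigned value, with displayed values at the table
    precision; the frame's ``attrs['span']`` carries max - min."""
    rows = sorted(fit.values.items(), key=lambda kv: kv[1])
    df = pd.DataFrame(rows, columns=["node", "value"])
    df["value_reported"] = df["value"].round(precision)
    df["links"] = df["node"].map(fit.link_counts).fillna(0).astype(int)
    df.attrs["span"] = fit.span
    df.attrs["s"] = fit.s
    df.attrs["n_m"] = fit.n_m
    df.attrs["n_c"] = fit.n_c
    return df
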