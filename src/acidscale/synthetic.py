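"""Seeded synthetic inputs with the statistical structure of the real data.

Three generators emulate the three experimental stages:

* :func:`gen_ladder` - noisy pairwise difference measurements over a
  connected compound graph (spanning tree plus extra edges), optionally
  with planted outlier series, with the ground truth returned for recovery
  tests;
* :func:`gen_titration` - Beer-Lambert mixture spectra of a two-acid
  titration, with the per-step dissociation state obtained from the exact
  proton-transfer equilibrium, plus the pure-form basis spectra;
* :func:`gen_trace` - a differential-potentiometry trace as baseline +
  drift + white noise at a nominal 10 s cadence.

Every generator is a pure function of its spec: the seed fully determines
the output.  The titration generator works on the ion-pair acidity level
(Delta pK_ip); the Fuoss correction is applied downstream exactly as for
real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .ladder import LadderMeasurement
from .potentiometry import PotentialTrace
from .spectra import PureFormBasis, SpectrumMatrix

__all__ = [
    "SyntheticScaleSpec",
    "SyntheticTitrationSpec",
    "SyntheticTraceSpec",
    "gen_ladder",
    "gen_titration",
    "gen_trace",
    "solve_two_acid_equilibrium",
]


# ---------------------------------------------------------------------------
# ladder generator


@dataclass(frozen=True)
class SyntheticScaleSpec:
    """Measurement-graph generator settings.

    Defaults mirror the dimensions of the measured acidity ladder: 33
    compounds, 64 pairwise measurements, scatter 0.07 units.
    """

    n_nodes: int = 33
    n_edges: int = 64
    value_range: tuple[float, float] = (0.0, 15.6)
    noise_sd: float = 0.07
    outlier_count: int = 0
    outlier_magnitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least two nodes")
        if self.n_edges < self.n_nodes - 1:
            raise ValueError(
                f"{self.n_edges} edges cannot connect {self.n_nodes} nodes "
                f"(need at least {self.n_nodes - 1})"
            )


def gen_ladder(spec: SyntheticScaleSpec) -> tuple[dict, list[LadderMeasurement], list[int]]:
    """Generate (true values, measurements, indices of planted outliers).

    A random spanning tree guarantees connectivity; remaining edges pair
    random distinct nodes.  Each measured delta is the true difference plus
    Gaussian noise; outlier edges additionally shift by +-outlier_magnitude.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = [f"acid{i:02d}" for i in range(spec.n_nodes)]
    lo, hi = spec.value_range
    truth = dict(zip(nodes, np.sort(rng.uniform(lo, hi, spec.n_nodes))[::-1]))

    edges: list[tuple[str, str]] = []
    order = rng.permutation(spec.n_nodes)
    for k in range(1, spec.n_nodes):
        parent = order[rng.integers(0, k)]
        edges.append((nodes[parent], nodes[order[k]]))
    while len(edges) < spec.n_edges:
        i, j = rng.choice(spec.n_nodes, size=2, replace=False)
        edges.append((nodes[i], nodes[j]))

    outlier_idx = sorted(
        rng.choice(len(edges), size=spec.outlier_count, replace=False).tolist()
    ) if spec.outlier_count else []
    measurements = []
    for idx, (a, b) in enumerate(edges):
        delta = truth[b] - truth[a] + rng.normal(0.0, spec.noise_sd)
        if idx in outlier_idx:
            delta += rng.choice([-1.0, 1.0]) * spec.outlier_magnitude
        measurements.append(LadderMeasurement(a, b, float(delta), source="synthetic"))
    return truth, measurements, outlier_idx


# ---------------------------------------------------------------------------
# two-acid titration equilibrium


def solve_two_acid_equilibrium(
    delta_pk: float, c1: float, c2: float, base_added: float
) -> tuple[float, float]:
    """Dissociation degrees (alpha1, alpha2) of two acids sharing one pot.

    Given the acidity difference delta_pk = pK(HA2) - pK(HA1) the
    proton-transfer equilibrium fixes the ratio

        alpha1 (1 - alpha2) / (alpha2 (1 - alpha1)) = 10^delta_pk

    and the amount of added strong base fixes the mass balance
    c1*alpha1 + c2*alpha2 = base_added.  Eliminating alpha2 leaves a
    strictly monotone one-dimensional root problem solved to ~1e-12.
    """
    if c1 <= 0 or c2 <= 0:
        raise ValueError("total concentrations must be positive")
    if not (0.0 <= base_added <= c1 + c2 + 1e-15 * (c1 + c2)):
        raise ValueError(
            f"base_added={base_added} outside [0, c1+c2={c1 + c2}]"
        )
    if base_added <= 0.0:
        return 0.0, 0.0
    if base_added >= c1 + c2:
        return 1.0, 1.0
    ratio = 10.0**delta_pk

    def alpha2_of(a1: float) -> float:
        return a1 / (ratio * (1.0 - a1) + a1)

    def residual(a1: float) -> float:
        return c1 * a1 + c2 * alpha2_of(a1) - base_added

    a1 = brentq(residual, 0.0, 1.0, xtol=1e-14, rtol=8.9e-16)
    return float(a1), float(alpha2_of(a1))


# ---------------------------------------------------------------------------
# titration spectra generator


@dataclass(frozen=True)
class SyntheticTitrationSpec:
    """Two-acid titration settings.

    Concentrations default to the 1e-4 mol/L scale of real cuvette
    titrations; absorptivity bands are sums of 1-3 Gaussians per form with
    peak molar absorbances around 1e4 L mol^-1 cm^-1 so peak absorbances
    are of order 1.
    """

    delta_pk: float = 1.20
    c1: float = 1.0e-4
    c2: float = 1.0e-4
    n_steps: int = 12
    noise_sd: float = 0.0  # absorbance units
    wl_min: float = 250.0
    wl_max: float = 450.0
    n_wavelengths: int = 200
    max_condition: float = 1e4
    seed: int = 0


def _random_bands(rng: np.random.Generator, wl: np.ndarray) -> np.ndarray:
    """Molar absorptivity curve: 1-3 Gaussian bands, nonnegative."""
    n_bands = rng.integers(1, 4)
    eps = np.zeros_like(wl)
    for _ in range(n_bands):
        center = rng.uniform(wl[0] + 10, wl[-1] - 10)
        width = rng.uniform(8.0, 30.0)
        height = rng.uniform(3e3, 1.5e4)
        eps += height * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return eps


def gen_titration(
    spec: SyntheticTitrationSpec,
) -> tuple[PureFormBasis, SpectrumMatrix, dict]:
    """Generate (pure-form basis, mixture spectra, truth).

    ``truth`` holds the per-step (alpha1, alpha2), the base amounts and the
    generating delta_pk.  Absorptivity parameters are redrawn (seeded)
    until the 4-component basis is well conditioned.
    """
    rng = np.random.default_rng(spec.seed)
    wl = np.linspace(spec.wl_min, spec.wl_max, spec.n_wavelengths)

    for _ in range(50):
        eps = {k: _random_bands(rng, wl) for k in ("HA1", "A1", "HA2", "A2")}
        basis_mat = np.column_stack([eps[k] for k in ("HA1", "A1", "HA2", "A2")])
        if np.linalg.cond(basis_mat) <= spec.max_condition:
            break
    else:
        raise RuntimeError("could not draw a well-conditioned basis")

    conc_ref = {"HA1": spec.c1, "A1": spec.c1, "HA2": spec.c2, "A2": spec.c2}
    basis_spectra = {k: eps[k] * conc_ref[k] for k in eps}
    if spec.noise_sd > 0:
        for k in basis_spectra:
            basis_spectra[k] = basis_spectra[k] + rng.normal(0, spec.noise_sd, wl.size)
    basis = PureFormBasis(wl, "acid1", "acid2", basis_spectra, dict(conc_ref))

    total = spec.c1 + spec.c2
    base_amounts = np.linspace(0.0, total, spec.n_steps)
    alphas = []
    columns = []
    labels = []
    for i, b in enumerate(base_amounts):
        a1, a2 = solve_two_acid_equilibrium(spec.delta_pk, spec.c1, spec.c2, b)
        alphas.append((a1, a2))
        absorb = (
            eps["HA1"] * spec.c1 * (1 - a1)
            + eps["A1"] * spec.c1 * a1
            + eps["HA2"] * spec.c2 * (1 - a2)
            + eps["A2"] * spec.c2 * a2
        )
        if spec.noise_sd > 0:
            absorb = absorb + rng.normal(0, spec.noise_sd, wl.size)
        columns.append(absorb)
        labels.append(f"step{i:02d}")
    mixtures = SpectrumMatrix(wl, np.column_stack(columns), labels)
    truth = {
        "delta_pk": spec.delta_pk,
        "alphas": alphas,
        "base_amounts": base_amounts.tolist(),
    }
    return basis, mixtures, truth


# ---------------------------------------------------------------------------
# potentiometry trace generator


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Potential-trace settings: baseline + drift + white noise."""

    duration_s: float = 3600.0
    cadence_s: float = 10.0
    baseline_mv: float = 50.0
    drift_mv_per_h: float = 0.0
    noise_sd_mv: float = 0.3
    seed: int = 0


def gen_trace(spec: SyntheticTraceSpec, solution_pair=("s1", "s2")) -> PotentialTrace:
    """Generate a seeded differential-potentiometry trace."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration_s + spec.cadence_s / 2, spec.cadence_s)
    e = (
        spec.baseline_mv
        + spec.drift_mv_per_h * t / 3600.0
        + rng.normal(0.0, spec.noise_sd_mv, t.size)
    )
    return PotentialTrace(t, e, solution_pair=solution_pair)
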