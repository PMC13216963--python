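"""CSV/JSON readers and writers for the pipeline's interchange schemas.

All files are comma-separated UTF-8 with a period decimal and a mandatory
header row.  Schemas:

* spectra: ``wavelength_nm`` + one column per titration step;
* basis registry: ``acid,role,file`` with role HA or A-;
* ladder measurements: ``node_a,node_b,delta,kind,source``;
* anchors: ``node,value,mode``;
* pair results: ``acid1,acid2,delta_pkip,n_points,spread``;
* ion-pair corrections: ``acid1,acid2,delta_pkip,delta_pkd,delta_pka,counterion``;
* species radii: ``species,r_sphere_A,r_cuboid_A,r_surface_A,charge``;
* potential traces: ``time_s,potential_mV``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ionpair import CorrectedPair, IonRadius
from .ladder import AnchorSet, LadderMeasurement, ScaleFit
from .potentiometry import PotentialTrace
from .spectra import PairResult, PureFormBasis, SpectrumMatrix

__all__ = [
    "read_spectrum_csv",
    "read_basis_registry",
    "read_measurements_csv",
    "write_measurements_csv",
    "read_anchors_csv",
    "read_radii_csv",
    "read_trace_csv",
    "write_trace_csv",
    "write_pair_results_csv",
    "read_pair_results_csv",
    "write_corrections_csv",
    "write_scale_csv",
    "write_edge_report_csv",
    "write_fit_summary_json",
]


def read_spectrum_csv(path: str | Path) -> SpectrumMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError(
            f"{path}: first column must be 'wavelength_nm', found {df.columns[0]!r}"
        )
    return SpectrumMatrix.from_frame(df)


def read_basis_registry(path: str | Path) -> PureFormBasis:
    """Assemble a 4-component basis from a registry of pure-form spectra.

    The registry CSV has columns ``acid,role,file[,ref_conc]``; the two acid
    ids appear in row order, and files are resolved relative to the registry.
    """
    base = Path(path).parent
    reg = pd.read_csv(path)
    for col in ("acid", "role", "file"):
        if col not in reg.columns:
            raise ValueError(f"{path}: registry must have a {col!r} column")
    acids = list(dict.fromkeys(reg["acid"]))
    if len(acids) != 2:
        raise ValueError(f"{path}: basis registry must cover exactly 2 acids, found {acids}")
    role_key = {"HA": "HA", "A-": "A"}
    spectra: dict = {}
    ref_conc: dict = {}
    wavelengths = None
    for _, row in reg.iterrows():
        if row["role"] not in role_key:
            raise ValueError(f"{path}: role must be 'HA' or 'A-', found {row['role']!r}")
        idx = acids.index(row["acid"]) + 1
        key = f"{role_key[row['role']]}{idx}"
        sm = read_spectrum_csv(base / row["file"])
        if sm.absorbance.shape[1] != 1:
            raise ValueError(f"{row['file']}: a basis file must hold a single spectrum")
        if wavelengths is None:
            wavelengths = sm.wavelengths
        spectra[key] = sm.absorbance[:, 0]
        rc = row.get("ref_conc", 1.0)
        ref_conc[key] = 1.0 if pd.isna(rc) else float(rc)
    return PureFormBasis(wavelengths, acids[0], acids[1], spectra, ref_conc)


def read_measurements_csv(path: str | Path) -> list[LadderMeasurement]:
    df = pd.read_csv(path)
    return [
        LadderMeasurement(
            str(r.node_a),
            str(r.node_b),
            float(r.delta),
            kind=str(getattr(r, "kind", "pK_ip")),
            source=str(getattr(r, "source", "")),
        )
        for r in df.itertuples(index=False)
    ]


def write_measurements_csv(path: str | Path, measurements: Iterable[LadderMeasurement]) -> None:
    pd.DataFrame(
        [
            {"node_a": m.node_a, "node_b": m.node_b, "delta": m.delta,
             "kind": m.kind, "source": m.source}
            for m in measurements
        ]
    ).to_csv(path, index=False)


def read_anchors_csv(path: str | Path) -> AnchorSet:
    df = pd.read_csv(path)
    modes = set(df["mode"])
    if len(modes) != 1:
        raise ValueError(f"{path}: anchor file mixes modes {sorted(modes)}")
    return AnchorSet(modes.pop(), dict(zip(df["node"].astype(str), df["value"].astype(float))))


def read_radii_csv(path: str | Path) -> dict[str, IonRadius]:
    df = pd.read_csv(path)
    out = {}
    for r in df.itertuples(index=False):
        out[str(r.species)] = IonRadius(
            str(r.species),
            None if pd.isna(r.r_sphere_A) else float(r.r_sphere_A),
            None if pd.isna(r.r_cuboid_A) else float(r.r_cuboid_A),
            None if pd.isna(r.r_surface_A) else float(r.r_surface_A),
            charge=int(getattr(r, "charge", -1)),
        )
    return out


def read_trace_csv(path: str | Path, solution_pair=("s1", "s2"), polarity: int = 1) -> PotentialTrace:
    df = pd.read_csv(path)
    return PotentialTrace(
        df["time_s"].to_numpy(float),
        df["potential_mV"].to_numpy(float),
        solution_pair=tuple(solution_pair),
        polarity=polarity,
    )


def write_trace_csv(path: str | Path, trace: PotentialTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "potential_mV": trace.potentials}).to_csv(
        path, index=False
    )


def write_pair_results_csv(path: str | Path, results: Sequence[PairResult]) -> None:
    pd.DataFrame(
        [
            {"acid1": p.acid1, "acid2": p.acid2, "delta_pkip": p.delta_pkip,
             "n_points": p.n_points, "spread": p.spread}
            for p in results
        ]
    ).to_csv(path, index=False)


def read_pair_results_csv(path: str | Path) -> list[PairResult]:
    df = pd.read_csv(path)
    return [
        PairResult(str(r.acid1), str(r.acid2), float(r.delta_pkip),
                   int(r.n_points), float(r.spread))
        for r in df.itertuples(index=False)
    ]


def write_corrections_csv(path: str | Path, pairs: Sequence[CorrectedPair]) -> None:
    pd.DataFrame(
        [
            {"acid1": p.acid1, "acid2": p.acid2, "delta_pkip": p.delta_pkip,
             "delta_pkd": p.delta_pkd, "delta_pka": p.delta_pka,
             "counterion": p.counterion}
            for p in pairs
        ]
    ).to_csv(path, index=False)


def write_scale_csv(path: str | Path, fit: ScaleFit, precision: int = 1) -> None:
    from .ladder import scale_report

    scale_report(fit, precision=precision).to_csv(path, index=False)


def write_edge_report_csv(path: str | Path, fit: ScaleFit) -> None:
    fit.residuals.to_csv(path, index=False)


def write_fit_summary_json(path: str | Path, fit: ScaleFit) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "s": fit.s,
                "n_m": fit.n_m,
                "n_c": fit.n_c,
                "ss": fit.ss,
                "span": fit.span,
                "offset": fit.offset,
                "anchor_mode": fit.anchor_mode,
                "excluded_edges": [list(e) for e in fit.excluded_edges],
            },
            indent=2,
        )
    )
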