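"""Run configuration: the solvent constants and thresholds in one place.

Defaults reproduce the working constants of the 1,2-difluorobenzene
study: electrode slope -58.35 mV/pH, residual-exclusion threshold 0.75,
trace QC limits 1 mV and 4 mV/h, relative permittivity 13.4, proton
solvation Gibbs energies -899 (1,2-DFB) and -1105 (water) kJ/mol,
bridging-solution pH_abs^H2O values 6.0 and 8.9, dual-source baseline
uncertainty 0.5 and single-source uncertainty 1.0.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    # solvent / physics
    epsilon_r: float = 13.4
    temperature_pka_K: float = 297.25
    temperature_phabs_K: float = 298.15
    electrode_slope_mv: float = -58.35
    dG_solv_H_solvent: float = -899.0
    dG_solv_H_water: float = -1105.0
    # thresholds
    alpha_window: tuple = (0.05, 0.95)
    exclusion_threshold: float = 0.75
    qc_std_mv: float = 1.0
    qc_drift_mv_per_h: float = 4.0
    # anchoring / reporting
    anchor_mode: str = "offset_multi"
    bridge_phabs: dict = field(
        default_factory=lambda: {"MeCN/formate-60-40": 6.0, "EtOH/ammonium-formate": 8.9}
    )
    baseline_u: float = 0.5
    single_source_u: float = 1.0
    precision: int = 1
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "alpha_window" in data:
            data["alpha_window"] = tuple(data["alpha_window"])
        return cls(**data)
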