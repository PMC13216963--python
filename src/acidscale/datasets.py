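"""Packaged reference tables and their validated loaders.

Four small CSV tables ship with the package:

* ``table3`` - the 33 directly measured acids with their 1,2-DFB pKa
  values and literature values in MeCN and 1,2-DCE, plus a compound-class
  tag (the "arylmalononitrile" tag marks the ArCH(CN)2 subset used for the
  class-specific regression);
* ``table5_estimates`` - 104 compounds with pKa estimates transferred from
  MeCN and/or 1,2-DCE;
* ``table2_kong`` - 40 literature pKa values anchored to a different
  reference, to be offset-corrected;
* ``anchors`` - the nine compounds whose computational pKa values anchor
  the absolute scale (the values themselves are consumed as user inputs).

Each table is pinned by a SHA-256 checksum so silent transcription drift
is caught at load time, and validated against the expected row structure.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["load_fixture", "FIXTURE_CHECKSUMS"]

FIXTURE_CHECKSUMS = {
    "table3": "sha256:e89d5e50afe12d0e3def7ffdbb3016768b990c2381c060f3f5eddc592c7f205d",
    "table5_estimates": "sha256:6a6383c303df475874f6c77a97eba6b0735f57c4bcf16a1cc0dec9ae0faf6f8c",
    "table2_kong": "sha256:78a7910ceb0094f0e7b6e7fb194e9273d0d0e635f8c179a7f39012291bf2b245",
    "anchors": "sha256:7f9ced477f154e61b72900b926ff2cd0deb76c400c139f8f1f8924aba6454bc9",
}

_FILES = {
    "table3": "table3.csv",
    "table5_estimates": "table5_estimates.csv",
    "table2_kong": "table2_kong.csv",
    "anchors": "anchors.csv",
}


def _validate(name: str, df: pd.DataFrame) -> None:
    if name == "table3":
        assert len(df) == 33, f"table3 must have 33 rows, found {len(df)}"
        assert df["pka_mecn"].notna().sum() == 29, "table3 must have 29 MeCN values"
        assert df["pka_dce"].notna().sum() == 18, "table3 must have 18 DCE values"
        assert (df["class"] == "arylmalononitrile").sum() == 10
    elif name == "table5_estimates":
        assert len(df) == 104, f"table5 must have 104 rows, found {len(df)}"
        dual = df[["est_mecn", "est_dce"]].notna().all(axis=1).sum()
        assert dual == 36, f"table5 must have 36 dual-source rows, found {dual}"
    elif name == "table2_kong":
        assert len(df) == 40, f"table2 must have 40 rows, found {len(df)}"
    elif name == "anchors":
        assert len(df) == 9, f"anchor list must have 9 compounds, found {len(df)}"


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table by name, verifying its checksum."""
    if name not in _FILES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FILES)}"
        )
    ref = resources.files("acidscale.fixtures") / _FILES[name]
    raw = ref.read_bytes()
    digest = "sha256:" + hashlib.sha256(raw).hexdigest()
    expected = FIXTURE_CHECKSUMS[name]
    if digest != expected:
        raise ValueError(
            f"fixture {name!r} checksum mismatch: file has {digest}, expected "
            f"{expected}; the packaged table has been altered"
        )
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    _validate(name, df)
    return df
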