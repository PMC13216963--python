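"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed pKa tables).

    Python's built-in ``round`` is banker's rounding; printed acidity tables
    round .x5 away from zero, so 0.65 -> 0.7 and -0.65 -> -0.7.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    # nudge by one ulp-scale epsilon so that values that are exactly .5 in
    # decimal but stored slightly below it in binary still round up
    eps = abs(x) * 1e-12 + 1e-12
    return math.copysign(math.floor(abs(x) * factor + 0.5 + eps), x) / factor


def round_up(x: float, ndigits: int = 1) -> float:
    """Round upward (toward +inf) at ``ndigits`` decimals; used for
    conservative reporting of combined uncertainties (0.34 -> 0.4)."""
    factor = 10.0**ndigits
    return math.ceil(x * factor - 1e-9) / factor
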