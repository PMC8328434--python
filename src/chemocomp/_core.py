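"""Small numerical helpers shared across modules."""

from __future__ import annotations

import math

#: Relative tolerance below which degenerate limits replace the closed forms.
LIMIT_TOL = 1e-9


def log_mean(x1: float, x2: float) -> float:
    """Logarithmic mean (x2 - x1)/(ln x2 - ln x1) of two positive numbers.

    This is the time average of an exponential trajectory passing through
    ``x1`` and ``x2``, used for time-averaged grazer (ciliate) densities.
    Returns ``x1`` when the two values coincide (the continuous limit).
    """
    if x1 <= 0 or x2 <= 0:
        raise ValueError(f"log_mean requires positive inputs, got ({x1}, {x2})")
    dlog = math.log(x2) - math.log(x1)
    if abs(dlog) < LIMIT_TOL:
        return x1
    return (x2 - x1) / dlog


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, sig - 1 - exponent)
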