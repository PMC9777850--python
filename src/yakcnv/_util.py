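"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Python's built-in ``round`` is banker's rounding; copy numbers and
    per-individual means use the conventional half-away rule instead
    (2.5 -> 3, -2.5 -> -3).
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))
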