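"""Small shared helpers used across reporting modules."""

from __future__ import annotations

import math

__all__ = ["percent"]


def percent(numerator: int, denominator: int) -> int:
    """Rounded integer percentage, half away from zero.

    This is the convention used for every headline percentage in the
    run report (e.g. 22,174 of 90,817 -> 24).
    """
    if denominator == 0:
        raise ValueError("percent with zero denominator is undefined")
    x = 100 * numerator / denominator
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
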