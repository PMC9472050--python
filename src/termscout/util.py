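"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (display convention for percentages).

    Returns an int when ndigits == 0.
    """
    factor = 10 ** ndigits
    scaled = x * factor
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return int(rounded) if ndigits == 0 else rounded / factor
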