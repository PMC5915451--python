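"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero-free (upward).

    Python's built-in round() rounds halves to even, which is the wrong
    convention for class-count rules like Sturges'.
    """
    return int(math.floor(x + 0.5))
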