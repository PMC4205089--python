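"""Small shared helpers."""

from __future__ import annotations

import math


def percent_round_half_away(k: float, n: float) -> int:
    """Whole-percent share of ``k`` in ``n``, rounded half away from zero.

    Matches how registry audit tables are conventionally printed (0.5 rounds
    up for positive shares).  ``n == 0`` yields 0.
    """
    if n == 0:
        return 0
    x = 100.0 * k / n
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))
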