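"""Display rounding helpers.

Reported m/z, R and Kd values use round-half-up (the convention of the
published tables), not banker's rounding. Full precision is kept internally;
these helpers are applied only at the reporting layer.
"""

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero."""
    if math.isnan(x) or math.isinf(x):
        return x
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)
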