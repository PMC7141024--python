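"""Half-up decimal rounding for report output.

Internal arithmetic is always full precision; rounding is applied only when
values are printed in report tables (1 decimal for trophic positions,
2 decimals for per-mil summaries). Python's built-in ``round`` uses
banker's rounding, which does not match how the reference tables were
rounded, so reports use explicit half-up.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` half-up to ``ndigits`` decimal places.

    >>> round_half_up(2.25, 1)
    2.3
    >>> round(2.25, 1)   # contrast: banker's rounding
    2.2
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
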