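"""Numeric reporting conventions.

All internal computation is carried at full float precision; rounding happens
only when numbers are reported or when a hand-calculation mode deliberately
mimics working from printed summaries.  The house style is 2 decimals, with a
third decimal for probabilities below 0.01 (so a 0.4% toxicity bound prints
as 0.004, not 0.00).
"""

from __future__ import annotations

__all__ = ["round_report", "format_value"]


def round_report(x: float, precision: int = 2) -> float:
    """Round for reporting: ``precision`` decimals, one more below 0.01."""
    if abs(x) < 0.01:
        return round(x, precision + 1)
    return round(x, precision)


def format_value(x: float, precision: int = 2) -> str:
    """Render a number under the house rounding convention."""
    if x != x:  # NaN
        return "--"
    if abs(x) < 0.01 and x != 0:
        return f"{x:.{precision + 1}f}"
    return f"{x:.{precision}f}"
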