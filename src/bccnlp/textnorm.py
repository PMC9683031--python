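"""Shared text/value normalisation used by lookup, rule actions and scoring."""

from __future__ import annotations

import re

_WS = re.compile(r"\s+")


def normalize_text(s: str) -> str:
    """Lowercase and collapse internal whitespace; strip the ends."""
    return _WS.sub(" ", s.strip()).lower()


def values_equal(a, b) -> bool:
    """Compare two scalar feature values after normalisation.

    Booleans only compare with booleans; numeric values (or numeric-looking
    strings) compare as floats; everything else compares as normalised text.
    """
    if isinstance(a, bool) != isinstance(b, bool):
        return False
    if isinstance(a, bool):
        return a == b
    if isinstance(a, (int, float)) and isinstance(b, (int, float)):
        return float(a) == float(b)
    sa, sb = normalize_text(str(a)), normalize_text(str(b))
    if sa == sb:
        return True
    try:
        return float(sa) == float(sb)
    except ValueError:
        return False
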