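"""Elemental formula parsing for mass-balance checks."""

from __future__ import annotations

import re
from collections import Counter

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when an elemental formula cannot be parsed."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into an element -> count map.

    Only flat formulas (no parentheses, no charges) are supported; that is all
    a curated small-molecule template needs.
    """
    if formula is None or formula == "":
        raise FormulaError("empty formula")
    pos = 0
    counts: Counter[str] = Counter()
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
        element, digits = m.groups()
        counts[element] += int(digits) if digits else 1
        pos = m.end()
    if pos != len(formula):
        raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
    return dict(counts)
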