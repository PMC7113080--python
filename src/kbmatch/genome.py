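"""Chromosome naming and ordering helpers shared across the package.

All coordinates in this package are 1-based, fully closed intervals on
GRCh37-style chromosome names (``1``-``22``, ``X``, ``Y``, ``MT``).
"""

from __future__ import annotations

DEFAULT_BUILD = "GRCh37"

_MAIN_CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]
_MAIN_ORDER = {name: i for i, name in enumerate(_MAIN_CHROMOSOMES)}

VALID_BASES = frozenset("ACGTN")


def normalize_chromosome(name: object) -> str:
    """Normalize a chromosome label: strip ``chr`` prefixes, map ``M`` to ``MT``.

    Unrecognized names are returned stripped but otherwise untouched so they
    still sort deterministically (after the main chromosomes).
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    upper = s.upper()
    if upper in ("M", "MT"):
        return "MT"
    if upper in _MAIN_ORDER:
        return upper
    return s


def chromosome_sort_key(name: str) -> tuple[int, int, str]:
    """Sort key giving natural order 1-22, X, Y, MT, then others lexicographic."""
    n = normalize_chromosome(name)
    if n in _MAIN_ORDER:
        return (0, _MAIN_ORDER[n], "")
    return (1, 0, n)


def is_valid_base_string(seq: str) -> bool:
    return all(c in VALID_BASES for c in seq)
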