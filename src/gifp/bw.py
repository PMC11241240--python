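"""Ballesteros-Weinstein generic residue numbering.

A generic position is written ``X.YY`` (e.g. ``3.32``) where ``X`` is a
transmembrane helix number (1-7, plus 8 for helix 8) or a two-digit loop
code naming the flanking helices (e.g. ``45`` for ECL2), and ``YY`` is the
offset relative to the segment's most conserved residue, which is assigned
offset 50.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

__all__ = ["BWPosition", "parse_bw"]

# topological order of segments along the receptor chain
_SEGMENT_ORDER = {
    1: 0, 12: 1, 2: 2, 23: 3, 3: 4, 34: 5, 4: 6, 45: 7,
    5: 8, 56: 9, 6: 10, 67: 11, 7: 12, 78: 13, 8: 14,
}

_BW_RE = re.compile(r"^(\d{1,2})\.(\d{1,2})$")


@total_ordering
@dataclass(frozen=True)
class BWPosition:
    """A generic residue position such as TM3 offset 32 (``3.32``)."""

    segment: int
    offset: int

    def __post_init__(self) -> None:
        if self.segment not in _SEGMENT_ORDER:
            raise ValueError(f"unknown BW segment: {self.segment!r}")
        if not 1 <= self.offset <= 99:
            raise ValueError(f"BW offset out of range 1-99: {self.offset!r}")

    @property
    def sort_key(self) -> tuple[int, int]:
        return (_SEGMENT_ORDER[self.segment], self.offset)

    def __lt__(self, other: "BWPosition") -> bool:
        if not isinstance(other, BWPosition):
            return NotImplemented
        return self.sort_key < other.sort_key

    def __str__(self) -> str:
        return f"{self.segment}.{self.offset:02d}"

    def __repr__(self) -> str:
        return f"BWPosition({self})"


def parse_bw(text: str) -> BWPosition:
    """Parse a ``X.YY`` / ``XY.YY`` string into a :class:`BWPosition`.

    Raises ``ValueError`` for malformed strings or unknown segments.
    """
    m = _BW_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed BW position string: {text!r}")
    return BWPosition(segment=int(m.group(1)), offset=int(m.group(2)))
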