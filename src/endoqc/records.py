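"""Format-independent alignment record model.

All coordinates are 0-based, half-open.  SAM's 1-based POS is converted on
read.  ``sequence`` is stored in reference-forward orientation (as in SAM);
reverse-strand molecules are reverse-complemented downstream where the
molecule's own 5'->3' orientation matters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# operations that consume the query sequence
_QUERY_OPS = frozenset("MIS=X")
# operations that consume the reference
_REF_OPS = frozenset("MDN=X")


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment data."""


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into ``(length, op)`` tuples.

    Raises :class:`AlignmentError` if the string contains anything besides
    well-formed operations.
    """
    if cigar in ("", "*"):
        return []
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise AlignmentError(f"malformed CIGAR: {cigar!r}")
    return [(int(n), op) for n, op in ops]


def cigar_query_length(cigar: str) -> int:
    """Number of query (read) bases consumed by ``cigar``."""
    return sum(n for n, op in parse_cigar(cigar) if op in _QUERY_OPS)


def cigar_reference_length(cigar: str) -> int:
    """Number of reference bases consumed by ``cigar``."""
    return sum(n for n, op in parse_cigar(cigar) if op in _REF_OPS)


@dataclass(slots=True)
class AlignmentRecord:
    """One sequenced read with its mapping state.

    ``ref_start`` is 0-based (converted from SAM POS); ``-1`` for unmapped
    records.  ``is_primary`` is False for secondary and supplementary
    alignments alike.
    """

    read_id: str
    sequence: str
    is_mapped: bool
    is_reverse: bool = False
    mapq: int = 0
    cigar: str = ""
    md: str | None = None
    is_primary: bool = True
    is_duplicate: bool = False
    ref_name: str | None = None
    ref_start: int = -1
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        """Check the record's internal invariants; raise on violation."""
        if self.length < 1:
            raise AlignmentError(f"{self.read_id}: empty sequence")
        if self.md is not None and not self.is_mapped:
            raise AlignmentError(f"{self.read_id}: MD tag on unmapped record")
        if self.is_mapped and self.is_primary:
            qlen = cigar_query_length(self.cigar)
            if qlen != self.length:
                raise AlignmentError(
                    f"{self.read_id}: CIGAR query length {qlen} != "
                    f"sequence length {self.length}"
                )
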