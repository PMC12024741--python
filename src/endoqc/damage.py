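"""Terminal deamination damage profiling from alignment records.

Reconstructs per-read (read base, reference base) columns from CIGAR plus
either the MD tag or a reference sequence, orients them to the molecule's
own 5'->3' direction, and accumulates per-position substitution rates at
each fragment end.  Summary statistics:

* ``n_db`` — length of the run, starting at the terminal base, of positions
  whose rate is strictly above the window-average rate;
* ``r_dm`` — the maximum defined per-position rate in the window;
* ``cv``  — sample SD / mean across samples.
"""

from __future__ import annotations

import math
import re
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

from .records import AlignmentRecord, AlignmentError, parse_cigar

_MD_RE = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
ENDS = (FIVE_PRIME, THREE_PRIME)

#: substitution name -> (reference source base, damaged read base)
SUBSTITUTIONS = {"CT": ("C", "T"), "GA": ("G", "A")}
#: conventional double-stranded library profile for each end
DEFAULT_SUBSTITUTION = {FIVE_PRIME: "CT", THREE_PRIME: "GA"}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MdCigarError(AlignmentError):
    """MD tag and CIGAR disagree for a record."""


@dataclass(slots=True)
class PairwiseAlignment:
    """Aligned (read, reference) columns in molecule 5'->3' orientation.

    Insertions, deletions and soft-clipped bases contribute no column; their
    sizes are kept for audit in ``n_inserted``/``n_deleted``/``n_clipped``.
    """

    read_id: str
    pairs: list[tuple[str, str]]
    n_inserted: int = 0
    n_deleted: int = 0
    n_clipped: int = 0


def _expand_md(md: str) -> list[tuple[str, str | None]]:
    """Expand an MD tag into ('match', None) / ('mismatch', ref) / ('del', ref) events."""
    events: list[tuple[str, str | None]] = []
    pos = 0
    for m in _MD_RE.finditer(md):
        pos = m.end()
        if m.group(1) is not None:
            events.extend(("match", None) for _ in range(int(m.group(1))))
        elif m.group(2) is not None:
            events.extend(("del", base.upper()) for base in m.group(2)[1:])
        else:
            events.append(("mismatch", m.group(3).upper()))
    if pos != len(md):
        raise MdCigarError(f"malformed MD tag: {md!r}")
    return events


def reconstruct_pairwise(
    record: AlignmentRecord,
    reference: dict[str, str] | None = None,
) -> PairwiseAlignment:
    """Recover aligned (read base, ref base) columns for one mapped record.

    Reference bases come from slicing ``reference`` when provided, otherwise
    from expanding the MD tag against the CIGAR.  The output is oriented to
    the original molecule's 5'->3': for reverse-strand records both the
    column order and the bases are reverse-complemented.
    """
    if not (record.is_mapped and record.is_primary):
        raise AlignmentError(f"{record.read_id}: need a mapped primary record")
    use_reference = (
        reference is not None
        and record.ref_name is not None
        and record.ref_name in reference
    )
    if not use_reference and record.md is None:
        raise AlignmentError(f"{record.read_id}: neither MD tag nor reference available")

    cigar_ops = parse_cigar(record.cigar)
    pairs: list[tuple[str, str]] = []
    n_ins = n_del = n_clip = 0
    qpos = 0
    rpos = record.ref_start
    ref_seq = reference[record.ref_name] if use_reference else None

    if use_reference:
        for n, op in cigar_ops:
            if op in ("M", "=", "X"):
                for i in range(n):
                    pairs.append((record.sequence[qpos + i], ref_seq[rpos + i]))
                qpos += n
                rpos += n
            elif op == "I":
                n_ins += n
                qpos += n
            elif op in ("D", "N"):
                n_del += n
                rpos += n
            elif op == "S":
                n_clip += n
                qpos += n
            elif op == "H":
                pass
            else:
                raise AlignmentError(f"{record.read_id}: unsupported CIGAR op {op!r}")
    else:
        md_events = _expand_md(record.md)
        md_i = 0

        def next_md(kind_wanted: tuple[str, ...]) -> tuple[str, str | None]:
            nonlocal md_i
            if md_i >= len(md_events):
                raise MdCigarError(
                    f"{record.read_id}: MD tag exhausted before CIGAR "
                    f"(MD {record.md!r}, CIGAR {record.cigar!r})"
                )
            kind, base = md_events[md_i]
            if kind not in kind_wanted:
                raise MdCigarError(
                    f"{record.read_id}: MD/CIGAR inconsistency "
                    f"(MD {record.md!r}, CIGAR {record.cigar!r})"
                )
            md_i += 1
            return kind, base

        for n, op in cigar_ops:
            if op in ("M", "=", "X"):
                for _ in range(n):
                    read_base = record.sequence[qpos]
                    kind, base = next_md(("match", "mismatch"))
                    ref_base = read_base if kind == "match" else base
                    pairs.append((read_base, ref_base))
                    qpos += 1
            elif op == "I":
                n_ins += n
                qpos += n
            elif op in ("D", "N"):
                for _ in range(n):
                    next_md(("del",))
                n_del += n
            elif op == "S":
                n_clip += n
                qpos += n
            elif op == "H":
                pass
            else:
                raise AlignmentError(f"{record.read_id}: unsupported CIGAR op {op!r}")
        if md_i != len(md_events):
            raise MdCigarError(
                f"{record.read_id}: MD tag longer than CIGAR "
                f"(MD {record.md!r}, CIGAR {record.cigar!r})"
            )

    if record.is_reverse:
        pairs = [
            (rb.translate(_COMPLEMENT), fb.translate(_COMPLEMENT))
            for rb, fb in reversed(pairs)
        ]
    return PairwiseAlignment(
        read_id=record.read_id,
        pairs=pairs,
        n_inserted=n_ins,
        n_deleted=n_del,
        n_clipped=n_clip,
    )


@dataclass(slots=True)
class DamageProfile:
    end: str
    substitution: str
    window: int
    ref_base_count: list[int] = field(default_factory=list)
    damage_count: list[int] = field(default_factory=list)

    @property
    def rates(self) -> list[float]:
        """Per-position rate; NaN where no source base was seen."""
        return [
            (d / r) if r > 0 else math.nan
            for r, d in zip(self.ref_base_count, self.damage_count)
        ]


@dataclass(slots=True)
class DamageSummary:
    n_db: int
    r_dm: float
    window_mean: float


@dataclass(slots=True)
class DispersionSummary:
    mean: float
    sd: float
    cv: float | None  # None when mean == 0


def compute_damage_profile(
    records: Iterable[AlignmentRecord],
    end: str = THREE_PRIME,
    substitution: str | None = None,
    window: int = 25,
    reference: dict[str, str] | None = None,
    *,
    mapq_min: int = 0,
    count_duplicates: bool = False,
    all_mismatches: bool = False,
) -> DamageProfile:
    """Accumulate terminal substitution counts over mapped primary records.

    Position ``i`` (1-based, distance from the chosen end) counts molecules
    whose reference base there is the substitution's source base; the damage
    count adds those read as the target base (or as any mismatch when
    ``all_mismatches``).  Each aligned column is attributed only to its
    nearer end, so fragments shorter than ``2*window`` never contribute a
    base to both ends; ties at the exact middle go to the 5' end.  N bases
    on either side of a column are skipped.
    """
    if end not in ENDS:
        raise ValueError(f"unknown end: {end!r}")
    if substitution is None:
        substitution = DEFAULT_SUBSTITUTION[end]
    if substitution not in SUBSTITUTIONS:
        raise ValueError(f"unknown substitution: {substitution!r}")
    src, tgt = SUBSTITUTIONS[substitution]
    ref_count = [0] * window
    dmg_count = [0] * window
    n_used = 0
    for rec in records:
        if not (rec.is_mapped and rec.is_primary):
            continue
        if rec.is_duplicate and not count_duplicates:
            continue
        if rec.mapq < mapq_min:
            continue
        pw = reconstruct_pairwise(rec, reference)
        pairs = pw.pairs
        n = len(pairs)
        if n == 0:
            continue
        n_used += 1
        for j, (read_base, ref_base) in enumerate(pairs):
            d5 = j + 1
            d3 = n - j
            if end == FIVE_PRIME:
                d = d5
                if d > window or d3 < d5:
                    continue
            else:
                d = d3
                if d > window or d5 <= d3:
                    continue
            if ref_base != src or read_base == "N":
                continue
            ref_count[d - 1] += 1
            if (read_base != src) if all_mismatches else (read_base == tgt):
                dmg_count[d - 1] += 1
    if n_used == 0:
        raise ValueError("no usable mapped primary records")
    return DamageProfile(
        end=end,
        substitution=substitution,
        window=window,
        ref_base_count=ref_count,
        damage_count=dmg_count,
    )


def summarize_damage(profile: DamageProfile) -> DamageSummary:
    """Derive ``n_db``, ``r_dm`` and the window mean from a profile.

    ``n_db`` is the maximal run, starting at position 1 (the terminal
    base), of positions with a defined rate *strictly* greater than the
    mean of all defined rates in the window.  An undefined position
    terminates the run.
    """
    from fractions import Fraction

    counts = list(zip(profile.damage_count, profile.ref_base_count))
    defined = [Fraction(d, c) for d, c in counts if c > 0]
    if not defined:
        raise ValueError("all positions undefined: no source bases in window")
    # exact rational arithmetic so a constant profile never exceeds its own
    # mean through rounding
    mean_frac = sum(defined) / len(defined)
    n_db = 0
    for d, c in counts:
        if c > 0 and Fraction(d, c) > mean_frac:
            n_db += 1
        else:
            break
    return DamageSummary(
        n_db=n_db, r_dm=float(max(defined)), window_mean=float(mean_frac)
    )


def dispersion(values: Sequence[float]) -> DispersionSummary:
    """Mean, sample SD (n-1) and coefficient of variation of ``values``."""
    n = len(values)
    if n < 2:
        raise ValueError("need >= 2 values for dispersion")
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    cv = (sd / mean) if mean != 0 else None
    return DispersionSummary(mean=mean, sd=sd, cv=cv)
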