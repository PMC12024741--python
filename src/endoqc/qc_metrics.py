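"""Per-sample alignment quality metrics and read-size-stratified analysis.

Three sample-level statistics drive everything downstream:

* ``r_m``  — mapped / total cleaned primary reads (endogenous proportion)
* ``r_m0`` — multi-mapped / mapped reads (undefined when nothing maps)
* ``a_l`` — mean read length in bp

plus a 10-bp read-length stratification of ``r_m``/``r_m0`` with an OLS
trend fit over bin midpoints.
"""

from __future__ import annotations

import math
from collections.abc import Iterable
from dataclasses import dataclass

from scipy import stats as _scipy_stats

from .records import AlignmentRecord

#: how a mapped primary record is classified as multi-mapped
MULTI_DEFS = ("mapq0", "xt_tag")


def is_multi_mapped(rec: AlignmentRecord, multi_def: str = "mapq0") -> bool:
    if multi_def == "mapq0":
        return rec.mapq == 0
    if multi_def == "xt_tag":
        return rec.tags.get("XT") == "R"
    raise ValueError(f"unknown multi-mapping definition: {multi_def!r}")


@dataclass(slots=True)
class SampleMetrics:
    sample_id: str
    n_total: int
    n_mapped: int
    n_multi: int
    r_m: float
    r_m0: float | None  # None when n_mapped == 0
    a_l: float


@dataclass(slots=True)
class SizeBin:
    lower: int  # inclusive
    upper: int  # exclusive, lower + step
    midpoint: float
    n_total: int
    n_mapped: int
    n_multi: int
    r_m: float
    r_m0: float | None
    included_in_fit: bool


@dataclass(slots=True)
class TrendFit:
    response: str  # "r_m" or "r_m0"
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


def _scoped(records: Iterable[AlignmentRecord], count_duplicates: bool) -> Iterable[AlignmentRecord]:
    for rec in records:
        if not rec.is_primary:
            continue
        if not count_duplicates and rec.is_duplicate:
            continue
        yield rec


def compute_sample_metrics(
    records: Iterable[AlignmentRecord],
    sample_id: str = "sample",
    *,
    count_duplicates: bool = True,
    multi_def: str = "mapq0",
    a_l_scope: str = "all",
) -> SampleMetrics:
    """Count primary records and derive ``r_m``, ``r_m0`` and ``a_l``.

    ``a_l_scope`` is ``"all"`` (every cleaned read, the default) or
    ``"mapped"``.  Raises ``ValueError`` on an empty sample.
    """
    if a_l_scope not in ("all", "mapped"):
        raise ValueError(f"unknown a_l scope: {a_l_scope!r}")
    n_total = n_mapped = n_multi = 0
    length_sum = 0
    length_n = 0
    for rec in _scoped(records, count_duplicates):
        n_total += 1
        if rec.is_mapped:
            n_mapped += 1
            if is_multi_mapped(rec, multi_def):
                n_multi += 1
        if a_l_scope == "all" or rec.is_mapped:
            length_sum += rec.length
            length_n += 1
    if n_total == 0:
        raise ValueError(f"empty sample: no primary records for {sample_id!r}")
    return SampleMetrics(
        sample_id=sample_id,
        n_total=n_total,
        n_mapped=n_mapped,
        n_multi=n_multi,
        r_m=n_mapped / n_total,
        r_m0=(n_multi / n_mapped) if n_mapped > 0 else None,
        a_l=(length_sum / length_n) if length_n else math.nan,
    )


def bin_by_read_size(
    records: Iterable[AlignmentRecord],
    step: int = 10,
    min_reads: int = 100,
    *,
    count_duplicates: bool = True,
    multi_def: str = "mapq0",
) -> list[SizeBin]:
    """Stratify primary records into ``[k*step, (k+1)*step)`` length bins.

    Bin edges are anchored at multiples of ``step`` so edges are
    sample-independent.  Bins with fewer than ``min_reads`` records are
    still emitted but flagged ``included_in_fit=False``.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    counts: dict[int, list[int]] = {}  # k -> [n_total, n_mapped, n_multi]
    for rec in _scoped(records, count_duplicates):
        k = rec.length // step
        bucket = counts.setdefault(k, [0, 0, 0])
        bucket[0] += 1
        if rec.is_mapped:
            bucket[1] += 1
            if is_multi_mapped(rec, multi_def):
                bucket[2] += 1
    if not counts:
        raise ValueError("empty record stream")
    bins = []
    for k in sorted(counts):
        n_total, n_mapped, n_multi = counts[k]
        bins.append(
            SizeBin(
                lower=k * step,
                upper=(k + 1) * step,
                midpoint=k * step + step / 2,
                n_total=n_total,
                n_mapped=n_mapped,
                n_multi=n_multi,
                r_m=n_mapped / n_total,
                r_m0=(n_multi / n_mapped) if n_mapped > 0 else None,
                included_in_fit=n_total >= min_reads,
            )
        )
    return bins


def fit_size_trend(bins: list[SizeBin], response: str = "r_m") -> TrendFit:
    """Ordinary least squares of a bin response on the bin midpoint.

    ``bins`` may pool per-sample bin lists (one point per sample x bin, as
    in a scatter of subsampled ranges).  Excluded bins and bins with an
    undefined response are skipped.  The p-value is the two-sided t-test on
    the slope.
    """
    if response not in ("r_m", "r_m0"):
        raise ValueError(f"unknown response: {response!r}")
    xs, ys = [], []
    for b in bins:
        if not b.included_in_fit:
            continue
        y = b.r_m if response == "r_m" else b.r_m0
        if y is None:
            continue
        xs.append(b.midpoint)
        ys.append(y)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 included points, got {len(xs)}")
    if len(set(xs)) < 2:
        raise ValueError("zero midpoint variance")
    if len(set(ys)) == 1:
        # flat response: zero slope explains nothing, no evidence of trend
        return TrendFit(response=response, slope=0.0, intercept=ys[0],
                        r_squared=0.0, p_value=1.0, n_points=len(xs))
    res = _scipy_stats.linregress(xs, ys)
    return TrendFit(
        response=response,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=len(xs),
    )
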