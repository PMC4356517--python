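"""Junction statistics: expected segment counts, chi-square goodness of fit,
pathway proportions, fold-decrease and adjusted-colony arithmetic."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats as sps

from .cassette import IntervalMap
from .events import NHEJ_DELETION, RECOMB_COMPLEX_CHIMERA, RECOMB_SINGLE_CROSSOVER, UNRESOLVED

Weighting = Literal["per_interval", "per_bp"]


@dataclass(frozen=True)
class SegmentCounts:
    """Observed and expected junction counts in one reporting segment."""

    label: str
    observed: int
    expected: float
    n_total: int


@dataclass(frozen=True)
class GofResult:
    """Chi-square goodness-of-fit of observed vs expected segment counts."""

    statistic: float
    df: int
    p_value: float
    per_segment_flags: tuple[bool, ...]


def _segment_weights(interval_map: IntervalMap, weighting: Weighting) -> np.ndarray:
    k = interval_map.n_segments
    if weighting == "per_interval":
        counts = np.zeros(k)
        for i in range(interval_map.n_intervals):
            counts[interval_map.segment_of_interval(i)] += 1
        return counts / counts.sum()
    if weighting == "per_bp":
        edges = np.asarray(interval_map.segment_edges, dtype=float)
        lengths = np.diff(edges)
        return lengths / lengths.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def expected_counts_from_segments(
    interval_map: IntervalMap,
    segment_indices: Sequence[int],
    weighting: Weighting = "per_interval",
) -> list[SegmentCounts]:
    """Segment table from raw per-junction segment indices.

    ``per_interval`` weights the expectation by the number of homology
    intervals whose midpoint falls in each segment (junctions are observable
    only at interval resolution); ``per_bp`` weights by segment length.
    """
    segment_indices = list(segment_indices)
    if not segment_indices:
        raise ValueError("no mappable junctions")
    n = len(segment_indices)
    weights = _segment_weights(interval_map, weighting)
    k = interval_map.n_segments
    observed = np.bincount(segment_indices, minlength=k)
    if observed.size > k:
        raise ValueError("segment index out of range")
    return [
        SegmentCounts(label=f"segment_{i + 1}", observed=int(observed[i]),
                      expected=float(n * weights[i]), n_total=n)
        for i in range(k)
    ]


def expected_counts(
    interval_map: IntervalMap,
    calls: Iterable,
    weighting: Weighting = "per_interval",
) -> list[SegmentCounts]:
    """Observed vs expected junction counts per reporting segment.

    ``calls`` are junction calls; only those with a mapped crossover segment
    (single-crossover recombination events) contribute.
    """
    segments = [c.segment_index for c in calls if getattr(c, "segment_index", None) is not None]
    return expected_counts_from_segments(interval_map, segments, weighting)


def chi_square_gof(counts: Sequence[SegmentCounts], alpha: float = 0.05) -> GofResult:
    """Chi-square goodness-of-fit over segments, df = segments - 1.

    Per-segment significance flags come from a post-hoc one-segment-vs-rest
    chi-square at the same alpha, with no multiple-testing correction.
    """
    observed = np.array([c.observed for c in counts], dtype=float)
    expected = np.array([c.expected for c in counts], dtype=float)
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be > 0")
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    df = len(counts) - 1
    p_value = float(sps.chi2.sf(statistic, df))
    n = observed.sum()
    flags = []
    for i in range(len(counts)):
        o2 = np.array([observed[i], n - observed[i]])
        e2 = np.array([expected[i], n - expected[i]])
        stat2 = float(np.sum((o2 - e2) ** 2 / e2))
        flags.append(bool(sps.chi2.sf(stat2, 1) < alpha))
    return GofResult(statistic, df, p_value, tuple(flags))


def pathway_proportions(calls: Iterable) -> tuple[float, float]:
    """Percent of resolved junctions repaired by Alu/Alu recombination vs NHEJ.

    Recombination counts junctions with an intact (chimeric) Alu — single
    crossovers and complex chimeras; NHEJ is the complement.  Unresolved
    calls are excluded from the denominator.
    """
    classes = [c if isinstance(c, str) else c.event_class for c in calls]
    resolved = [c for c in classes if c != UNRESOLVED]
    if not resolved:
        raise ValueError("no resolved calls")
    n_recomb = sum(
        1 for c in resolved if c in (RECOMB_SINGLE_CROSSOVER, RECOMB_COMPLEX_CHIMERA)
    )
    recomb_pct = 100.0 * n_recomb / len(resolved)
    return recomb_pct, 100.0 - recomb_pct


def fold_decrease(reference_count: float, test_count: float) -> float:
    """Colony-count fold decrease relative to the reference construct.

    Quotients below 2 are reported to one decimal place, others to the
    nearest integer (the convention of the reporter's summary table).
    """
    if test_count <= 0:
        raise ValueError("test_count must be > 0")
    q = reference_count / test_count
    return round(q, 1) if q < 2 else float(round(q))


def adjusted_colony_counts(
    colony_count: float, proportions: tuple[float, float]
) -> tuple[float, float]:
    """Split a colony count by pathway percentages (which must sum to 100)."""
    if not np.isclose(sum(proportions), 100.0):
        raise ValueError("proportions must sum to 100")
    return tuple(colony_count * p / 100.0 for p in proportions)
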