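"""Junction caller: recover the repair event from a product sequence.

Given a sequenced deletion product and the reporter cassette it came from,
the caller anchors the product to the cassette by exact flank matching,
normalizes the deletion breakpoints to their leftmost equivalent placement,
measures junction microhomology, and classifies the event:

* a product carrying exactly one full-length (possibly chimeric) Alu is an
  Alu/Alu recombination product; per-diagnostic-site genotyping localizes the
  crossover to a homology interval, or flags a complex chimera when the
  parental patches interleave;
* any other deletion is a non-homologous end-joining (NHEJ) product, annotated
  with its junction microhomology and breakpoint topology relative to the two
  Alu spans.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

from .cassette import AluPair, IntervalMap, ReporterCassette, build_interval_map
from .events import (
    NHEJ_DELETION,
    RECOMB_COMPLEX_CHIMERA,
    RECOMB_SINGLE_CROSSOVER,
    UNRESOLVED,
)

COMPLEX = "COMPLEX"

#: genotype codes: 1 = parent 1 allele, 2 = parent 2 allele, 0 = missing
MISSING = 0

TopologyMode = Literal["leftmost", "any_placement"]


@dataclass(frozen=True)
class JunctionCall:
    """Caller output for one product; mirrors the simulator truth record."""

    event_class: str
    left_breakpoint: int | None = None
    right_breakpoint: int | None = None
    microhomology_len: int | None = None
    breakpoint_ambiguity: int | None = None
    deletion_size: int | None = None
    crossover_interval: int | None = None
    patch_alleles: tuple[int, ...] | None = None
    genotype_vector: tuple[int, ...] | None = None
    segment_index: int | None = None
    topology: str | None = None
    insertion: str = ""


def measure_microhomology(
    cassette_sequence: str, left_breakpoint: int, right_breakpoint: int
) -> tuple[int, int, int]:
    """Junction microhomology and leftmost-normalized breakpoints.

    Returns ``(microhomology_len, left, right)`` where ``(left, right)`` is the
    leftmost placement of the deletion and ``microhomology_len`` is the maximal
    m such that shifting both breakpoints together by any offset in [0, m]
    yields the identical product sequence.
    """
    if not 0 <= left_breakpoint < right_breakpoint <= len(cassette_sequence):
        raise ValueError("invalid breakpoints")
    seq = cassette_sequence
    left, right = left_breakpoint, right_breakpoint
    while left > 0 and seq[left - 1] == seq[right - 1]:
        left -= 1
        right -= 1
    m = 0
    while right + m < len(seq) and seq[left + m] == seq[right + m]:
        m += 1
    return m, left, right


def locate_crossover(genotype_vector: Sequence[int]) -> int | str:
    """Map a per-diagnostic-site genotype vector to a homology interval.

    Interval ``i`` is the span between diagnostic sites ``i-1`` and ``i``; an
    all-parent-2 product recombined before the first site (interval 0) and an
    all-parent-1 product after the last (interval ``n_sites``).  A single
    parent1->parent2 switch whose first parent-2 site is ``i`` maps to
    interval ``i``.  Two or more switches, or any parent2->parent1 switch,
    is a complex chimera (``COMPLEX``); more than 10% missing genotypes is
    ``UNRESOLVED``.
    """
    vec = list(genotype_vector)
    if any(g not in (0, 1, 2) for g in vec):
        raise ValueError("genotypes must be 0 (missing), 1 or 2")
    if not vec:
        return 0  # identical parents: the single interval spans the element
    n_missing = sum(1 for g in vec if g == MISSING)
    if n_missing / len(vec) > 0.10:
        return UNRESOLVED
    observed = [(i, g) for i, g in enumerate(vec) if g != MISSING]
    if not observed:
        return UNRESOLVED
    switches = sum(1 for (_, a), (_, b) in zip(observed, observed[1:]) if a != b)
    values = [g for _, g in observed]
    if switches == 0:
        return len(vec) if values[0] == 1 else 0
    if switches == 1 and values[0] == 1:
        # first observed parent-2 site bounds the crossover interval
        return next(i for i, g in observed if g == 2)
    return COMPLEX


def genotype_product(
    product: str, cassette: ReporterCassette, pair: AluPair
) -> tuple[tuple[int, ...], float] | None:
    """Genotype the candidate chimeric Alu span of a product.

    The span is read at the alu1 position (the promoter-proximal frame a
    recombination product preserves).  Requires an ungapped pair.  Returns the
    per-site genotype vector and the fraction of non-diagnostic positions
    matching the shared parental base, or None when the span does not fit in
    the product.
    """
    if not pair.is_ungapped:
        raise ValueError("per-site genotyping requires an ungapped (substitution-only) pair")
    start = cassette["alu1"].start
    L = pair.n_columns
    if len(product) < start + L:
        return None
    span = product[start : start + L]
    genotypes = []
    for site in pair.diagnostic_sites:
        base = span[site]
        if base == pair.alu1.bases[site]:
            genotypes.append(1)
        elif base == pair.alu2.bases[site]:
            genotypes.append(2)
        else:
            genotypes.append(MISSING)
    shared = [i for i in range(L) if i not in set(pair.diagnostic_sites)]
    if shared:
        match_frac = sum(1 for i in shared if span[i] == pair.alu1.bases[i]) / len(shared)
    else:
        match_frac = 1.0
    return tuple(genotypes), match_frac


def _alu_intact(
    feature_start: int, feature_end: int, left: int, right: int, ambiguity: int
) -> bool:
    """True if some equivalent deletion placement leaves the span untouched."""
    for offset in (0, ambiguity):
        if right + offset <= feature_start or left + offset >= feature_end:
            return True
    return False


def classify_nhej_topology(
    call: JunctionCall, cassette: ReporterCassette, mode: TopologyMode = "leftmost"
) -> str:
    """Which Alu spans the two NHEJ breakpoints fall in.

    ``both_Alus`` when the left breakpoint lies in the alu1 span and the right
    in alu2; ``one_Alu`` when exactly one does; else ``no_Alu``.  The default
    uses the leftmost-normalized breakpoints strictly; ``any_placement``
    counts a breakpoint as in-Alu if any equivalent placement within the
    microhomology window is.
    """
    if call.event_class != NHEJ_DELETION:
        raise ValueError("topology is defined only for NHEJ deletion calls")
    alu1, alu2 = cassette["alu1"], cassette["alu2"]
    amb = call.breakpoint_ambiguity or 0
    offsets = range(amb + 1) if mode == "any_placement" else (0,)
    left_in = any(alu1.start <= call.left_breakpoint + o < alu1.end for o in offsets)
    right_in = any(alu2.start <= call.right_breakpoint + o < alu2.end for o in offsets)
    if left_in and right_in:
        return "both_Alus"
    if left_in or right_in:
        return "one_Alu"
    return "no_Alu"


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def _single_crossover_products(
    cassette: ReporterCassette, pair: AluPair
) -> Iterable[tuple[int, str]]:
    """Exact product sequence of every possible single-crossover event.

    Used to resolve crossovers on gapped pairs, where per-site genotyping of
    the product span is not defined.
    """
    # local import: the simulator builds on the caller's microhomology code
    from .simulate import simulate_recombination_product

    for idx in range(pair.n_sites + 1):
        event = simulate_recombination_product(cassette, pair, idx)
        yield idx, event.product_sequence


def call_junction(
    product: str,
    cassette: ReporterCassette,
    pair: AluPair,
    interval_map: IntervalMap | None = None,
    min_anchor: int = 30,
    shared_match_threshold: float = 0.99,
    topology_mode: TopologyMode = "leftmost",
) -> JunctionCall:
    """Recover the repair event underlying one product sequence.

    The product is anchored to the cassette by its longest exact prefix and
    suffix matches (each must reach ``min_anchor`` bp); the unmatched middle
    defines the deletion and any untemplated insertion.  Products identical to
    the cassette, or with anchors shorter than ``min_anchor``, are
    ``UNRESOLVED``.
    """
    if interval_map is None:
        interval_map = build_interval_map(pair)
    ref = cassette.sequence
    if product == ref:
        return JunctionCall(event_class=UNRESOLVED)
    p = _common_prefix_len(product, ref)
    s = _common_suffix_len(product, ref)
    if p < min_anchor or s < min_anchor:
        return JunctionCall(event_class=UNRESOLVED)

    if p + s >= len(product):
        # pure deletion; microhomology makes the placement ambiguous
        deletion = len(ref) - len(product)
        if deletion <= 0:
            return JunctionCall(event_class=UNRESOLVED)
        insertion = ""
        mh, left, right = measure_microhomology(ref, p, p + deletion)
    else:
        insertion = product[p : len(product) - s]
        left, right = p, len(ref) - s
        deletion = right - left
        if deletion <= 0:
            return JunctionCall(event_class=UNRESOLVED)
        mh = 0

    base = JunctionCall(
        event_class=NHEJ_DELETION,
        left_breakpoint=left,
        right_breakpoint=right,
        microhomology_len=mh,
        breakpoint_ambiguity=mh,
        deletion_size=deletion,
        insertion=insertion,
    )

    alu1, alu2 = cassette["alu1"], cassette["alu2"]
    alu1_intact = _alu_intact(alu1.start, alu1.end, left, right, mh)
    alu2_intact = _alu_intact(alu2.start, alu2.end, left, right, mh)
    net_deletion = len(ref) - len(product)

    # A recombination product carries exactly one full-length chimeric Alu in
    # the alu1 frame; both parental Alus intact means a spacer-only NHEJ
    # deletion.  Patchy chimeras defeat single-deletion anchoring (their
    # interleaved patches masquerade as an untemplated insertion), so the
    # chimera test keys on the net length change, not on the anchored span.
    if not (alu1_intact and alu2_intact):
        if pair.is_ungapped:
            if net_deletion == alu2.start - alu1.start:
                result = genotype_product(product, cassette, pair)
                if result is not None:
                    genotypes, shared_frac = result
                    if shared_frac >= shared_match_threshold:
                        located = locate_crossover(genotypes)
                        if located == UNRESOLVED:
                            return replace(base, event_class=UNRESOLVED, genotype_vector=genotypes)
                        if located == COMPLEX:
                            return replace(
                                base,
                                event_class=RECOMB_COMPLEX_CHIMERA,
                                genotype_vector=genotypes,
                                patch_alleles=genotypes,
                                # no single deletion interval exists: report the
                                # nominal Alu-anchored span (simulator convention)
                                left_breakpoint=alu1.start,
                                right_breakpoint=alu1.start + net_deletion,
                                deletion_size=net_deletion,
                                microhomology_len=0,
                                breakpoint_ambiguity=0,
                                insertion="",
                            )
                        return replace(
                            base,
                            event_class=RECOMB_SINGLE_CROSSOVER,
                            genotype_vector=genotypes,
                            patch_alleles=genotypes,
                            crossover_interval=located,
                            segment_index=interval_map.segment_of_interval(located),
                        )
        else:
            for idx, candidate in _single_crossover_products(cassette, pair):
                if product == candidate:
                    n = pair.n_sites
                    genotypes = tuple([1] * idx + [2] * (n - idx))
                    return replace(
                        base,
                        event_class=RECOMB_SINGLE_CROSSOVER,
                        genotype_vector=genotypes,
                        patch_alleles=genotypes,
                        crossover_interval=idx,
                        segment_index=interval_map.segment_of_interval(idx),
                    )

    call = base
    return replace(call, topology=classify_nhej_topology(call, cassette, topology_mode))
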