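"""Synthetic repair-product generator for the reporter cassette.

Produces deletion products with known ground truth for each event class
recovered from the reporter: single-crossover Alu/Alu recombination (a single
chimeric Alu), complex chimeras (interleaved parental patches from mismatch
processing of the heteroduplex), and NHEJ deletions with emergent junction
microhomology.  Products are filtered by the reporter's selection logic: only
deletions that remove the polyA terminator and I-SceI site while leaving the
promoter and puroR gene intact, within the detectable size window, yield a
puromycin-resistant colony.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .caller import call_junction, measure_microhomology
from .cassette import AluPair, IntervalMap, ReporterCassette, build_interval_map
from .events import (
    NHEJ_DELETION,
    RECOMB_COMPLEX_CHIMERA,
    RECOMB_SINGLE_CROSSOVER,
    RepairEvent,
)


def selection_filter(event: RepairEvent, cassette: ReporterCassette) -> bool:
    """Whether a repair product yields a selectable (puro^r) colony.

    Detectable iff, for some breakpoint placement equivalent under the
    microhomology window, the deletion removes the entire polyA and I-SceI
    features while leaving the promoter and puroR intact, and the deletion
    size falls inside the cassette's detectable window.
    """
    lo, hi = cassette.detectable_deletion_window
    if not lo <= event.deletion_size <= hi:
        return False
    promoter = cassette["promoter"]
    polya = cassette["polyA"]
    sce = cassette["sceI_site"]
    puror = cassette["puroR"]
    left, right = event.left_breakpoint, event.right_breakpoint
    # offsets o with: promoter intact, polyA..sceI removed, puroR intact
    o_min = max(promoter.end - left, sce.end - right, 0)
    o_max = min(polya.start - left, puror.start - right, event.microhomology_len)
    return o_min <= o_max


def _crossover_cut_column(pair: AluPair, interval_index: int) -> int:
    if not 0 <= interval_index <= pair.n_sites:
        raise IndexError(
            f"interval_index {interval_index} out of range for {pair.n_sites + 1} intervals"
        )
    if interval_index == pair.n_sites:
        return pair.n_columns
    return pair.diagnostic_sites[interval_index]


def simulate_recombination_product(
    cassette: ReporterCassette, pair: AluPair, interval_index: int
) -> RepairEvent:
    """Single-crossover Alu/Alu recombination resolving in a homology interval.

    The product keeps the alu1 (parent-1) alleles at diagnostic sites before
    the interval and alu2 (parent-2) alleles from the interval on, deleting
    everything between the two crossover points — for a substitution-only pair
    a deletion of exactly ``alu2.start - alu1.start`` bp.
    """
    cut = _crossover_cut_column(pair, interval_index)
    prefix1 = sum(1 for c in pair.columns[:cut] if c.pos1 is not None)
    prefix2 = sum(1 for c in pair.columns[:cut] if c.pos2 is not None)
    left = cassette["alu1"].start + prefix1
    right = cassette["alu2"].start + prefix2
    product = cassette.sequence[:left] + cassette.sequence[right:]
    mh, left0, right0 = measure_microhomology(cassette.sequence, left, right)
    patches = tuple([1] * interval_index + [2] * (pair.n_sites - interval_index))
    event = RepairEvent(
        event_class=RECOMB_SINGLE_CROSSOVER,
        left_breakpoint=left0,
        right_breakpoint=right0,
        microhomology_len=mh,
        deletion_size=right0 - left0,
        product_sequence=product,
        detectable=False,
        crossover_interval=interval_index,
        patch_alleles=patches,
    )
    return _with_detectability(event, cassette)


def simulate_complex_chimera(
    cassette: ReporterCassette, pair: AluPair, patch_alleles: tuple[int, ...]
) -> RepairEvent:
    """A recombination product with interleaved parental patches.

    ``patch_alleles`` gives the requested parent (1 or 2) at every diagnostic
    site and must contain at least two parent switches; a monotone vector is a
    single-crossover event and is rejected.
    """
    patch_alleles = tuple(patch_alleles)
    if len(patch_alleles) != pair.n_sites:
        raise ValueError("patch_alleles must have one entry per diagnostic site")
    if any(a not in (1, 2) for a in patch_alleles):
        raise ValueError("patch alleles must be 1 or 2")
    switches = sum(1 for a, b in zip(patch_alleles, patch_alleles[1:]) if a != b)
    if switches < 2:
        raise ValueError(
            f"{switches} parent switch(es): that is a single-crossover event, "
            "use simulate_recombination_product"
        )
    # parent of origin per alignment column: diagnostic sites carry the
    # requested allele; columns between sites follow the preceding site
    site_of_column = np.searchsorted(pair.diagnostic_sites, np.arange(pair.n_columns), "left")
    chimera = []
    for col_idx, col in enumerate(pair.columns):
        site = min(site_of_column[col_idx], pair.n_sites - 1)
        parent = patch_alleles[site]
        if col.kind == "match":
            chimera.append(pair.alu1.bases[col.pos1])
        elif parent == 1 and col.pos1 is not None:
            chimera.append(pair.alu1.bases[col.pos1])
        elif parent == 2 and col.pos2 is not None:
            chimera.append(pair.alu2.bases[col.pos2])
    alu1, alu2 = cassette["alu1"], cassette["alu2"]
    product = cassette.sequence[: alu1.start] + "".join(chimera) + cassette.sequence[alu2.end :]
    deletion = len(cassette.sequence) - len(product)
    event = RepairEvent(
        event_class=RECOMB_COMPLEX_CHIMERA,
        left_breakpoint=alu1.start,
        right_breakpoint=alu1.start + deletion,
        microhomology_len=0,
        deletion_size=deletion,
        product_sequence=product,
        detectable=False,
        patch_alleles=patch_alleles,
    )
    return _with_detectability(event, cassette)


def simulate_nhej_deletion(
    cassette: ReporterCassette,
    left_breakpoint: int,
    right_breakpoint: int,
    insertion: str = "",
) -> RepairEvent:
    """An NHEJ deletion joining two cassette positions, optionally with an
    untemplated insertion.

    Junction microhomology is not imposed: it emerges from the cassette
    sequence at the chosen breakpoints and is recorded (with leftmost-aligned
    breakpoints) as truth.
    """
    promoter, puror = cassette["promoter"], cassette["puroR"]
    if not (promoter.end <= left_breakpoint < right_breakpoint <= puror.start):
        raise ValueError(
            "breakpoints must satisfy promoter.end <= left < right <= puroR.start"
        )
    product = (
        cassette.sequence[:left_breakpoint] + insertion + cassette.sequence[right_breakpoint:]
    )
    if insertion:
        mh, left0, right0 = 0, left_breakpoint, right_breakpoint
    else:
        mh, left0, right0 = measure_microhomology(
            cassette.sequence, left_breakpoint, right_breakpoint
        )
    event = RepairEvent(
        event_class=NHEJ_DELETION,
        left_breakpoint=left0,
        right_breakpoint=right0,
        microhomology_len=mh,
        deletion_size=right0 - left0,
        product_sequence=product,
        detectable=False,
        insertion=insertion,
    )
    return _with_detectability(event, cassette)


def _with_detectability(event: RepairEvent, cassette: ReporterCassette) -> RepairEvent:
    from dataclasses import replace

    return replace(event, detectable=selection_filter(event, cassette))


@dataclass(frozen=True)
class MixturePreset:
    """Event-class mixture and breakpoint distributions for a colony set.

    ``five_prime_bias_weight`` w draws the crossover interval from the first
    reporting segment with probability w and uniformly over all intervals
    otherwise (w = 0 is the uniform null).  ``microhomology_seeking`` samples
    NHEJ breakpoints proportional to 2^microhomology over candidate draws,
    emulating the 5-25 nt microhomology preference of MMEJ.
    """

    p_single_crossover: float = 1.0
    p_complex_chimera: float = 0.0
    p_nhej: float = 0.0
    five_prime_bias_weight: float = 0.0
    microhomology_seeking: bool = False
    nhej_candidate_draws: int = 16
    name: str = "custom"

    def __post_init__(self) -> None:
        total = self.p_single_crossover + self.p_complex_chimera + self.p_nhej
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class probabilities must sum to 1, got {total}")

    @classmethod
    def from_pathway_split(
        cls,
        recombination_pct: float,
        nhej_pct: float,
        complex_fraction: float = 0.0,
        **kwargs,
    ) -> "MixturePreset":
        """Preset from a (recombination %, NHEJ %) pathway split, with an
        optional fraction of the recombination channel as complex chimeras."""
        if not math.isclose(recombination_pct + nhej_pct, 100.0, abs_tol=1e-6):
            raise ValueError("pathway percentages must sum to 100")
        p_rec = recombination_pct / 100.0
        return cls(
            p_single_crossover=p_rec * (1 - complex_fraction),
            p_complex_chimera=p_rec * complex_fraction,
            p_nhej=nhej_pct / 100.0,
            **kwargs,
        )


def sample_crossover_interval(
    rng: np.random.Generator, interval_map: IntervalMap, five_prime_bias_weight: float = 0.0
) -> int:
    """Draw a crossover interval: uniform, or 5'-segment-enriched with weight w."""
    n = interval_map.n_intervals
    if five_prime_bias_weight > 0 and rng.random() < five_prime_bias_weight:
        first_segment = [i for i in range(n) if interval_map.segment_of_interval(i) == 0]
        return int(first_segment[rng.integers(len(first_segment))])
    return int(rng.integers(n))


def _sample_nhej_breakpoints(
    rng: np.random.Generator, cassette: ReporterCassette, preset: MixturePreset
) -> tuple[int, int]:
    """Breakpoints straddling the I-SceI break, uniform over the legal span
    (optionally microhomology-seeking)."""
    sce = cassette["sceI_site"]
    lo_left, hi_left = cassette["promoter"].end, sce.start
    lo_right, hi_right = sce.end, cassette["puroR"].start

    def draw() -> tuple[int, int]:
        return (
            int(rng.integers(lo_left, hi_left + 1)),
            int(rng.integers(lo_right, hi_right + 1)),
        )

    if not preset.microhomology_seeking:
        return draw()
    candidates = [draw() for _ in range(preset.nhej_candidate_draws)]
    weights = np.array(
        [
            2.0 ** min(measure_microhomology(cassette.sequence, l, r)[0], 25)
            for l, r in candidates
        ]
    )
    choice = rng.choice(len(candidates), p=weights / weights.sum())
    return candidates[choice]


def _sample_patch_vector(
    rng: np.random.Generator, n_sites: int
) -> tuple[int, ...]:
    """Patch vector with 2 or 3 parent switches at random site boundaries."""
    if n_sites < 3:
        raise ValueError("complex chimeras need at least 3 diagnostic sites")
    n_switches = int(rng.integers(2, min(4, n_sites)))
    cuts = sorted(rng.choice(np.arange(1, n_sites), size=n_switches, replace=False).tolist())
    parent = int(rng.integers(1, 3))
    vec: list[int] = []
    prev = 0
    for cut in [*cuts, n_sites]:
        vec.extend([parent] * (cut - prev))
        parent = 3 - parent
        prev = cut
    return tuple(vec)


@dataclass(frozen=True)
class ColonySet:
    """A simulated set of selectable colonies with their ground truth."""

    events: tuple[RepairEvent, ...]
    rejected: int  # non-detectable draws discarded (the analogue of undetected repair)
    seed: int


def simulate_colony_set(
    cassette: ReporterCassette,
    pair: AluPair,
    n: int,
    preset: MixturePreset,
    seed: int,
    interval_map: IntervalMap | None = None,
) -> ColonySet:
    """Draw exactly ``n`` detectable repair products under a mixture preset.

    Non-detectable draws are rejection-sampled and counted.  NHEJ draws whose
    product is indistinguishable from a single-crossover recombination product
    (in-register junctions between the Alus) are resampled: such colonies are
    operationally recombination products and belong to that channel.  The RNG
    stream is single and the draw order is fixed (class, then positions, then
    any bases), so output is reproducible given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if interval_map is None:
        interval_map = build_interval_map(pair)
    rng = np.random.default_rng(seed)
    probs = np.array([preset.p_single_crossover, preset.p_complex_chimera, preset.p_nhej])
    events: list[RepairEvent] = []
    rejected = 0
    # the mixture describes the composition of the detected colony set (pathway
    # splits are measured among sequenced colonies), so the class draw is kept
    # and only positions are resampled until the product is selectable
    while len(events) < n:
        cls = int(rng.choice(3, p=probs))
        while True:
            if cls == 0:
                idx = sample_crossover_interval(rng, interval_map, preset.five_prime_bias_weight)
                event = simulate_recombination_product(cassette, pair, idx)
            elif cls == 1:
                patches = _sample_patch_vector(rng, pair.n_sites)
                event = simulate_complex_chimera(cassette, pair, patches)
            else:
                left, right = _sample_nhej_breakpoints(rng, cassette, preset)
                event = simulate_nhej_deletion(cassette, left, right)
                if event.detectable:
                    check = call_junction(event.product_sequence, cassette, pair, interval_map)
                    if check.event_class != NHEJ_DELETION:
                        rejected += 1
                        continue
            if event.detectable:
                events.append(event)
                break
            rejected += 1
    return ColonySet(tuple(events), rejected, seed)
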