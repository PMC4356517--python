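"""Repair-event truth records and event-class vocabulary shared by the
simulator and the junction caller."""

from __future__ import annotations

from dataclasses import dataclass

RECOMB_SINGLE_CROSSOVER = "RECOMB_SINGLE_CROSSOVER"
RECOMB_COMPLEX_CHIMERA = "RECOMB_COMPLEX_CHIMERA"
NHEJ_DELETION = "NHEJ_DELETION"
UNRESOLVED = "UNRESOLVED"

EVENT_CLASSES = (RECOMB_SINGLE_CROSSOVER, RECOMB_COMPLEX_CHIMERA, NHEJ_DELETION)


@dataclass(frozen=True)
class RepairEvent:
    """Simulator ground truth for one repair product.

    ``left_breakpoint``/``right_breakpoint`` are the 0-based half-open deletion
    span on the cassette, leftmost-aligned; ``microhomology_len`` is the length
    of the shared flank sequence making the placement ambiguous (so any shift
    of both breakpoints by 0..microhomology_len yields the same product).  For
    complex chimeras (interleaved parental patches) no single deletion interval
    exists; breakpoints there are the nominal Alu-anchored span and
    microhomology is reported as 0.

    ``patch_alleles`` gives the parent of origin (1 or 2) at every diagnostic
    site of the chimeric Alu, monotone for single crossovers; absent for NHEJ.
    """

    event_class: str
    left_breakpoint: int
    right_breakpoint: int
    microhomology_len: int
    deletion_size: int
    product_sequence: str
    detectable: bool
    crossover_interval: int | None = None
    patch_alleles: tuple[int, ...] | None = None
    insertion: str = ""

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.deletion_size != self.right_breakpoint - self.left_breakpoint:
            raise ValueError("deletion_size must equal right_breakpoint - left_breakpoint")
        if self.microhomology_len < 0:
            raise ValueError("microhomology_len must be >= 0")
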