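"""Reporter-construct model: diverged Alu pairs, homology intervals, cassette assembly.

The reporter is a single-copy, single-strand construct carrying two direct-repeat
Alu elements separated by a selectable spacer (a neomycin-resistance gene, a
polyadenylation signal and an I-SceI recognition site), flanked by a promoter and
a promoterless puromycin-resistance gene.  A double-strand break at the I-SceI
site that is repaired by a deletion removing the polyA terminator places puroR
under the promoter, so only deletion products within a size window are
selectable.

Coordinates are 0-based, half-open, on the top strand throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from Bio import Align

DNA_ALPHABET = "ACGT"

#: I-SceI homing endonuclease 18-bp recognition sequence.
SCEI_SITE = "TAGGGATAACAGGGTAAT"

DivergenceMode = Literal["evenly_spaced", "random", "scrambled"]


@dataclass(frozen=True)
class AluSequence:
    """A single Alu element (or synthetic stand-in) as plain DNA.

    Parameters
    ----------
    id : str
        Record label, carried into FASTA output.
    bases : str
        Upper-case DNA over ``{A, C, G, T}``; no gaps or ambiguity codes.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 50:
            raise ValueError(f"Alu sequence must be >= 50 bp, got {len(self.bases)}")
        if set(self.bases) - set(DNA_ALPHABET):
            bad = sorted(set(self.bases) - set(DNA_ALPHABET))
            raise ValueError(f"non-ACGT characters in sequence: {bad}")

    @property
    def length(self) -> int:
        return len(self.bases)


class AlignedColumn(NamedTuple):
    """One column of the pairwise alignment of the two parental Alus.

    ``pos1``/``pos2`` are the 0-based positions in each parent, or ``None``
    for a gap; ``kind`` is ``match``, ``mismatch`` or ``indel``.
    """

    pos1: int | None
    pos2: int | None
    kind: Literal["match", "mismatch", "indel"]


@dataclass(frozen=True)
class AluPair:
    """An aligned pair of parental Alu elements with diagnostic columns.

    Diagnostic sites are the alignment columns at which the parents differ;
    each maximal indel run is collapsed to a single site (an indel run bounds
    junction mappability exactly like one diagnostic substitution).  Site
    coordinates are alignment-column indices, which for ungapped (equal-length,
    substitution-only) pairs coincide with sequence positions in either parent
    and in any chimeric recombination product.
    """

    alu1: AluSequence
    alu2: AluSequence
    columns: tuple[AlignedColumn, ...]
    diagnostic_sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in itertools.pairwise(self.diagnostic_sites)):
            raise ValueError("diagnostic_sites must be strictly increasing")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def n_sites(self) -> int:
        return len(self.diagnostic_sites)

    @property
    def is_ungapped(self) -> bool:
        return all(c.kind != "indel" for c in self.columns)

    @property
    def divergence_pct(self) -> float:
        """Percent diverged columns: mismatches plus collapsed indel runs, over
        total alignment columns."""
        return divergence_percent(self)

    def allele(self, site_index: int, parent: int) -> str:
        """Base carried by ``parent`` (1 or 2) at a diagnostic site.

        Only defined for substitution columns; indel-run sites raise.
        """
        col = self.columns[self.diagnostic_sites[site_index]]
        if col.kind != "mismatch":
            raise ValueError("allele() is defined only for substitution sites")
        if parent == 1:
            return self.alu1.bases[col.pos1]
        if parent == 2:
            return self.alu2.bases[col.pos2]
        raise ValueError("parent must be 1 or 2")

    @classmethod
    def from_ungapped(cls, alu1: AluSequence, alu2: AluSequence) -> "AluPair":
        """Build a pair by positional comparison of equal-length sequences."""
        if alu1.length != alu2.length:
            raise ValueError("from_ungapped requires equal-length sequences")
        columns = tuple(
            AlignedColumn(i, i, "match" if a == b else "mismatch")
            for i, (a, b) in enumerate(zip(alu1.bases, alu2.bases))
        )
        sites = tuple(i for i, c in enumerate(columns) if c.kind == "mismatch")
        return cls(alu1, alu2, columns, sites)


@dataclass(frozen=True)
class Feature:
    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


FEATURE_ORDER = ("promoter", "alu1", "neoR", "polyA", "sceI_site", "alu2", "puroR")


@dataclass(frozen=True)
class ReporterCassette:
    """The assembled reporter construct.

    ``features`` are non-overlapping and appear in the fixed order
    promoter, alu1, neoR, polyA, sceI_site, alu2, puroR.
    ``detectable_deletion_window`` is the (min, max) deletion size, in bp,
    selectable as a puromycin-resistant colony.
    """

    features: tuple[Feature, ...]
    sequence: str
    detectable_deletion_window: tuple[int, int] = (897, 1881)

    def __post_init__(self) -> None:
        names = tuple(f.name for f in self.features)
        if names != FEATURE_ORDER:
            raise ValueError(f"features must be exactly {FEATURE_ORDER} in order, got {names}")
        for a, b in itertools.pairwise(self.features):
            if b.start < a.end:
                raise ValueError(f"overlapping features: {a.name} and {b.name}")
        sce = self["sceI_site"]
        if not (self["alu1"].end <= sce.start and sce.end <= self["alu2"].start):
            raise ValueError("sceI_site must lie between alu1 and alu2")
        if self.features[-1].end > len(self.sequence):
            raise ValueError("features extend beyond the sequence")

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def spacer_length(self) -> int:
        return self["alu2"].start - self["alu1"].end


@dataclass(frozen=True)
class IntervalMap:
    """Homology intervals between consecutive diagnostic sites.

    A recombination junction can only be localized to the span between two
    diagnostic sites, so the element is tiled by ``n_sites + 1`` half-open
    intervals cut at each site.  ``segment_edges`` define coarser reporting
    segments (default three 100-bp segments) to which intervals are assigned
    by midpoint.
    """

    intervals: tuple[tuple[int, int], ...]
    segment_edges: tuple[int, ...]

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def n_segments(self) -> int:
        return len(self.segment_edges) - 1

    def segment_of_interval(self, interval_index: int) -> int:
        """Reporting segment containing the interval's midpoint."""
        start, end = self.intervals[interval_index]
        mid = (start + end) / 2.0
        for seg in range(self.n_segments):
            if mid < self.segment_edges[seg + 1]:
                return seg
        return self.n_segments - 1

    def interval_of_position(self, position: int) -> int:
        """Homology interval containing a (chimera-coordinate) position."""
        for i, (s, e) in enumerate(self.intervals):
            if s <= position < e:
                return i
        raise ValueError(f"position {position} outside the element")


def synthetic_consensus(length: int = 300, seed: int = 0, id: str = "Alu_consensus") -> AluSequence:
    """Seeded-random DNA standing in for an Alu consensus.

    The 300-bp default matches the three-100-bp-segment framing used when
    reporting junction distributions; a real consensus (~281 bp for Ya5) can
    be supplied via FASTA instead, in which case the final segment is shorter.
    """
    rng = np.random.default_rng(seed)
    return AluSequence(id, _random_dna(rng, length))


def generate_diverged_alu(
    consensus: AluSequence,
    divergence_pct: float,
    mode: DivergenceMode = "evenly_spaced",
    seed: int = 0,
) -> AluSequence:
    """Derive a diverged copy of a consensus Alu.

    ``evenly_spaced`` places ``k = round(L * d / 100)`` substitutions at
    positions spread uniformly across the element (for 5% on a 300-bp element:
    one substitution every 20 bp, at positions 19, 39, ..., 299).  ``random``
    places ``k`` substitutions at seeded uniformly sampled distinct positions.
    ``scrambled`` returns a seeded permutation of the consensus and ignores
    ``divergence_pct``.  Substituted bases are drawn seeded-uniformly from the
    three non-reference alternatives.
    """
    if not 0 <= divergence_pct <= 100:
        raise ValueError("divergence_pct must be in [0, 100]")
    rng = np.random.default_rng(seed)
    bases = list(consensus.bases)
    L = len(bases)

    if mode == "scrambled":
        perm = rng.permutation(L)
        out = "".join(bases[i] for i in perm)
        return AluSequence(f"{consensus.id}_scrambled", out)

    k = round(L * divergence_pct / 100.0)
    if divergence_pct > 0 and k == 0:
        raise ValueError(
            f"divergence {divergence_pct}% is unrepresentable at length {L} (0 substitutions)"
        )
    if k == 0:
        return AluSequence(f"{consensus.id}_0pct", consensus.bases)

    if mode == "evenly_spaced":
        positions = sorted({round((i + 1) * L / k) - 1 for i in range(k)})
        if len(positions) != k:  # only possible for k > L
            raise ValueError("divergence too high for evenly spaced placement")
    elif mode == "random":
        positions = sorted(rng.choice(L, size=k, replace=False).tolist())
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for p in positions:
        alternatives = [b for b in DNA_ALPHABET if b != bases[p]]
        bases[p] = alternatives[rng.integers(3)]
    label = f"{consensus.id}_{divergence_pct:g}pct_{mode}"
    return AluSequence(label, "".join(bases))


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment parameters; defaults suit 70-100% identical repeats."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


def align_pair(
    alu1: AluSequence,
    alu2: AluSequence,
    scoring: AlignmentScoring | None = None,
) -> AluPair:
    """Globally align two Alus and collapse each maximal gap run to one
    diagnostic site.

    Equal-length pairs whose gapless (positional) alignment already attains
    the optimal score are returned as the positional comparison, so
    substitution-only pairs reduce exactly to per-position diagnostics.
    """
    if not alu1.bases or not alu2.bases:
        raise ValueError("cannot align empty sequences")
    scoring = scoring or AlignmentScoring()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend

    if alu1.length == alu2.length:
        gapless = sum(
            scoring.match if a == b else scoring.mismatch
            for a, b in zip(alu1.bases, alu2.bases)
        )
        if gapless >= aligner.score(alu1.bases, alu2.bases):
            return AluPair.from_ungapped(alu1, alu2)

    aln = aligner.align(alu1.bases, alu2.bases)[0]
    idx1, idx2 = aln.indices  # -1 marks a gap in that row
    columns: list[AlignedColumn] = []
    for i1, i2 in zip(idx1.tolist(), idx2.tolist()):
        if i1 < 0 or i2 < 0:
            columns.append(AlignedColumn(None if i1 < 0 else i1, None if i2 < 0 else i2, "indel"))
        elif alu1.bases[i1] == alu2.bases[i2]:
            columns.append(AlignedColumn(i1, i2, "match"))
        else:
            columns.append(AlignedColumn(i1, i2, "mismatch"))

    sites: list[int] = []
    in_indel_run = False
    for c_idx, col in enumerate(columns):
        if col.kind == "mismatch":
            sites.append(c_idx)
            in_indel_run = False
        elif col.kind == "indel":
            if not in_indel_run:
                sites.append(c_idx)
                in_indel_run = True
        else:
            in_indel_run = False
    return AluPair(alu1, alu2, tuple(columns), tuple(sites))


def divergence_percent(pair: AluPair) -> float:
    """Percent divergence: (mismatch columns + collapsed indel runs) / total columns x 100."""
    mismatches = sum(1 for c in pair.columns if c.kind == "mismatch")
    indel_runs = 0
    in_run = False
    for c in pair.columns:
        if c.kind == "indel":
            if not in_run:
                indel_runs += 1
                in_run = True
        else:
            in_run = False
    return 100.0 * (mismatches + indel_runs) / len(pair.columns)


def build_interval_map(pair: AluPair, segment_length: int = 100) -> IntervalMap:
    """Tile the element with homology intervals cut at each diagnostic site.

    With no diagnostic sites the whole element is a single interval (a
    junction in an identical pair cannot be mapped).  Segments are
    ``ceil(L / segment_length)`` spans, the last truncated if L is not a
    multiple of ``segment_length``.
    """
    L = pair.n_columns
    cuts = [0, *pair.diagnostic_sites, L]
    # a site at column 0 or L would create an empty leading/trailing interval;
    # keep it (the spec tiling: interval count = site count + 1) but guard order
    intervals = tuple((cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1))
    n_seg = max(1, -(-L // segment_length))
    edges = tuple(min(i * segment_length, L) for i in range(n_seg + 1))
    return IntervalMap(intervals, edges)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(DNA_ALPHABET))[rng.integers(0, 4, size=n)])


def build_cassette(
    pair: AluPair,
    spacer_length: int = 1100,
    promoter_length: int = 1200,
    reporter_length: int = 600,
    window: tuple[int, int] = (897, 1881),
    seed: int = 0,
) -> ReporterCassette:
    """Assemble the full reporter construct around an Alu pair.

    The spacer between the Alus is tiled by neoR, polyA and the 18-bp I-SceI
    site; filler sequence (promoter, neoR, polyA, puroR) is seeded-random DNA.
    Defaults (promoter 1200, Alu 300, spacer 1100, puroR 600) give a 3500-bp
    construct with ``alu2.start - alu1.end = 1100``.
    """
    if spacer_length < len(SCEI_SITE):
        raise ValueError(
            f"spacer_length must be >= {len(SCEI_SITE)} bp (I-SceI site), got {spacer_length}"
        )
    if promoter_length <= 0 or reporter_length <= 0:
        raise ValueError("promoter and reporter lengths must be positive")
    rng = np.random.default_rng(seed)

    remainder = spacer_length - len(SCEI_SITE)
    polya_len = min(200, remainder // 3)
    neo_len = remainder - polya_len

    parts: list[tuple[str, str]] = [
        ("promoter", _random_dna(rng, promoter_length)),
        ("alu1", pair.alu1.bases),
        ("neoR", _random_dna(rng, neo_len)),
        ("polyA", _random_dna(rng, polya_len)),
        ("sceI_site", SCEI_SITE),
        ("alu2", pair.alu2.bases),
        ("puroR", _random_dna(rng, reporter_length)),
    ]
    features = []
    cursor = 0
    for name, seq in parts:
        features.append(Feature(name, cursor, cursor + len(seq)))
        cursor += len(seq)
    sequence = "".join(seq for _, seq in parts)
    return ReporterCassette(tuple(features), sequence, window)
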