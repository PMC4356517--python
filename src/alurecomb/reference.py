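"""Published measurements for the reporter divergence series.

These are experimental observations (mean puro^r colony counts per 10^6 cells
with standard errors, and pathway splits from sequenced repair junctions) for
reporter constructs whose two Alu elements differ by the stated percent
divergence.  They serve as worked-example inputs for the fold-decrease and
adjusted-colony arithmetic and as mixture presets for the simulator; they are
not recomputable quantities.

Keys are percent divergence; 75 is the scrambled-sequence control (mean of the
two scrambled constructs).  Pathway splits are (Alu/Alu recombination %,
NHEJ %); the 0.7% construct was not sequenced, so it has no split.
"""

from __future__ import annotations

#: mean puro^r colonies per 10^6 cells, by Alu divergence (%)
COLONY_MEANS: dict[float, float] = {
    0: 1164,
    0.7: 822,
    3: 209,
    5: 77,
    10: 50,
    15: 334,
    20: 267,
    30: 195,
    75: 21,
}

#: standard errors of the colony means
COLONY_SE: dict[float, float] = {
    0: 34,
    0.7: 25,
    3: 39,
    5: 8,
    10: 6,
    15: 52,
    20: 46,
    30: 16,
    75: 6,
}

#: (Alu/Alu recombination %, NHEJ %) among sequenced repair junctions
PATHWAY_SPLITS: dict[float, tuple[float, float]] = {
    0: (100, 0),
    3: (69, 31),
    5: (55, 45),
    10: (44, 56),
    15: (9, 91),
    20: (0, 100),
    30: (0, 100),
    75: (0, 100),
}

#: number of mapped Alu/Alu recombination junctions in the pooled 5' bias analysis
N_MAPPED_RECOMBINATION_JUNCTIONS: int = 169
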