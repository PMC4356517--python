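# alurecomb

Simulation and junction analysis for an Alu/Alu recombination reporter.

Alu elements are ~300-bp primate SINE repeats, abundant enough that a DNA
double-strand break (DSB) between two of them is often repaired using their
mutual homology, deleting everything in between. Whether that repair runs
through single-strand annealing (one chimeric Alu), through microhomology-
mediated end joining, or through ordinary non-homologous end joining (NHEJ)
depends strongly on how diverged the two Alus are. `alurecomb` models the
selection-based reporter used to measure this: two direct-repeat Alus flanking
a `neoR`–polyA–I-SceI spacer, with an upstream promoter and a promoterless
`puroR` gene, so that only deletion products in a defined size window
(897–1881 bp by default) produce selectable colonies.

The package is aimed at people analysing repair-junction sequences from such
constructs (or benchmarking junction callers on them). It provides:

* **cassette model** — diverged Alu pair generation (evenly spaced, random or
  scrambled substitutions), global pairwise alignment with indel-run
  collapsing, the map of homology intervals between diagnostic sites, and
  cassette assembly with FASTA/JSON/GFF3 I/O;
* **repair simulator** — selectable products with known truth for
  single-crossover recombinants, complex (patchy) chimeras and NHEJ
  deletions, under configurable class mixtures and crossover-bias presets;
* **junction caller** — anchors a product sequence to the cassette, leftmost-
  normalizes the deletion breakpoints (reporting the microhomology ambiguity
  window explicitly), genotypes the chimeric Alu at every diagnostic site and
  classifies the event;
* **statistics** — interval-weighted expected junction counts per reporting
  segment, chi-square goodness-of-fit with per-segment flags, pathway
  proportions, fold-decrease and adjusted-colony arithmetic.

## The model in brief

For a pair of Alus aligned with diagnostic (differing) columns at positions
$s_1 < s_2 < \dots < s_k$, a recombination junction is only mappable to one of
the $k+1$ homology intervals between consecutive sites. A product genotyped as
parent 1 at sites $1..i-1$ and parent 2 from site $i$ on is a single crossover
in interval $i$; two or more parent switches mark a complex chimera. A
deletion junction with flanks sharing $m$ bases has $m+1$ equivalent
breakpoint placements; breakpoints are reported leftmost with
`breakpoint_ambiguity = m`. Observed junction counts per 100-bp segment are
compared to the expectation $E_i = n \cdot I_i / I$ (with $I_i$ intervals
whose midpoint falls in segment $i$) by $\chi^2 = \sum_i (O_i - E_i)^2 / E_i$
on $k-1$ degrees of freedom.

## Worked example

```sh
python examples/02_simulate_and_call.py
```

```
simulated 200 colonies (110 non-selectable draws rejected)
called classes: {'NHEJ_DELETION': 95, 'RECOMB_SINGLE_CROSSOVER': 85, 'RECOMB_COMPLEX_CHIMERA': 20}
class agreement with truth: 200/200
NHEJ junction microhomology: mean 0.74 bp, max 5 bp
NHEJ topology: {'one_Alu': 51, 'both_Alus': 43, 'no_Alu': 1}
```

200 selectable products were drawn from a 45/10/45 mixture of single
crossovers, complex chimeras and NHEJ deletions on a 5%-diverged pair; the
caller recovered every event class from sequence alone; NHEJ junction
microhomology (not imposed, emergent from the cassette sequence) averages
under 1 bp for uniformly drawn breakpoints; most NHEJ deletions break inside
at least one Alu, as the selectable window forces them into the Alu
neighbourhood. The other examples build the reporter, test a 5'-biased
junction distribution (chi-square p ≈ 6e-10 at 60% of 169 junctions in the
first segment) and reproduce the published fold-decrease column (1.4, 6, 15,
23, 3, 4, 6, 55) from the divergence-series colony counts.

The same pipeline is scriptable from the shell:

```sh
alurecomb simulate --n 100 --seed 5 --outdir run
alurecomb call run/products.fasta run/cassette.json run/pair.fasta -o calls.tsv
alurecomb stats calls.tsv run/pair.fasta -o report.json --summary summary.tsv
alurecomb report report.json
```

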