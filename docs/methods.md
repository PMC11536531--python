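# Methods

## Enrichment model

Contamination is tested per assembly, not per contig. The null assumes
every site is an independent, uniform draw over {A, C, G, T}, so a fixed
adapter of length L occurs at a given window start with probability 1/4^L.
An assembly of total length X with y contigs exposes X − (L−1)·y window
starts, giving the expected chance count λ = (X − (L−1)y)/4^L; for the
12-base universal adapter this is (X − 11y)/4¹². Occurrence counts are
modelled as Poisson(λ), and the p-value for an observed count k is the
upper tail Pr(O ≥ k).

Two modelling caveats are deliberate properties of this null, not bugs:

* **Composition.** The null ignores GC content and repeat structure. A
  genome whose composition favors the adapter's 12-mer will be slightly
  anti-conservative; this matches the screening use case, where candidate
  flags are followed by positional evidence (hits clustered at contig
  extremities) before repair.
* **Orientation.** λ as written above is the expectation for a *single*
  12-mer, while the default observed count k includes both the adapter
  and its reverse complement. That pairing reproduces the convention of
  published database screens and is the package default. It makes the
  null anti-conservative by at most a factor of two in expectation; users
  wanting a strand-symmetric null can pass ``lambda_both_strands=True``
  (CLI ``--lambda-both-strands``), which doubles λ. The strictly
  conservative calibration guarantee (flag rate ≤ α on clean data) holds
  under the symmetric null; under the default it holds approximately
  (flag rate ≤ 1 − e^(−2λ·α-quantile), empirically ~1.2% at α = 1% for
  the 100 kb / 20-contig geometry used in the calibration tests).

## Numerics of the deep tail

Significance thresholds of interest reach 1e-16, far below where the
printed alternating form 1 − e^(−λ)Σλ^j/j! can be summed in double
precision. The implementation instead evaluates the regularized lower
incomplete gamma function P(k, λ) (scipy's ``gammainc``), which equals
the Poisson upper tail exactly and is stable for λ down to ~1e-12 and k
up to ~1e4. Values below 1e-300 are clamped to that floor (displayed as
``<1e-300`` in TSV output); k = 0 returns exactly 1. Tests verify
agreement with a 60-digit arbitrary-precision evaluation of the printed
form to relative error < 1e-10 across λ ∈ [1e-6, 10], k ∈ [0, 50].

## Multiple testing and reporting

Across a batch of assemblies, Benjamini–Hochberg step-up q-values are
computed jointly (statsmodels ``fdr_bh``), with significance declared at
q ≤ 0.1 by default. Because BH depends on the whole p-value vector,
splitting a database into separate runs and concatenating is not
equivalent to one joint run; the CLI warns when joint correction is
disabled. Alongside the FDR call, three fixed p-value thresholds
{0.01, 0.001, 1e-16} are reported as first-class columns, with the
expected number of chance flags (n·α) printed for each.

## Trimming rule

A hit interval overlapping the first (or last) 300 bases of a contig
triggers removal of the first (or last) 450 bases. "Overlapping" rather
than "contained": any overlap means adapter residue inside the window.
Both ends may be trimmed. The 450/300 asymmetry buys a 150-base safety
margin past the detection window, removing the adapter-fragment stack and
flanking low-quality sequence in one fixed cut. Contigs left shorter than
``min_retained`` (default 100 bases; set 1 to disable) are dropped and
logged — emitting sub-100-base stubs would only pollute downstream
analyses. Trim lengths below the detection window are permitted (the
sweep command exercises them); they simply may leave residue.

## Perfect-overlap reassembly

The merger joins trimmed contigs whose ends share an **exact** overlap of
≥ 40 bases (40 matching the customary assembler default for minimal
overlap). All four end-pairings of a contig pair are searched — plain
suffix→prefix in both orders, and the two reverse-complement dovetails —
plus containments (a contig wholly inside another, either orientation)
and self-overlaps (candidate circularizations, which are reported but
never collapsed). Overlap search is anchored on the first 40 bases of the
downstream contig and scanned with C-level string search, so it is linear
in practice.

Merging is greedy, longest overlap first, ties broken lexicographically
by contig id — deterministic output. Each contig end participates in at
most one join; chains propagate (A+B, then AB+C); merges that would
circularize a chain are skipped. At merge time the overlap is re-verified
against the current sequences; a mismatch raises an internal invariant
error. Merged ids join member ids with "+"; the merged strand follows
the first contig of the chain. Contained contigs are absorbed (they
contribute no sequence) and counted as merged.

This is deliberately stricter than consensus assemblers run in
high-identity mode (e.g. 99% identity with quality-weighted consensus):
requiring 100% identity trades a little sensitivity near remaining
sequencing errors for exact reproducibility and no consensus ambiguity.
Merge counts on real data are therefore expected to approximate, not
equal, those of a consensus assembler.

## Synthetic data generator

The generator emulates the empirically observed contamination structure:
universal adapters near contig 3′ ends flanked by partial forward/
reverse-specific adapter sequences (`CACACGTCTGAACTCCAGTCA` /
`CGTCGTGTAGGGAAAGAGTGT`, fragment lengths drawn 5–21), reverse
complements near 5′ starts, and random junk between the adapter and the
contig tip. Defaults: junk flank 30 bases (placing adapters tens of bases
from the tip, as observed in contaminated assemblies), hidden overlap
60 bases, GC 0.5, i.i.d. sites. Seeds are mandatory in the library API;
identical seeds give byte-identical output.

Key design choice: ``hidden_overlap`` is defined as the genuine overlap
remaining **after** the default trim. At each break the generator plants
a genomic duplication of hidden_overlap + (450 − plant_left) +
(450 − plant_right) bases (plant = junk + adapter + fragment, ≤ ~330
bases), so the 300/450 rule leaves exactly ``hidden_overlap`` bases of
genuine overlap at every junction and the repair pipeline restores the
reference base-exactly. Defining the knob on the post-trim scale is what
makes round-trip guarantees expressible; a fixed pre-trim duplication of
60 bases could never survive two 450-base cuts.

What the generator does **not** emulate: sequencing errors (so real
assemblies may fail the 100%-identity merge where a consensus assembler
would succeed), GC/composition bias, repeats longer than chance 40-mers,
coverage structure, and read-level artifacts. Passing round-trip tests
therefore demonstrates correctness of the detection/trim/merge logic, not
that real assemblies always re-merge; on real data the trim stage is
unconditionally safe while the merge stage is opportunistic.

Chance adapter occurrences in random references are retained (they are
the null). They are harmless to round trips in practice: a chance hit
triggers a spurious trim only if it lands within 300 bases of a genuine
(outer) contig end, probability ~10⁻⁴ per synthetic assembly at the sizes
used.

## Trim-length sweep behaviour

On synthetic data with junk flanks drawn 20–290 bases and 60-base hidden
overlaps, the mean ΔN50 across the grid {150, 250, 350, 450, 550, 650}
is maximal at 450. The response is a plateau, not a peak: any trim length
long enough to clear every plant (> max plant, ~330 bases here) and short
enough to preserve ≥ 40 bases of hidden overlap (< 460 here) yields the
identical merged assembly, so 350 can tie 450; 150/250 lose junctions
whose plants they fail to clear, and 550/650 destroy the hidden overlap
entirely. The package asserts 450 attains the maximum and strictly beats
the grid's extremes.

## Problem sizes in tests and the acceptance script

Null calibration uses 5,000 clean assemblies of 100 kb / 20 contigs in
the test suite and 2,000 in the acceptance script; round trips use 1–10
breaks on 50–275 kb references; the GLM uses 200 assemblies with 0–25
breaks (0–50 planted adapters). These sizes give stable statistics
(binomial SE ≈ 0.0014 on the calibration fraction) while keeping a full
run in tens of seconds on one CPU.

## Known limitations

* Exact matching only: a single sequencing error inside an adapter copy
  hides it from detection (no mismatch-tolerant scan).
* The uniform-composition null can be anti-conservative for genomes
  whose k-mer spectrum favors the adapter sequence.
* The merger requires perfect overlaps; assemblies with residual errors
  in trimmed regions will under-merge relative to consensus assemblers.
* Circular contigs are flagged but not circularized.
* FASTQ/read-level trimming is out of scope — this package operates on
  assembled contigs only.
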