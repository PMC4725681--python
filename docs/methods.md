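# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical choices behind them, and what the
synthetic-data generator does and does not emulate.

## Pipeline model

A nuclear DNA barcode is modelled as a locus of the form

```
[forward primer site, 20 bp][inner region, variable][reverse primer site, 20 bp]
```

where the primer sites are conserved across the species of interest and the
inner region discriminates them. The discovery half of the pipeline searches
genome collections for such loci; the application half assigns sequenced
amplicons to species by exact comparison of inner regions and converts
marker read counts into mass fractions.

## Seed screening and extension

Seeds (e.g. elements known to be identical across several plant genomes)
are screened against two anchor genomes — one dicot, one monocot in the
original application, to avoid clade bias — and kept only when they produce
a local alignment scoring at least `min_score` in **both** anchors. The
phrasing of the screening rule could also be read as "at least one anchor";
the stricter both-anchors reading was adopted as the one consistent with
screening for broadly conserved material.

The search engine is a k-mer-prescreened Smith–Waterman: sequence pairs
sharing no exact word of `word_size` (default 11) bases are skipped, which
is the classic seeding precondition; otherwise the full affine-gap DP is
run (numba-compiled kernels). Scoring defaults: match +1, mismatch −2, gap
open −5, gap extend −2 (a gap of length L costs `5 + 2(L−1)`), with
`min_score = 40`. E-values are not computed; a raw score threshold keeps
desk-scale runs deterministic. Multiple hits per subject are produced by
recursive splitting — record the best local alignment, then search the
subject segments strictly left and right of its footprint — which is
deterministic and exactly replicable by an independent DP oracle. Hits are
extended by a flank of 200 bases on each side (clipped at genome bounds),
enough to contain a full 350-bp design window; minus-strand hits are
reverse-complemented so all regions read in seed orientation.

## Alignment and conservation

The built-in multiple aligner is a center-star progressive alignment: the
center is the sequence with the highest summed pairwise 6-mer-profile
similarity (ties to input order), all others are aligned to it globally
(match +1, mismatch −1, gap open −4, gap extend −1), and the pairwise
alignments are merged under once-a-gap-always-a-gap. It is deterministic
and adequate for the high-identity region families this pipeline produces;
it is *not* benchmarked against Clustal/MAFFT, and externally computed
alignments (aligned FASTA or Clustal format) are the intended path for
production-scale jobs.

Conservation is summarised per column as the majority-base fraction with
**gaps counted in the denominator**: a column where any species carries an
indel is penalised, because a primer window must be indel-free to anneal
uniformly across species. Majority ties break by fixed base order
A < C < G < T. Consensus calls are either strict (majority base,
gap-majority columns omitted) or IUPAC-degenerate (code covering every base
at frequency ≥ 0.25).

## Primer design

Primer windows are 20 consecutive columns with every column's majority
fraction ≥ 0.90 and gap fraction ≤ 0 (both configurable; how conserved is
conserved enough is ultimately an assay decision, so these are operational
defaults rather than biological constants). Windows are paired whenever the
upstream window ends at or before the downstream window starts and the
implied amplicon — measured **primer-inclusive**, from upstream window
start to downstream window end — lies in [100, 350] bp. Primer-inclusive
measurement is fixed by the reference locus arithmetic: a 20 + 154 + 20
locus yields the expected 194-bp product. The forward primer is the strict
consensus of the upstream window; the reverse primer is the reverse
complement of the downstream window's consensus (windows are only ever
scanned on the profile's forward orientation). Pairs are named
`<seed>-aaa`, `<seed>-aab`, … with a base-26 counter (capacity 17 576 pairs
per seed). Melting temperature, GC content and dimer screens are
deliberately out of scope.

## In-silico PCR

A primer anneals wherever a semi-global alignment against the subject
accumulates at most `max_errors` mismatches plus gaps; IUPAC-degenerate
primer letters match compatible bases at zero cost. The error-profile per
site end is computed exactly by a Sellers semi-global DP; overlapping
candidate placements (ends closer than one primer length) are collapsed to
the placement with fewest errors, ties to the leftmost, mirroring how
e-PCR-style tools report single sites. Site starts and the mismatch/gap
split are recovered with edlib in prefix mode on reversed strings. Two
presets mirror the two scans performed in practice: genome scans cap the
**total** errors across both primers at 4; nucleotide-database scans cap
errors **per primer** at 2. Scan product-size bounds default to [50, 1000]
bp — deliberately wider than the design-time 100–350 bp, so that length
distributions of predicted products can be inspected rather than
pre-filtered. Products are predicted on both strands and normalised so the
inner sequence always reads forward-primer-first; nearby loci legitimately
yield cross-products when within the size bounds.

Reference records keep only the inner sequence (both primer spans removed)
because that is the unit compared with primer-trimmed reads. An inner
sequence is *diagnostic* when the whole reference set attributes it to
exactly one species; species tallies per taxonomy division (Plants,
Invertebrates, Vertebrates, other) count species owning at least one
diagnostic sequence.

## Taxonomy

Both NCBI-taxdump (`nodes.dmp`/`names.dmp`, optional `division.dmp`) and a
simplified 5-column lineage TSV load into the same structure: a rooted tree
whose single root is its own parent; cycles and orphans are structural
errors. The LCA of a taxid set is the deepest node ancestral-or-equal to
all members (computed by lineage-prefix intersection). Divisions are
inherited from the nearest labelled ancestor when a node's own division is
empty. Merged/deleted-taxid remapping and homonym disambiguation are out of
scope.

## Read assignment

Reads are expected post error-correction, in the fusion-primer layout
`MID + primer + inner + revcomp(other primer)`, sequenced bidirectionally.

* **Demultiplexing** matches the 5'-prefix against the MID scheme exactly
  (budget configurable, default 0 mismatches, as in fastx-style splitters);
  ambiguous or unmatched reads go to an unassigned bin, and every read
  lands in exactly one bin.
* **Orientation and trimming**: a read starting (within 2 errors,
  semi-global) with the forward primer keeps its orientation, one starting
  with the reverse primer is flipped; the 5' primer span is removed and the
  3' span removed best-effort — a truncated read missing its 3' primer is
  kept, since full-length identity clustering will sort it out. Ties in
  the cut position (a substitution at a terminal primer base) resolve to
  the longest primer span so primer bases never leak into the inner
  sequence.
* **Clustering** is exact full-length string identity over the union of
  trimmed reads and reference inner sequences (the cd-hit-est
  `-c 1.0 -aL 1 -aS 1` regime). This is intentionally strict: reads with
  residual errors become *unassigned* rather than misassigned.
* **Conclusions**: a mixed cluster (reads + references) concludes at its
  single reference species, or at the LCA of its reference species when
  they share the sequence. The ranked report orders mixed clusters by
  descending read count, ties by representative sequence
  (deterministic); reference-only clusters are excluded from the ranked
  table but retained in the totals. Count conservation holds at every
  stage: routed + unassigned = input; trimmed + rejected = routed;
  assigned + unassigned = trimmed.

## Relative quantification

Summing all assigned reads per species is a poor mixture estimator: locus
copy number differs between species, some references are shared between
species, and per-locus amplification efficiency varies widely. Instead one
**marker** locus per species is chosen from its pure-sample run — the
cluster with the most reads among clusters holding exactly one reference
record of that species — as the locus presumed closest to optimal
amplification. In the mixture, each species' raw count is its marker
cluster's read count (0 when absent); correction multiplies by the species'
1C genome mass in pg (`corrected = reads × C`), since read counts track
template copy number while mixtures are specified by mass; percentages are
`100 × corrected / Σ corrected`, rounded half-up to one decimal (matching
the printed presentation), so a percent vector sums to 100.0 ± 0.1.
Correction direction is fixed by the published arithmetic
(2688 × 1.13 = 3037.44). Note that two of the published corrected-maize
cells are inconsistent with their own raw counts (667 × 2.73 ≠ 1848.21;
1103 × 2.73 ≠ 2765.49, presumably transcription slips); the package
reproduces the internally consistent cells.

## Synthetic data: what it emulates, and what it does not

The generator plants the default barcode locus architecture — the published
20-mer primers around a 154-bp inner region, 194 bp primer-inclusive — into
random background genomes: one ancestral inner sequence, mutated per
species at `inner_divergence` (default 0.05, a plausible between-species
divergence for a discriminating nuclear locus) and per copy at
`copy_divergence` (default 0; study scenarios use 0.02 so copies are
distinguishable). Copies are non-overlapping, primer sites exact by
default, optionally on the minus strand. Reads are drawn per species with
probability ∝ `weight / C` (template copies per unit mass) and uniformly
across that species' copies, half from each sequencing direction, with MID
and primers prepended as in the fusion-primer layout.

The error model is substitution-only at a default of 0.2 %/base. This rate
is calibrated so that the expected fraction of reads assigned under
full-length exact clustering, ≈ (1 − e)^194 ≈ 0.73, matches the ~28 %
unassigned fraction reported for error-corrected reads in the reference
experiments; simulated runs show 25–27 % unassigned. Homopolymer indels of
the original pyrosequencing instrument are omitted (an indel read is
unassigned by construction under exact clustering, so modelling them only
rescales the assigned fraction); PCR chimeras, per-locus amplification
bias, and quality values are not modelled. Consequently, passing tests
demonstrate the pipeline's *logic* — routing, trimming, clustering,
conclusions and the quantification arithmetic — not robustness to
instrument-specific artefacts or to reference databases with errors.

The end-to-end mixture scenarios use equal locus copy number (3) in both
genomes: because simulated reads spread uniformly across a species' copies,
unequal copy number would dilute the marker cluster asymmetrically by
construction. Copy-number heterogeneity (the motivation for the marker
approach) is exercised separately in marker-selection tests.

## Numerical and determinism choices

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical inputs and seeds give byte-identical
  outputs (asserted in tests).
* Alignment DP kernels are exact (no banding or X-drop); numba compiles
  them at first use.
* Tie-breaks are fixed everywhere: best-local-alignment cell by smallest
  (subject end, query end); traceback prefers diagonal, then vertical;
  majority base by A < C < G < T; primer-site collapse to fewest errors
  then leftmost; trim cuts to the longest primer span; cluster ordering by
  (−reads, representative); marker ties to report order.
* Degenerate inputs: empty FASTA files are valid (empty list); a
  single-sequence alignment's consensus is that sequence; an empty
  reference set tallies zero everywhere; a zero total in quantification
  reports 0 % rather than dividing by zero.

## Problem sizes used in the test suite

Oracle-equivalence tests run on 2 kb × 400–500 b alignment instances,
2 kb subjects for primer-site search, 10⁴ sequences for clustering, and
~200-node random taxonomies for LCA. End-to-end mixture recovery uses two
10-kb genomes, 3 locus copies, 3000-read pure samples and 10⁴-read
mixtures at 25:75 / 50:50 / 75:25 across five seeds, recovering every
percentage within ±3 points. These sizes exercise every code path of the
full-scale computation; only the collection sizes are reduced.

## Known limitations

* The center-star aligner degrades on low-identity or heavily-indel'd
  region families; load an external alignment for those.
* Primer-site collapse reports one site per overlapping placement group, so
  two true sites closer than one primer length merge into one.
* The homology search's word prescreen can miss genuinely weak homologies
  with no shared 11-mer (by design, mirroring seeded search tools).
* Quantification assumes the marker loci amplify comparably between
  species; it corrects for genome size, not for PCR efficiency differences
  between the chosen markers.
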