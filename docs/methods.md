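# Methods

## The call being made

The analysis asks, for every lineage-specific lncRNA: does another lineage
carry a lncRNA at the *same genomic position* relative to the *same
(orthologous) protein-coding anchor gene*, in the *same relative
direction*, even though the sequences no longer align?  A locus is reported
"sequence-diverged, positionally conserved" when at least one such call in
another lineage is positive.  The chain of definitions that makes this
reproducible:

* **lncRNA candidate** — transcript ≥ 200 nt whose longest ORF (all six
  frames, ATG-only start, TAA/TAG/TGA stops, stop codon excluded from the
  length) is < 100 aa.
* **Localization** — a transcript maps to its genome only when exactly one
  HSP passes the e-value cutoff and covers ≥ 50% of the query; multiple
  HSPs or low coverage reject the transcript (this also removes spliced
  and repetitive cases by construction).
* **Category** — NAT ≻ GATU ≻ LINC precedence.  NAT: overlaps a coding
  gene on the opposite strand (distance 0).  GATU: edge-to-edge gap
  < 500 bp.  LINC: gap ≥ 500 bp (a gap of exactly 500 bp is a LINC, because
  the intergenic rule is stated with ≥).  Nearest-gene ties break on
  lexicographic gene id.  Distances are edge-to-edge, 0-based half-open
  internally; GFF3 I/O converts to/from 1-based inclusive.
* **Lineage-specific** — a cluster at the tested identity cutoff whose
  members all belong to one lineage, span ≥ 2 distinct species
  (`min_species_transcribed`, default 2), and have no hit in the optional
  outgroup database at the same cutoffs.  A cluster spanning every
  configured lineage is labelled "All"; everything else is "unassigned".
  The positional analysis runs on the highest configured cutoff (50%).

## Alignment and statistics

Pairwise similarity is BLASTN-flavoured: match +2, mismatch −3, gap of
length L costs 5 + 2L.  The engine seeds on shared 11-mers, requires two
seeds on nearby diagonals (band 64) before triggering, and resolves each
seeded region with an exact affine-gap Smith–Waterman kernel (numba) on the
padded sub-rectangle; problems smaller than ~250k cells skip the heuristics
and run one exact DP.  Identity is coverage-weighted — identical positions
divided by *query length* — so short spurious hits cannot pass a high
cutoff, matching how OrthoMCL's percent-match cutoff behaves.  E-values use
Karlin–Altschul statistics: λ is solved exactly for the scoring scheme
(root of the lattice equation under uniform base frequencies); K is a fixed
documented approximation (0.30, exposed in `Scoring`) — at the 1e-10
threshold the decision would only move if K were wrong by orders of
magnitude.  Hit tables are written in outfmt-6-compatible TSV.

## RBH + MCL clustering

An edge requires mutual best hits *per species pair* (ties keep all tied
best hits, avoiding input-order dependence), with both directions passing
the identity and e-value cutoffs; within-species hits are ignored.  The
three cutoffs (10/20/50%) are clustered independently.  MCL runs on the
column-stochastic adjacency with self-loops (loop weight = the node's
maximum incident edge weight): expansion = matrix square, inflation = 1.5
(entrywise power + renormalization, the OrthoMCL default; the source
publications rarely state it), pruning below 1e-5, convergence when the
iterate stops changing by 1e-6.  Clusters are the connected components of
the converged matrix support, which makes the partition well-defined and
deterministic; a non-converged run (max 100 iterations) returns its current
partition with a flag.

## Synteny and projection

Collinearity is computed in gene-rank space (DAGchainer-style), not base
pairs: ranks are robust to intergenic-length noise and match how
synteny-browser tools operate.  Anchors are RBH gene pairs (nucleotide
level, ≥ 50% identity).  Chains maximize (+1 per anchor − 0.05 per skipped
rank on either genome) under a per-step rank-gap cap (default 20), tried in
both orientations; chains shorter than 4 anchors are discarded, anchors are
consumed greedily best-chain-first, and consecutive anchors sharing a gene
(tandem duplicates) collapse to the best-weight one beforehand.  These
constants are this package's choices — the upstream tools never publish
theirs — and are all exposed in configuration.  A query region projects
through a block via its flanking anchors: the projected interval spans the
b-side partners of the nearest anchors at or beyond the query edges
(coordinates swap automatically in inverted blocks).

## The positional window

The original analysis used a genome browser by eye; a reproducible
geometric stand-in is required.  The search window is the projected anchor
gene's body extended to the midpoint of the adjacent intergenic interval on
the matched side (5′ side for an upstream query, 3′ for downstream, bare
gene body for antisense/overlapping queries).  Matching directions are
computed natively in each genome relative to the local anchor's strand,
which makes inversion handling automatic: an inverted segment flips both
the physical side and the anchor strand, leaving "upstream" upstream.  A
candidate matches when it overlaps the window and has the query's relative
direction; ties resolve to the lexicographically smallest transcript id.
Loci are counted once per cluster (representative = lowest transcript id).

## Telomere statistic

Distance of a locus to the nearest chromosome end,
`min(start, chrom_length − end)`, with "within" inclusive at the 2.5 Mb
threshold.  The statistic is measured on the lncRNA locus itself (the
neighbour-gene alternative differs by at most one intergenic interval).
It is reported over the positionally conserved set; on the synthetic
default the chromosome is < 2.5 Mb long, so the fraction is trivially 100%
— the statistic is exercised non-trivially in unit tests with realistic
chromosome lengths.

## RNA structure

Two folding routes:

* `fold_nussinov` — exact base-pair maximization (AU/GC/GU wobble pairs,
  hairpin loops ≥ 3), the enumeration-testable core.
* `fold_energy` — Zuker-style minimum free energy under a reduced
  nearest-neighbour model: a 36-entry stacking table (approximate
  Watson–Crick/wobble values, kcal/mol), logarithmic hairpin
  (5.6 + 1.6·ln(size/3)) and interior/bulge (3.2 + 1.1·ln size, capped at
  30 unpaired) penalties, and an affine multiloop term
  (3.4 + 0.4/branch + 0.1/unpaired).  No dangles, coaxial stacking or
  special loops.  Consequence, stated prominently: absolute energies are on
  the right scale but will **not** reproduce full Turner-parameter folders
  (RNAfold); the published per-transcript MFE values can only be checked
  through the optional `external_fold_adapter`, which shells out to an
  RNAfold-compatible engine.  The built-in model is the default and the
  only one under test; its MFE is verified by brute-force enumeration at
  small n and by independent loop-decomposition rescoring of every reported
  structure.

The two stability conventions are deliberately kept as separate contexts
rather than reconciled, because they answer different questions and are
mutually inconsistent on their face: `mirna_precursor` calls −80 ≤ MFE ≤
−30 kcal/mol stable (a precursor hairpin window), while `lncrna_structure`
calls MFE < −80 kcal/mol stable.  Callers must choose a context.

## Synthetic data: what it emulates and what it does not

The generator draws one ancestral genome (alternating gene / intergenic
segments, one chromosome by default) and derives every species through a
two-level tree: lineage ancestor mutated at the segment's class rate, then
each species at `rate × within_lineage_scale` (default 0.25).  A star tree
over species cannot express the study's central contrast — high
within-lineage similarity with cross-lineage divergence — which is why the
lineage level exists.  Rates: coding genes `cds_divergence` (default 0.10),
intergenic DNA and fast lncRNA classes `lnc_divergence` (default 0.40,
intron-like; the published work gives no number for "highly diverged", so
these defaults are the module's choice, exposed in config).  Planted
classes:

* `sequence_conserved` — carried and transcribed by all lineages, evolves
  at the coding rate (sequence-constrained by definition; cross-lineage
  identity ≈ 78%, comfortably above the 50% cutoff);
* `positional_only` — carried by all lineages at the same anchor offset
  and relative direction, lncRNA rate between lineages (cross-lineage
  identity ≈ 35%, invisible at 50%) but within-lineage identity ≈ 81%;
* `private` — exists and is transcribed in exactly one lineage.

Categories are planted at configurable anchor offsets (LINC 1000 bp, GATU
100 bp, NAT overlapping the anchor's 3′ end by 200 bp with the overhang
carved as part of the locus).  Intergenic intervals holding a planted locus
are widened so the anchor stays the nearest gene and the positional window
reaches the locus.  Coding mRNAs for a sample of genes (20 by default) are
included in the transcript sets so the ORF filter is exercised with true
negatives; heavily mutated copies occasionally slip under 100 aa, which is
realistic noise and is handled by the lineage-spanning labels downstream.
Mutation is substitution-only: no indels, duplications, inversions or
rearrangements (inversions are exercised by unit fixtures in the synteny
module instead), no codon-aware evolution, no expression noise, identical
coordinates across species.  Passing the recovery test therefore shows the
*inference chain* is correct under its stated assumptions; it does not show
robustness to assembly gaps, splice variation or genuine genome
rearrangement.

## Recovery experiment (the analysis-level check)

Default conditions: three lineages of 3+2+2 species, one chromosome of 200
collinear genes (1 kb genes, mean 3 kb intergenic), 10 planted lncRNAs per
class, lncRNA length 500 nt, seed threaded through a single named
generator.  The pipeline must label planted `positional_only` loci
"sequence-diverged, positionally conserved" with sensitivity and precision
≥ 0.9 (scored at planted-locus level via the truth ids carried in
transcript names), call planted `private` loci positionally conserved at a
rate ≤ 0.1, and place `sequence_conserved` loci in cross-lineage clusters
at the 50% cutoff with sensitivity ≥ 0.9.  `scripts/acceptance.py` runs
exactly this from scratch at the given seed; the end-to-end run takes
~2 minutes on one CPU at these problem sizes (chosen so the whole suite
stays desk-scale).

## Numerical and degenerate-input choices

* Deterministic everywhere: sorted iteration orders, lexicographic
  tie-breaks (nearest gene, matched candidate, cluster representative,
  best-hit ties keep all), fixed cluster/block id assignment; re-running a
  fixed config is byte-identical (provenance carries a config hash and the
  package version, deliberately no wall-clock).
* Chromosomes with no coding genes make a located TU "unclassifiable";
  empty target candidate sets can never produce a positive call; an empty
  transcript set yields an empty, successful report.
* Traceback tie rules: Smith–Waterman prefers diagonal > query-gap >
  subject-gap; Nussinov prefers pairing (i, j) over bifurcation; the energy
  traceback re-derives decisions from the filled tables with a 1e-7
  tolerance in the documented option order.
* Folding length guard: 5,000 nt default cap (O(n³) recursion); the
  pipeline folds the positionally conserved representatives, mirroring
  what the original analysis folded, rather than every transcript.

## Known limitations

Nucleotide-only comparison (no protein-level outgroup screen — the local
outgroup FASTA screen stands in for remote database checks); pairwise
synteny only (no k-way blocks, no WGD-depth accounting); single-sequence
folding only (no consensus/alignment folding, no pseudoknots, no base-pair
probabilities); the positional window is a geometric substitute for a
curator's browser judgement and its width is a free parameter.
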