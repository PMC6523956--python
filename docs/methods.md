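# Methods

This note documents the models, parameter choices and deliberate
simplifications behind soxkit, and what the synthetic-data tests do and
do not demonstrate about real genomes.

## Genome model and gene order

Genes are 1-based inclusive intervals on named chromosomes (GFF3
convention), but every positional rule downstream — tandem adjacency,
proximity windows, flank windows, collinear gaps — operates on *ranks*:
the 0-based index of a gene along its chromosome ordered by ascending
start, ties broken lexicographically by gene id. The field states these
rules in gene counts ("within 20 genes", "adjacent"), not base pairs,
so ranks are the native coordinate. Only features of type `gene` are
ranked; transcript and exon children are ignored because the analysis
is gene-level. CDS records are checked to translate to their linked
protein after trimming a single terminal stop; internal stops are
errors.

## Homology search

All similarity scores are exact Smith–Waterman local alignments
(Biopython's pairwise aligner) under BLOSUM62 with gap existence 11 /
extension 1 — the classic protein-search defaults — rather than
heuristic word-seeded search. At the scale this package targets
(hundreds of proteins per genome survey) exactness is affordable and
keeps every E-value comparable. E-values use the Karlin–Altschul form
E = K·m·n·exp(−λS) with the standard gapped constants λ = 0.267,
K = 0.041; m is the query length and n the summed length of the
searched set. Heuristic seeding, composition-based statistics and full
profile HMMs are out of scope.

The HMG-box domain scan uses an ungapped position-specific log-odds
profile of length 79 built from aligned reference domains with a +1
pseudocount per residue and a uniform background. Because log-odds
scores in nats satisfy Σ p·e^s = 1 under the background, λ = 1 solves
the Karlin–Altschul equation exactly and `n_windows · exp(−score)` is a
conservative E-value bound; the domain gate defaults to E ≤ 1e−4.
Overlapping hits are merged keeping the best-scoring window.

Family mining intersects three strategies: seed-protein hits at
E ≤ 1e−5, domain confirmation at E ≤ 1e−4, and deduplication to one
protein per gene (longest isoform, ties by protein id). Group
assignment takes the reference domain with the highest identity,
requiring ≥ 0.70; identity divides matches by the longer sequence so
that residues the aligner gaps out still count against identity —
otherwise gapping a mismatched stretch would inflate it past the
threshold. Ties break by alignment score, then label.

## Duplication typing

Classification follows the documented MCScanX precedence — singleton →
WGD/segmental → tandem → proximal → dispersed — with its default
parameters exposed: top 5 hits per query in the hit graph, collinear
blocks of ≥ 5 pairs with rank gaps ≤ 25 (parallel or antiparallel
chains, found by longest-chain dynamic programming per chromosome
pair), proximity window 10 genes, tandem requiring rank distance
exactly 1. Percentages are reported to one decimal with half-up
rounding, matching how such tables are conventionally printed.
Genome-wide duplicate landscapes produced by other tools with unstated
settings are not reproduced; the bundled per-species family counts are
treated as inputs to the summary operation.

## Microsynteny

For each unordered family gene pair, windows of k = 20 genes up- and
downstream of both anchors are compared. A conserved pair is a flanker
whose *genome-wide* best non-self hit (E < 1e−5) lies in the opposite
window — the stricter reading; evaluating best hits within windows only
would inflate block counts. Each gene joins at most one conserved pair
(greedy by ascending E-value), so one promiscuous flanker cannot count
twice; overlapping same-chromosome windows share no double-counted
gene. ≥ 2 conserved pairs declare a block. Either-direction best hits
are accepted by default (a reciprocal-best requirement is the obvious
stricter alternative and can be imposed by filtering the pair list).

## NG86 Ka/Ks

Synonymous sites per codon are counted with denominator 3 per position
(changes to stop codons count as nonsynonymous), so N + S = 3·n_codons
holds exactly and the site totals of the two sequences are averaged.
Multi-difference codons are resolved by averaging over all minimal
substitution pathways, excluding pathways through stop codons and
re-weighting the rest equally (if every pathway is blocked, all are
used so the counts stay defined). Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3) is applied to both proportions; p ≥ 3/4 yields
NaN (a sentinel, never an exception), as does Ks = 0 for the ratio.
Undefined window ratios are reported as NaN and should be excluded from
plots rather than clamped, to avoid fabricating selection peaks.

NG86 was chosen as the concrete counting estimator because it is fully
specifiable and is the classical method behind the usual desktop tools;
maximum-likelihood estimators (GY94/codeml-style) and per-site tests
are out of scope. Only the standard genetic code is supported — the
target taxa are vertebrates.

Sliding windows default to 150 bp windows at 9 bp steps over the
ungapped codon alignment (window count = floor((L−w)/s) + 1); codons
only partially covered by a window are excluded from its estimate. The
x-axis convention is ungapped codon-alignment base pairs.

Selection calls: purifying below 0.9, neutral in [0.9, 1.1], positive
above 1.1. The band absorbs estimation noise around 1; the strict
textbook thresholds (<1, =1, >1) are recovered by setting the band to
(1, 1).

## qPCR quantification

The Livak formulation: technical replicates average to one CT per
gene × sample; ΔCT = CT_gene − CT_reference per sample; biological
replicates average on the ΔCT (cycle) scale, not the linear scale;
ΔΔCT is taken against the calibrator condition and fold = 2^(−ΔΔCT)
exactly. No amplification-efficiency correction is applied. The
estimator is invariant to per-sample plate shifts by construction.
Whether multiple tissues share one calibrator is a design choice left
to the caller (the calibrator condition is a parameter). Z-scored
expression matrices use the population (n) standard deviation, the
common heatmap convention; constant rows map to zeros and are flagged.

## The synthetic-data generator

`simulate.simulate_genome` emulates the data regime of a genome-wide
family survey, with every planted entity recorded in a truth table.

* **Background genes**: uniform amino-acid composition, lengths
  200–600 — simple, and sufficient to make the E-value gates
  meaningful (random pairs score far below every cutoff).
* **Family members**: a single random 79-aa core is mutated at ~10 % of
  sites per group to give reference domains, and each member's domain
  mutates its group reference at a further ~4 %. This hierarchy keeps
  within-family identity well above the 70 % group rule while making
  nearest-reference group assignment well-posed; a flat per-member
  mutation from one shared core would leave group labels ambiguous.
  Members also carry an exact 12-aa group motif, and their non-domain
  regions are drawn with hydrophilic-biased composition, emulating the
  uniformly negative GRAVY of HMG-box transcription factors.
* **Duplicate pairs** (tandem, proximal, WGD, microsynteny anchors) are
  produced by *codon-level* evolution of the source CDS at a configured
  dN/dS (default ω = 0.2, t = 0.1 expected substitutions per codon), so
  the selection stage sees pairs with known ω. The substitution kernel
  proposes uniform single-nucleotide changes, rejects stops, and
  accepts nonsynonymous proposals with probability proportional to ω —
  the same symmetric-rate assumptions NG86's site counting makes, so
  estimator recovery is unbiased by design. Codon-usage bias, indels,
  transition/transversion asymmetry and alternative transcripts are
  deliberately absent; passing recovery tests therefore demonstrates
  correctness of the counting machinery, not robustness to those
  real-data features.
* **Layout**: each planted entity consumes fresh chromosomes (tandem
  and proximal pairs one; WGD pairs and microsynteny anchor pairs two,
  with their collinear segments / conserved flankers placed at fixed
  offsets within the 20-gene windows; dispersed singles two per
  chromosome, far apart). Fresh chromosomes guarantee that planted
  flanking homologs can never leak into another anchor's window, which
  is what makes precision = recall = 1 the *correct* expectation at the
  default thresholds rather than a lucky draw. Infeasible requests
  (more entities than chromosomes, chromosomes shorter than the
  planted layouts) fail before any file is emitted.
* **Singletons cannot be planted**: family membership is defined by a
  shared domain, so every member has a significant family homolog and
  the singleton class is structurally empty for domain-defined
  families — consistent with such surveys reporting zero family
  singletons across species. The classifier's singleton branch is
  exercised directly with hit-graph-free inputs in the unit tests.
* A **domain-ablated negative control** (a reference protein with the
  domain scrambled) is planted by default: it is found by the seed
  search and must be rejected by the domain scan.
* **Determinism**: one `numpy` generator seeded from the config drives
  every draw; a fixed seed yields byte-identical FASTA/GFF3/JSON.

Default problem sizes — 12 chromosomes × 26 genes (312 proteins), 18
family members, 200 replicate codon pairs of 500 codons for estimator
recovery — were chosen so the full suite, including the exact
all-vs-all alignment of the synthetic proteome, completes in a few
minutes while leaving every statistical check with ample margin.

## Numerical choices

* pI bisection brackets [0, 14] and stops at |Q| < 1e−4 (with an
  effectively unlimited interval floor), so the returned pH satisfies
  the near-zero-charge property directly; it agrees with a 0.001-pH
  grid scan to < 0.01 in tests. The Bjellqvist pKa set (C-term 3.55,
  D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, N-term 7.5, K 10.0, R 12.0)
  is the default because the published tables this package mirrors
  were produced with the ExPASy tool; the set is configurable.
* Average (not monoisotopic) masses; molecular weight reported in kDa
  to 5 decimals, matching the conventional table format.
* Alignment tie-breaking is delegated to the pairwise aligner's
  deterministic traceback; all orderings that feed results (hits,
  members, blocks, classes) sort on explicit keys so outputs are
  independent of input order.

## Known limitations

* Exact all-vs-all alignment is quadratic; the package targets
  family-survey scale (≲ a few thousand proteins), not whole-proteome
  MCScanX throughput.
* The local profile scan replaces external domain databases; its
  E-value is a conservative bound, not a calibrated Pfam E-value.
* Real-genome runs require the caller to supply seed proteins and an
  aligned reference-domain set; published physicochemical table values
  can only be reproduced with the corresponding public sequences, which
  this package does not download.
* Phylogenetic tree building, de novo motif discovery, per-site
  likelihood selection tests, PPI/GO annotation and RNA-seq
  quantification are outside the package's scope; the expression module
  consumes already-quantified matrices only.
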