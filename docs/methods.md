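# Methods

## Coordinate model and I/O

All internal coordinates are 0-based half-open on the forward strand;
conversion to the 1-based inclusive conventions of GFF3 and the candidate
table happens only at the I/O boundary. FASTA is read through Biopython
SeqIO (upper-cased, U→T), MAF through Biopython AlignIO with
reverse-strand reference blocks flipped to reference-forward orientation,
GFF3 and BED6 through small column parsers with explicit error reporting.
A '.' strand is rejected for CDS/rRNA/tRNA because the overlap filters
require strand; N residues are allowed in genomes but windows containing N
are excluded from structure scanning and GC is computed over non-N
residues only.

## Energy model of the folding engine

The scanner uses its own deterministic nearest-neighbour model rather than
an external thermodynamic folder, so that the repository is self-contained
and the engine can be verified against exhaustive enumeration:

- pair types AU, UA, GC, CG, GU, UG with strengths s(GC) = 3.3,
  s(AU) = 2.1, s(GU) = 1.4 kcal/mol; stacking two adjacent pairs
  contributes −(s₁+s₂)/2;
- hairpin loops (≥ 3 unpaired nt): 5.0 + 1.3 ln(l/3); bulges:
  3.6 + 1.3 ln(l); internal loops (l = l₁+l₂): 2.0 + 1.3 ln(l/2);
  interior loops are bounded at 8 total unpaired nt;
- no multibranch loops: every closed substructure is a single (possibly
  interrupted) stem-loop, though disjoint stem-loops may sit side by side
  at the external level; no dangling ends or terminal mismatches;
- no base pair spans more than `max_span` (default 120) nt; the unpaired
  structure scores 0, so the MFE is ≤ 0.

The magnitudes are rounded from typical Watson–Crick stacking and loop
initiation values; the intent is a model that ranks stem-rich folds
realistically, not one that reproduces measured free energies. The test
suite proves the dynamic program equal to a brute-force enumeration of all
valid structures on random 15-mers, and checks dot-bracket validity
(balance, minimum hairpin loop 3, span bound) on longer random sequences.

## Shuffle null and Z-score

Shuffling preserves the exact multiset of overlapping dinucleotides (hence
mononucleotide counts and both terminal residues): a uniformly random
last-exit-edge arborescence toward the final residue is drawn by rejection
sampling, remaining out-edges are uniformly permuted, and the sequence is
read off the Eulerian path. This samples uniformly over all valid
arrangements; a swap-based shuffler was rejected because it biases the
null. Uniformity is tested against a brute-force enumeration of the valid
arrangement set of a small word.

z = (E_native − mean E_shuffled)/sd(E_shuffled) with 1000 shuffles and the
sample (ddof = 1) standard deviation; sd = 0 (e.g. homopolymers) defines
z = 0 so unstructured sequences can never pass a negative cutoff through a
degenerate denominator.

## Structure scan

Windows of `max_span` nt are placed every `step` = 40 nt (the start ladder
is symmetrized so that scanning the reverse complement visits the mirror
windows; the per-window shuffle stream is seeded from the window sequence
content, making the scan exactly strand-symmetric). Each window is folded,
trimmed to its outermost paired extent, and discarded if the trimmed span
is < 50 nt. The z statistic is evaluated per trimmed locus — the same
convention in which one stability value is reported per candidate locus.
Because the locus is *selected* as the stable part of its window, the null
distribution of this per-locus z is left-shifted; the −3.0 cutoff
corresponds to roughly the top few percent of loci, which is precisely the
selectivity the cutoff is meant to express.

Shuffle energies are drawn in stages (20, then 100, then the full 1000)
and a window is abandoned early when its provisional z misses a generous
checkpoint threshold (−2.5, −2.85). Reported z values always come from the
full 1000 draws; early stopping only removes windows that could not have
reached −3.0, with the caveat that a borderline locus whose provisional z
fluctuates above a checkpoint may occasionally be screened out. Planted
hairpins sit at z ≤ −8 and are unaffected. Overlapping same-strand hits
are merged into the lowest-z representative (ties: lower start).

## Conservation

Per position: the number of species (including the reference; range
0..n_species) whose aligned residue is non-gap and identical to the
reference; 0 where no block covers the position; overlapping blocks take
the maximum. A coverage-only variant (aligned, any residue) is available.
The alignment-quality statistic instead averages matches among the *other*
species only (range 0..n_species−1, unit weights) — both conventions are
deliberate and documented because summary scores of this kind are quoted
either way.

## dRNA-seq integration

A read belongs to a locus when ≥ 50 % of its length lies inside — robust
to ragged 454-style read ends. Enrichment: primary_enriched when
(+)-library/(−)-library ≥ 2 with ≥ 10 reads total (the library logic is
biological; the numeric thresholds are package defaults, config-exposed).
Antisense pairing: the smaller strand total × 10 must reach the larger
(both non-zero). No library-size normalization is applied by default since
screens of this kind quote raw counts; a per-million option exists on the
ratio helpers' inputs by pre-scaling. Head-to-head (h2h) and tail-to-tail
(t2t) classes describe opposite-strand gene pairs whose 5′ or 3′ ends
respectively fall inside the pair's overlap; full containment is classed
as neither.

## Candidate calling

Seeds = maximal runs of strand total coverage ≥ 5 (runs ≤ 20 nt apart
merged, bridging coverage dips of long-read data) ∪ structure-hit
intervals, merged per strand. Hard filters: length ≥ 25 nt; any overlap
with CDS/rRNA/tRNA (either strand) removes a seed from the novel set, with
expressed tRNA-overlapping loci rerouted to class tRNA_locus and seeds in
h2h/t2t mRNA overlap regions to those classes. A novel seed is retained
with read support (≥ 5 sense reads) OR ≥ 2 of {structure hit, median
conservation ≥ 9 of 11, external evidence} — the evidence combination is a
package decision (config-exposed) since integrative screens rarely state a
formal rule. Per-candidate summaries: mean local GC; *median* conservation
per alignment source (robust to block edges); best-z overlapping structure
hit on either strand (an unoriented structured locus folds on both
strands, and one stability value is reported per location); imported
external probabilities (e.g. a structure-conservation screen) rendered
non-significant below 0.5. IDs: n1… in genome order with antisense
partners sharing an ID, t2tK/h2hK per overlap class, tN;K for tRNA loci
(N = tRNA ordinal, K = running locus index).

## Synthetic study conditions

Defaults: 100 kb genome, background GC 0.43 (i.i.d. chain), 12 intergenic
ncRNAs + 3 antisense-pair loci (hairpin cassettes: 24–30 bp stems with
GC-pair probability tuned to overall GC ≈ 0.66, loops 4–8 nt → spans
52–68 nt), 20 AT-rich ORFs (start/stop codons, no internal stops), 2 tRNA
placeholders; 11-species gap-free alignment with identity 0.9 over planted
ncRNAs and 0.6 in 30 background blocks (i.i.d. substitutions, no indel
model — sufficient for conservation counting, not a phylogenetic
simulation); 454-like reads of 50–400 nt, 30 per transcript in the
TEX-treated library and half that untreated, with 5′-anchored starts at
0.75 vs 0.15 probability. These scales keep a full scan + call + score run
in minutes on one core while preserving the contrasts the method relies
on. What passing proves: the pipeline detects GC-rich, strongly structured
hairpin cassettes against an i.i.d. background with clean read signal. What
it does not probe: transcriptional noise, operonic read-through, repeats,
indels in alignments, sequencing error, or ncRNAs whose structure is weaker
than their conservation.

## Numerical and degenerate-input choices

Deterministic outputs for a fixed seed everywhere (content-derived shuffle
substreams in the scan; explicit rng_seed fields elsewhere). Ties in hit
merging break toward the lower start; identical-stop annotation matches
prefer an identical-start partner; empty inputs raise (empty genome, empty
anticodon set) or return empty results (no reads, no seeds) as documented
per function. Candidate tables are written sorted by (start, strand) so
equal inputs give byte-identical files.

## Known limitations

The energy model omits multiloops, dangles and measured Turner parameters,
so absolute MFE values are not comparable to thermodynamic folders — only
the shuffle-standardized z is interpreted. The per-locus z convention and
the staged screen are described above. The h2h/t2t classifier considers
pairwise CDS overlaps only. External structure-conservation evidence is
imported, never recomputed.
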