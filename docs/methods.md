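# Methods

This note records the models, conventions and numerical choices behind
mitoglyph, and what the synthetic-data tests do and do not demonstrate.

## Coordinate model and the audit

Features live on a circle of length *L* with 1-based inclusive
coordinates; internally all arithmetic is 0-based half-open and converts
back at the boundary. At most one feature wraps the origin (`end < start`;
length = *L* − start + 1 + end). Strand is relative to *cox1* ("+" = the
cox1 strand), and a feature's reading orientation is 5'→3' on its own
strand.

The `inc` value is attached to the junction *preceding* each gene in
circle order anchored at cox1, so the anchor's own `inc` is the wrap gap
after the last gene. Gaps at junctions flanking the control region are
attributed to the CR and excluded from the intergenic totals (published
intergenic totals for these genomes require that convention); overlap
totals count every junction with `inc < 0`, ties at zero counting as
abutting. The conservation identity Σ lengths − Σ overlaps + Σ gaps = *L*
is checked on every input and is the generator's master invariant.

The bundled whitefly annotation is transcribed from its published table.
Two cells of that table are internally inconsistent at the 1–2 bp level
(one tRNA Size cell vs its coordinates; one tRNA/PCG boundary off by one
between neighbouring rows); the fixture resolves both in the unique way
that keeps every published total (gene sizes, the inc column, the PCG bp
sum, the codon count, the intergenic total) simultaneously consistent, and
says so in a comment. Strand assignments are reconstructed from the
ancestral insect arrangement plus the rearrangements described for this
genome, because a plain-text table loses the typographic strand marking;
they should be cross-checked against the source accession where
available, and no test asserts per-strand gene counts.

Codon audit: starts must match ATN; stops are TAA/TAG or the single-T
incomplete token `T-` (completed to UAA by polyadenylation). Complete
codons = (Σ PCG bp − incomplete-stop nucleotides)/3; the audit also
reports "amino acids excluding stops" because published counts mix the two
conventions (3610 vs 3600 here). The punctuation check proposes trimming a
PCG that runs > 3 bp into a downstream tRNA back to the tRNA boundary —
refined, when sequence is present, to the nearest in-frame TAA/TAG or
in-frame terminal T within 60 nt — and flags PCGs outside a configurable
family length table (`data/pcg_reference_lengths.yaml`).

## Composition and codon usage

Skews follow (A−T)/(A+T) and (G−C)/(G+C) on the given strand; an empty
base class yields an undefined (None) skew, never NaN. Multi-gene classes
concatenate member regions in reading orientation. Codon-position pools
require in-frame regions with incomplete terminal nucleotides removed.

RSCU uses per-amino-acid synonymous families under the invertebrate
mitochondrial code by default (Ser |F| = 8, Leu |F| = 6; the two stop
codons observed form their own family). A `codon_box` mode splits families
by the first two codon positions (Leu → UUR + CUN, Ser → UCN + AGN),
because published tables sometimes normalise six-fold families that way —
the bundled counts reproduce the published Ser/Lys/stop cells under the
amino-acid convention and the published Leu cells only under the split
convention, so both are first-class and the choice is explicit. Reported
tables round half-up to 2 decimals only at serialisation; tests compare at
±0.005 on percentages/RSCU and ±0.001 on skews.

## tRNA cloverleaf model

The fold is an exhaustive search over arm-boundary placements: acceptor
stem 6–7 pairs, optional DHU arm (stem 3–4, loop 3–10), spacers 1–3 and
0–2 nt, anticodon stem 4–5 pairs with a fixed 7-nt loop (anticodon at loop
positions 3–5; no wobble repositioning), variable loop 3–9 nt (long
trnS-type variable arms are treated as unpaired spacer), TψC stem 3–5 with
loop 3–9. There is no discriminator/CCA modelling — genomic tRNA genes
generally lack the CCA. G–U counts as a valid pair; every other non-WC
pair is a mismatch. Score = valid pairs − 1·mismatches − 2·(missing DHU);
a structure is only returned when its valid pairs reach 18 (four-arm) or
14 (three-arm), thresholds at which the generator's perfect templates pass
and shuffled sequences fail. Ties break deterministically: score, then
valid pairs, fewer mismatches, four arms over three, lexicographically
smallest placement. The DNA alphabet (T, not U) is used throughout,
matching annotation-table anticodon spellings.

`rescue_scan` searches intergenic gaps and non-coding records (padded
60 bp into flanking genes) on both strands. For speed it anchors on
candidate anticodon loops whose decoded identity is sought and combines
left/right arm placements through their additive scores — the same grid
and scoring as the public fold, which is what the brute-force-oracle
property test checks. The anticodon must lie in unannotated territory;
otherwise alternative reading frames of genuine annotated tRNAs flood the
candidate list. Overlapping candidates reduce to the best score per locus.
Optional homology corroboration mirrors the original re-annotation
workflow (structure + homologous alignment): with reference sequences
given, a candidate needs ≥ 0.55 ungapped sliding identity to its
reference. Without references, precision against AT-rich random territory
is markedly lower — pair-counting alone is a weak discriminator, which is
exactly why covariance-model scanners exist (out of scope here).
Rescued DHU-less tRNAs can be reported with shifted boundaries when a
four-arm fold absorbing flanking nucleotides outscores the true three-arm
fold; recovery tests therefore match candidates to planted loci by
majority overlap, with exact ±2 bp agreement asserted for four-arm cases.

## Gene orders and rearrangement

Orders are signed circular permutations anchored at cox1 forward,
excluding control region and non-coding spans. A boundary g→h matches its
strand-flipped reversal −h→−g; with that equivalence every circular order
of *n* common genes has exactly *n* adjacencies, giving the exact identity
shared + breakpoint distance = *n* (brute-force checked). Minimum-event
inference is NP-hard, so `classify_events` is openly heuristic: decompose
the observed order into maximal reference-consecutive strips, keep the
heaviest forward chain as anchor, and label the rest (flipped in place =
inversion; moved = transposition; moved + flipped = inverse
transposition; absent = loss); ties in the anchor choice set an
`ambiguous` flag rather than being silently resolved. Re-applying the
classified events to the reference must reproduce the observed order on
scripted cases. `remnant_scan` emits a TDRL-style remnant when a lost
gene's reference flanks are adjacent in the observed order around a
non-coding gap ≥ 40 bp (configurable).

The gene-order tree is a *descriptive* UPGMA clustering of normalised
breakpoint distance (distance / common-gene count), hand-rolled in a few
lines because deterministic lexicographic tie-breaking is required;
a test cross-checks its cophenetic distances against scipy's average
linkage. It is not a substitute for model-based phylogenetics.

Gene-order fixtures: the study genome's order comes from its published
annotation table; the ancestral insect order is the standard
Drosophila-like arrangement; the other whitefly orders are reconstructed
from the published comparative narrative and carry a provenance comment.
Tests pin only what that narrative pins (the shared 17-gene block and
trnQ-trnV, the per-lineage cox3-trnG-nad3(-trnA-trnR(-trnN)) inverse
transposition, the trnS1/trnE/trnF steps, per-genome absences).

## Repeat scanning

For each candidate period p, positions where the sequence equals itself
shifted by p are found; a unit start is valid when a full p-window matches
the next unit at ≥ the identity threshold (default 0.85), and maximal runs
of valid starts become arrays with fractional terminal copies. There is no
indel model — unit identity is mean ungapped identity of consecutive
units — which suits short, well-conserved control-region arrays but not
diverged minisatellites. An array of unit p also self-matches at 2p, 3p, …
so overlapping candidates whose spans differ by less than one larger unit
are pruned to the smallest period; final selection is maximal
non-overlapping by longest span then smallest unit. Array boundaries can
shift by a few positions (up to ~(1−identity)·p) when background happens
to match in phase at an edge; homopolymer runs satisfy the tandem
definition and are reported as arrays too, alongside `find_homopolymers`.

## Synthetic genomes

The generator realises a serialisable plan — circle-ordered genes with
sizes and the inc vector, strands, codon assignments, anticodons, DHU
presence, control-region plan, deletion plan — as sequence + annotation +
truth record, bit-reproducibly per seed. Defaults mirror the bundled
annotation: its gene order, sizes and inc values, its start/stop codons
(ATN starts; TAA/TAG; single-T incomplete stops on the three genes that
have them), its anticodons, DHU-less trnS1/trnS2, a 875-bp control region
with a 12-T run and 128 bp × 2 and 19 bp × 8 arrays at the published
offsets (2% per-copy divergence), and per-class composition targets taken
from the published composition table (tRNA 77.2% AT, rRNA 76.6%, CR
66.9%, other non-coding 70.9%).

Realisation order resolves overlap constraints: PCG start/stop codons are
written first; tRNAs are built next from deterministic maximal-pairing
templates, adapting stems around already-fixed nucleotides (a forced
position's partner takes its complement, so overlapped tRNAs still fold
perfectly); PCG interiors are then drawn codon-by-codon from the
codon-usage profile (stop codons excluded from interior draws), with
overlap positions keeping their fixed values; rRNA, CR and leftover
territory fill from their composition targets. Because coding sequence is
codon-sampled, composition targets are exact in expectation only for
non-coding classes and emergent for PCGs (the default profile lands
within ~0.1 of the published PCG and third-position AT%). The tRNA class
compensates its free-position draw for the fixed anticodon nucleotides.
Deletion modes: `unannotated` (gene present in sequence, absent from
annotation — rescue's target), `remnant` (territory left as random
non-coding — remnant_scan's target), `excised` (gene and territory
removed, gaps merged).

What passing on synthetic data does *not* show: real mitogenomes have
sequence homology across species, composition heterogeneity along the
molecule, tRNA stem mismatches (the study genome has 39 across 21 tRNAs;
planted stems are perfect by default), and repeat units with indels. The
rescue precision figure in particular is measured with homologous
references emulated by 20%-mutated copies of the planted gene; real
cross-species references are a different (usually easier) similarity
regime.

## Test-size and tolerance choices

Property tests run at: 200 sequences for the fold-vs-oracle equality, 100
genomes (1–3 hidden tRNAs each) for rescue recall ≥ 0.95 / precision
≥ 0.9, 1000 coordinate-level genomes for the conservation identity, 100
planted perfect arrays (unit 10–200, 2–10 copies) for repeat recall, and
500 random order pairs for the breakpoint pseudo-metric — sizes chosen so
the whole suite completes in about a minute on one core while keeping
binomial noise well below the asserted margins. Composition recovery is
asserted on counts pooled over eight seeded genomes because single-genome
class sizes (0.9–2.5 kb) put binomial noise at or above the ±1.5-point
band; pooling tests the same unbiasedness claim at adequate power. All
stochastic tests are seeded.
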