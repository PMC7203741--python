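# Methods

## Model

A diploid genome sequenced at total fold-coverage *c* and assembled into
a "primary" contig set should represent every locus exactly once.  Where
the assembler kept both haplotype copies of a locus, reads split between
the copies and each copy sits near the haploid depth *h* ≈ *c*/2; where a
locus is represented once, it sits near the diploid depth *d* ≈ *c*; a
collapsed repeat with *m* extra genomic copies sits near *m·d*.  The
genome-wide depth histogram is therefore a mixture with peaks at *h* and
*d* (either may dominate, depending on how haplotype-resolved the
assembly is), and a threshold *T* in the valley between them separates
haplotype-resolved from collapsed sequence.  Depth is the arbiter that
sequence similarity lacks: similar sequence at depth < *T* is haplotypic
duplication; similar sequence at or above *T* is repeat and must not be
purged.

## Pipeline

**Depth collection** (`coverage`).  Each retained read-to-assembly PAF
record adds +1 over its full target span (difference arrays + prefix
sum, so results are order-invariant).  Records are retained when primary
(`tp:A:P` if the tag exists; untagged records are kept — PAF produced
without tags would otherwise contribute nothing) and `mapq >= min_mapq`
(default 0).  Span-level counting ignores CIGAR detail; at 40× and
10 kb+ reads the difference is negligible for threshold decisions.  The
histogram caps depths at `d_max` (default 4× the modal depth, floor 500)
in an overflow bin.

**Cutoff selection** (`cutoffs`).  The histogram is smoothed with a
moving average (window 5, edge-inclusive reflection so total mass is
conserved exactly); window 5 suppresses Poisson jitter without merging
peaks ≥ 10 apart.  The global smoothed peak p1 at depth ≥ `min_depth`
(default 4, excluding the overflow bin) anchors the search; a secondary
peak is sought in [0.4·p1, 0.65·p1] first and [1.5·p1, 2.5·p1] second —
lower window first because when p1 is the diploid peak, a
collapsed-repeat bump near 2·p1 must not be mistaken for its partner.  A
candidate qualifies if it is a local maximum (scipy `find_peaks`), its
height is at least 10% of p1's, and the valley between them dips below
95% of the lower peak — the height and valley conditions stop repeat
shoulders and noise from being read as a peak.  With two peaks, h and d are
the smaller and larger, T = argmin of the smoothed counts strictly
between them (ties toward the lower depth — conservative, classifying
less as haploid), L = max(2, h/4), H = 2.5·d, and the mode records which
peak is taller.  Unimodal histograms take p1 as the diploid peak:
T = 0.75·p1, L = max(2, 0.375·p1), H = 2.5·p1.  All constants are
parameters; the decision depends only on histogram shape, so cutoffs are
invariant under uniform count scaling.  Manual `-L/-T/-H` overrides
bypass detection but still enforce L < T < H.

**N-splitting** (`assembly_prep`).  Scaffolds are cut at N-runs of
length ≥ `min_gap` (default 1, the strictest reading of "gap");
shorter N-runs stay inside segments.  The segment map records original
coordinates so every call is lifted back onto the input assembly, and
split/merge is exactly reversible.  A segment spanning its whole contig
keeps the contig's name; actual fragments are named
`contig:start-end`.

**Chaining** (`purge_core`).  Self-alignment records are filtered
(self-hits out; `nmatch >= 500`, `alnlen >= 1000`; symmetric A→B/B→A
duplicates collapsed by canonical pair orientation) and chained per
segment pair and strand with a collinear DP: transitions allowed when
query and target gaps lie in [−`max_overlap` (100), `max_gap` (100 kb)]
with target order matching the strand, cost
`gap_open (100) + |qgap − tgap| · gap_scale (0.05)`.  Chains are
extracted best-score-first (each anchor in at most one chain) and kept
at score ≥ `min_chain_score` (10 kb) — high enough that incidental
repeat matches rarely chain, low enough for ~15 kb overlaps.  The DP is
verified against exhaustive path enumeration in the tests.

**Calling** (`purge_core`).  Segments with ≥ 80% of bases below L are
JUNK; ≥ 80% above H are HIGHCOV (collapsed repeats — reported, not
removed: explicit repeat handling is limited and removing high-depth
sequence risks overpurging).  Both are excluded from further calling.
Haplotigs: visiting segments in increasing length (deterministic nested
resolution), a segment is called when chains to strictly longer segments
cover ≥ `cov_frac` (0.8) of it and its mean depth is < T; all its
matches leave the working set.  Overlaps: a chain is a dovetail
candidate when it reaches within the end tolerance
(max(15 kb, 15% of the matched span)) of a strand-consistent end of each
segment; "unambiguous" means it is the only candidate touching each of
those two contig ends (ambiguous ends are left alone rather than
guessed).  If the matched interval's mean depth is < T on *both*
segments, the interval on the shorter segment (ties broken toward the
lexicographically larger name) is trimmed, extended to the contig end
when the residual overhang is within tolerance.  Calls are lifted to
input coordinates and merged with priority JUNK > HAPLOTIG > OVLP >
HIGHCOV.

**Extraction** (`seq_extract`).  Removed intervals are excised (not
masked); a fully covered contig moves whole to the removed set; residual
fragments < `min_keep` (1 kb, too short to scaffold) are removed as
SHORT; surviving fragments of a modified contig are renamed `name_1,
name_2, ...`.  Base accounting is exact and property-tested.

## K-mer evaluation

Canonical k-mers (lexicographic min of k-mer and reverse complement,
k ≤ 31, 2-bit packed, exact counts) are tallied for the read set and for
an assembly, and joined into a matrix M[r][c] = distinct k-mers with
read multiplicity r and assembly copy number c.  Single-locus k-mers are
those with r in the band spanning the haploid and diploid coverage peaks
with half-peak margins, [h/2, d + h/2): sequencing-error k-mers fall
below it, repeat k-mers above it.  Duplication is the excess copy count
D = Σ_band Σ_{c≥2} M[r][c]·(c−1), and purging quality is
1 − D(after)/D(before).  The band choice follows from the diagnostic
itself: retained haplotypic duplication puts two-copy k-mers across the
haploid *and* diploid multiplicity range (homozygous k-mers of a
duplicated region sit at d; same-haplotype duplicates sit at h), so the
band must span both peaks.  With fully phased alternate-haplotype
duplicates — the synthetic generator's construction — the two-copy
excess concentrates in the diploid part of the band.

## Synthetic scenarios

`synthetic.SimConfig` defaults define the study conditions: 2 Mb genome,
heterozygosity 1% (substitutions; 1–10 bp indels at a tenth of that
rate, capped so planted coordinates stay within chain tolerances),
10 primary contigs, 4 haplotigs (one reverse-complemented), 3 overlap
pairs of 50 kb, 2 junk contigs at ~1×, 1 collapsed repeat at 2× diploid
depth, 10 kb reads at 40× total, seed 42 — sized so every code path is
exercised in well under a minute.  Reads are placed by construction at
their true draft locations (uniform sampling per haplotype with end
overhang so coverage is flat; haplotype-B reads divert to planted
B-copies), which removes any aligner dependency from the tests; an
exact A↔B coordinate map keeps planted anchors collinear through
indels.  Self-alignment anchors are emitted in 5 gapped pieces per
relationship with identity 1 − heterozygosity, plus mirrored duplicates
and sub-threshold noise records to exercise filtering.

What the generator does **not** emulate: sequencing error, chimeric or
clipped reads, structural variants, segmental-duplication families,
low-complexity and satellite sequence, GC-coverage bias, and mosaic
(same-haplotype) duplication.  Passing the closed loop therefore shows
the machinery is correct and calibrated for cleanly diverged haplotypes
at adequate coverage; it does not bound performance on real assemblies,
where anchor noise and depth dispersion are higher.

## Numerical choices and degenerate inputs

Ties in the valley argmin and in best-chain extraction are broken toward
lower coordinates; equal-length overlap partners trim the
lexicographically larger name — all choices deterministic, so identical
inputs give byte-identical outputs.  Histograms with no mass at depth
≥ `min_depth` raise an "insufficient coverage" error suggesting manual
cutoffs rather than guessing.  Secondary peaks closer than 2 depth units
to p1 are treated as unimodal (no strict interior for the valley).
All-N contigs yield zero segments but stay in the segment map so
reconstruction is exact.  An empty purge plan is the identity on the
assembly.

## Limitations

Depth gating assumes a single sequencing library of roughly uniform
coverage; wildly uneven coverage (e.g. amplified material) breaks the
haploid/diploid separation.  Overlap calling trims only unambiguous
1-to-1 dovetails; tangles of three or more contigs at one junction are
left for manual review.  Contigs are never joined across a removed
overlap — joining is the scaffolder's job, and doing it here risks false
joins.  HIGHCOV regions are reported rather than removed by default;
`--remove-highcov` exists but is deliberately opt-in.
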