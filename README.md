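# haplopurge

Remove haplotypic duplication — contained haplotigs and heterozygous
overlaps — from a primary genome assembly, using assembly self-alignment
chaining gated by long-read depth.

## The problem

Long-read assemblers of heterozygous diploid genomes (outbred insects,
molluscs, fish, grapes, ...) often fail to recognise that two diverged
sequences are alleles of the same locus.  The primary contig set then
carries a region twice: either as an extra *haplotig* (a contig fully
contained, at the sequence level, in another contig's alternate
haplotype) or as a *heterozygous overlap* (two primary contigs that
should abut instead share a diverged terminal copy of the junction
region).  Both inflate the assembly, double genes, and — crucially —
block scaffolders, which cannot join contigs whose ends overlap.

Sequence similarity alone cannot distinguish haplotypic duplication from
genuine repeats.  Read depth can: a locus present once per haplotype in
the assembly splits its reads between the two copies and sits at the
**haploid** depth *h*, while a correctly collapsed locus collects reads
from both haplotypes at the **diploid** depth *d* ≈ 2*h*, and collapsed
repeats sit higher still.  haplopurge combines both signals:

1. **Depth** — map long reads to the assembly (minimap2, PAF in), count
   per-base depth, and select three thresholds from the depth histogram:
   junk floor *L*, haploid/diploid transition *T* (the valley between the
   *h* and *d* peaks), repeat ceiling *H*.  Either peak may dominate; a
   unimodal histogram is treated as the diploid peak.
2. **Split** — cut scaffolds into contigs at N-gaps (coordinates are
   lifted back at the end).
3. **Haplotigs** — chain the all-by-all self-alignment into collinear
   chains (score = matched bases − affine gap costs); a segment mostly
   covered by chains to longer segments *and* at mean depth < *T* is a
   haplotig and is removed whole.  Segments dominated by depth < *L* are
   junk; segments above *H* are flagged collapsed repeats and protected.
4. **Overlaps** — among the remaining chains, an unambiguous dovetail
   whose matched interval sits below *T* on **both** contigs is a
   heterozygous overlap; the matched interval on the shorter contig is
   trimmed.

The package also provides a k-mer copy-number spectrum evaluator
(read-multiplicity × assembly-copy-number, k = 21 by default): excess
assembly copies of single-locus k-mers quantify retained duplication, and
the reduction of that excess measures what purging achieved.  A synthetic
diploid-scenario generator (`haplopurge simulate`) plants haplotigs,
overlaps, junk and collapsed repeats with ground truth, so the whole
pipeline is testable with no external data.

## Worked example

Generate the default synthetic scenario (2 Mb diploid genome, 1%
heterozygosity, 40× reads; 4 planted haplotigs, 3 planted 50 kb
heterozygous overlaps, 2 junk contigs, 1 collapsed repeat) and purge it:

```sh
haplopurge simulate -o demo
haplopurge run demo/draft.fa demo/reads.paf demo/self.paf -o demo/out
```

The run report (also written to `demo/out/report.json`) prints:

```json
{
  "bases_by_label": {"HAPLOTIG": 260002, "JUNK": 40000, "OVLP": 150000},
  "cutoffs": {"low": 5, "transition": 28, "high": 95,
              "mode": "diploid-dominant", "peaks": [21, 38]},
  "n_haplotig_segments": 4,
  "n_overlap_intervals": 3,
  "input_bases": 2489922,
  "purged_bases": 2039920,
  "removed_bases": 450002
}
```

Reading this: the depth histogram showed a haploid peak at 21× and a
diploid peak at 38×, with the transition cutoff *T* = 28 placed in the
valley between them.  All 4 planted haplotigs (260 kb), all 3 planted
overlaps (150 kb) and both junk contigs (40 kb) were identified — the
purge plan is in `demo/out/dups.bed` — while the collapsed-repeat contig
(depth ≈ 2*d*) was left untouched.  `purged.fa` holds the deduplicated
primary assembly, `removed.fa` the excised sequence with coordinates and
labels in the names.

The k-mer evaluation compares the assembly before and after purging
against the read set:

```sh
haplopurge kstats reads.fa demo/draft.fa --after demo/out/purged.fa \
    --cutoffs demo/out/cutoffs.tsv -k 21
# duplicated_kmer_reduction   1.0000
```

i.e. every excess assembly copy of a single-locus k-mer was removed.

## Library use

Every pipeline stage is an importable function operating on plain types
(`ContigSeq`, `PafRecord`, `BedInterval`, `DepthProfile`, `Chain`,
`PurgePlan`):

```python
from haplopurge import (compute_depth, build_histogram, find_cutoffs,
                        split_at_gaps, filter_self_alignments,
                        call_haplotigs, call_overlaps, apply_plan)
```

See `docs/methods.md` for the model, parameter meanings and defaults,
what the synthetic generator does and does not emulate, and known
limitations.
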