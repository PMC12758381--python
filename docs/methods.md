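# Methods

## The problem

Structural variants (insertions and deletions of ≥50 bp) cluster in
low-complexity regions — stretches dominated by repeatedly occurring
short motifs, closely related to tandem repeats — and those regions also
concentrate the errors of long-read SV callers, largely because pairwise
read alignment places gaps inconsistently inside impure repeats.
`lcrsv` quantifies this by (i) building an LCR stratification of the
reference, (ii) assigning every SV to exactly one stratum, and (iii)
reporting matching-based error rates per stratum and per LCR
allele-length bin. A synthetic-data module generates inputs with known
ground truth so the whole chain is verifiable.

All interval work uses BED conventions (0-based, half-open); VCF
positions are converted once at the I/O boundary. Abutting intervals
`[a,b)` + `[b,c)` are always coalesced — a biological LCR should not be
split at an arbitrary bookkeeping boundary.

## Stratification-BED construction (`regions`)

Pipeline order: satellite filter → minimum-length filter → union with
polymorphic LCRs → pad → final merge.

- **Satellite filter.** A candidate is dropped when it overlaps a
  satellite interval (alpha/HSAT-class centromeric repeats in real data)
  by ≥1 bp. The fractional alternative (drop when the overlapped
  fraction reaches a cutoff) is config-exposed; any-overlap is the
  default because satellite annotations are themselves generous and a
  candidate touching one is suspect.
- **Minimum length** 50 bp, inclusive, matching the SV size definition.
- **Padding** 5 bp per side: LCR boundaries from sequence scanners are
  not exact, and insertions are conventionally left-aligned to sit right
  before exact tandem repeats, i.e. just outside the detected repeat.
  Padding can create new overlaps, so a final merge follows; `pad(p)`
  followed by `merge` is idempotent under re-merging, which the property
  tests assert.

## Bubble annotation (`bubbles`)

A variant bubble (a site where pangenome assembly paths diverge and
rejoin) is labeled from its alleles' per-base annotation fractions:

- **LCR rule:** length-weighted mean `lcr_frac` over all allele
  sequences ≥ 0.70 (inclusive). The per-sequence-count alternative
  (fraction of alleles that are majority-LCR) is available as
  `mode="count"`; base-weighting is the default because it is robust to
  grossly unequal allele lengths.
- **SegDup priority:** when the length-weighted mean `segdup_frac`
  reaches 0.5 the bubble is SegDup, never LCR — an LCR inside a long
  polymorphic segmental duplication has most of its bubble sequence
  annotated SegDup, and mislabeling it LCR would leak SegDup variation
  into the LCR stratum. The 0.5 cutoff is a package choice
  (config-exposed); no principled external value exists.
- **Support filter:** non-reference alleles need ≥5 supporting
  assemblies, not counting the benchmarked sample (HG002 by default) —
  the truth set must not vote for its own variants — nor the reference
  pseudo-sample. Bubbles left with only the reference allele are not
  polymorphic and are dropped.
- **Maximum allele length** of a final LCR record: the longest retained
  allele (reference included) over all support-passing bubbles
  intersecting the record by ≥1 bp, with ties resolved by taking the
  overall maximum; fallback is the record's own reference length.

## Partitioning and classification (`stratify`)

Every base receives one label with priority
`NotConf > LCR > SegDup > Other`: bases outside the benchmark's
confident regions are NotConf regardless of annotation, LCR excludes
NotConf bases, SegDup excludes both. Coverages therefore sum exactly to
the genome length, which is asserted rather than assumed.

An SV's interval: for a deletion, the deleted bases excluding the VCF
anchor (records are assumed left-aligned; no re-normalization is
attempted); for an insertion, the single anchor base. The anchor-point
default works because the stratification BED is padded — an insertion
placed immediately before a repeat still lands inside the padded
interval. A `padded` mode (anchor ± flank) exists for sensitivity
analysis. The SV is assigned the highest-priority label covering ≥70%
(inclusive) of its interval, else `Other`.

Truth and call sets are filtered before scoring: `*`-allele records
(redundant encodings of alleles hidden by an overlapping deletion) are
removed, as are SVs under 50 bp and SVs not fully contained in the
confident regions (the containment fraction is config-exposed;
full containment is the default reading of "contained in the confident
regions"). Multi-allelic records are split per-ALT at VCF ingestion.

## Matching (`matching`)

The built-in matcher is deliberately simple: candidate pairs share
chromosome and svtype, have breakpoint distance ≤ `refdist` (500 bp),
size similarity `min/max ≥ pctsize` (0.7), and — when both records carry
an insertion sequence — edit-distance similarity ≥ `pctseq` (0.7,
computed with edlib). Pairs are ranked by the unweighted mean of the
distance, size, and (when available) sequence similarities and assigned
greedily one-to-one; ties break on the symmetric key
`(chrom, min(pos), max(pos))`, which makes swapping call and truth sets
exactly swap FP and FN — a tested invariant. Greedy assignment is exact
when breakpoint noise is small relative to variant spacing, which the
simulator guarantees; it is a documented simplification relative to
benchmarking tools that re-normalize variant representations by
multi-sequence alignment. For real-data evaluation the package instead
ingests tp-base/fp/fn VCFs from an external truvari run and only checks
the conservation identities. Genotype is ignored throughout: matching
evaluates variant presence.

## Metrics (`metrics`)

FDR = FP/(FP+TP), FNR = FN/(FN+TP). A TP pair contributes to FDR tables
under the call's stratum and to FNR tables under the truth variant's
stratum; the two can disagree when noise moves a call across a boundary,
and such discordant pairs are counted in the report. Zero-denominator
rates are emitted as missing, never 0. Length-bin reports use edges
0/100/250/500/1000/2000/∞ over the maximum allele length, with edge
values falling in the upper bin (a 2,000-bp region belongs to the
≥2 kb bin); the edges are a package default, config-exposed, not an
externally fixed choice.

## Synthetic data (`simulate`)

What it emulates, and the default study conditions:

- **LCRs** are impure tandem repeats: a random unit (10–40 bp) tiled
  15–60 times with independent per-base substitutions at rate 0.09,
  mirroring the ~91% unit identity typical of the impure repeats that
  break read alignment. 200 per 1-Mb genome.
- **SegDups** are pairs of 8-kb blocks at ~99% identity; **NotConf**
  blocks cover 5% of the genome and are carved as whole intervals
  disjoint from other features.
- **Truth SVs** default to 260 per run — 180 in LCR (69%), 10 in SegDup,
  70 in Other, with roughly two insertions per deletion — matching the
  composition reported for a well-studied human benchmark sample.
  Lengths are uniform on 50–200 bp. Deletions are placed fully inside
  partition bases of the intended stratum and insertions anchored on
  one, with a 65-bp margin to segment boundaries (larger than the
  truncated caller noise, so intended labels survive perturbation) and
  ≥300 bp spacing between SVs (an order of magnitude above breakpoint
  jitter, so one-to-one matching is unambiguous). Placement packs SVs
  into randomly ordered, randomly offset segments; infeasible requests
  fail loudly with the missing-capacity estimate rather than degrading.
  LCR insertions copy the sequence immediately upstream of their anchor
  (tandem-duplication-like); others are random.
- **Caller emulation** is statistical, not mechanistic: per stratum,
  truth SVs are dropped with probability `fnr`; survivors get Gaussian
  breakpoint jitter (sd 10 bp) and length error (sd 5 bp), truncated to
  ±`refdist`/2 and to size ratios ≥ `pctsize` so injected rates are the
  only error source (truncation can be disabled to stress the matcher);
  false calls are added in the stratum's own partition bases at a
  Poisson rate with mean `TP·fdr/(1−fdr)`, making the expected
  FP/(FP+TP) equal `fdr`. False calls are kept ≥600 bp (refdist + 100)
  from every truth SV — stricter than mere non-overlap — so the matcher
  cannot rescue an injected FP as a TP and dilute the injected rates.
  Default injected rates are 0.15/0.15 (LCR), 0.20/0.20 (SegDup),
  0.02/0.02 (Other), reproducing the order-of-magnitude gap between
  repeat and unique sequence seen in real caller evaluations.
- **Bubbles** attach to 30% of planted LCRs, each with the reference
  allele plus 1–3 alternates (lengths 0.3–4× the reference), support
  counts drawn half below and half at/above the rarity threshold, and
  HG002 present in ~30% of support lists.

What the simulator does *not* model — and hence what passing tests do
not show about real data: read-level signal (no FASTQ/BAM), alignment
ambiguity, representation differences between callers (the very thing
multi-sequence-alignment benchmarking exists to normalize), clustered or
overlapping SVs, and sequence-content-dependent error rates. Synthetic
recovery demonstrates that the bookkeeping — stratification,
classification, matching, rate estimation — is unbiased, not that any
particular caller behaves as modeled.

## Numerical and reproducibility choices

- All thresholds are inclusive exactly as stated (≥70% overlap, ≥50 bp,
  ≥5 supporters) and tested at their boundaries.
- Same seed ⇒ byte-identical outputs; each pipeline stage draws from a
  generator deterministically derived from the single run seed.
- Rate-recovery checks use 20 caller replicates of 1,000 SVs per class
  with injected per-class rates spanning {0.05, 0.2, 0.5} and require
  mean estimates within 2 standard errors (of the mean) of the targets;
  seeds were fixed before the first run. A 2-SE band is a ~94% interval
  per quantity, so an occasional honest miss is possible by
  construction. Problem sizes throughout (≤2.4-Mb genomes, ≤3,000 SVs
  per condition) were chosen so the full suite runs in seconds while
  keeping every per-class count large enough for the statistical bands
  to be meaningful.
- Degenerate inputs: empty region sets, zero requested SVs, and
  zero-error configurations are all defined and tested (the last must
  give exactly FDR = FNR = 0).

## Known limitations

- The greedy matcher can in principle mispair variants closer than
  `refdist` with similar sizes; the simulator's spacing avoids this, but
  on real data the truvari-ingestion path is the recommended route.
- Insertion classification by anchor base ignores the inserted
  sequence's own repeat content.
- Bubble allele annotation fractions are taken as given (simulated or
  precomputed upstream); the package does not compute them from raw
  assemblies.
- `ingest_truvari` reuses the truth-side representation for both members
  of a TP pair, so call-side stratification of externally matched TPs
  follows the truth record.
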