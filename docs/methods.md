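# Methods

`sibtrace` reconstructs the pollen parent of open-pollinated half-sib
seedlings from a small panel of individual-specific SNPs, and validates
the assignments genome-wide with method-of-moments identity-by-descent
(IBD).  Every stage is driven by a synthetic open-pollination simulator
with full ground truth, so the whole chain is testable without any
external data.

## Study design being emulated

One known mother tree is surrounded by a pool of candidate pollen
parents (default 150).  One focal father is a bud variety carrying a
handful of private SNPs: sites where he is heterozygous (0/1) and every
other candidate parent — the mother included — is homozygous reference
(0/0).  Open pollination produces seedlings (default 332) that share the
mother but have unknown fathers.  Because an offspring receives one
allele from each parent, a seedling heterozygous at such a private site
must have received the alternate allele from the focal father; a
chromosome-distributed panel of k private sites detects a true focal
offspring with probability 1 − 2⁻ᵏ (0.9990 for k = 10).

## Population simulator (`popsim`)

* **Founders.**  Genotypes are drawn under Hardy–Weinberg proportions at
  per-site alternate-allele frequencies sampled uniformly from a
  configurable interval (default [0.1, 0.9] in the end-to-end scenario).
* **Planted marker sites.**  `plant_specific_sites` adds n new sites
  (default 10, at most one per non-excluded chromosome, chromosomes 1
  and 7 excluded by default) that are 0/1 in the focal father and 0/0 in
  all other founders.
* **Offspring.**  Each offspring draws a father from a weight vector
  (default: focal father 0.37, the rest uniform), then inherits one
  allele from each parent independently at every site.
* **Unlinked sites.**  Sites segregate independently — no recombination
  map.  This is exact for a one-marker-per-chromosome panel and adequate
  for moment-based IBD, whose per-site expectations do not involve
  linkage; what the simulator consequently cannot exercise is
  linkage-based (segment) IBD or LD pruning, which the package does not
  implement.
* **Error models.**  Genotyping error is a symmetric state flip: with
  probability e a call is replaced by one of the other two non-missing
  states, uniformly.  Missingness is independent per call.  Both default
  to 0; neither models allele-drop-out asymmetry or depth-dependent
  error, so passing tests bound behaviour under exchangeable noise only.

All simulators are bit-deterministic for a fixed seed; the pipeline fans
one global seed out to per-stage seeds through `SeedSequence`.

## Marker selection (`snp_select`)

A site is individual-specific when **all** sequencing replicates of the
target are 0/1 and every other sample is 0/0 (`strict` mode, default) or
merely homozygous, 0/0 or 1/1 (`literal` mode).  Strict is the default
because a hom-alt non-target parent transmits the alternate allele to
its own offspring and would create false positives under the presence
rule; `literal` is retained because published screens are sometimes
phrased that way, and the package demonstrates the resulting
false-positive risk in tests.  Missing calls disqualify a site
(conservative).  The panel builder then selects greedily in
(chromosome, position) order under a per-chromosome limit (default 1)
and exclusion list, raising an explicit infeasibility error naming the
deficit when the constraints cannot be met.

## Amplicon model (`amplicon`)

The two-round multiplex-PCR product is modelled on the top strand as

```
i5_index(5) · i5_barcode(5) · i5_adapter(19) · insert(120)
           · rc(i7_adapter)(19) · rc(i7_barcode)(5) · rc(i7_index)(5)
```

for a 178 bp construct; the SNP sits at 1-based offset 60 of the 120 bp
insert.  Read 1 is the construct prefix and read 2 the
reverse-complement suffix (default 150 bp each), so R1 begins with the
i5 index+barcode tag and R2 with the i7 tag.  Published product lengths
for such constructs are not always consistent with component arithmetic;
this package derives all lengths from the components.

* **Read simulation.**  Per sample and site the pair depth is
  Poisson(depth_mean) (default 2300); heterozygotes draw alt molecules
  Binomial(depth, ½).  Substitution errors occur per base at rate
  10^(−Q/10) (default Q30 → 10⁻³), implemented by drawing the exact
  binomial number of error events per batch and placing them without
  replacement.  Quality strings are flat at Q.  PCR efficiency bias,
  duplicates, indels and quality decay along the read are not modelled.
* **Demultiplexing** requires both 10 nt tags to match one scheme entry
  within `max_mismatch` (default 0 — the tags are only 5+5 nt);
  ambiguous or unmatched pairs go to the unassigned bin, so assignment
  partitions the input exactly.  The 19-row printed scheme extends
  combinatorially (19 × 19 = 361 samples) for study-scale pools.
* **Alignment** is ungapped: each trimmed read is placed at the
  window/offset/strand minimising Hamming distance against the
  mini-reference (200 bp SNP-centred windows, 2000 bp total for a
  10-site panel), with reads above a 10 % mismatch ceiling discarded.
  Exact placements come from substring lookup and near-exact ones from
  non-overlapping 20-mer seeds (a read with fewer than six errors always
  retains an exact seed chunk); seedless reads fall back to the full
  scan.  The seeded path is tested against an exhaustive
  all-window/all-offset oracle.  Indels are out of scope — the loci are
  short fixed amplicons.
* **Calling** thresholds pileup counts: no_call below min_depth
  (default 100 read observations; both mates of a pair count); otherwise
  the alt fraction f = alt/(ref+alt) maps to hom_ref (f < 0.2), hom_alt
  (f > 0.8) or het (inside the band, inclusive).  At 2300× and Q30 the
  binomial fluctuation of f is ~0.01, so the band is insensitive over a
  wide range.

## Parentage (`parentage`)

A sample is classified a focal offspring when it is heterozygous at at
least `min_het_sites` panel sites (default 1).  no_call sites are
excluded from the count; samples with every panel site no_call are
flagged indeterminate rather than counted as non-offspring.  The default
of 1 follows the presence rule as published; it is configurable upward
because a single erroneous het call would otherwise suffice to
misassign.  `detection_power` gives the closed form
P[Bin(k, p·(1−fnr)) ≥ m].

A note on sensitivity: a true focal offspring inherits zero of the ten
private alleles with probability 2⁻¹⁰, and no presence-rule method can
detect such a seedling.  The scenario summary therefore reports
sensitivity both against all true focal offspring and against the
detectable subset (≥ 1 transmitted private allele); only the latter can
be expected to reach 1.0.

## IBD (`ibd`)

Method-of-moments estimation equates observed identity-by-state class
counts (sharing 0/1/2 alleles, on unordered allele multisets) to their
HWE expectations given the latent IBD state, using founder allele
frequencies:

| | IBD0 | IBD1 | IBD2 |
|---|---|---|---|
| IBS0 | 2p²q² | 0 | 0 |
| IBS1 | 4p³q + 4pq³ | 2p²q + 2pq² | 0 |
| IBS2 | p⁴ + q⁴ + 4p²q² | 1 − (2p²q + 2pq²) | 1 |

Z0, Z1, Z2 are solved sequentially, bounded (Z0 > 1 maps to (1, 0, 0):
such a pair carries no evidence of sharing, and letting residual noise
leak into Z1/Z2 would bias unrelated pairs upward), clamped to [0, 1]
and renormalised; PI_HAT = Z2 + Z1/2.  The formulas are verified in the
tests against exhaustive enumeration over ordered parental allele draws
to 12 decimals.  No small-sample bias correction is applied to the IBS
expectations (PLINK applies one; the moment solve here uses the raw
expectations — a documented difference, negligible at thousands of
sites).  Frequencies are computed from founders only, to avoid
relatedness bias; sites with minor-allele frequency below 0.01 are
excluded (variance guard), and pairs with fewer than 200 usable sites
are flagged low-confidence.  First-degree classification uses the
inclusive window 0.4358 ≤ PI_HAT ≤ 0.5625.

## End-to-end scenario (`pipeline`, CLI `sibtrace`)

`run_scenario` composes simulate → select → mkref → simreads → demux →
align → call → assign → ibd, writing every artifact in a standard text
format (VCF v4.2 GT-only, FASTA wrapped at 60 columns, Phred+33 FASTQ,
TSV, YAML, JSON).  Genome coordinates are 1-based in files; window
arithmetic is 0-based half-open internally with conversions centralised
in the mini-reference coordinate map.  Pooled FASTQs are gzipped by
default (gzip mtime pinned to 0 so runs are byte-deterministic per
seed).  The IBD validation runs on the simulated "resequencing"
genotypes (as in the emulated design, where whole-genome resequencing
validated the panel calls), not on the 10-site amplicon calls.

Default problem sizes — 151 founders, 332 offspring, 12 chromosomes
with 420 background sites each (≈5k sites for IBD), 10-site panel,
2300× mean depth (≈7.6M read pairs), Q30 — mirror the emulated study
and run end to end in about two minutes on one CPU; the IBD validation
suite uses 50 replicate pairs at 5,000 unlinked sites.

## Known limitations

* Unlinked-site simulation: no segment-based IBD, no LD.
* Ungapped alignment: indels in amplicons are not handled.
* Flat quality profile and symmetric error models.
* The presence rule targets one focal father; multi-father exclusion or
  likelihood-based (LOD) parentage is out of scope.
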