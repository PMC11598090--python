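# sibtrace

Parentage reconstruction for open-pollinated half-sib populations using
small panels of **individual-specific SNPs**, with an in-silico
two-round multiplex-PCR amplicon sequencing pipeline and
method-of-moments IBD validation.

## The problem

In fruit-tree breeding, open pollination of a known mother tree yields
half-sib seedlings whose pollen parents are unknown.  When the father of
interest is a bud variety, it carries a few **private heterozygous
SNPs** — sites where it is 0/1 while every other candidate parent in the
orchard is 0/0.  Since a diploid offspring inherits one allele from each
parent, a seedling that is heterozygous at such a site must descend from
that father.  A chromosome-distributed panel of k private sites detects
a true offspring with probability

    P(detected) = 1 − (1/2)^k        (= 0.9990234375 for k = 10)

and, with a strictly screened panel, never flags anyone else.
Assignments can be validated genome-wide with pairwise
identity-by-descent: Ẑ₀, Ẑ₁, Ẑ₂ are solved by the method of moments from
identity-by-state class counts and founder allele frequencies under HWE,
and π̂ = Ẑ₂ + Ẑ₁/2 is expected to be 0.5 for parent–offspring pairs
(first-degree window 0.4358 ≤ π̂ ≤ 0.5625).

`sibtrace` implements the full chain — individual-specific SNP screening
from a multi-sample VCF, panel construction, amplicon construct
modelling (i5/i7 adapters, combinatorial dual 5 nt barcodes + 5 nt
indexes), paired-end read simulation, demultiplexing, targeted ungapped
alignment against a mini-reference of SNP-centred windows, threshold
genotype calling, presence-rule parentage assignment, and
method-of-moments IBD — driven by a Mendelian open-pollination simulator
with full ground truth, so everything is testable without external data.
It is aimed at breeders and population geneticists who want to design or
sanity-check marker-based parentage assays before going to the lab.

## Worked example

```bash
sibtrace run -c docs/example.yaml -o out/
```

with `docs/example.yaml` setting 40 candidate fathers, 60 offspring, a
10-site panel excluding chr1/chr7, 800× depth and seed 7 prints

```
wrote 18 artifacts to out/
sensitivity: 1.0
sensitivity_detectable: 1.0
specificity: 1.0
ibd_first_degree_concordance: 1.0
```

meaning: every seedling truly fathered by the focal parent (and carrying
at least one transmitted private allele) was assigned to him, no other
seedling was, and every assigned full-sib falls inside the first-degree
IBD window with the father.  Inspecting the artifacts:

```text
$ head -4 out/parentage.tsv
sample          n_called_sites  n_het_panel_sites  is_focal_offspring  indeterminate
offspring_0001  10              7                  True                False
offspring_0002  10              0                  False               False
offspring_0003  10              0                  False               False

$ head -3 out/ibd.tsv
sample_a        sample_b    z0        z1        z2        pi_hat    n_sites  low_confidence  first_degree
offspring_0001  father_017  0.000000  0.982907  0.017093  0.508546  1210     False           True
offspring_0002  father_017  1.000000  0.000000  0.000000  0.000000  1210     False           False
```

`offspring_0001` is heterozygous at 7 of the 10 panel sites (each
private allele transmits with probability ½) and shares π̂ ≈ 0.51 with
the focal father — a parent–offspring pair.  `offspring_0002` carries no
private allele and shows π̂ = 0 — another father's seedling.

Each stage is also available separately (`sibtrace simulate`, `select`,
`mkref`, `simreads`, `demux`, `call`, `assign`, `ibd`); the outputs of
one stage are valid inputs of the next, in standard formats (VCF v4.2,
FASTA, Phred+33 FASTQ, TSV, YAML).

The defaults of `sibtrace run` mirror the emulated study design — 1
mother, 150 candidate fathers, 332 offspring, a 10-site panel, Q30
paired 150 bp reads at ~2300× per site (≈7.6M read pairs) — and complete
in about two minutes on one CPU.  See `docs/methods.md` for the models,
thresholds and their rationale.

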