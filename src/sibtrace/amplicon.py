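"""In-silico two-round multiplex PCR, sequencing, demultiplexing and calling.

The modelled library construct mirrors a two-round amplicon protocol:
round one amplifies a fixed-length locus insert with locus-specific
primers tailed by the i5/i7 sequencing adapters; round two adds a
per-sample 5 nt barcode and 5 nt index on each side.  On the top strand
the final molecule is::

    i5_index . i5_barcode . i5_adapter . insert . rc(i7_adapter) . rc(i7_barcode) . rc(i7_index)

so read 1 starts with the i5 tag (index+barcode) and read 2 — the
reverse complement of the other end — starts with the i7 tag followed by
the i7 adapter.  With the default 5+5 nt tags, 19 nt adapters and a
120 bp insert the full construct is 178 bp.

Alignment is a deliberately simple ungapped (Hamming-distance) scan
against a mini-reference of short windows centred on each panel SNP:
amplicons are short fixed loci and indels are out of scope, so a seeded
exact/near-exact match is both faster and easier to verify than a full
aligner.  Genotypes are called from pileup allele counts with simple
depth and allele-fraction thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

from .genotypes import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING, VariantSite
from .io_utils import ReadPair, phred_error_rate
from .snp_select import Panel

# -- printed construct components -------------------------------------------
I5_ADAPTER = "TCGTCGGCAGCGTCAGATG"
I7_ADAPTER = "TCTCACACATATTCTCTGT"
I5_INDEX = "AATAT"
I7_INDEX = "CCTCT"

#: Per-sample 5 nt barcodes of the 19-sample reference scheme.
I5_BARCODES_19 = (
    "AGGTA", "ATGAA", "TACCA", "CAGAA", "CAAGT", "TTCGT", "TCCGA", "TGAGC",
    "CTGAC", "CCTCG", "AGGTG", "TCTAA", "TTGGA", "TCTAG", "TCTGG", "CTATT",
    "AGGCA", "TTAGT", "ATCCG",
)
I7_BARCODES_19 = (
    "GGAGA", "CAAGA", "TACCA", "CAGAA", "CAAGT", "TTCGT", "TCCGA", "TGAGC",
    "CTGAC", "CCTCG", "AGGTG", "TCTAA", "TTGGA", "TCTAG", "TCTGG", "CTATT",
    "AGGCA", "TTAGT", "ATCCG",
)

INSERT_LENGTH = 120
SNP_OFFSET = 60  # 1-based offset of the SNP within the insert
DEFAULT_WINDOW = 200
DEFAULT_READ_LENGTH = 150
TAG_LENGTH = 10  # index (5) + barcode (5)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Barcode scheme
# ---------------------------------------------------------------------------

class BarcodeTag(NamedTuple):
    i5_index: str
    i5_barcode: str
    i7_index: str
    i7_barcode: str

    @property
    def i5_tag(self) -> str:
        return self.i5_index + self.i5_barcode

    @property
    def i7_tag(self) -> str:
        return self.i7_index + self.i7_barcode


@dataclass
class BarcodeScheme:
    """Combinatorial dual 5 nt index + 5 nt barcode tags, one pair per sample."""

    entries: dict[str, BarcodeTag]
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        for sample, tag in self.entries.items():
            for part in tag:
                if len(part) != 5:
                    raise ValueError(f"{sample}: tags must be 5 nt, got {part!r}")
        pairs = [(t.i5_tag, t.i7_tag) for t in self.entries.values()]
        if len(set(pairs)) != len(pairs):
            raise ValueError("combinatorial (i5, i7) tag pairs must be unique across samples")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def samples(self) -> list[str]:
        return list(self.entries)

    def tag_for(self, sample: str) -> BarcodeTag:
        try:
            return self.entries[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in barcode scheme") from None

    @classmethod
    def reference_scheme(cls, sample_names: Sequence[str] | None = None,
                         max_mismatch: int = 0) -> "BarcodeScheme":
        """The printed 19-sample scheme (row k pairs i5 barcode k with i7 barcode k)."""
        if sample_names is None:
            sample_names = [f"sample_{i + 1:02d}" for i in range(19)]
        if len(sample_names) > 19:
            raise ValueError("reference scheme holds at most 19 samples")
        entries = {
            name: BarcodeTag(I5_INDEX, I5_BARCODES_19[k], I7_INDEX, I7_BARCODES_19[k])
            for k, name in enumerate(sample_names)
        }
        return cls(entries, max_mismatch)

    @classmethod
    def combinatorial(cls, sample_names: Sequence[str], max_mismatch: int = 0) -> "BarcodeScheme":
        """Cross the 19 i5 barcodes with the 19 i7 barcodes: up to 361 samples."""
        cap = len(I5_BARCODES_19) * len(I7_BARCODES_19)
        if len(sample_names) > cap:
            raise ValueError(f"combinatorial scheme holds at most {cap} samples")
        entries = {}
        for k, name in enumerate(sample_names):
            i, j = divmod(k, len(I7_BARCODES_19))
            entries[name] = BarcodeTag(I5_INDEX, I5_BARCODES_19[i], I7_INDEX, I7_BARCODES_19[j])
        return cls(entries, max_mismatch)

    # -- TSV round trip -----------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\ti5_index\ti5_barcode\ti7_index\ti7_barcode\n")
            for sample, t in self.entries.items():
                fh.write(f"{sample}\t{t.i5_index}\t{t.i5_barcode}\t{t.i7_index}\t{t.i7_barcode}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, max_mismatch: int = 0) -> "BarcodeScheme":
        entries = {}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                sample, i5i, i5b, i7i, i7b = line.rstrip("\n").split("\t")[:5]
                entries[sample] = BarcodeTag(i5i, i5b, i7i, i7b)
        return cls(entries, max_mismatch)


# ---------------------------------------------------------------------------
# Mini-reference
# ---------------------------------------------------------------------------

@dataclass
class MiniReference:
    """Short per-panel-site alignment windows with a genome coordinate map.

    ``origins[name] = (chrom, start0)`` maps window coordinates back to
    the source genome: window offset ``k`` is genome position
    ``start0 + k + 1`` (1-based).
    """

    names: list[str]
    seqs: dict[str, str]
    snp_offsets: dict[str, int]  # 0-based offset of the SNP in each window
    origins: dict[str, tuple[str, int]]
    window: int = DEFAULT_WINDOW
    sites: dict[str, VariantSite] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def lift_over(self, name: str, offset0: int) -> tuple[str, int]:
        """Window-local 0-based offset -> (chrom, 1-based genome position)."""
        chrom, start0 = self.origins[name]
        return chrom, start0 + offset0 + 1

    def write(self, fasta_path: str | Path, map_path: str | Path | None = None) -> None:
        from .io_utils import write_fasta

        write_fasta({n: self.seqs[n] for n in self.names}, fasta_path)
        if map_path is not None:
            with open(map_path, "w") as fh:
                fh.write("name\tchrom\tstart0\tsnp_offset0\tsnp_pos\tref\talt\n")
                for n in self.names:
                    chrom, start0 = self.origins[n]
                    site = self.sites[n]
                    fh.write(
                        f"{n}\t{chrom}\t{start0}\t{self.snp_offsets[n]}\t"
                        f"{site.pos}\t{site.ref}\t{site.alt}\n"
                    )

    @classmethod
    def read(cls, fasta_path: str | Path, map_path: str | Path) -> "MiniReference":
        from .io_utils import read_fasta

        seqs = read_fasta(fasta_path)
        names, snp_offsets, origins, sites = [], {}, {}, {}
        with open(map_path) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                n, chrom, start0, off0, pos, ref, alt = line.rstrip("\n").split("\t")[:7]
                names.append(n)
                snp_offsets[n] = int(off0)
                origins[n] = (chrom, int(start0))
                sites[n] = VariantSite(chrom, int(pos), ref, alt)
        window = len(next(iter(seqs.values()))) if seqs else DEFAULT_WINDOW
        return cls(names, seqs, snp_offsets, origins, window, sites)


def build_mini_reference(
    genome: Mapping[str, str], panel: Panel | Sequence[VariantSite], window: int = DEFAULT_WINDOW
) -> MiniReference:
    """One ``window``-length genome slice per panel site, SNP centred.

    The SNP sits at 1-based window position ``window // 2`` (mirroring
    the insert convention); windows are clamped at chromosome ends, with
    the true SNP offset recorded in the coordinate map.
    """
    sites = list(panel.sites) if isinstance(panel, Panel) else list(panel)
    names: list[str] = []
    seqs: dict[str, str] = {}
    offsets: dict[str, int] = {}
    origins: dict[str, tuple[str, int]] = {}
    site_map: dict[str, VariantSite] = {}
    for site in sites:
        if site.chrom not in genome:
            raise ValueError(f"panel site {site} absent from genome")
        chrom_seq = genome[site.chrom]
        if len(chrom_seq) < window:
            raise ValueError(f"chromosome {site.chrom} shorter than window {window}")
        start0 = site.pos - 1 - (window // 2 - 1)
        start0 = min(max(start0, 0), len(chrom_seq) - window)  # clamp at ends
        seq = chrom_seq[start0 : start0 + window]
        if seq[site.pos - 1 - start0] != site.ref:
            raise ValueError(
                f"genome base at {site.chrom}:{site.pos} is {seq[site.pos - 1 - start0]!r}, "
                f"expected ref {site.ref!r}"
            )
        name = f"{site.chrom}_{site.pos}"
        names.append(name)
        seqs[name] = seq
        offsets[name] = site.pos - 1 - start0
        origins[name] = (site.chrom, start0)
        site_map[name] = site
    return MiniReference(names, seqs, offsets, origins, window, site_map)


# ---------------------------------------------------------------------------
# Constructs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconConstruct:
    """One second-round PCR product: sample tags + adapters + locus insert."""

    site: VariantSite
    sample: str
    allele: str  # "ref" | "alt"
    insert: str
    sequence: str
    tag: BarcodeTag

    def __len__(self) -> int:
        return len(self.sequence)


def locus_insert(genome: Mapping[str, str], site: VariantSite, allele: str,
                 insert_length: int = INSERT_LENGTH, snp_offset: int = SNP_OFFSET) -> str:
    """Fixed-length locus sequence with the chosen allele at the SNP offset."""
    if allele not in ("ref", "alt"):
        raise ValueError(f"allele must be 'ref' or 'alt', got {allele!r}")
    chrom_seq = genome[site.chrom]
    start0 = site.pos - 1 - (snp_offset - 1)
    if start0 < 0 or start0 + insert_length > len(chrom_seq):
        raise ValueError(f"insert window for {site} runs off chromosome {site.chrom}")
    seq = chrom_seq[start0 : start0 + insert_length]
    if seq[snp_offset - 1] != site.ref:
        raise ValueError(
            f"genome base at {site.chrom}:{site.pos} is {seq[snp_offset - 1]!r}, "
            f"expected ref {site.ref!r}"
        )
    base = site.ref if allele == "ref" else site.alt
    return seq[: snp_offset - 1] + base + seq[snp_offset:]


def build_constructs(
    genome: Mapping[str, str],
    panel: Panel | Sequence[VariantSite],
    scheme: BarcodeScheme,
    sample: str,
    alleles: Sequence[str] = ("ref", "alt"),
    insert_length: int = INSERT_LENGTH,
    snp_offset: int = SNP_OFFSET,
) -> list[AmpliconConstruct]:
    """All requested per-locus constructs for one sample."""
    tag = scheme.tag_for(sample)
    sites = list(panel.sites) if isinstance(panel, Panel) else list(panel)
    out = []
    for site in sites:
        for allele in alleles:
            insert = locus_insert(genome, site, allele, insert_length, snp_offset)
            seq = (
                tag.i5_index + tag.i5_barcode + I5_ADAPTER
                + insert
                + revcomp(I7_ADAPTER) + revcomp(tag.i7_barcode) + revcomp(tag.i7_index)
            )
            out.append(AmpliconConstruct(site, sample, allele, insert, seq, tag))
    return out


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

_MUT = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    buf = list(seq)
    for p in positions.tolist():
        choices = _MUT.get(buf[p], list("ACGT"))
        buf[p] = choices[rng.integers(0, len(choices))]
    return "".join(buf)


def _read_batch(
    template: str,
    count: int,
    error_rate: float,
    rng: np.random.Generator,
) -> Iterator[str]:
    """``count`` copies of ``template`` with sparse substitution errors.

    The number of error bases is Binomial(count * len, e); error
    positions are drawn without replacement across the batch, so
    per-base error events are exchangeable with independent Bernoulli
    draws.  Error-free reads share the template string object.
    """
    n = len(template)
    if count == 0:
        return
    if error_rate <= 0.0:
        for _ in range(count):
            yield template
        return
    n_err = rng.binomial(count * n, error_rate)
    by_read: dict[int, list[int]] = {}
    if n_err:
        cells = rng.choice(count * n, size=min(n_err, count * n), replace=False)
        for c in cells.tolist():
            by_read.setdefault(c // n, []).append(c % n)
    for i in range(count):
        if i in by_read:
            yield _mutate(template, np.array(by_read[i]), rng)
        else:
            yield template


def generate_reads(
    genome: Mapping[str, str],
    panel: Panel | Sequence[VariantSite],
    scheme: BarcodeScheme,
    genotypes: GenotypeMatrix,
    depth_mean: float = 2300,
    read_length: int = DEFAULT_READ_LENGTH,
    quality_q: float | None = 30,
    seed: int | None = None,
    depth_distribution: str = "poisson",
) -> Iterator[ReadPair]:
    """Simulate barcoded paired-end amplicon reads for every sample/site.

    Per sample and panel site the pair depth is drawn around
    ``depth_mean`` (Poisson by default, or ``"fixed"``); heterozygous
    samples draw ref/alt molecules Binomial(depth, 1/2).  R1 is the
    construct prefix, R2 the reverse-complement suffix, each
    ``read_length`` long, with independent per-base substitution errors
    at rate ``10**(-Q/10)``.  ``quality_q=None`` disables errors
    (error-free mode).  Read names encode the true sample, locus and
    allele, so downstream assignments can be scored against ground truth.
    """
    sites = list(panel.sites) if isinstance(panel, Panel) else list(panel)
    if depth_distribution not in ("poisson", "fixed"):
        raise ValueError("depth_distribution must be 'poisson' or 'fixed'")
    if depth_mean <= 0:
        warnings.warn("depth_mean <= 0: no reads generated", stacklevel=2)
        return
    err = 0.0 if quality_q is None else phred_error_rate(quality_q)
    qual_q = 40 if quality_q is None else int(min(quality_q, 60))
    qual = chr(qual_q + 33) * read_length
    rng = np.random.default_rng(seed)

    for sample in genotypes.samples:
        if sample not in scheme.entries:
            raise KeyError(f"sample {sample!r} not in barcode scheme")
        row = genotypes.calls_for(sample)
        constructs = {
            (c.site.key, c.allele): c
            for c in build_constructs(genome, sites, scheme, sample)
        }
        for site in sites:
            g = int(row[genotypes.site_index(site.key)])
            if g == MISSING:
                continue
            depth = (
                int(rng.poisson(depth_mean))
                if depth_distribution == "poisson"
                else int(round(depth_mean))
            )
            if depth == 0:
                continue
            if g == HOM_REF:
                n_alt = 0
            elif g == HOM_ALT:
                n_alt = depth
            else:
                n_alt = int(rng.binomial(depth, 0.5))
            serial = 0
            for allele, count in (("ref", depth - n_alt), ("alt", n_alt)):
                if count == 0:
                    continue
                seq = constructs[(site.key, allele)].sequence
                if read_length > len(seq):
                    raise ValueError(
                        f"read_length {read_length} exceeds construct length {len(seq)}"
                    )
                t1 = seq[:read_length]
                t2 = revcomp(seq)[:read_length]
                reads1 = _read_batch(t1, count, err, rng)
                reads2 = _read_batch(t2, count, err, rng)
                base = f"{sample}|{site.chrom}:{site.pos}|{allele}"
                for s1, s2 in zip(reads1, reads2):
                    yield ReadPair(f"{base}|{serial}", s1, qual, s2, qual)
                    serial += 1


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def iter_demultiplex(
    pairs: Iterable[ReadPair], scheme: BarcodeScheme
) -> Iterator[tuple[str | None, ReadPair]]:
    """Assign each read pair to a sample by its combinatorial dual tags.

    A pair is assigned iff both the 10 nt i5 tag (R1 prefix) and the
    10 nt i7 tag (R2 prefix) match one scheme entry within
    ``scheme.max_mismatch``; anything else — including an ambiguous
    match — goes to the unassigned bin (``None``).  Assignment is
    exclusive, so assigned + unassigned partition the input.
    """
    exact = {(t.i5_tag, t.i7_tag): s for s, t in scheme.entries.items()}
    mm = scheme.max_mismatch
    if mm == 0:
        for pair in pairs:
            yield exact.get((pair.seq1[:TAG_LENGTH], pair.seq2[:TAG_LENGTH])), pair
        return
    entries = list(scheme.entries.items())
    for pair in pairs:
        t5, t7 = pair.seq1[:TAG_LENGTH], pair.seq2[:TAG_LENGTH]
        hit = exact.get((t5, t7))
        if hit is None:
            matches = [
                s for s, t in entries
                if hamming(t5, t.i5_tag) <= mm and hamming(t7, t.i7_tag) <= mm
            ]
            hit = matches[0] if len(matches) == 1 else None
        yield hit, pair


def demultiplex(
    pairs: Iterable[ReadPair], scheme: BarcodeScheme
) -> tuple[dict[str, list[ReadPair]], list[ReadPair]]:
    """Materialised demultiplexing: per-sample read lists + unassigned bin."""
    assigned: dict[str, list[ReadPair]] = {s: [] for s in scheme.samples}
    unassigned: list[ReadPair] = []
    for sample, pair in iter_demultiplex(pairs, scheme):
        if sample is None:
            unassigned.append(pair)
        else:
            assigned[sample].append(pair)
    return assigned, unassigned


def trim_pair(
    pair: ReadPair,
    insert_length: int = INSERT_LENGTH,
    adapter_length: int = len(I5_ADAPTER),
) -> tuple[str, str]:
    """Strip tags and adapters by construct geometry.

    Returns the insert-oriented portions of both mates: R1 after its
    10 nt tag + adapter, and the reverse complement of the same region
    of R2 — so both returned strings read in insert (genome window)
    orientation.
    """
    start = TAG_LENGTH + adapter_length
    end = start + insert_length
    return pair.seq1[start:end], revcomp(pair.seq2[start:end])


# ---------------------------------------------------------------------------
# Ungapped alignment against the mini-reference
# ---------------------------------------------------------------------------

class AlignmentHit(NamedTuple):
    name: str      # window name
    offset: int    # 0-based offset of the read start in the window (+ strand)
    strand: str    # '+' or '-'
    distance: int


class UngappedAligner:
    """Hamming-distance placement of short reads in mini-reference windows.

    Each read is assigned to the window/offset/strand minimising the
    number of mismatches over all ungapped placements; reads whose best
    distance exceeds ``max_mismatch_frac`` of their length are
    discarded.  Exact placements are found by substring lookup and
    near-exact ones by non-overlapping k-mer seeding (a read with fewer
    errors than seed chunks always retains an exact chunk); seedless
    reads fall back to the full scan.
    """

    def __init__(self, reference: MiniReference, max_mismatch_frac: float = 0.10,
                 seed_k: int = 20):
        self.reference = reference
        self.max_mismatch_frac = max_mismatch_frac
        self.seed_k = seed_k
        self._strands: dict[tuple[str, str], str] = {}
        for name in reference.names:
            seq = reference.seqs[name]
            self._strands[(name, "+")] = seq
            self._strands[(name, "-")] = revcomp(seq)
        self._kmer_index: dict[str, list[tuple[str, str, int]]] = {}
        for (name, strand), seq in self._strands.items():
            for i in range(len(seq) - seed_k + 1):
                self._kmer_index.setdefault(seq[i : i + seed_k], []).append((name, strand, i))
        self._exact_cache: dict[int, dict[str, tuple[str, str, int]]] = {}

    def _exact_index(self, length: int) -> dict[str, tuple[str, str, int]]:
        idx = self._exact_cache.get(length)
        if idx is None:
            idx = {}
            for (name, strand), seq in self._strands.items():
                for i in range(len(seq) - length + 1):
                    idx.setdefault(seq[i : i + length], (name, strand, i))
            self._exact_cache[length] = idx
        return idx

    def _candidates(self, read: str) -> set[tuple[str, str, int]]:
        k = self.seed_k
        cands: set[tuple[str, str, int]] = set()
        for c in range(0, len(read) - k + 1, k):
            for name, strand, i in self._kmer_index.get(read[c : c + k], ()):
                off = i - c
                if 0 <= off <= len(self._strands[(name, strand)]) - len(read):
                    cands.add((name, strand, off))
        return cands

    def align(self, read: str) -> AlignmentHit | None:
        if not read:
            return None
        ceiling = int(self.max_mismatch_frac * len(read))
        exact = self._exact_index(len(read)).get(read)
        if exact is not None:
            name, strand, i = exact
            return self._hit(name, strand, i, len(read), 0)
        cands = self._candidates(read)
        if not cands:
            cands = {
                (name, strand, off)
                for (name, strand), seq in self._strands.items()
                for off in range(len(seq) - len(read) + 1)
            }
        best: tuple[int, str, str, int] | None = None
        for name, strand, off in cands:
            seq = self._strands[(name, strand)]
            d = hamming(read, seq[off : off + len(read)])
            key = (d, name, strand, off)
            if best is None or key < best:
                best = key
        if best is None or best[0] > ceiling:
            return None
        d, name, strand, off = best
        return self._hit(name, strand, off, len(read), d)

    def _hit(self, name: str, strand: str, off: int, read_len: int, dist: int) -> AlignmentHit:
        if strand == "-":
            # report the offset on the forward strand of the window
            off = len(self._strands[(name, "-")]) - off - read_len
        return AlignmentHit(name, off, strand, dist)

    def base_at(self, read: str, hit: AlignmentHit, window_offset0: int) -> str | None:
        """The read base covering forward-strand window position ``window_offset0``."""
        rel = window_offset0 - hit.offset
        if not (0 <= rel < len(read)):
            return None
        if hit.strand == "+":
            return read[rel]
        return revcomp(read)[rel]


@dataclass
class PileupCounts:
    ref: int = 0
    alt: int = 0
    other: int = 0
    discarded: int = 0

    @property
    def depth(self) -> int:
        return self.ref + self.alt


def trim_and_align(
    demuxed: Iterable[tuple[str | None, ReadPair]],
    reference: MiniReference,
    max_mismatch_frac: float = 0.10,
    insert_length: int = INSERT_LENGTH,
) -> tuple[dict[tuple[str, str], PileupCounts], int]:
    """Trim, align and pile up demultiplexed read pairs.

    Returns per (sample, window name) allele counts at the SNP column
    plus the number of discarded (unalignable) reads; both mates of a
    pair contribute an observation when they cover the SNP.  Unassigned
    pairs are skipped.
    """
    aligner = UngappedAligner(reference, max_mismatch_frac)
    pileups: dict[tuple[str, str], PileupCounts] = {}
    n_discarded = 0
    for sample, pair in demuxed:
        if sample is None:
            continue
        for read in trim_pair(pair, insert_length):
            if not read:
                continue
            hit = aligner.align(read)
            if hit is None:
                n_discarded += 1
                continue
            counts = pileups.setdefault((sample, hit.name), PileupCounts())
            base = aligner.base_at(read, hit, reference.snp_offsets[hit.name])
            if base is None:
                continue
            site = reference.sites[hit.name]
            if base == site.ref:
                counts.ref += 1
            elif base == site.alt:
                counts.alt += 1
            else:
                counts.other += 1
    return pileups, n_discarded


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------

NO_CALL = -1
_CALL_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", NO_CALL: "no_call"}


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample, per-site call derived from pileup allele counts."""

    sample: str
    site: VariantSite
    ref_count: int
    alt_count: int
    other_count: int
    call: int  # genotype code, NO_CALL when depth is insufficient

    @property
    def call_name(self) -> str:
        return _CALL_NAMES[self.call]


def call_genotype(
    sample: str,
    site: VariantSite,
    counts: PileupCounts,
    min_depth: int = 100,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> GenotypeCall:
    """Threshold caller: no_call below ``min_depth``; otherwise the alt
    fraction f = alt/(ref+alt) maps to hom_ref (f < low), hom_alt
    (f > high) or het (inside the band, boundaries inclusive)."""
    low, high = het_band
    if not (0.0 <= low <= high <= 1.0):
        raise ValueError(f"het_band must satisfy 0 <= low <= high <= 1, got {het_band}")
    depth = counts.ref + counts.alt
    if depth < min_depth:
        call = NO_CALL
    else:
        f = counts.alt / depth
        call = HOM_REF if f < low else HOM_ALT if f > high else HET
    return GenotypeCall(sample, site, counts.ref, counts.alt, counts.other, call)


def call_all_genotypes(
    pileups: Mapping[tuple[str, str], PileupCounts],
    reference: MiniReference,
    samples: Sequence[str],
    min_depth: int = 100,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> list[GenotypeCall]:
    """Calls for every (sample, panel site), no_call where no reads aligned."""
    out = []
    for sample in samples:
        for name in reference.names:
            counts = pileups.get((sample, name), PileupCounts())
            out.append(
                call_genotype(sample, reference.sites[name], counts, min_depth, het_band)
            )
    return out


def write_calls_tsv(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tref\talt\tref_count\talt_count\tother_count\tcall\n")
        for c in calls:
            fh.write(
                f"{c.sample}\t{c.site.chrom}\t{c.site.pos}\t{c.site.ref}\t{c.site.alt}\t"
                f"{c.ref_count}\t{c.alt_count}\t{c.other_count}\t{c.call_name}\n"
            )


def read_calls_tsv(path: str | Path) -> list[GenotypeCall]:
    name_to_code = {v: k for k, v in _CALL_NAMES.items()}
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            sample, chrom, pos, ref, alt, rc, ac, oc, call = line.rstrip("\n").split("\t")[:9]
            out.append(
                GenotypeCall(
                    sample,
                    VariantSite(chrom, int(pos), ref, alt),
                    int(rc), int(ac), int(oc),
                    name_to_code[call],
                )
            )
    return out
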