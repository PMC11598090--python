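"""Readers/writers for VCF, FASTA and FASTQ, plus Phred quality helpers.

Conventions
-----------
* VCF coordinates are 1-based (standard); any half-open 0-based window
  arithmetic elsewhere in the package converts through here or through
  the mini-reference coordinate map.
* Only the GT FORMAT field is consumed from VCFs; phased genotypes
  (``0|1``) are normalised to their unphased state.
* FASTQ qualities are Phred+33; FASTA output wraps at 60 columns.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pysam
from Bio import SeqIO

from .genotypes import GT_STRINGS, GenotypeMatrix, VariantSite

PHRED_OFFSET = 33
MAX_PHRED = 60


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


class VcfFormatError(FormatError):
    pass


class FastqFormatError(FormatError):
    pass


# ---------------------------------------------------------------------------
# Phred utilities
# ---------------------------------------------------------------------------

def phred_accuracy(q: float) -> float:
    """Percent probability of a correct base call at Phred quality ``q``.

    ``100 * (1 - 10**(-q/10))``; Q30 -> 99.9, Q40 -> 99.99.
    """
    if q < 0:
        raise ValueError(f"Phred quality must be >= 0, got {q}")
    return 100.0 * (1.0 - 10.0 ** (-q / 10.0))


def phred_error_rate(q: float) -> float:
    """Per-base error probability at Phred quality ``q`` (``10**(-q/10)``)."""
    if q < 0:
        raise ValueError(f"Phred quality must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def decode_qualities(qual: str) -> np.ndarray:
    """Phred+33 string -> integer scores."""
    scores = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - PHRED_OFFSET
    if scores.size and (scores.min() < 0 or scores.max() > MAX_PHRED):
        raise FastqFormatError(
            f"quality scores outside [0, {MAX_PHRED}]: {qual!r}"
        )
    return scores


def encode_qualities(scores: Iterable[int]) -> str:
    out = []
    for q in scores:
        if q < 0 or q > MAX_PHRED:
            raise ValueError(f"Phred score {q} outside [0, {MAX_PHRED}]")
        out.append(chr(int(q) + PHRED_OFFSET))
    return "".join(out)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a multi-sample VCF (GT only) into a :class:`GenotypeMatrix`.

    Accepts phased or unphased diploid GTs; multi-allelic records,
    non-SNP alleles, non-diploid genotypes and ref==alt raise
    :class:`VcfFormatError` naming the offending line.
    """
    import cyvcf2

    path = str(path)
    try:
        vcf = cyvcf2.VCF(path, gts012=True)
    except Exception as exc:  # malformed header or unreadable file
        raise VcfFormatError(f"{path}: cannot parse VCF header ({exc})") from exc
    samples = list(vcf.samples)
    header_lines = vcf.raw_header.count("\n")

    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    # gts012=True: 0=hom ref, 1=het, 2=hom alt, 3=unknown
    code_map = np.array([0, 1, 2, -1], dtype=np.int8)
    for i, variant in enumerate(vcf):
        line_no = header_lines + 1 + i
        if len(variant.ALT) != 1:
            raise VcfFormatError(
                f"{path} line {line_no}: expected exactly one ALT allele"
            )
        ref, alt = variant.REF, variant.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            raise VcfFormatError(f"{path} line {line_no}: not a SNP ({ref}>{alt})")
        if ref == alt:
            raise VcfFormatError(f"{path} line {line_no}: ref equals alt ({ref})")
        if variant.ploidy != 2:
            raise VcfFormatError(
                f"{path} line {line_no}: non-diploid GT (ploidy {variant.ploidy})"
            )
        try:
            sites.append(VariantSite(variant.CHROM, variant.POS, ref, alt))
        except ValueError as exc:
            raise VcfFormatError(f"{path} line {line_no}: {exc}") from exc
        gt = np.asarray(variant.gt_types, dtype=np.int64)
        rows.append(code_map[gt])
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, sites, calls)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GT-only VCF v4.2 (unphased, 1-based positions)."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=sibtrace"]
    for chrom in matrix.chroms():
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    for j, site in enumerate(matrix.sites):
        gts = "\t".join(GT_STRINGS[int(c)] for c in matrix.calls[:, j])
        lines.append(
            f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (paired)
# ---------------------------------------------------------------------------

class ReadPair(NamedTuple):
    """A simulated/parsed paired-end read with Phred+33 quality strings."""

    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # mtime=0 keeps outputs byte-identical across runs
            return gzip.GzipFile(path, "wb", compresslevel=1, mtime=0)  # type: ignore[return-value]
        return gzip.open(path, "rt")
    return open(path, mode)


def write_fastq_pair(
    pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path
) -> int:
    """Write paired reads to two FASTQ files (gzipped iff path ends .gz).

    Returns the number of pairs written.  Raises
    :class:`FastqFormatError` if a record's sequence and quality lengths
    disagree.
    """
    n = 0
    buf1: list[str] = []
    buf2: list[str] = []
    gz1, gz2 = str(path1).endswith(".gz"), str(path2).endswith(".gz")
    f1 = _open_text(path1, "w")
    f2 = _open_text(path2, "w")
    try:
        for p in pairs:
            if len(p.seq1) != len(p.qual1) or len(p.seq2) != len(p.qual2):
                raise FastqFormatError(
                    f"read {p.name}: sequence/quality length mismatch"
                )
            buf1.append(f"@{p.name}\n{p.seq1}\n+\n{p.qual1}\n")
            buf2.append(f"@{p.name}\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
            if len(buf1) >= 20000:
                _flush(f1, buf1, gz1)
                _flush(f2, buf2, gz2)
        _flush(f1, buf1, gz1)
        _flush(f2, buf2, gz2)
    finally:
        f1.close()
        f2.close()
    return n


def _flush(fh, buf: list[str], binary: bool) -> None:
    if buf:
        data = "".join(buf)
        fh.write(data.encode("ascii") if binary else data)
        buf.clear()


def read_fastq_pair(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream paired FASTQ files in lockstep.

    Raises :class:`FastqFormatError` on record-count mismatch or on a
    record whose sequence and quality lengths differ.
    """
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        it1, it2 = iter(f1), iter(f2)
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise FastqFormatError(
                    f"unpaired FASTQ files: {path1} and {path2} differ in record count"
                )
            for r in (r1, r2):
                if r.quality is None or len(r.sequence) != len(r.quality):
                    raise FastqFormatError(
                        f"read {r.name}: sequence/quality length mismatch"
                    )
            yield ReadPair(r1.name, r1.sequence, r1.quality, r2.sequence, r2.quality)


# ---------------------------------------------------------------------------
# Small TSV helpers used by several stages
# ---------------------------------------------------------------------------

def write_sites_tsv(sites: Iterable[VariantSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\n")


def read_sites_tsv(path: str | Path) -> list[VariantSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise FormatError(f"{path}: expected 'chrom\\tpos\\tref\\talt' header")
        for line in fh:
            if not line.strip():
                continue
            chrom, pos, ref, alt = line.rstrip("\n").split("\t")[:4]
            sites.append(VariantSite(chrom, int(pos), ref, alt))
    return sites
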