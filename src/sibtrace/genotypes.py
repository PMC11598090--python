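"""Core containers for diploid genotype data.

Genotypes are stored as small integer codes counting copies of the
alternate allele: 0 (hom ref, VCF ``0/0``), 1 (het, ``0/1``), 2 (hom alt,
``1/1``), and -1 for missing (``./.``).  A :class:`GenotypeMatrix` is a
dense samples x sites matrix of those codes; it is the substrate that
marker selection, parentage assignment, and IBD estimation all operate on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

_VALID_CALLS = frozenset({HOM_REF, HET, HOM_ALT, MISSING})

#: VCF GT string for each internal code (unphased representation).
GT_STRINGS: Mapping[int, str] = {
    HOM_REF: "0/0",
    HET: "0/1",
    HOM_ALT: "1/1",
    MISSING: "./.",
}

_BASES = ("A", "C", "G", "T")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural sort key so that chr2 < chr10."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP: chromosome, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for base, name in ((self.ref, "ref"), (self.alt, "alt")):
            if base not in _BASES:
                raise ValueError(f"{name} allele must be a single base A/C/G/T, got {base!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.pos)

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(eq=False)
class GenotypeMatrix:
    """Per-sample diploid calls at an ordered set of variant sites.

    Parameters
    ----------
    samples
        Ordered, unique sample labels (rows).
    sites
        Ordered :class:`VariantSite` list (columns); (chrom, pos) unique.
    calls
        int8 array of shape ``(len(samples), len(sites))`` with values in
        {0, 1, 2, -1}.
    """

    samples: list[str]
    sites: list[VariantSite]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.sites = list(self.sites)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample labels")
        keys = {s.key for s in self.sites}
        if len(keys) != len(self.sites):
            raise ValueError("duplicate (chrom, pos) in site list")
        if self.calls.size and not np.isin(self.calls, (-1, 0, 1, 2)).all():
            bad = np.unique(self.calls[~np.isin(self.calls, (-1, 0, 1, 2))])
            raise ValueError(f"invalid genotype codes: {bad.tolist()}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, label: str) -> int:
        try:
            return self.samples.index(label)
        except ValueError:
            raise KeyError(f"unknown sample label {label!r}") from None

    def site_index(self, key: tuple[str, int]) -> int:
        lookup = self.__dict__.get("_site_lookup")
        if lookup is None or len(lookup) != len(self.sites):
            lookup = {s.key: j for j, s in enumerate(self.sites)}
            self.__dict__["_site_lookup"] = lookup
        try:
            return lookup[key]
        except KeyError:
            raise KeyError(f"unknown site {key[0]}:{key[1]}") from None

    def calls_for(self, label: str) -> np.ndarray:
        """Genotype vector (one row) for a sample."""
        return self.calls[self.sample_index(label)]

    def site_calls(self, site: VariantSite | tuple[str, int]) -> np.ndarray:
        key = site.key if isinstance(site, VariantSite) else site
        return self.calls[:, self.site_index(key)]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), list(self.sites), self.calls.copy())

    # -- derived views --------------------------------------------------
    def restrict_to_sites(self, sites: Sequence[VariantSite]) -> "GenotypeMatrix":
        """Submatrix over ``sites`` in the given order."""
        cols = [self.site_index(s.key) for s in sites]
        return GenotypeMatrix(list(self.samples), list(sites), self.calls[:, cols].copy())

    def restrict_to_samples(self, labels: Sequence[str]) -> "GenotypeMatrix":
        rows = [self.sample_index(s) for s in labels]
        return GenotypeMatrix(list(labels), list(self.sites), self.calls[rows].copy())

    def add_sites(self, new_sites: Sequence[VariantSite], new_calls: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix with extra columns, sorted by (chrom, pos)."""
        new_calls = np.asarray(new_calls, dtype=np.int8)
        if new_calls.shape != (self.n_samples, len(new_sites)):
            raise ValueError("new_calls shape inconsistent with samples/new_sites")
        sites = self.sites + list(new_sites)
        calls = np.concatenate([self.calls, new_calls], axis=1) if self.n_sites else new_calls
        order = sorted(range(len(sites)), key=lambda j: sites[j].sort_key())
        return GenotypeMatrix(
            list(self.samples), [sites[j] for j in order], calls[:, order].copy()
        )

    def with_replicates(self, label: str, replicate_labels: Sequence[str]) -> "GenotypeMatrix":
        """Replace one sample row by identically-genotyped replicate rows.

        Models an individual sequenced more than once (e.g. a target
        parent run twice so replicate concordance can screen out false
        heterozygous calls).
        """
        i = self.sample_index(label)
        samples = self.samples[:i] + list(replicate_labels) + self.samples[i + 1 :]
        rows = np.concatenate(
            [
                self.calls[:i],
                np.repeat(self.calls[i : i + 1], len(replicate_labels), axis=0),
                self.calls[i + 1 :],
            ],
            axis=0,
        )
        return GenotypeMatrix(samples, list(self.sites), rows)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s.chrom, None)
        return sorted(seen, key=chrom_sort_key)


@dataclass
class PedigreeTruth:
    """Ground truth for a simulated open-pollination design.

    Records the known mother, the true father of every simulated
    offspring, which father is the focal (target) pollen parent, and the
    marker sites planted as private heterozygous variants of that father.
    """

    mother: str | None = None
    father_of: dict[str, str] = field(default_factory=dict)
    focal_father: str | None = None
    planted_specific_sites: list[VariantSite] = field(default_factory=list)

    def merged_with(self, other: "PedigreeTruth") -> "PedigreeTruth":
        """Combine two partial truth records (later fields win when set)."""
        return PedigreeTruth(
            mother=other.mother or self.mother,
            father_of={**self.father_of, **other.father_of},
            focal_father=other.focal_father or self.focal_father,
            planted_specific_sites=(
                other.planted_specific_sites or self.planted_specific_sites
            ),
        )

    def true_focal_offspring(self) -> set[str]:
        if self.focal_father is None:
            return set()
        return {o for o, f in self.father_of.items() if f == self.focal_father}


def sorted_sites(sites: Iterable[VariantSite]) -> list[VariantSite]:
    return sorted(sites, key=VariantSite.sort_key)
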