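"""Synthetic open-pollination simulator with full ground truth.

Emulates the study design this package targets: one known mother tree
surrounded by a pool of candidate pollen parents, one focal father
carrying a handful of private heterozygous SNPs distributed across
chromosomes, and open-pollinated offspring produced by Mendelian
segregation.  Sites are simulated unlinked (independent segregation),
which is faithful for a panel of one-marker-per-chromosome sites and is
adequate for method-of-moments IBD, whose per-site expectations do not
depend on linkage.

All simulators are deterministic for a fixed seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    HET,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    PedigreeTruth,
    VariantSite,
    chrom_sort_key,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Panel sites must sit at least this far from chromosome ends so that a
#: 120 bp amplicon insert and a 200 bp mini-reference window both fit.
DEFAULT_MARGIN = 150


def _rng(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genome(
    chrom_names: Sequence[str],
    chrom_length: int | Mapping[str, int] = 5000,
    seed: int | None = None,
) -> dict[str, str]:
    """Uniform-random A/C/G/T chromosome sequences."""
    rng = _rng(seed)
    genome: dict[str, str] = {}
    for chrom in chrom_names:
        n = chrom_length[chrom] if isinstance(chrom_length, Mapping) else int(chrom_length)
        if n < 2 * DEFAULT_MARGIN:
            raise ValueError(f"chromosome length {n} too short (need >= {2 * DEFAULT_MARGIN})")
        genome[chrom] = _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")
    return genome


def _draw_positions(
    rng: np.random.Generator,
    n: int,
    chrom_len: int,
    margin: int,
    taken: set[int] = frozenset(),  # type: ignore[assignment]
) -> np.ndarray:
    lo, hi = margin + 1, chrom_len - margin  # 1-based inclusive bounds
    pool = hi - lo + 1
    if pool < n + len(taken):
        raise ValueError(f"cannot place {n} sites on a chromosome of length {chrom_len}")
    positions: set[int] = set()
    while len(positions) < n:
        cand = rng.integers(lo, hi + 1, size=n - len(positions))
        for p in cand.tolist():
            if p not in taken and p not in positions:
                positions.add(p)
    return np.array(sorted(positions))


def _site_at(
    rng: np.random.Generator, chrom: str, pos: int, genome: Mapping[str, str] | None
) -> VariantSite:
    if genome is not None:
        ref = genome[chrom][pos - 1]
    else:
        ref = chr(_BASES[rng.integers(0, 4)][0])
    alt = ref
    while alt == ref:
        alt = chr(_BASES[rng.integers(0, 4)][0])
    return VariantSite(chrom, int(pos), ref, alt)


def simulate_founders(
    n_fathers: int,
    chrom_names: Sequence[str],
    sites_per_chrom: int | Sequence[int] | Mapping[str, int],
    allele_freq_range: tuple[float, float] = (0.05, 0.95),
    seed: int | None = None,
    genome: Mapping[str, str] | None = None,
    chrom_length: int = 5000,
    margin: int = DEFAULT_MARGIN,
    mother_label: str = "mother",
    father_prefix: str = "father",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate the candidate-parent pool under Hardy-Weinberg proportions.

    One mother plus ``n_fathers`` fathers; at each site the alternate
    allele frequency is drawn uniformly from ``allele_freq_range`` and
    genotypes follow HWE (two independent allele draws).  Returns the
    founder matrix and the per-site allele-frequency table
    (chrom, pos, ref, alt, alt_freq).
    """
    if n_fathers < 2:
        raise ValueError(f"n_fathers must be >= 2, got {n_fathers}")
    if not chrom_names:
        raise ValueError("chrom_names must be nonempty")
    lo, hi = allele_freq_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"allele_freq_range must satisfy 0 < lo <= hi < 1, got {allele_freq_range}")
    if isinstance(sites_per_chrom, Mapping):
        per_chrom = {c: int(sites_per_chrom[c]) for c in chrom_names}
    elif isinstance(sites_per_chrom, (int, np.integer)):
        per_chrom = {c: int(sites_per_chrom) for c in chrom_names}
    else:
        counts = list(sites_per_chrom)
        if len(counts) != len(chrom_names):
            raise ValueError("per-chromosome site counts must match chrom_names length")
        per_chrom = dict(zip(chrom_names, (int(c) for c in counts)))
    if any(c < 1 for c in per_chrom.values()):
        raise ValueError("sites_per_chrom must be >= 1 on every chromosome")

    rng = _rng(seed)
    sites: list[VariantSite] = []
    for chrom in sorted(chrom_names, key=chrom_sort_key):
        clen = len(genome[chrom]) if genome is not None else chrom_length
        for pos in _draw_positions(rng, per_chrom[chrom], clen, margin):
            sites.append(_site_at(rng, chrom, int(pos), genome))

    samples = [mother_label] + [f"{father_prefix}_{i + 1:03d}" for i in range(n_fathers)]
    n, m = len(samples), len(sites)
    freqs = rng.uniform(lo, hi, size=m)
    calls = (
        (rng.random((n, m)) < freqs).astype(np.int8)
        + (rng.random((n, m)) < freqs).astype(np.int8)
    )
    matrix = GenotypeMatrix(samples, sites, calls)
    table = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "alt_freq": freqs,
        }
    )
    return matrix, table


def plant_specific_sites(
    founders: GenotypeMatrix,
    focal_father: str,
    n_sites: int,
    excluded_chroms: Sequence[str] = (),
    seed: int | None = None,
    genome: Mapping[str, str] | None = None,
    chrom_length: int = 5000,
    margin: int = DEFAULT_MARGIN,
    one_per_chrom: bool = True,
    mother: str | None = None,
) -> tuple[GenotypeMatrix, PedigreeTruth]:
    """Add private heterozygous marker sites carried only by the focal father.

    Each planted site is het (0/1) in ``focal_father`` and hom ref (0/0)
    in every other founder, the mother included — the configuration that
    makes the downstream presence rule informative.  With
    ``one_per_chrom`` (panel-emulation mode, the default) at most one
    site is placed per non-excluded chromosome.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    focal_idx = founders.sample_index(focal_father)
    truth = PedigreeTruth(
        mother=mother if mother is not None else founders.samples[0],
        focal_father=focal_father,
    )
    if n_sites == 0:
        return founders.copy(), truth

    excluded = set(excluded_chroms)
    all_chroms = founders.chroms() or []
    eligible = [c for c in all_chroms if c not in excluded]
    if genome is not None:
        eligible = [c for c in sorted(genome, key=chrom_sort_key) if c not in excluded]
    rng = _rng(seed)

    if one_per_chrom:
        if n_sites > len(eligible):
            raise ValueError(
                f"cannot place {n_sites} one-per-chromosome sites on "
                f"{len(eligible)} eligible chromosomes "
                f"(short by {n_sites - len(eligible)})"
            )
        chosen = [eligible[i] for i in sorted(rng.choice(len(eligible), n_sites, replace=False))]
    else:
        if not eligible:
            raise ValueError("no eligible chromosomes to place sites on")
        chosen = [eligible[i] for i in rng.integers(0, len(eligible), size=n_sites)]

    taken: dict[str, set[int]] = {}
    for s in founders.sites:
        taken.setdefault(s.chrom, set()).add(s.pos)
    new_sites: list[VariantSite] = []
    for chrom in chosen:
        clen = len(genome[chrom]) if genome is not None else chrom_length
        chrom_taken = taken.setdefault(chrom, set())
        pos = int(_draw_positions(rng, 1, clen, margin, chrom_taken)[0])
        chrom_taken.add(pos)
        new_sites.append(_site_at(rng, chrom, pos, genome))

    new_calls = np.full((founders.n_samples, len(new_sites)), HOM_REF, dtype=np.int8)
    new_calls[focal_idx, :] = HET
    planted = sorted(new_sites, key=VariantSite.sort_key)
    truth.planted_specific_sites = planted
    return founders.add_sites(new_sites, new_calls), truth


def simulate_offspring(
    founders: GenotypeMatrix,
    mother: str,
    father_weights: Mapping[str, float],
    n_offspring: int,
    seed: int | None = None,
    offspring_prefix: str = "offspring",
) -> tuple[GenotypeMatrix, PedigreeTruth]:
    """Mendelian open-pollination: each offspring draws a father, then one
    allele from each parent independently at every (unlinked) site."""
    if n_offspring < 0:
        raise ValueError("n_offspring must be >= 0")
    if not father_weights:
        raise ValueError("father_weights must be nonempty")
    labels = list(father_weights)
    weights = np.array([father_weights[f] for f in labels], dtype=float)
    if (weights < 0).any():
        raise ValueError("father weights must be nonnegative")
    if not np.isclose(weights.sum(), 1.0, atol=1e-8):
        raise ValueError(f"father weights must sum to 1, got {weights.sum():.6f}")
    mother_idx = founders.sample_index(mother)
    father_rows = np.array([founders.sample_index(f) for f in labels])

    mg = founders.calls[mother_idx].astype(np.int16)
    if (mg == MISSING).any() or (founders.calls[father_rows] == MISSING).any():
        raise ValueError("parental genotypes may not be missing")

    rng = _rng(seed)
    samples = [f"{offspring_prefix}_{i + 1:04d}" for i in range(n_offspring)]
    m = founders.n_sites
    if n_offspring == 0:
        empty = GenotypeMatrix([], list(founders.sites), np.empty((0, m), dtype=np.int8))
        return empty, PedigreeTruth(mother=mother)

    father_choice = rng.choice(len(labels), size=n_offspring, p=weights)
    fg = founders.calls[father_rows[father_choice]].astype(np.int16)  # (n, m)
    allele_m = (rng.random((n_offspring, m)) < mg[None, :] / 2.0).astype(np.int8)
    allele_f = (rng.random((n_offspring, m)) < fg / 2.0).astype(np.int8)
    calls = allele_m + allele_f
    truth = PedigreeTruth(
        mother=mother,
        father_of={s: labels[k] for s, k in zip(samples, father_choice)},
    )
    return GenotypeMatrix(samples, list(founders.sites), calls), truth


def apply_genotyping_error(
    matrix: GenotypeMatrix, error_rate: float, seed: int | None = None
) -> GenotypeMatrix:
    """Symmetric state-flip error model.

    Each non-missing call is independently replaced, with probability
    ``error_rate``, by one of the other two non-missing states chosen
    uniformly.  Missing calls are untouched.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise ValueError(f"error_rate must be in [0, 1], got {error_rate}")
    out = matrix.copy()
    if error_rate == 0.0 or out.calls.size == 0:
        return out
    rng = _rng(seed)
    flip = (rng.random(out.calls.shape) < error_rate) & (out.calls != MISSING)
    # new state = (old + 1 + b) mod 3 with b ~ Bernoulli(1/2): uniform over the
    # two other states
    b = (rng.random(out.calls.shape) < 0.5).astype(np.int8)
    flipped = (out.calls + 1 + b) % 3
    out.calls[flip] = flipped[flip]
    return out


def apply_missingness(
    matrix: GenotypeMatrix, missing_rate: float, seed: int | None = None
) -> GenotypeMatrix:
    """Set calls to missing independently with probability ``missing_rate``."""
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError(f"missing_rate must be in [0, 1], got {missing_rate}")
    out = matrix.copy()
    if missing_rate == 0.0 or out.calls.size == 0:
        return out
    rng = _rng(seed)
    out.calls[rng.random(out.calls.shape) < missing_rate] = MISSING
    return out


# ---------------------------------------------------------------------------
# Truth-table serialization (tab-separated text)
# ---------------------------------------------------------------------------

def write_truth(truth: PedigreeTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#mother={truth.mother or ''}\n")
        fh.write(f"#focal_father={truth.focal_father or ''}\n")
        planted = ",".join(
            f"{s.chrom}:{s.pos}:{s.ref}:{s.alt}" for s in truth.planted_specific_sites
        )
        fh.write(f"#planted={planted}\n")
        fh.write("offspring\tfather\n")
        for off, father in truth.father_of.items():
            fh.write(f"{off}\t{father}\n")


def read_truth(path) -> PedigreeTruth:
    truth = PedigreeTruth()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#mother="):
                truth.mother = line.split("=", 1)[1] or None
            elif line.startswith("#focal_father="):
                truth.focal_father = line.split("=", 1)[1] or None
            elif line.startswith("#planted="):
                spec = line.split("=", 1)[1]
                if spec:
                    for item in spec.split(","):
                        chrom, pos, ref, alt = item.split(":")
                        truth.planted_specific_sites.append(
                            VariantSite(chrom, int(pos), ref, alt)
                        )
            elif line and not line.startswith(("offspring\t", "#")):
                off, father = line.split("\t")
                truth.father_of[off] = father
    return truth
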