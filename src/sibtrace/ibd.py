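"""Method-of-moments pairwise identity-by-descent (Z0, Z1, Z2, PI_HAT).

For two diploid individuals, each site falls in an identity-by-state
class (sharing 0, 1 or 2 alleles).  Under Hardy-Weinberg equilibrium
with alt frequency p (q = 1 - p) the per-site IBS-class probabilities
conditional on the latent IBD state are::

    P(IBS0 | IBD0) = 2 p^2 q^2
    P(IBS1 | IBD0) = 4 p^3 q + 4 p q^3
    P(IBS2 | IBD0) = p^4 + q^4 + 4 p^2 q^2
    P(IBS0 | IBD1) = 0
    P(IBS1 | IBD1) = 2 p^2 q + 2 p q^2
    P(IBS2 | IBD1) = 1 - P(IBS1 | IBD1)
    P(IBS0 | IBD2) = P(IBS1 | IBD2) = 0,   P(IBS2 | IBD2) = 1

Summing these over sites and equating to the observed IBS counts gives
the genome-wide IBD-state proportions sequentially (Z0 from IBS0, then
Z1, then Z2), after which PI_HAT = Z2 + Z1/2.  The expectation of
PI_HAT is 0.5 for parent-offspring pairs, and (Z0, Z1, Z2) =
(0.25, 0.5, 0.25) for full sibs.  No small-sample bias correction is
applied to the IBS expectations (some reference implementations apply
one); estimates are clamped to [0, 1] and renormalised instead.

Reference allele frequencies should come from the founder pool rather
than from the (related) offspring, to avoid relatedness bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

#: First-degree PI_HAT window (boundaries inclusive).
FIRST_DEGREE_LOW = 0.4358
FIRST_DEGREE_HIGH = 0.5625


class IbdDegeneracyError(ArithmeticError):
    """A moment-solve step had a zero expected count."""


@dataclass(frozen=True)
class IBDEstimate:
    sample_a: str
    sample_b: str
    z0: float
    z1: float
    z2: float
    pi_hat: float
    n_sites_used: int
    low_confidence: bool = False


def allele_frequencies(
    matrix: GenotypeMatrix, founder_labels: Sequence[str] | None = None
) -> np.ndarray:
    """Per-site alt-allele frequency from the founder samples.

    Missing calls are skipped per site; all-missing sites get NaN and
    monomorphic sites (frequency exactly 0 or 1) should be excluded by
    callers (:func:`polymorphic_mask`).
    """
    if founder_labels is not None:
        if len(founder_labels) < 2:
            raise ValueError("at least two founders are required")
        matrix = matrix.restrict_to_samples(list(founder_labels))
    elif matrix.n_samples < 2:
        raise ValueError("at least two founders are required")
    calls = matrix.calls.astype(float)
    called = calls != MISSING
    alt = np.where(called, calls, 0.0).sum(axis=0)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return freqs


def polymorphic_mask(freqs: np.ndarray, min_maf: float = 0.01) -> np.ndarray:
    """Sites usable for IBD: called, polymorphic, and MAF >= ``min_maf``."""
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freqs, 1.0 - freqs)
        return np.isfinite(freqs) & (maf >= min_maf)


def ibs_profile(g1: np.ndarray, g2: np.ndarray) -> tuple[int, int, int]:
    """Counts (N0, N1, N2) of co-called sites sharing 0/1/2 alleles by state.

    IBS is computed on unordered allele multisets: 0/0 vs 1/1 shares 0
    alleles, 0/1 vs 0/1 shares 2.  Sites missing in either sample are
    skipped.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must be aligned on the same site set")
    ok = (g1 != MISSING) & (g2 != MISSING)
    ibs = 2 - np.abs(g1[ok].astype(int) - g2[ok].astype(int))
    return (
        int((ibs == 0).sum()),
        int((ibs == 1).sum()),
        int((ibs == 2).sum()),
    )


def ibs_class_probs(p: float | np.ndarray) -> np.ndarray:
    """IBS-class probabilities given IBD state under HWE.

    Returns an array of shape ``(3, 3) [+ p.shape]`` indexed
    ``[ibs, ibd]``.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    zero = np.zeros_like(p)
    one = np.ones_like(p)
    p_ibs1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    return np.array(
        [
            [2 * p**2 * q**2, zero, zero],
            [4 * p**3 * q + 4 * p * q**3, p_ibs1_ibd1, zero],
            [p**4 + q**4 + 4 * p**2 * q**2, 1.0 - p_ibs1_ibd1, one],
        ]
    )


def mom_ibd(
    g1: np.ndarray,
    g2: np.ndarray,
    freqs: np.ndarray,
    sample_a: str = "a",
    sample_b: str = "b",
    min_maf: float = 0.01,
    min_sites: int = 200,
) -> IBDEstimate:
    """Method-of-moments IBD estimate for one sample pair.

    ``freqs`` are founder alt-allele frequencies aligned with the
    genotype vectors.  Pairs with fewer than ``min_sites`` usable
    polymorphic co-called sites are flagged low-confidence (the estimate
    is still returned).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    freqs = np.asarray(freqs, dtype=float)
    if not (g1.shape == g2.shape == freqs.shape):
        raise ValueError("genotype vectors and frequencies must be aligned")
    usable = polymorphic_mask(freqs, min_maf) & (g1 != MISSING) & (g2 != MISSING)
    n = int(usable.sum())
    if n == 0:
        raise IbdDegeneracyError("no usable polymorphic co-called sites")
    a, b, p = g1[usable], g2[usable], freqs[usable]

    n0, n1, n2 = ibs_profile(a, b)
    probs = ibs_class_probs(p)  # (3 ibs, 3 ibd, n sites)
    expected = probs.sum(axis=2)  # (3 ibs, 3 ibd) summed over sites

    if expected[0, 0] <= 0:
        raise IbdDegeneracyError("zero expected IBS0 count in the IBD0 solve step")
    z0 = n0 / expected[0, 0]
    if expected[1, 1] <= 0:
        raise IbdDegeneracyError("zero expected IBS1 count in the IBD1 solve step")
    z1 = (n1 - z0 * expected[1, 0]) / expected[1, 1]
    if expected[2, 2] <= 0:
        raise IbdDegeneracyError("zero expected IBS2 count in the IBD2 solve step")
    z2 = (n2 - z0 * expected[2, 0] - z1 * expected[2, 1]) / expected[2, 2]

    # sequential bounding: a pair whose IBS0 count already exceeds the
    # no-sharing expectation carries no evidence of IBD, so z0 > 1 maps to
    # (1, 0, 0) rather than letting residual noise leak into z1/z2
    if z0 > 1.0:
        z0, z1, z2 = 1.0, 0.0, 0.0
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    total = z.sum()
    if total <= 0:
        raise IbdDegeneracyError("all IBD-state estimates clamped to zero")
    z = z / total
    pi_hat = float(z[2] + z[1] / 2.0)
    return IBDEstimate(
        sample_a, sample_b, float(z[0]), float(z[1]), float(z[2]),
        pi_hat, n, low_confidence=n < min_sites,
    )


def classify_first_degree(
    estimate: IBDEstimate,
    low: float = FIRST_DEGREE_LOW,
    high: float = FIRST_DEGREE_HIGH,
) -> bool:
    """True iff ``low <= pi_hat <= high`` (putative parent-offspring window)."""
    if low > high:
        raise ValueError(f"low {low} exceeds high {high}")
    return low <= estimate.pi_hat <= high


def pairwise_ibd(
    matrix: GenotypeMatrix,
    pairs: Iterable[tuple[str, str]],
    freqs: np.ndarray,
    min_maf: float = 0.01,
    min_sites: int = 200,
    low: float = FIRST_DEGREE_LOW,
    high: float = FIRST_DEGREE_HIGH,
) -> pd.DataFrame:
    """IBD estimates + first-degree classification for a list of pairs."""
    rows = []
    for a, b in pairs:
        est = mom_ibd(
            matrix.calls_for(a), matrix.calls_for(b), freqs,
            sample_a=a, sample_b=b, min_maf=min_maf, min_sites=min_sites,
        )
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "z0": est.z0,
                "z1": est.z1,
                "z2": est.z2,
                "pi_hat": est.pi_hat,
                "n_sites": est.n_sites_used,
                "low_confidence": est.low_confidence,
                "first_degree": classify_first_degree(est, low, high),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_a", "sample_b", "z0", "z1", "z2", "pi_hat",
            "n_sites", "low_confidence", "first_degree",
        ],
    )


def write_ibd_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
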