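"""Mendelian presence-rule parentage assignment over a SNP panel.

An offspring of the focal father must carry one allele from him at every
locus; at a panel site where the focal father is heterozygous for a
private allele and every other candidate parent is homozygous reference,
a heterozygous offspring call can only come from the focal father.  A
sample is therefore classified a focal offspring when it is het at at
least ``min_het_sites`` panel sites (default 1).  Each private site
transmits with probability 1/2, so a k-site panel detects a true
offspring with probability 1 - 2**(-k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .amplicon import NO_CALL, GenotypeCall
from .genotypes import HET, MISSING, GenotypeMatrix, VariantSite
from .snp_select import Panel


@dataclass(frozen=True)
class ParentageCall:
    """Classification of one sample under the presence rule.

    ``is_focal_offspring`` is None for indeterminate samples (every
    panel site no_call), which are reported separately rather than
    counted as non-offspring.
    """

    sample: str
    n_het_panel_sites: int
    n_called_sites: int
    is_focal_offspring: bool | None
    min_het_sites: int

    @property
    def indeterminate(self) -> bool:
        return self.is_focal_offspring is None


def panel_calls_from_genotype_calls(
    calls: Iterable[GenotypeCall],
) -> dict[str, dict[tuple[str, int], int]]:
    """Regroup flat per-sample/site calls into sample -> site-key -> code."""
    out: dict[str, dict[tuple[str, int], int]] = {}
    for c in calls:
        out.setdefault(c.sample, {})[c.site.key] = c.call
    return out


def panel_calls_from_matrix(
    matrix: GenotypeMatrix, panel: Panel | Sequence[VariantSite]
) -> dict[str, dict[tuple[str, int], int]]:
    """Panel-site call map straight from a genotype matrix (missing -> no_call)."""
    sites = list(panel.sites) if isinstance(panel, Panel) else list(panel)
    cols = [matrix.site_index(s.key) for s in sites]
    out: dict[str, dict[tuple[str, int], int]] = {}
    for i, sample in enumerate(matrix.samples):
        out[sample] = {
            sites[k].key: (NO_CALL if matrix.calls[i, c] == MISSING else int(matrix.calls[i, c]))
            for k, c in enumerate(cols)
        }
    return out


def assign_parentage(
    panel_calls: Mapping[str, Mapping[tuple[str, int], int]],
    panel: Panel | Sequence[VariantSite],
    min_het_sites: int = 1,
) -> list[ParentageCall]:
    """Apply the presence rule to every sample.

    ``panel_calls`` maps sample -> (chrom, pos) -> genotype code
    (NO_CALL allowed).  no_call sites are excluded from both the het
    count and the called-site count; a sample with all panel sites
    no_call is flagged indeterminate.
    """
    if min_het_sites < 1:
        raise ValueError("min_het_sites must be >= 1")
    sites = list(panel.sites) if isinstance(panel, Panel) else list(panel)
    keys = [s.key for s in sites]
    out = []
    for sample, calls in panel_calls.items():
        observed = [calls.get(k, NO_CALL) for k in keys]
        called = [c for c in observed if c != NO_CALL]
        n_het = sum(1 for c in called if c == HET)
        verdict: bool | None
        if not called:
            verdict = None
        else:
            verdict = n_het >= min_het_sites
        out.append(ParentageCall(sample, n_het, len(called), verdict, min_het_sites))
    return out


def detection_power(
    panel_size: int,
    per_site_transmission: float = 0.5,
    false_negative_rate: float = 0.0,
    min_het_sites: int = 1,
) -> float:
    """P[Binomial(panel_size, p*(1-fnr)) >= min_het_sites].

    The probability that a true focal offspring shows at least
    ``min_het_sites`` heterozygous panel calls, with each private allele
    transmitted with probability ``per_site_transmission`` and detected
    with probability ``1 - false_negative_rate``.
    """
    for name, p in (
        ("per_site_transmission", per_site_transmission),
        ("false_negative_rate", false_negative_rate),
    ):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if panel_size < 0:
        raise ValueError("panel_size must be >= 0")
    if min_het_sites > panel_size:
        warnings.warn(
            f"min_het_sites {min_het_sites} exceeds panel_size {panel_size}: power is 0",
            stacklevel=2,
        )
        return 0.0
    if panel_size == 0:
        return 0.0
    p_eff = per_site_transmission * (1.0 - false_negative_rate)
    return float(stats.binom.sf(min_het_sites - 1, panel_size, p_eff))


def write_parentage_tsv(calls: Iterable[ParentageCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tn_called_sites\tn_het_panel_sites\tis_focal_offspring\tindeterminate\n")
        for c in calls:
            verdict = "" if c.is_focal_offspring is None else str(c.is_focal_offspring)
            fh.write(
                f"{c.sample}\t{c.n_called_sites}\t{c.n_het_panel_sites}\t"
                f"{verdict}\t{c.indeterminate}\n"
            )
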