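"""Screening a candidate-parent VCF for individual-specific SNPs.

An individual-specific SNP is heterozygous (0/1) in every sequencing
replicate of the target individual while being absent as a carried
allele from all other candidate parents.  Two screening modes are
offered:

``strict``
    non-target samples must be hom ref (0/0).  This is the default: a
    hom-alt non-target parent would transmit the alt allele to its own
    offspring and create false positives under the downstream presence
    rule.
``literal``
    non-target samples may be hom ref or hom alt (0/0 or 1/1), i.e. any
    homozygous state; retained because some published screens phrase the
    filter this way.

Missing calls in any sample disqualify a site (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .genotypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    VariantSite,
    chrom_sort_key,
    sorted_sites,
)
from . import io_utils

MODES = ("strict", "literal")
#: alias kept for the mode named after the published phrasing
MODE_ALIASES = {"paper_literal": "literal"}


class PanelInfeasibleError(ValueError):
    """Raised when no panel satisfying the constraints exists."""


@dataclass
class Panel:
    """A chromosome-distributed set of target-specific SNPs.

    Invariants: with ``per_chrom_limit == 1`` no two sites share a
    chromosome, and no site lies on an excluded chromosome.
    """

    sites: list[VariantSite]
    target_label: str = ""
    per_chrom_limit: int = 1
    excluded_chroms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.sites = list(self.sites)
        self.excluded_chroms = tuple(self.excluded_chroms)
        counts: dict[str, int] = {}
        for s in self.sites:
            if s.chrom in self.excluded_chroms:
                raise ValueError(f"panel site {s} lies on excluded chromosome {s.chrom}")
            counts[s.chrom] = counts.get(s.chrom, 0) + 1
        over = {c: n for c, n in counts.items() if n > self.per_chrom_limit}
        if over:
            raise ValueError(f"per-chromosome limit {self.per_chrom_limit} exceeded: {over}")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def chroms(self) -> list[str]:
        return sorted({s.chrom for s in self.sites}, key=chrom_sort_key)


def select_specific_sites(
    matrix: GenotypeMatrix,
    target_replicates: Sequence[str],
    mode: str = "strict",
) -> list[VariantSite]:
    """Return sites heterozygous in all target replicates and (per mode)
    absent from every non-target sample, sorted by (chrom, pos)."""
    mode = MODE_ALIASES.get(mode, mode)
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not target_replicates:
        raise ValueError("at least one target replicate is required")
    t_rows = [matrix.sample_index(s) for s in target_replicates]
    o_rows = [i for i in range(matrix.n_samples) if i not in set(t_rows)]

    calls = matrix.calls
    target_ok = (calls[t_rows] == HET).all(axis=0)
    others = calls[o_rows]
    if mode == "strict":
        others_ok = (others == HOM_REF).all(axis=0)
    else:
        others_ok = np.isin(others, (HOM_REF, HOM_ALT)).all(axis=0)
    no_missing = (calls != MISSING).all(axis=0)
    keep = target_ok & others_ok & no_missing
    return sorted_sites(s for s, k in zip(matrix.sites, keep) if k)


def build_panel(
    candidates: Sequence[VariantSite],
    panel_size: int,
    per_chrom_limit: int = 1,
    excluded_chroms: Sequence[str] = (),
    seed: int | None = None,
    randomize: bool = False,
    target_label: str = "",
) -> Panel:
    """Greedy chromosome-distributed panel from a candidate site list.

    Candidates are taken in (chrom, pos) order — deterministic
    tie-breaking — unless ``randomize`` shuffles them with ``seed``.
    Raises :class:`PanelInfeasibleError`, naming the deficit, when the
    per-chromosome limit and exclusions cannot yield ``panel_size`` sites.
    """
    if panel_size < 0:
        raise ValueError("panel_size must be >= 0")
    if panel_size == 0:
        return Panel([], target_label, per_chrom_limit, tuple(excluded_chroms))
    if not candidates:
        raise ValueError("candidate site list is empty")
    excluded = set(excluded_chroms)
    pool = [s for s in sorted_sites(candidates) if s.chrom not in excluded]
    capacity: dict[str, int] = {}
    for s in pool:
        capacity[s.chrom] = capacity.get(s.chrom, 0) + 1
    max_possible = sum(min(n, per_chrom_limit) for n in capacity.values())
    if max_possible < panel_size:
        raise PanelInfeasibleError(
            f"only {max_possible} sites selectable on {len(capacity)} eligible "
            f"chromosomes (limit {per_chrom_limit}/chromosome); "
            f"short by {panel_size - max_possible} of the requested {panel_size}"
        )
    if randomize:
        rng = np.random.default_rng(seed)
        pool = [pool[i] for i in rng.permutation(len(pool))]
    chosen: list[VariantSite] = []
    used: dict[str, int] = {}
    for s in pool:
        if used.get(s.chrom, 0) < per_chrom_limit:
            chosen.append(s)
            used[s.chrom] = used.get(s.chrom, 0) + 1
            if len(chosen) == panel_size:
                break
    return Panel(sorted_sites(chosen), target_label, per_chrom_limit, tuple(excluded_chroms))


# ---------------------------------------------------------------------------
# Panel serialization: BED-like TSV (chrom, pos, ref, alt) + YAML metadata
# ---------------------------------------------------------------------------

def write_panel(panel: Panel, tsv_path: str | Path, yaml_path: str | Path | None = None) -> None:
    io_utils.write_sites_tsv(panel.sites, tsv_path)
    if yaml_path is not None:
        meta = {
            "target_label": panel.target_label,
            "per_chrom_limit": panel.per_chrom_limit,
            "excluded_chroms": list(panel.excluded_chroms),
            "n_sites": len(panel),
        }
        Path(yaml_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_panel(tsv_path: str | Path, yaml_path: str | Path | None = None) -> Panel:
    sites = io_utils.read_sites_tsv(tsv_path)
    meta = {}
    if yaml_path is not None and Path(yaml_path).exists():
        meta = yaml.safe_load(Path(yaml_path).read_text()) or {}
    return Panel(
        sites,
        target_label=meta.get("target_label", ""),
        per_chrom_limit=meta.get("per_chrom_limit", 1),
        excluded_chroms=tuple(meta.get("excluded_chroms", ())),
    )
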