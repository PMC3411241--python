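"""Site-frequency and diversity statistics per taxon group and region class.

All statistics work on alternate-allele dosage with pairwise missing-data
exclusion. Accessions are treated as inbred sequence samples, so the sample
size n entering Watterson's harmonic correction is the accession count (one
consensus sequence per accession), configurable to 2n for outbred data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, MISSING


@dataclass
class DiversitySummary:
    group: str
    n_accessions: int
    s: int
    theta_w: float
    rate_coding: Optional[float] = None
    rate_noncoding: Optional[float] = None
    noncoding_coding_ratio: Optional[float] = None
    specific_count: Optional[int] = None
    shared_counts: dict = field(default_factory=dict)


def _site_column(genotypes: GenotypeMatrix, site, mask) -> np.ndarray:
    j = genotypes.site_index(site) if isinstance(site, str) else int(site)
    col = genotypes.calls[mask, j]
    return col[col != MISSING]


def minor_allele_frequency(genotypes: GenotypeMatrix, site, subset=None) -> float:
    """MAF at ``site`` within ``subset``: min(f, 1-f) of the alt-allele
    frequency f = dosage sum / (2 * non-missing count)."""
    mask = genotypes.accession_mask(subset)
    col = _site_column(genotypes, site, mask)
    if col.size == 0:
        raise ValueError(f"site {site!r}: all calls missing in subset")
    f = col.sum() / (2.0 * col.size)
    return float(min(f, 1.0 - f))


def site_mafs(genotypes: GenotypeMatrix, subset=None) -> np.ndarray:
    """Vector of per-site MAFs (NaN where every call is missing)."""
    mask = genotypes.accession_mask(subset)
    calls = genotypes.calls[mask]
    miss = calls == MISSING
    n = (~miss).sum(axis=0)
    total = np.where(miss, 0, calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, total / (2.0 * n), np.nan)
    return np.minimum(f, 1.0 - f)


def filter_by_maf(genotypes: GenotypeMatrix, threshold: float = 0.05,
                  subset=None) -> GenotypeMatrix:
    """Retain sites with MAF strictly greater than ``threshold`` in ``subset``.

    Strict inequality: a site at exactly the threshold is dropped. Idempotent.
    """
    if not 0.0 <= threshold < 0.5:
        raise ValueError("threshold must lie in [0, 0.5)")
    mafs = site_mafs(genotypes, subset)
    keep = np.flatnonzero(np.nan_to_num(mafs, nan=0.0) > threshold)
    return genotypes.subset_sites(keep)


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson correction for n sequences."""
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(genotypes: GenotypeMatrix, subset=None,
                    total_length: float = 1.0,
                    sequences_per_accession: int = 1):
    """Watterson's theta per site: S / (a_n * total_length).

    S counts sites polymorphic within the subset; n is the number of
    sequences (accession count for inbred panels; set
    ``sequences_per_accession=2`` for outbred data). Returns ``(theta, S)``.
    """
    mask = genotypes.accession_mask(subset)
    if mask.sum() < 2:
        raise ValueError("watterson_theta needs >= 2 accessions")
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    mafs = site_mafs(genotypes, mask)
    s = int(np.sum(np.nan_to_num(mafs, nan=0.0) > 0))
    n_seq = int(mask.sum()) * sequences_per_accession
    theta = s / (harmonic_number(n_seq) * total_length)
    return theta, s


def polymorphism_rates(genotypes: GenotypeMatrix, subset=None, *,
                       coding_length: float, noncoding_length: float):
    """Polymorphic sites per 1000 bp in coding vs noncoding regions.

    Sequenced lengths are explicit inputs (they are a property of the
    sequencing design, not the genotype calls). Returns a dict with
    ``rate_coding``, ``rate_noncoding`` and their ratio (None when the coding
    rate is zero or the coding length is zero).
    """
    mask = genotypes.accession_mask(subset)
    mafs = site_mafs(genotypes, mask)
    poly = np.nan_to_num(mafs, nan=0.0) > 0
    is_coding = np.array([s.region_class == "coding" for s in genotypes.sites])
    n_cod = int(np.sum(poly & is_coding))
    n_non = int(np.sum(poly & ~is_coding))
    rate_c = 1000.0 * n_cod / coding_length if coding_length > 0 else None
    rate_n = 1000.0 * n_non / noncoding_length if noncoding_length > 0 else None
    ratio = None
    if rate_c and rate_n is not None:
        ratio = rate_n / rate_c
    return {"rate_coding": rate_c, "rate_noncoding": rate_n,
            "noncoding_coding_ratio": ratio,
            "n_coding_polymorphic": n_cod, "n_noncoding_polymorphic": n_non}


def classify_shared_polymorphisms(genotypes: GenotypeMatrix,
                                  groups: Optional[Sequence[str]] = None):
    """Partition polymorphic sites by the set of groups they segregate in.

    A site belongs to category ``frozenset({A})`` if polymorphic (MAF > 0
    within group) only in A (group-specific), to ``frozenset({A, B})`` if in
    exactly those two, and so on. Categories are exhaustive and disjoint over
    the polymorphic-site set.
    """
    if groups is None:
        groups = sorted(set(genotypes.groups))
    if any(g not in groups for g in genotypes.groups):
        missing = sorted(set(genotypes.groups) - set(groups))
        raise ValueError(f"accessions with unlabeled groups: {missing}")
    per_group = {g: site_mafs(genotypes, genotypes.accession_mask(g)) > 0
                 for g in groups}
    counts: dict[frozenset, int] = {}
    site_sets = []
    for j in range(genotypes.n_sites):
        in_groups = frozenset(g for g in groups if per_group[g][j])
        site_sets.append(in_groups)
        if in_groups:
            counts[in_groups] = counts.get(in_groups, 0) + 1
    return counts, site_sets


def singleton_count(genotypes: GenotypeMatrix, subset=None) -> int:
    """Sites whose minor allele occurs on exactly one sequence copy within
    the subset (dosage-count 1 for an inbred panel means one heterozygote;
    a single homozygote carrier, count 2 on a selfed line, also counts as a
    singleton accession)."""
    mask = genotypes.accession_mask(subset)
    calls = genotypes.calls[mask]
    miss = calls == MISSING
    alt = np.where(miss, 0, calls)
    n = (~miss).sum(axis=0)
    total = alt.sum(axis=0)
    minor_is_alt = total <= n  # alt freq <= 0.5
    carriers_alt = (alt > 0).sum(axis=0)
    carriers_ref = ((alt < 2) & ~miss).sum(axis=0)
    carriers = np.where(minor_is_alt, carriers_alt, carriers_ref)
    poly = (total > 0) & (total < 2 * n)
    return int(np.sum(poly & (carriers == 1)))


def maf_spectrum(genotypes: GenotypeMatrix, subset=None,
                 bins: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
                 overall_prefilter: float = 0.05) -> pd.DataFrame:
    """Histogram of within-subset site MAFs.

    Sites failing the overall-sample MAF > ``overall_prefilter`` filter are
    discarded first (set it to None to skip); sites monomorphic within the
    subset are then excluded, and the remainder binned on (0, 0.5].
    """
    g = genotypes
    if overall_prefilter is not None:
        g = filter_by_maf(g, overall_prefilter, subset=None)
    mafs = site_mafs(g, subset)
    mafs = mafs[np.nan_to_num(mafs, nan=0.0) > 0]
    edges = np.asarray(bins, dtype=float)
    counts, _ = np.histogram(mafs, bins=edges)
    # np.histogram's bins are left-closed; MAF bins are (lo, hi] so move
    # boundary values up a bin (a MAF of exactly 0.1 belongs to (0, 0.1])
    for k in range(1, len(edges) - 1):
        on_edge = int(np.sum(np.isclose(mafs, edges[k])))
        counts[k] -= on_edge
        counts[k - 1] += on_edge
    return pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:], "count": counts,
    })


def diversity_summary(genotypes: GenotypeMatrix, group: str, *,
                      total_length: float = 1.0,
                      coding_length: Optional[float] = None,
                      noncoding_length: Optional[float] = None) -> DiversitySummary:
    mask = genotypes.accession_mask(group)
    theta, s = watterson_theta(genotypes, mask, total_length=total_length)
    summary = DiversitySummary(group=group, n_accessions=int(mask.sum()),
                               s=s, theta_w=theta)
    if coding_length and noncoding_length:
        rates = polymorphism_rates(genotypes, mask, coding_length=coding_length,
                                   noncoding_length=noncoding_length)
        summary.rate_coding = rates["rate_coding"]
        summary.rate_noncoding = rates["rate_noncoding"]
        summary.noncoding_coding_ratio = rates["noncoding_coding_ratio"]
    return summary
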