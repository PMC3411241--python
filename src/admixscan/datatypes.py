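"""Shared domain containers for the association-mapping pipeline.

Genotypes are biallelic sites coded as alternate-allele dosage (0/1/2) with an
explicit missing code; accessions carry a taxon group label (wild relative,
admixed cherry type, cultivated). Structure memberships (Q), kinship (K) and
phenotypes are thin validated wrappers over numpy/pandas objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

REGION_CLASSES = ("coding", "noncoding")
VARIANT_CLASSES = ("SNP", "indel")
GROUPS = ("esculentum", "cerasiforme", "pimpinellifolium", "other")
TRAITS = ("FW", "LCN", "SSC")


@dataclass(frozen=True)
class SiteAnnotation:
    """Per-site map and region metadata.

    ``genetic_pos`` is in centimorgans on a single reference map;
    ``physical_pos`` (optional) is 1-based bp on the chromosome pseudomolecule.
    """

    site_id: str
    chromosome: str
    genetic_pos: float
    region_class: str
    variant_class: str = "SNP"
    fragment_id: str = ""
    physical_pos: Optional[int] = None
    contig_id: Optional[str] = None
    ref: str = "A"
    alt: str = "T"

    def __post_init__(self) -> None:
        if self.genetic_pos < 0:
            raise ValueError(f"site {self.site_id}: genetic_pos must be >= 0")
        if self.physical_pos is not None and self.physical_pos <= 0:
            raise ValueError(f"site {self.site_id}: physical_pos must be positive")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(
                f"site {self.site_id}: region_class {self.region_class!r} "
                f"not in {REGION_CLASSES}"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"site {self.site_id}: variant_class {self.variant_class!r} "
                f"not in {VARIANT_CLASSES}"
            )


class GenotypeMatrix:
    """Accessions x sites matrix of alternate-allele dosages.

    Calls are integers in {0, 1, 2} plus :data:`MISSING` (-1). Heterozygotes
    are retained; every downstream operation states its own missing-data
    policy — nothing is imputed here.
    """

    def __init__(
        self,
        accessions: Sequence[str],
        groups: Sequence[str],
        sites: Sequence[SiteAnnotation],
        calls: np.ndarray,
    ) -> None:
        self.accessions = list(accessions)
        self.groups = list(groups)
        self.sites = list(sites)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.accessions), len(self.sites)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.sites)} sites"
            )
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {calls[i, j]} for accession "
                f"{self.accessions[i]!r} at site {self.sites[j].site_id!r}"
            )
        if len(self.groups) != len(self.accessions):
            raise ValueError("groups length does not match accessions")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accession ids")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids")
        self.calls = calls
        self._site_index = {sid: j for j, sid in enumerate(ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def site_index(self, site_id: str) -> int:
        return self._site_index[site_id]

    def dosage(self, dtype=float) -> np.ndarray:
        """Calls as float with missing mapped to NaN."""
        d = self.calls.astype(dtype)
        d[self.calls == MISSING] = np.nan
        return d

    # -- subsetting ----------------------------------------------------------
    def accession_mask(self, subset=None) -> np.ndarray:
        """Boolean mask from ``None`` (all), accession ids, group names or mask."""
        if subset is None:
            return np.ones(self.n_accessions, dtype=bool)
        arr = np.asarray(subset)
        if arr.dtype == bool:
            if arr.shape != (self.n_accessions,):
                raise ValueError("boolean subset has wrong length")
            return arr
        names = set(map(str, np.atleast_1d(arr)))
        if names <= set(self.groups):
            return np.array([g in names for g in self.groups])
        unknown = names - set(self.accessions)
        if unknown:
            raise KeyError(f"unknown accessions/groups: {sorted(unknown)}")
        return np.array([a in names for a in self.accessions])

    def subset_accessions(self, subset) -> "GenotypeMatrix":
        m = self.accession_mask(subset)
        return GenotypeMatrix(
            [a for a, k in zip(self.accessions, m) if k],
            [g for g, k in zip(self.groups, m) if k],
            self.sites,
            self.calls[m],
        )

    def subset_sites(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            self.accessions,
            self.groups,
            [self.sites[j] for j in idx],
            self.calls[:, idx],
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.accessions == other.accessions
            and self.groups == other.groups
            and self.sites == other.sites
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_accessions} accessions x {self.n_sites} sites)"


class PhenotypeTable:
    """Long-format phenotype records (accession, trait, value [, year, rep]).

    Raw multi-year records and per-accession adjusted means share this
    container; adjusted means simply lack year/rep columns.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"accession", "trait", "value"}
        if not required <= set(frame.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        frame = frame.copy()
        frame["value"] = pd.to_numeric(frame["value"], errors="raise")
        for trait, lower, strict in (("FW", 0.0, True), ("LCN", 1.0, False), ("SSC", 0.0, False)):
            vals = frame.loc[frame["trait"] == trait, "value"]
            bad = vals < lower if not strict else vals <= lower
            if bad.any():
                acc = frame.loc[bad[bad].index[0], "accession"]
                raise ValueError(f"{trait} value out of range for accession {acc!r}")
        keys = [c for c in ("accession", "trait", "year", "rep") if c in frame.columns]
        if frame.duplicated(subset=keys).any():
            dup = frame[frame.duplicated(subset=keys)].iloc[0]
            raise ValueError(f"duplicate phenotype record: {dup[keys].to_dict()}")
        self.frame = frame.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return sorted(self.frame["trait"].unique())

    def trait_values(self, trait: str) -> pd.DataFrame:
        return self.frame[self.frame["trait"] == trait].reset_index(drop=True)

    def adjusted_series(self, trait: str) -> pd.Series:
        """Per-accession value series (requires one record per accession)."""
        sub = self.trait_values(trait)
        if sub["accession"].duplicated().any():
            raise ValueError(
                f"trait {trait}: multiple records per accession; adjust means first"
            )
        return sub.set_index("accession")["value"]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class QMatrix:
    """Per-accession membership proportions in K ancestral pools."""

    accessions: list[str]
    proportions: np.ndarray  # n x K, rows sum to 1
    log_likelihood: Optional[float] = None
    source: str = "estimated"

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 2 or self.proportions.shape[0] != len(self.accessions):
            raise ValueError("proportions must be n_accessions x K")
        if ((self.proportions < -1e-12) | (self.proportions > 1 + 1e-12)).any():
            raise ValueError("membership proportions must lie in [0, 1]")
        if not np.allclose(self.proportions.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1 within 1e-8")

    @property
    def k(self) -> int:
        return self.proportions.shape[1]

    def covariates(self) -> np.ndarray:
        """K-1 membership columns (drop last) for use as fixed covariates."""
        return self.proportions[:, :-1]

    def reorder(self, accessions: Sequence[str]) -> "QMatrix":
        idx = [self.accessions.index(a) for a in accessions]
        return QMatrix(list(accessions), self.proportions[idx],
                       self.log_likelihood, self.source)


@dataclass
class KinshipMatrix:
    """Symmetric relatedness matrix, diagonal fixed at 2.0, entries >= 0."""

    accessions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accessions)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square over accessions")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        if not np.allclose(np.diag(self.values), 2.0):
            raise ValueError("kinship diagonal must equal 2.0")
        if (self.values < 0).any():
            raise ValueError("kinship entries must be >= 0")

    def reorder(self, accessions: Sequence[str]) -> "KinshipMatrix":
        idx = [self.accessions.index(a) for a in accessions]
        return KinshipMatrix(list(accessions), self.values[np.ix_(idx, idx)])


__all__ = [
    "MISSING",
    "REGION_CLASSES",
    "VARIANT_CLASSES",
    "GROUPS",
    "TRAITS",
    "SiteAnnotation",
    "GenotypeMatrix",
    "PhenotypeTable",
    "QMatrix",
    "KinshipMatrix",
]
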