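"""Pairwise linkage disequilibrium, permutation significance, decay-curve
fitting and recombination-hotspot scanning.

The r^2 estimator is the squared Pearson correlation of dosage vectors over
pairwise-complete accessions. On fully homozygous data this equals the
haplotype-frequency r^2 = D^2 / (p_A p_a p_B p_b) exactly (each selfed
accession reads as one haplotype carried twice); on heterozygous data it is a
genotypic approximation and is documented as such.

The decay of mean r^2 with inter-site distance x is modelled as

    y = a + b * exp(-c * x)

i.e. high LD (a + b) at zero distance decaying to the asymptote a. The
published form of this regression is typographically ambiguous between
exp(-c*x) and exp(-c/x); with non-negative amplitude only exp(-c*x)
decreases with distance and can reproduce a fit that falls from ~1 at short
range through ~0.3 at 1 cM toward ~0.1 beyond 10 cM, so this orientation is
adopted throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datatypes import GenotypeMatrix, MISSING


@dataclass
class LDRecord:
    site_a: str
    site_b: str
    r2: float
    d_cm: Optional[float] = None
    d_kb: Optional[float] = None
    perm_p: Optional[float] = None
    n_used: int = 0


def _pair_dosages(genotypes: GenotypeMatrix, site_a, site_b, subset):
    mask = genotypes.accession_mask(subset)
    ja = genotypes.site_index(site_a) if isinstance(site_a, str) else int(site_a)
    jb = genotypes.site_index(site_b) if isinstance(site_b, str) else int(site_b)
    a = genotypes.calls[mask, ja]
    b = genotypes.calls[mask, jb]
    ok = (a != MISSING) & (b != MISSING)
    return a[ok].astype(float), b[ok].astype(float), ja, jb


def _r2_from_dosage(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        raise ValueError("site monomorphic in the usable subset; r2 undefined")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def pairwise_r2(genotypes: GenotypeMatrix, site_a, site_b, subset=None) -> LDRecord:
    """LD between two sites as squared dosage correlation over
    pairwise-complete accessions (>= 4 required)."""
    a, b, ja, jb = _pair_dosages(genotypes, site_a, site_b, subset)
    if a.size < 4:
        raise ValueError("fewer than 4 pairwise-complete accessions")
    r2 = _r2_from_dosage(a, b)
    sa, sb = genotypes.sites[ja], genotypes.sites[jb]
    d_cm = abs(sa.genetic_pos - sb.genetic_pos)
    d_kb = None
    if sa.physical_pos is not None and sb.physical_pos is not None:
        d_kb = abs(sa.physical_pos - sb.physical_pos) / 1000.0
    return LDRecord(sa.site_id, sb.site_id, r2, d_cm=d_cm, d_kb=d_kb, n_used=a.size)


def permutation_pvalue(genotypes: GenotypeMatrix, site_a, site_b, subset=None,
                       n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation significance of r^2 with the add-one estimator:
    (1 + #{permuted r^2 >= observed}) / (n_perm + 1)."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a, b, _, _ = _pair_dosages(genotypes, site_a, site_b, subset)
    if a.size < 4:
        raise ValueError("fewer than 4 pairwise-complete accessions")
    observed = _r2_from_dosage(a, b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(a)
        if perm.var() == 0:
            continue
        if _r2_from_dosage(perm, b) >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def heterozygosity_index(genotypes: GenotypeMatrix, subset=None) -> np.ndarray:
    """Per-site expected heterozygosity 2 f (1 - f) of the alt frequency."""
    from .diversity import site_mafs

    maf = site_mafs(genotypes, subset)
    return 2.0 * maf * (1.0 - maf)


def representative_sites(genotypes: GenotypeMatrix, subset=None) -> list[int]:
    """One site per fragment: greatest heterozygosity index, leftmost on ties."""
    het = np.nan_to_num(heterozygosity_index(genotypes, subset), nan=-1.0)
    best: dict[str, int] = {}
    for j, site in enumerate(genotypes.sites):
        k = site.fragment_id or site.site_id
        if k not in best or het[j] > het[best[k]] + 1e-15:
            best[k] = j
    return sorted(best.values())


def ld_matrix(genotypes: GenotypeMatrix, sites: Optional[Sequence] = None,
              subset=None, mode: str = "all_polymorphisms",
              maf_threshold: Optional[float] = 0.05) -> pd.DataFrame:
    """All unordered pairwise r^2 records as a long-format table.

    ``mode='one_per_fragment'`` keeps one representative site per fragment
    (greatest heterozygosity index, leftmost on ties). Sites are MAF-filtered
    at ``maf_threshold`` (strict >) unless it is None. Pairs undefined after
    missing exclusion (monomorphic or < 4 complete) are dropped.
    """
    if mode not in ("all_polymorphisms", "one_per_fragment"):
        raise ValueError(f"unknown mode {mode!r}")
    g = genotypes
    if sites is not None:
        idx = [g.site_index(s) if isinstance(s, str) else int(s) for s in sites]
        g = g.subset_sites(idx)
    if maf_threshold is not None:
        from .diversity import filter_by_maf

        g = filter_by_maf(g, maf_threshold, subset=subset)
    if mode == "one_per_fragment":
        g = g.subset_sites(representative_sites(g, subset))
    mask = g.accession_mask(subset)
    calls = g.calls[mask]
    records = []
    for ja in range(g.n_sites):
        for jb in range(ja + 1, g.n_sites):
            a, b = calls[:, ja], calls[:, jb]
            ok = (a != MISSING) & (b != MISSING)
            if ok.sum() < 4:
                continue
            af, bf = a[ok].astype(float), b[ok].astype(float)
            if af.var() == 0 or bf.var() == 0:
                continue
            sa, sb = g.sites[ja], g.sites[jb]
            d_kb = np.nan
            if sa.physical_pos is not None and sb.physical_pos is not None:
                d_kb = abs(sa.physical_pos - sb.physical_pos) / 1000.0
            records.append(
                (sa.site_id, sb.site_id, _r2_from_dosage(af, bf),
                 abs(sa.genetic_pos - sb.genetic_pos), d_kb, int(ok.sum()))
            )
    return pd.DataFrame(records,
                        columns=["site_a", "site_b", "r2", "d_cm", "d_kb", "n_used"])


# ---------------------------------------------------------------------------
# decay model


class LDDecayModel:
    """Nonlinear regression of r^2 on inter-site distance,
    y = a + b * exp(-c * x).

    scikit-learn style estimator: ``fit(X, y)`` with X the distances
    (1d or (n, 1)), then ``predict(X)``. Fitted attributes ``a_``, ``b_``,
    ``c_``, ``residual_sse_``, ``n_pairs_``, ``converged_``.

    Parameters
    ----------
    distance_unit : 'cM' or 'kb', recorded for reporting only.
    n_starts : number of multi-start initializations for the decay scale c
        (the fit is non-convex in c); increasing it never worsens the SSE.
    """

    def __init__(self, distance_unit: str = "cM", n_starts: int = 8):
        self.distance_unit = distance_unit
        self.n_starts = n_starts

    def get_params(self, deep: bool = True) -> dict:
        return {"distance_unit": self.distance_unit, "n_starts": self.n_starts}

    def set_params(self, **params) -> "LDDecayModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _curve(x, a, b, c):
        return a + b * np.exp(-c * x)

    def fit(self, X, y) -> "LDDecayModel":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        finite = np.isfinite(x) & np.isfinite(y) & (x > 0)
        x, y = x[finite], y[finite]
        if x.size < 10:
            raise ValueError("need >= 10 records with finite positive distance")
        if np.ptp(x) == 0:
            raise ValueError("all distances equal; decay scale unidentifiable")
        bounds = ([0.0, 0.0, 1e-9], [1.0, 1.5, np.inf])
        scale0 = 1.0 / max(np.median(x), 1e-9)
        best = None
        for c0 in np.geomspace(scale0 / 30, scale0 * 30, self.n_starts):
            a0 = float(np.clip(np.percentile(y, 10), 0.0, 1.0))
            b0 = float(np.clip(np.percentile(y, 90) - a0, 1e-3, 1.5))
            try:
                popt, _ = curve_fit(self._curve, x, y, p0=[a0, b0, c0],
                                    bounds=bounds, maxfev=20000)
            except RuntimeError:
                continue
            sse = float(np.sum((self._curve(x, *popt) - y) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
        if best is None:
            self.converged_ = False
            self.a_, self.b_, self.c_ = np.nan, np.nan, np.nan
            self.residual_sse_ = np.nan
            self.n_pairs_ = int(x.size)
            return self
        self.residual_sse_, (self.a_, self.b_, self.c_) = best[0], tuple(best[1])
        self.n_pairs_ = int(x.size)
        self.converged_ = True
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).reshape(-1)
        if (x <= 0).any():
            raise ValueError("distance must be positive (model undefined at x <= 0)")
        return self._curve(x, self.a_, self.b_, self.c_)

    def distance_at(self, r2: float) -> float:
        """Distance at which the fitted curve crosses a given r^2 level
        (NaN when the level is outside (a, a+b))."""
        if not (self.a_ < r2 < self.a_ + self.b_):
            return float("nan")
        return float(-np.log((r2 - self.a_) / self.b_) / self.c_)


@dataclass
class DecayFit:
    a: float
    b: float
    c: float
    distance_unit: str
    residual_sse: float
    n_pairs: int
    converged: bool


def fit_ld_decay(records: pd.DataFrame, distance_unit: str = "cM") -> DecayFit:
    """Fit the decay model to an ``ld_matrix`` table. Pairs at distance zero
    (e.g. sites within one sequenced fragment) are excluded — the regression
    is on map distance and x = 0 carries no distance information."""
    col = {"cM": "d_cm", "kb": "d_kb"}[distance_unit]
    model = LDDecayModel(distance_unit=distance_unit)
    model.fit(records[col].to_numpy(), records["r2"].to_numpy())
    return DecayFit(model.a_, model.b_, model.c_, distance_unit,
                    model.residual_sse_, model.n_pairs_, model.converged_)


def predict_decay(fit: DecayFit, x) -> np.ndarray:
    """Evaluate a + b * exp(-c * x) at positive distances x."""
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("distance must be positive")
    return fit.a + fit.b * np.exp(-fit.c * x)


# ---------------------------------------------------------------------------
# hotspot scan


def hotspot_ratio_scan(annotations, threshold: Optional[float] = None) -> pd.DataFrame:
    """kb/cM ratio for consecutive markers ordered by map position.

    A low ratio flags a candidate recombination hotspot (much more genetic
    than physical distance). Intervals with zero cM spread are reported with
    an infinite ratio and flagged unbounded. Markers must carry both
    coordinates and be sorted by strictly increasing cM.
    """
    anns = [a for a in annotations]
    cms = [a.genetic_pos for a in anns]
    if any(b < a for a, b in zip(cms, cms[1:])):
        raise ValueError("annotations must be sorted by increasing genetic position")
    if any(a.physical_pos is None for a in anns):
        raise ValueError("every marker needs a physical position")
    rows = []
    for a, b in zip(anns, anns[1:]):
        d_cm = b.genetic_pos - a.genetic_pos
        d_kb = abs(b.physical_pos - a.physical_pos) / 1000.0
        if d_cm == 0:
            ratio, unbounded = np.inf, True
        else:
            ratio, unbounded = d_kb / d_cm, False
        rows.append({
            "marker_a": a.site_id, "marker_b": b.site_id,
            "d_kb": d_kb, "d_cm": d_cm, "kb_per_cm": ratio,
            "unbounded": unbounded,
            "candidate_hotspot": (threshold is not None and not unbounded
                                  and ratio < threshold),
        })
    return pd.DataFrame(rows)
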