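"""Marker-trait association under the naive GLM, structured Q model and the
K+Q mixed model, with BH-FDR correction, effect summaries and the P-value
calibration diagnostic.

The mixed model is y = X b + m a + u + e with Var(u) = K sg2 and
Var(e) = I se2 (X holds the intercept and K-1 structure covariates).
Variance components come from REML on the spectral decomposition of the
kinship matrix (single random effect); the marker is then tested by a
partial F statistic on data whitened by V^(-1/2), V = sg2 K + se2 I, with
residual degrees of freedom. Whitening by a matrix known up to scale means
that sg2 = 0 reduces the test exactly to the ordinary GLM F test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix, KinshipMatrix, PhenotypeTable, QMatrix
from .diversity import site_mafs
from .phenotypes import transform_trait

#: analysis-scale transform per trait (fruit weight and locule number are
#: log-transformed; soluble solids analyzed raw)
DEFAULT_TRANSFORMS = {"FW": "log", "LCN": "log", "SSC": "none"}


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# core test machinery


def _partial_f(y: np.ndarray, X: np.ndarray, m: np.ndarray):
    """Partial F test of marker m added to design X (possibly whitened).

    Returns (p, F, beta, df_resid) or None when the marker is collinear
    with the design.
    """
    Q, _ = np.linalg.qr(X)
    ey = y - Q @ (Q.T @ y)
    em = m - Q @ (Q.T @ m)
    smm = float(em @ em)
    if smm <= 1e-10 * max(float(m @ m), 1.0):
        return None
    beta = float(em @ ey) / smm
    rss_red = float(ey @ ey)
    rss_full = max(rss_red - beta * beta * smm, 0.0)
    df = y.size - X.shape[1] - 1
    if df <= 0:
        return None
    if rss_full <= 1e-14 * max(rss_red, 1e-300):
        # numerically perfect fit: report the floor rather than failing
        return np.finfo(float).tiny, np.inf, beta, df
    f = (rss_red - rss_full) / (rss_full / df)
    p = float(stats.f.sf(f, 1, df))
    return max(p, np.finfo(float).tiny), f, beta, df


def fit_marker_glm(y, marker, covariates: Optional[np.ndarray] = None):
    """Least-squares marker test: trait ~ intercept + covariates + marker.

    ``covariates`` are the K-1 structure membership columns for the Q model
    (or PCA axes), None for the naive GLM. Returns a dict with the partial-F
    P value, the homozygote-class effect (2x the dosage coefficient), and
    the marker partial R^2 = (RSS_reduced - RSS_full) / TSS.
    """
    y = np.asarray(y, float)
    m = np.asarray(marker, float)
    X = np.ones((y.size, 1))
    if covariates is not None and np.size(covariates):
        X = np.column_stack([X, np.asarray(covariates, float)])
    res = _partial_f(y, X, m)
    if res is None:
        return {"p_value": np.nan, "effect": np.nan, "r2_marker": np.nan,
                "f_stat": np.nan, "testable": False}
    p, f, beta, _ = res
    Q, _ = np.linalg.qr(X)
    ey = y - Q @ (Q.T @ y)
    em = m - Q @ (Q.T @ m)
    rss_red = float(ey @ ey)
    rss_full = rss_red - (float(em @ ey) ** 2) / float(em @ em)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = (rss_red - rss_full) / tss if tss > 0 else np.nan
    return {"p_value": p, "effect": 2.0 * beta, "r2_marker": r2,
            "f_stat": f, "testable": True}


def reml_variance_components(y, X, kinship, eig=None):
    """REML estimates (sg2, se2) for y = Xb + u + e, Var(u) = K sg2.

    Profiles the restricted likelihood over lambda = se2/sg2 on the spectral
    decomposition of K. Eigenvalues below zero (numerically non-PSD K after
    the diagonal/clamping adjustments) are clipped to zero with a warning.
    Returns (sg2, se2, (eigvals, eigvecs)).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    K = kinship.values if isinstance(kinship, KinshipMatrix) else np.asarray(kinship, float)
    if eig is None:
        S, U = np.linalg.eigh(K)
        if S.min() < -1e-8:
            warnings.warn("kinship not PSD; clipping negative eigenvalues to 0")
        S = np.clip(S, 0.0, None)
    else:
        S, U = eig
    yr = U.T @ y
    Xr = U.T @ X
    n, p = X.shape

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = 1.0 / (S + lam)
        Xw = Xr * w[:, None]
        xtx = Xr.T @ Xw
        try:
            beta = np.linalg.solve(xtx, Xw.T @ yr)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - Xr @ beta
        rss = float(np.sum(w * r * r))
        if rss <= 0:
            return np.inf
        sg2 = rss / (n - p)
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf
        return (n - p) * np.log(sg2) + float(np.sum(np.log(S + lam))) + logdet_xtx

    grid = np.linspace(-12.0, 12.0, 49)
    vals = [neg2_reml(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    opt = minimize_scalar(neg2_reml, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(opt.x))
    w = 1.0 / (S + lam)
    Xw = Xr * w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    r = yr - Xr @ beta
    sg2 = float(np.sum(w * r * r)) / (n - p)
    # boundary: an essentially unbounded lambda means sg2 -> 0
    if lam >= np.exp(11.5):
        se2 = sg2 * lam
        return 0.0, se2, (S, U)
    return sg2, sg2 * lam, (S, U)


def _whitener(S, U, sg2, se2):
    d = sg2 * S + se2
    if (d <= 0).any():
        d = np.maximum(d, 1e-10 * d.max())
    return (U * (1.0 / np.sqrt(d))[None, :]) @ U.T


def fit_marker_mlm(y, marker, q=None, kinship=None, method: str = "per_marker_reml",
                   covariates: Optional[np.ndarray] = None,
                   var_components: Optional[tuple] = None, eig=None):
    """Mixed-model marker test (K+Q).

    ``q`` may be a QMatrix (its K-1 membership columns become fixed
    covariates) or None; ``covariates`` appends extra fixed columns.
    ``var_components=(sg2, se2)`` fixes the variance components (the test
    then matches a generalized-least-squares oracle exactly); otherwise they
    are REML-estimated — once on the no-marker model under ``method='p3d'``,
    or under the marker-inclusive design for ``method='per_marker_reml'``.
    """
    y = np.asarray(y, float)
    m = np.asarray(marker, float)
    X = np.ones((y.size, 1))
    if q is not None:
        qcols = q.covariates() if isinstance(q, QMatrix) else np.asarray(q, float)
        if np.size(qcols):
            X = np.column_stack([X, qcols])
    if covariates is not None and np.size(covariates):
        X = np.column_stack([X, np.asarray(covariates, float)])
    K = kinship.values if isinstance(kinship, KinshipMatrix) else np.asarray(kinship, float)
    if eig is None:
        S, U = np.linalg.eigh(K)
        S = np.clip(S, 0.0, None)
    else:
        S, U = eig
    if var_components is not None:
        sg2, se2 = var_components
    elif method == "p3d":
        sg2, se2, _ = reml_variance_components(y, X, K, eig=(S, U))
    elif method == "per_marker_reml":
        sg2, se2, _ = reml_variance_components(y, np.column_stack([X, m]), K,
                                               eig=(S, U))
    else:
        raise ValueError(f"unknown method {method!r}")
    W = _whitener(S, U, sg2, se2)
    res = _partial_f(W @ y, W @ X, W @ m)
    if res is None:
        return {"p_value": np.nan, "effect": np.nan, "testable": False,
                "sigma_g2": sg2, "sigma_e2": se2}
    p, f, beta, _ = res
    return {"p_value": p, "effect": 2.0 * beta, "f_stat": f, "testable": True,
            "sigma_g2": sg2, "sigma_e2": se2}


def standardized_effect(y, dosage, reference_dosage: Optional[int] = None):
    """(mean of hom-alt class - mean of hom-ref class) / sd(trait), with the
    reference accession's homozygote class as baseline when given.

    Heterozygotes are excluded from the class means; both homozygote classes
    need >= 2 members, else NaN.
    """
    y = np.asarray(y, float)
    d = np.asarray(dosage, float)
    ok = np.isfinite(y) & np.isfinite(d)
    y, d = y[ok], d[ok]
    c0, c2 = y[d == 0], y[d == 2]
    if c0.size < 2 or c2.size < 2:
        return np.nan
    sd = y.std(ddof=1)
    if sd == 0:
        return np.nan
    eff = (c2.mean() - c0.mean()) / sd
    if reference_dosage == 2:
        eff = -eff
    return float(eff)


def _class_effect(raw_y, dosage, reference_dosage):
    """Raw-scale difference of homozygote class means, non-reference minus
    reference class."""
    y = np.asarray(raw_y, float)
    d = np.asarray(dosage, float)
    ok = np.isfinite(y) & np.isfinite(d)
    y, d = y[ok], d[ok]
    c0, c2 = y[d == 0], y[d == 2]
    if c0.size == 0 or c2.size == 0:
        return np.nan
    eff = c2.mean() - c0.mean()
    if reference_dosage == 2:
        eff = -eff
    return float(eff)


# ---------------------------------------------------------------------------
# scans


def run_scan(genotypes: GenotypeMatrix, phenotypes, trait: str,
             model: str = "KQ", q: Optional[QMatrix] = None,
             kinship: Optional[KinshipMatrix] = None,
             structure_source: str = "none",
             maf_threshold: float = 0.05,
             transform: Optional[str] = None,
             reference_accession: Optional[str] = None,
             mlm_method: str = "per_marker_reml",
             extra_covariate: Optional[pd.Series] = None,
             thresholds: tuple = (0.005, 0.05)) -> pd.DataFrame:
    """Scan every MAF-retained site for association with one trait.

    ``phenotypes`` is a PhenotypeTable of adjusted means (or a Series indexed
    by accession, already on the raw scale). The trait is transformed per
    ``transform`` (default: log for FW/LCN, none for SSC); allele effects are
    back-reported on the raw scale as homozygote class-mean differences,
    signed so the reference accession's allele class is the baseline.
    Missing marker calls are mean-imputed for the test statistic only
    (``n_used`` counts non-missing calls); markers with a single genotype
    class are skipped. BH adjustment is applied across the scan (one trait,
    one model = one family).
    """
    if model not in ("GLM", "Q", "KQ"):
        raise ValueError(f"unknown model {model!r}")
    if model in ("Q", "KQ") and q is None:
        raise ValueError(f"model {model} requires a Q matrix")
    if model == "KQ" and kinship is None:
        raise ValueError("model KQ requires a kinship matrix")
    if isinstance(phenotypes, PhenotypeTable):
        series = phenotypes.adjusted_series(trait)
    else:
        series = pd.Series(phenotypes)
    series = series.dropna()
    used = [a for a in genotypes.accessions if a in series.index]
    if len(used) < 0.5 * genotypes.n_accessions:
        raise ValueError(
            f"trait {trait}: phenotype missing for more than half the panel "
            f"({len(used)}/{genotypes.n_accessions} usable)"
        )
    g = genotypes.subset_accessions(used)
    raw_y = series.loc[used].to_numpy(float)
    if transform is None:
        transform = DEFAULT_TRANSFORMS.get(trait, "none")
    y = transform_trait(pd.Series(raw_y, index=used), transform).to_numpy()

    qcols = None
    if q is not None:
        qcols = q.reorder(used).covariates()
    extra = None
    if extra_covariate is not None:
        extra = extra_covariate.loc[used].to_numpy(float)[:, None]
    covs = None
    if qcols is not None or extra is not None:
        parts = [c for c in (qcols, extra) if c is not None]
        covs = np.column_stack(parts)
    k_used = kinship.reorder(used) if kinship is not None else None
    eig = None
    if k_used is not None:
        S, U = np.linalg.eigh(k_used.values)
        eig = (np.clip(S, 0.0, None), U)
    vc = None
    if model == "KQ" and mlm_method == "p3d":
        X0 = np.ones((len(used), 1))
        if covs is not None:
            X0 = np.column_stack([X0, covs])
        sg2, se2, _ = reml_variance_components(y, X0, k_used.values, eig=eig)
        vc = (sg2, se2)

    mafs = site_mafs(g)
    retained = np.flatnonzero(np.nan_to_num(mafs, nan=0.0) > maf_threshold)
    ref_idx = used.index(reference_accession) if reference_accession in used else None

    dose = g.dosage()
    col_mean = np.nanmean(np.where(np.isfinite(dose), dose, np.nan), axis=0)
    rows = []
    n_skipped = 0
    for j in retained:
        d = dose[:, j]
        obs = np.isfinite(d)
        d_filled = np.where(obs, d, col_mean[j])
        if np.unique(d_filled[obs]).size < 2:
            n_skipped += 1
            continue
        ref_dose = int(d[ref_idx]) if ref_idx is not None and obs[ref_idx] else None
        glm = fit_marker_glm(y, d_filled, covariates=qcols)
        if model == "GLM":
            fit = fit_marker_glm(y, d_filled, covariates=extra)
        elif model == "Q":
            fit = fit_marker_glm(y, d_filled, covariates=covs)
        else:
            fit = fit_marker_mlm(y, d_filled, q=qcols, kinship=k_used,
                                 method=mlm_method, covariates=extra,
                                 var_components=vc, eig=eig)
        if not fit["testable"] or not np.isfinite(fit["p_value"]):
            n_skipped += 1
            continue
        rows.append({
            "site_id": g.sites[j].site_id,
            "location_cm": g.sites[j].genetic_pos,
            "trait": trait,
            "model": model,
            "structure_source": structure_source,
            "p_value": fit["p_value"],
            "r2_marker": glm["r2_marker"],
            "effect": _class_effect(raw_y, d, ref_dose),
            "std_effect": standardized_effect(y, d, ref_dose),
            "maf": float(mafs[j]),
            "n_used": int(obs.sum()),
        })
    if n_skipped:
        warnings.warn(f"scan {trait}/{model}: skipped {n_skipped} degenerate markers")
    columns = ["site_id", "location_cm", "trait", "model", "structure_source",
               "p_value", "p_adjusted", "r2_marker", "effect", "std_effect",
               "maf", "n_used", "significant_a", "significant_b"]
    if not rows:
        warnings.warn(f"scan {trait}/{model}: no testable sites")
        return pd.DataFrame(columns=columns)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    out["significant_a"] = out["p_adjusted"] < thresholds[0]
    out["significant_b"] = out["p_adjusted"] < thresholds[1]
    return out[columns]


class AssociationScan:
    """Estimator wrapper around :func:`run_scan`.

    ``fit(genotypes, phenotypes)`` runs one scan per requested trait and
    stores the concatenated result table in ``results_``.
    """

    def __init__(self, model: str = "KQ", traits: Sequence[str] = ("FW", "LCN", "SSC"),
                 maf_threshold: float = 0.05, mlm_method: str = "per_marker_reml",
                 structure_source: str = "none",
                 reference_accession: Optional[str] = None,
                 thresholds: tuple = (0.005, 0.05)):
        self.model = model
        self.traits = tuple(traits)
        self.maf_threshold = maf_threshold
        self.mlm_method = mlm_method
        self.structure_source = structure_source
        self.reference_accession = reference_accession
        self.thresholds = thresholds

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "traits": self.traits,
                "maf_threshold": self.maf_threshold,
                "mlm_method": self.mlm_method,
                "structure_source": self.structure_source,
                "reference_accession": self.reference_accession,
                "thresholds": self.thresholds}

    def set_params(self, **params) -> "AssociationScan":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, genotypes, phenotypes, q=None, kinship=None) -> "AssociationScan":
        tables = []
        for trait in self.traits:
            tables.append(run_scan(
                genotypes, phenotypes, trait, model=self.model, q=q,
                kinship=kinship, structure_source=self.structure_source,
                maf_threshold=self.maf_threshold, mlm_method=self.mlm_method,
                reference_accession=self.reference_accession,
                thresholds=self.thresholds,
            ))
        self.results_ = pd.concat(tables, ignore_index=True)
        return self


# ---------------------------------------------------------------------------
# calibration diagnostic


@dataclass
class CalibrationDiagnostic:
    model: str
    grid: np.ndarray
    ecdf: np.ndarray
    max_deviation: float


def pvalue_cdf_diagnostic(results: dict[str, Sequence[float]],
                          n_grid: int = 101) -> list[CalibrationDiagnostic]:
    """Empirical CDF of raw P values per model against the uniform diagonal.

    A well-calibrated null scan tracks the diagonal; structure confounding
    pushes the ECDF above it. Models are returned ranked by the KS-type max
    absolute deviation (smaller = better calibrated).
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    out = []
    for model, pvals in results.items():
        p = np.sort(np.asarray(pvals, dtype=float))
        ecdf = np.searchsorted(p, grid, side="right") / max(p.size, 1)
        dev = float(np.max(np.abs(ecdf - grid)))
        out.append(CalibrationDiagnostic(model, grid, ecdf, dev))
    out.sort(key=lambda d: d.max_deviation)
    return out
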