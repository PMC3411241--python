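"""Population structure and relatedness: ML admixture estimation, Evanno's
delta-K model-order choice, admixed-accession classification, Ritland
marker-based kinship, and genotype PCA.

The admixture estimator is a deterministic-given-seed maximum-likelihood
(block-relaxation EM) fit of the standard admixture model — each of an
individual's 2L allele copies drawn from pool k with probability q_ik, pool
allele frequencies p_kl — the same model family as Bayesian MCMC structure
software, whose run-to-run spread is emulated here by independent random
restarts. Externally computed Q matrices can be imported through
:func:`admixscan.io.read_qmatrix` wherever a QMatrix is accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, KinshipMatrix, QMatrix

_EPS = 1e-9


class AdmixtureModel:
    """EM estimator of ancestry proportions Q and pool frequencies P.

    scikit-learn style: ``fit(G)`` with G a GenotypeMatrix or an (n, L)
    dosage array (NaN = missing); ``fit_transform`` returns the Q rows.
    Fitted attributes: ``q_`` (n, K), ``p_`` (K, L), ``log_likelihood_``,
    ``n_iter_``, ``converged_``.

    The complete-data log-likelihood increases monotonically every
    iteration; Q rows sum to 1 at every iterate.
    """

    def __init__(self, n_components: int = 2, max_iter: int = 500,
                 tol: float = 1e-6, seed: int = 0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "max_iter": self.max_iter,
                "tol": self.tol, "seed": self.seed}

    def set_params(self, **params) -> "AdmixtureModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _as_dosage(G):
        if isinstance(G, GenotypeMatrix):
            return G.dosage(), list(G.accessions)
        arr = np.asarray(G, dtype=float)
        return arr, [f"ind{i}" for i in range(arr.shape[0])]

    def _loglik(self, g, w, q, p):
        pi = np.clip(q @ p, _EPS, 1.0 - _EPS)
        return float(np.sum(w * (g * np.log(pi) + (2.0 - g) * np.log1p(-pi))))

    def fit(self, G, y=None) -> "AdmixtureModel":
        g, accessions = self._as_dosage(G)
        w = np.isfinite(g).astype(float)
        g = np.nan_to_num(g, nan=0.0)
        n, L = g.shape
        K = self.n_components
        if K < 1:
            raise ValueError("n_components must be >= 1")
        if K > n:
            raise ValueError("n_components exceeds number of accessions")
        freqs = g.sum(axis=0) / np.maximum(2.0 * w.sum(axis=0), _EPS)
        if not ((freqs > 0) & (freqs < 1)).any():
            raise ValueError("no polymorphic sites; admixture model undefined")
        rng = np.random.default_rng(self.seed)
        q = rng.dirichlet(np.ones(K), size=n)
        p = np.clip(freqs[None, :] + rng.uniform(-0.1, 0.1, size=(K, L)),
                    0.01, 0.99)
        gw = g * w
        g2w = (2.0 - g) * w
        ll_prev = -np.inf
        n_iter = 0
        self.converged_ = False
        self.loglik_path_: list[float] = []
        for n_iter in range(1, self.max_iter + 1):
            pi = np.clip(q @ p, _EPS, 1.0 - _EPS)
            A = gw / pi
            B = g2w / (1.0 - pi)
            # EM updates for q and p (block relaxation on the complete-data
            # expectations of allele-copy pool assignments)
            q_new = q * (A @ p.T + B @ (1.0 - p).T)
            denom = 2.0 * w.sum(axis=1, keepdims=True)
            q_new = q_new / np.maximum(denom, _EPS)
            q_new = q_new / q_new.sum(axis=1, keepdims=True)
            num = p * (q.T @ A)
            den = (1.0 - p) * (q.T @ B)
            p_new = num / np.maximum(num + den, _EPS)
            p_new = np.clip(p_new, _EPS, 1.0 - _EPS)
            q, p = q_new, p_new
            ll = self._loglik(g, w, q, p)
            self.loglik_path_.append(ll)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= self.tol * abs(ll_prev):
                ll_prev = ll
                self.converged_ = True
                break
            ll_prev = ll
        self.q_ = q
        self.p_ = p
        self.log_likelihood_ = ll_prev
        self.n_iter_ = n_iter
        self.accessions_ = accessions
        return self

    def fit_transform(self, G, y=None) -> np.ndarray:
        return self.fit(G).q_

    def transform(self, G=None) -> np.ndarray:
        return self.q_

    def to_qmatrix(self) -> QMatrix:
        return QMatrix(self.accessions_, self.q_,
                       log_likelihood=self.log_likelihood_, source="estimated")


def estimate_admixture(genotypes, K: int, seed: int = 0, max_iter: int = 500,
                       tol: float = 1e-6) -> QMatrix:
    """Thin wrapper over :class:`AdmixtureModel` returning a QMatrix."""
    model = AdmixtureModel(n_components=K, max_iter=max_iter, tol=tol, seed=seed)
    model.fit(genotypes)
    return model.to_qmatrix()


def structure_runs(genotypes, k_values: Sequence[int], n_replicates: int = 3,
                   seed: int = 0, **kwargs) -> dict[int, list[float]]:
    """Replicate log-likelihoods per K from independently seeded EM restarts
    (the spread across local optima stands in for MCMC run-to-run variance)."""
    runs: dict[int, list[float]] = {}
    for k in k_values:
        runs[k] = []
        for rep in range(n_replicates):
            model = AdmixtureModel(n_components=k, seed=seed + 1000 * k + rep,
                                   **kwargs)
            model.fit(genotypes)
            runs[k].append(model.log_likelihood_)
    return runs


def evanno_delta_k(runs: dict[int, list[float]]):
    """Evanno's delta-K from replicate log-likelihoods per K.

    delta K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K));
    endpoints are undefined, K values must be contiguous, and a K with zero
    replicate variance is skipped with a warning. Returns (table, best_k).
    """
    ks = sorted(runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need a contiguous K range of length >= 3")
    if any(len(runs[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicates per K")
    means = {k: float(np.mean(runs[k])) for k in ks}
    sds = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks[1:-1]:
        second = abs(means[k + 1] - 2.0 * means[k] + means[k - 1])
        if sds[k] == 0.0:
            warnings.warn(f"K={k}: zero replicate variance; delta K undefined")
            dk = np.nan
        else:
            dk = second / sds[k]
        rows.append({"K": k, "mean_logL": means[k], "sd_logL": sds[k],
                     "delta_k": dk})
    table = pd.DataFrame(rows)
    if table["delta_k"].notna().any():
        best_k = int(table.loc[table["delta_k"].idxmax(), "K"])
    else:
        best_k = None
    return table, best_k


def classify_admixed(q: QMatrix, threshold: float = 0.8) -> list[str]:
    """Label each accession ``group_k`` when its largest membership exceeds
    the threshold, else ``admixed``."""
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    labels = []
    for row in q.proportions:
        k = int(np.argmax(row))
        labels.append(f"group_{k + 1}" if row[k] > threshold else "admixed")
    return labels


# ---------------------------------------------------------------------------
# kinship


class RitlandKinship:
    """Marker-based Ritland (1996) kinship with the mixed-model adjustments:
    negative estimates clamped to 0 and the diagonal overwritten to 2.0.

    Per biallelic locus l with panel alt frequency p (computed from the
    marker panel itself) and individual allelic proportions x_i = dosage/2:

        theta_ij(l) = x_i x_j / p + (1 - x_i)(1 - x_j) / (1 - p) - 1

    (the m-allele Ritland estimator sum_a x_ia x_ja / p_a - 1 over m - 1,
    specialized to m = 2). The multilocus estimate averages over loci with
    both calls present, weighting each locus by m - 1 = 1; monomorphic
    markers are skipped with a warning.
    """

    def __init__(self, clamp_negative: bool = True, diagonal: float = 2.0):
        self.clamp_negative = clamp_negative
        self.diagonal = diagonal

    def get_params(self, deep: bool = True) -> dict:
        return {"clamp_negative": self.clamp_negative, "diagonal": self.diagonal}

    def set_params(self, **params) -> "RitlandKinship":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, G, y=None) -> "RitlandKinship":
        if isinstance(G, GenotypeMatrix):
            dose, accessions = G.dosage(), list(G.accessions)
        else:
            dose = np.asarray(G, dtype=float)
            accessions = [f"ind{i}" for i in range(dose.shape[0])]
        n, L = dose.shape
        if L < 2:
            raise ValueError("need >= 2 markers")
        obs = np.isfinite(dose)
        counts = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(dose, axis=0) / (2.0 * np.maximum(counts, 1))
        poly = (p > 0) & (p < 1) & (counts >= 2)
        n_skipped = int(L - poly.sum())
        if n_skipped:
            warnings.warn(f"skipping {n_skipped} monomorphic/unusable markers")
        if not poly.any():
            raise ValueError("all markers monomorphic; kinship undefined")
        x = dose[:, poly] / 2.0
        p = p[poly]
        obs = obs[:, poly]
        x0 = np.nan_to_num(x, nan=0.0)
        # per-pair average over loci observed in both individuals
        term_alt = (x0 / p) @ x0.T
        term_ref = ((1.0 - x0) * obs / (1.0 - p)) @ ((1.0 - x0) * obs).T
        shared = obs.astype(float) @ obs.astype(float).T
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = (term_alt + term_ref) / np.maximum(shared, 1.0) - 1.0
        theta[shared == 0] = 0.0
        theta = (theta + theta.T) / 2.0
        if self.clamp_negative:
            theta = np.maximum(theta, 0.0)
        np.fill_diagonal(theta, self.diagonal)
        self.kinship_ = KinshipMatrix(accessions, theta)
        self.n_markers_used_ = int(poly.sum())
        return self

    def fit_transform(self, G, y=None) -> np.ndarray:
        return self.fit(G).kinship_.values


def ritland_kinship(markers, subset=None) -> KinshipMatrix:
    """Thin wrapper over :class:`RitlandKinship`."""
    if isinstance(markers, GenotypeMatrix) and subset is not None:
        markers = markers.subset_accessions(subset)
    return RitlandKinship().fit(markers).kinship_


# ---------------------------------------------------------------------------
# PCA


class GenotypePCA:
    """Principal components of the centered dosage matrix.

    Missing calls are mean-imputed per site (standard for genotype PCA);
    axes are ordered by decreasing variance with a deterministic sign
    convention (the largest-magnitude site loading on each axis is positive).
    """

    def __init__(self, n_components: int = 4, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "scale": self.scale}

    def set_params(self, **params) -> "GenotypePCA":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, G, y=None) -> "GenotypePCA":
        if isinstance(G, GenotypeMatrix):
            dose = G.dosage()
        else:
            dose = np.asarray(G, dtype=float)
        col_mean = np.nanmean(dose, axis=0)
        dose = np.where(np.isfinite(dose), dose, col_mean[None, :])
        centered = dose - col_mean[None, :]
        if self.scale:
            p = col_mean / 2.0
            sd = np.sqrt(np.maximum(p * (1 - p), _EPS))
            centered = centered / sd[None, :]
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
        k = min(self.n_components, rank)
        if k < self.n_components:
            warnings.warn(
                f"requested {self.n_components} axes but rank is {rank}; truncating"
            )
        for j in range(k):
            lead = np.argmax(np.abs(vt[j]))
            if vt[j, lead] < 0:
                vt[j] *= -1
                u[:, j] *= -1
        n = centered.shape[0]
        total_var = float(np.sum(centered**2)) / n
        self.coords_ = u[:, :k] * s[:k]
        self.components_ = vt[:k]
        self.explained_variance_ratio_ = (s[:k] ** 2 / n) / total_var
        return self

    def fit_transform(self, G, y=None) -> np.ndarray:
        return self.fit(G).coords_


def pca_axes(genotypes, n_axes: int = 4):
    """Accession coordinates on the leading axes and variance fractions."""
    model = GenotypePCA(n_components=n_axes).fit(genotypes)
    return model.coords_, model.explained_variance_ratio_
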