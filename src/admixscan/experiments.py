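"""Self-contained benchmark experiments exercising the pipeline end to end.

Each routine simulates its own inputs from a seed, runs the relevant part of
the package, and returns the measured quantity. They back both the property
test-suite and the reproduction script, so every reported number is
recomputed from scratch at run time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .association import (
    bh_adjust,
    fit_marker_glm,
    fit_marker_mlm,
    reml_variance_components,
    run_scan,
)
from .datatypes import GenotypeMatrix
from .diversity import filter_by_maf, watterson_theta
from .ld import LDDecayModel, ld_matrix, fit_ld_decay
from .phenotypes import adjusted_means
from .simulate import make_fixture, preset_config, simulate_panel
from .structure import (
    estimate_admixture,
    evanno_delta_k,
    ritland_kinship,
    structure_runs,
)

TOTAL_SEQUENCED_BP = 44223.0  # sequenced length behind the per-site theta scale


def _sub_seed(seed: int, salt: int) -> int:
    return (seed * 1_000_003 + salt) % (2**31 - 1)


# ---------------------------------------------------------------------------
# LD


def decay_parameter_recovery(seed: int, n_pairs: int = 500,
                             truth=(0.10, 0.80, 2.0), noise_sd: float = 0.05):
    """Fit the decay curve to data generated exactly from it plus Gaussian
    noise; returns fitted and true (a, b, c)."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    a, b, c = truth
    x = rng.uniform(0.02, 10.0, n_pairs)
    y = a + b * np.exp(-c * x) + rng.normal(0.0, noise_sd, n_pairs)
    model = LDDecayModel().fit(x, y)
    return {"a": model.a_, "b": model.b_, "c": model.c_, "truth": truth,
            "n": n_pairs}


def r2_oracle_max_deviation(seed: int, n_datasets: int = 1000) -> dict:
    """Max |dosage-correlation r^2 - haplotype-count r^2| over random fully
    homozygous two-site datasets (the two must agree identically)."""
    rng = np.random.default_rng(_sub_seed(seed, 2))
    worst = 0.0
    done = 0
    while done < n_datasets:
        n = int(rng.integers(6, 60))
        ha = (rng.random(n) < rng.uniform(0.1, 0.9)).astype(float)
        hb = (rng.random(n) < rng.uniform(0.1, 0.9)).astype(float)
        if ha.var() == 0 or hb.var() == 0:
            continue
        done += 1
        # dosage correlation on 2*h
        da, db = 2 * ha, 2 * hb
        r2_dose = (np.cov(da, db, bias=True)[0, 1] ** 2) / (da.var() * db.var())
        pa, pb = ha.mean(), hb.mean()
        d = (ha * hb).mean() - pa * pb
        r2_hap = d * d / (pa * (1 - pa) * pb * (1 - pb))
        worst = max(worst, abs(r2_dose - r2_hap))
    return {"max_abs_diff": worst, "n": n_datasets}


def ld_decay_curve_on_panel(seed: int, n_seeds: int = 5) -> dict:
    """Fit the decay curve on simulated panels (admixed subset) and report
    the fitted r^2 at 1 cM and the distance where the curve crosses 0.3."""
    at1, cross = [], []
    for k in range(n_seeds):
        out = simulate_panel(preset_config("paper_like", _sub_seed(seed, 30 + k)))
        pairs = ld_matrix(out.genotypes, subset="cerasiforme", maf_threshold=0.05)
        fit = fit_ld_decay(pairs[pairs["d_cm"] > 0], "cM")
        at1.append(fit.a + fit.b * np.exp(-fit.c))
        if fit.a < 0.3 < fit.a + fit.b:
            cross.append(-np.log((0.3 - fit.a) / fit.b) / fit.c)
    return {"r2_at_1cm": float(np.mean(at1)),
            "cross_0.3_cm": float(np.mean(cross)) if cross else float("nan"),
            "n": n_seeds}


# ---------------------------------------------------------------------------
# mixed model


def _random_mlm_instance(rng, n=50):
    A = rng.standard_normal((n, n // 2))
    K = A @ A.T / (n // 2) + 0.05 * np.eye(n)
    y = rng.standard_normal(n)
    m = 2.0 * (rng.random(n) < 0.5)
    q = rng.standard_normal((n, 1))
    return y, m, q, K


def _gls_oracle_p(y, m, q, K, sg2, se2):
    from scipy import stats

    n = y.size
    V = sg2 * K + se2 * np.eye(n)
    Wi = np.linalg.inv(np.linalg.cholesky(V))
    X = np.column_stack([np.ones(n), q])
    yw, Xw, mw = Wi @ y, Wi @ X, Wi @ m
    Q, _ = np.linalg.qr(Xw)
    ey = yw - Q @ (Q.T @ yw)
    em = mw - Q @ (Q.T @ mw)
    beta = em @ ey / (em @ em)
    rss_red = ey @ ey
    rss_full = rss_red - beta**2 * (em @ em)
    df = n - X.shape[1] - 1
    f = (rss_red - rss_full) / (rss_full / df)
    return float(stats.f.sf(f, 1, df))


def mlm_oracle_max_deviation(seed: int, n_instances: int = 100) -> dict:
    """Max |MLM P - GLS oracle P| with fixed variance components, and max
    |MLM P - GLM P| at sg2 = 0, over random instances."""
    rng = np.random.default_rng(_sub_seed(seed, 3))
    worst_gls = worst_glm = 0.0
    for _ in range(n_instances):
        y, m, q, K = _random_mlm_instance(rng)
        sg2, se2 = rng.uniform(0.2, 2.0), rng.uniform(0.2, 2.0)
        p_mlm = fit_marker_mlm(y, m, q=q, kinship=K,
                               var_components=(sg2, se2))["p_value"]
        worst_gls = max(worst_gls, abs(p_mlm - _gls_oracle_p(y, m, q, K, sg2, se2)))
        p_zero = fit_marker_mlm(y, m, q=q, kinship=K,
                                var_components=(0.0, se2))["p_value"]
        p_glm = fit_marker_glm(y, m, covariates=q)["p_value"]
        worst_glm = max(worst_glm, abs(p_zero - p_glm))
    return {"max_gls_diff": worst_gls, "max_glm_diff": worst_glm,
            "n": n_instances}


def structured_null_type1(seed: int, n_reps: int = 200, n: int = 90,
                          n_markers: int = 300, shift_sd: float = 1.0,
                          fst: float = 0.3, alpha: float = 0.05) -> dict:
    """Empirical type-I error of the naive GLM and the K+Q mixed model on a
    structure-confounded null: two pools whose trait means differ by
    ``shift_sd`` residual standard deviations, no marker effects."""
    glm_rates, kq_rates = [], []
    half = n // 2
    for rep in range(n_reps):
        rng = np.random.default_rng(_sub_seed(seed, 40_000 + rep))
        pool = np.repeat([0, 1], [half, n - half])
        p = rng.uniform(0.05, 0.95, n_markers)
        sh = (1 - fst) / fst
        pf = np.stack([rng.beta(p * sh, (1 - p) * sh) for _ in range(2)])
        G = 2.0 * (rng.random((n, n_markers)) < pf[pool])
        y = shift_sd * pool + rng.standard_normal(n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kin = ritland_kinship(G)
        S, U = np.linalg.eigh(kin.values)
        eig = (np.clip(S, 0.0, None), U)
        qcov = pool.astype(float)[:, None]
        X0 = np.column_stack([np.ones(n), qcov])
        sg2, se2, _ = reml_variance_components(y, X0, kin.values, eig=eig)
        n_glm = n_kq = n_tested = 0
        for j in range(n_markers):
            m = G[:, j]
            if m.var() == 0:
                continue
            n_tested += 1
            if fit_marker_glm(y, m)["p_value"] < alpha:
                n_glm += 1
            p_kq = fit_marker_mlm(y, m, q=qcov, kinship=kin,
                                  var_components=(sg2, se2), eig=eig)["p_value"]
            if p_kq < alpha:
                n_kq += 1
        glm_rates.append(n_glm / n_tested)
        kq_rates.append(n_kq / n_tested)
    return {"glm_type1": float(np.mean(glm_rates)),
            "kq_type1": float(np.mean(kq_rates)), "n": n_reps}


def qtl_power(seed: int, n_sims: int = 100, adjusted_threshold: float = 0.005):
    """Fraction of simulated panels in which the planted large-effect
    locule-number QTL is detected at BH-adjusted P below the threshold under
    the K+Q scan (and fraction where it is the top hit)."""
    detected = top = 0
    r2s = []
    for k in range(n_sims):
        s = _sub_seed(seed, 50_000 + k)
        out = make_fixture("paper_like", s)
        g = out.genotypes
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gf = filter_by_maf(g, 0.05)
            q = estimate_admixture(gf, 2, seed=_sub_seed(s, 7))
            kin = ritland_kinship(gf)
            means = adjusted_means(out.phenotypes, "LCN")
            tab = run_scan(g, means, "LCN", model="KQ", q=q, kinship=kin,
                           mlm_method="p3d")
        qtl_id = out.truth["traits"]["LCN"]["qtl"][0]["site_id"]
        r2s.append(out.truth["traits"]["LCN"]["qtl"][0]["realized_r2"])
        row = tab[tab["site_id"] == qtl_id]
        if not row.empty and row["p_adjusted"].iloc[0] < adjusted_threshold:
            detected += 1
        if len(tab) and tab.loc[tab["p_value"].idxmin(), "site_id"] == qtl_id:
            top += 1
    return {"power": detected / n_sims, "top_hit_rate": top / n_sims,
            "mean_qtl_r2": float(np.mean(r2s)), "n": n_sims}


# ---------------------------------------------------------------------------
# structure


def evanno_k2_fraction(seed: int, n_meta: int = 20, n_per_pool: int = 45,
                       n_markers: int = 200, fst: float = 0.3) -> dict:
    """Fraction of two-pool simulations in which Evanno's delta-K picks
    K = 2 from EM replicate log-likelihoods."""
    good = 0
    for meta in range(n_meta):
        rng = np.random.default_rng(_sub_seed(seed, 60_000 + meta))
        p = rng.uniform(0.05, 0.95, n_markers)
        sh = (1 - fst) / fst
        pf = np.stack([rng.beta(p * sh, (1 - p) * sh) for _ in range(2)])
        pool = np.repeat([0, 1], n_per_pool)
        G = 2.0 * (rng.random((2 * n_per_pool, n_markers)) < pf[pool])
        runs = structure_runs(G, [1, 2, 3, 4], n_replicates=2,
                              seed=_sub_seed(seed, 61_000 + meta))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, best = evanno_delta_k(runs)
        good += best == 2
    return {"fraction_k2": good / n_meta, "n": n_meta}


# ---------------------------------------------------------------------------
# diversity


def watterson_neutral_check(seed: int, n_reps: int = 200, n_samples: int = 30,
                            seq_length: float = 50_000.0, ne: float = 5_000.0,
                            mu: float = 2.5e-8) -> dict:
    """Mean Watterson estimate against the configured scaled mutation rate
    of a neutral coalescent simulation (haploid samples: theta = 2 Ne mu)."""
    import msprime

    theta_true = 2.0 * ne * mu
    base = _sub_seed(seed, 70_000)
    estimates = []
    for rep in range(n_reps):
        rs = (base + rep) % (2**31 - 2) + 1
        ts = msprime.sim_ancestry(samples=n_samples, ploidy=1,
                                  population_size=ne,
                                  sequence_length=seq_length,
                                  recombination_rate=1e-8, random_seed=rs)
        mts = msprime.sim_mutations(ts, rate=mu, random_seed=rs,
                                    model=msprime.BinaryMutationModel())
        hap = mts.genotype_matrix().T  # samples x sites, 0/1
        calls = (2 * np.minimum(hap, 1)).astype(np.int8)
        g = _matrix_from_array(calls)
        theta, _ = watterson_theta(g, total_length=seq_length)
        estimates.append(theta)
    return {"theta_true": theta_true, "theta_mean": float(np.mean(estimates)),
            "relative_error": float(abs(np.mean(estimates) - theta_true) / theta_true),
            "n": n_reps}


def _matrix_from_array(calls: np.ndarray) -> GenotypeMatrix:
    from .datatypes import SiteAnnotation

    n, L = calls.shape
    sites = [SiteAnnotation(site_id=f"s{j}", chromosome="1", genetic_pos=float(j),
                            region_class="noncoding") for j in range(L)]
    return GenotypeMatrix([f"i{i}" for i in range(n)], ["other"] * n, sites, calls)


def theta_ordering_fraction(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of simulated panels with the diversity gradient
    wild > admixed > cultivated under Watterson's theta."""
    good = 0
    thetas = {g: [] for g in ("pimpinellifolium", "cerasiforme", "esculentum")}
    for k in range(n_seeds):
        out = simulate_panel(preset_config("paper_like", _sub_seed(seed, 80_000 + k)))
        th = {}
        for grp in thetas:
            th[grp], _ = watterson_theta(out.genotypes, grp,
                                         total_length=TOTAL_SEQUENCED_BP)
            thetas[grp].append(th[grp])
        good += (th["pimpinellifolium"] > th["cerasiforme"] > th["esculentum"])
    return {"fraction_ordered": good / n_seeds,
            "theta_wild": float(np.mean(thetas["pimpinellifolium"])),
            "theta_admixed": float(np.mean(thetas["cerasiforme"])),
            "theta_cultivated": float(np.mean(thetas["esculentum"])),
            "n": n_seeds}


# ---------------------------------------------------------------------------
# multiple testing


def bh_oracle_max_deviation(seed: int, n_vectors: int = 1000) -> dict:
    """Max deviation between the package BH adjustment and a literal
    step-up implementation over random P vectors."""
    rng = np.random.default_rng(_sub_seed(seed, 8))
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 120))
        p = rng.uniform(1e-9, 1.0, m)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        brute = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            brute[i] = min(running, 1.0)
        worst = max(worst, float(np.max(np.abs(adj - brute))))
    return {"max_abs_diff": worst, "n": n_vectors}
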