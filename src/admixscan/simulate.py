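"""Synthetic admixed selfing-crop panels.

The generator emulates the statistical structure of a tomato-like core
collection: three taxon groups (wild relative / admixed cherry type /
cultivated) drawn from two differentiated ancestral gene pools
(Balding-Nichols differentiation, with a domestication bottleneck removing a
fraction of cultivated-pool diversity), per-individual admixture proportions,
distance-dependent LD from founder-haplotype mosaic copying, near-complete
homozygosity from repeated selfing, and quantitative traits with planted QTL,
a structure-confounded mean shift, a polygenic background, and year/replicate
noise calibrated to a target broad-sense heritability.

The copying process is Li-Stephens-style, not genealogical: founder
haplotypes per pool carry Markov (Gaussian-copula) allele correlation along
the genetic map, and each sampled haplotype mosaics over founders with a
switch probability 1 - exp(-switch_rate * d) between sites d cM apart. LD
decay is therefore a directly tunable knob rather than an emergent property.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .datatypes import GenotypeMatrix, PhenotypeTable, QMatrix, SiteAnnotation
from . import io as _io

import pandas as pd

#: taxon labels for the three simulated groups, in (wild, admixed, cultivated) order
GROUP_LABELS = ("pimpinellifolium", "cerasiforme", "esculentum")

#: default physical-map profile: (start_cm, end_cm, kb_per_cm); the low-ratio
#: segment is a planted recombination hotspot for the kb/cM scan
DEFAULT_KB_PER_CM = ((0.0, 85.0, 750.0), (85.0, 87.0, 20.0), (87.0, np.inf, 750.0))


@dataclass
class SimConfig:
    """Full parameterization of a synthetic panel. Defaults give the
    tomato-like study conditions (90 accessions: 10 wild / 63 admixed /
    17 cultivated)."""

    n_wild: int = 10
    n_admixed: int = 63
    n_cultivated: int = 17
    n_sites: int = 350
    map_length: float = 140.0  # cM
    fst: float = 0.3
    bottleneck_keep: float = 0.55
    n_founder_haplotypes: int = 16
    switch_rate: float = 0.15  # per cM; controls LD decay (calibrated)
    freq_coherence_rate: float = 0.14  # per cM; copula coherence of site freqs
    # per-pool share of the drift: wild (large Ne) drifts less than the
    # domesticated pool; the mean keeps pairwise differentiation at fst
    pool_fst_split: tuple = (0.25, 1.75)
    admixture_alpha: float = 0.5
    admixture_beta: float = 0.5
    # a couple of cultivated accessions carry residual wild introgression,
    # the main source of the singleton excess seen inside crop germplasm
    n_introgressed_cultivated: int = 2
    introgression_q: float = 0.8
    selfing_generations: int = 10
    # (site_index, trait, effect on the analysis scale: log units for FW/LCN)
    qtl_spec: tuple = ()
    # trait -> analysis-scale shift per unit cultivated ancestry
    structure_effect: dict = field(default_factory=dict)
    # trait -> sd of the accession-level polygenic background
    background_sd: dict = field(default_factory=dict)
    background_corr_fw_ssc: float = -0.7
    trait_means: dict = field(
        default_factory=lambda: {"FW": 3.3, "LCN": 1.1, "SSC": 6.0}
    )
    target_h2: float = 0.95
    n_years: int = 2
    n_reps: int = 3
    year_sd_frac: float = 0.3
    missing_rate: float = 0.0
    layout: str = "uniform"  # or "strata" (three marker-density strata)
    kb_per_cm_profile: tuple = DEFAULT_KB_PER_CM
    coding_fraction: float = 0.31
    indel_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_wild, self.n_admixed, self.n_cultivated) <= 0:
            raise ValueError("group sizes must be positive")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        if not 0.0 < self.bottleneck_keep <= 1.0:
            raise ValueError("bottleneck_keep must lie in (0, 1]")
        if self.map_length <= 0:
            raise ValueError("map_length must be positive")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        if not 0.0 < self.target_h2 < 1.0:
            raise ValueError("target_h2 must lie in (0, 1)")

    @property
    def n_accessions(self) -> int:
        return self.n_wild + self.n_admixed + self.n_cultivated


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix
    annotations: list
    true_q: QMatrix
    phenotypes: PhenotypeTable
    truth: dict
    config: SimConfig


def _ar_chain(rng: np.random.Generator, corr: np.ndarray, size: int) -> np.ndarray:
    """Stationary Gaussian AR chain(s) with per-step correlation ``corr``."""
    L = corr.size
    x = np.empty((size, L))
    x[:, 0] = rng.standard_normal(size)
    noise = rng.standard_normal((size, L))
    for l in range(1, L):
        x[:, l] = corr[l] * x[:, l - 1] + np.sqrt(1.0 - corr[l] ** 2) * noise[:, l]
    return x


def simulate_ancestral_freqs(config: SimConfig, rng: Optional[np.random.Generator] = None,
                             positions_cm: Optional[np.ndarray] = None):
    """Draw per-pool allele frequencies under Balding-Nichols differentiation.

    Ancestral frequency p ~ U[0.05, 0.95] per site; each pool draws
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = fst. The cultivated pool loses a
    fraction (1 - bottleneck_keep) of its sites to the domestication
    bottleneck (frequency rounded to the nearer of 0/1).

    When ``positions_cm`` is given, the uniform and Beta deviates are drawn
    through a Gaussian copula with correlation exp(-freq_coherence_rate * d)
    between sites d cM apart: per-site marginals are exactly the
    Balding-Nichols law above, but neighbouring sites get similar
    frequencies — the frequency coherence that shared genealogy produces in
    real data, without which near-zero-distance pairs could not reach high
    r^2 (r^2 between two sites is bounded by their frequency mismatch).

    Returns ``(ancestral, pool_freqs)`` with ``pool_freqs`` of shape
    (2, n_sites): row 0 the wild pool, row 1 the cultivated pool.
    """
    from scipy.stats import beta as beta_dist

    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.n_sites
    # asymmetric drift: F_k = fst * split_k with mean(split) = 1, so
    # E[(p1-p2)^2] / E[p1(1-p2) + p2(1-p1)] = (F1+F2)/2 = fst as in the
    # symmetric law
    fsts = [min(config.fst * s, 0.999) for s in config.pool_fst_split]
    shapes = [(1.0 - f) / f for f in fsts]
    if positions_cm is None:
        p = rng.uniform(0.05, 0.95, size=L)
        pools = np.vstack([rng.beta(p * sh, (1.0 - p) * sh) for sh in shapes])
    else:
        d = np.diff(np.asarray(positions_cm, float), prepend=positions_cm[0])
        corr = np.exp(-config.freq_coherence_rate * d)
        corr[0] = 0.0
        chains = _ar_chain(rng, corr, 3)
        u = norm.cdf(chains)
        p = 0.05 + 0.90 * u[0]
        pools = np.vstack([
            beta_dist.ppf(np.clip(u[k + 1], 1e-12, 1 - 1e-12),
                          p * shapes[k], (1.0 - p) * shapes[k])
            for k in range(2)
        ])
    lost = rng.random(L) > config.bottleneck_keep
    pools[1, lost] = np.round(pools[1, lost])
    return p, pools


def _site_positions(config: SimConfig, rng: np.random.Generator):
    """Genetic positions (cM) and fragment ids.

    ``uniform`` layout scatters fragments of ~4 sites uniformly; ``strata``
    mirrors a three-density sequencing design: sparse whole-chromosome
    coverage, a 1-fragment/cM middle stretch, and five dense physical contigs.
    Sites within a fragment share a map position (a sequenced fragment spans
    well under a cM).
    """
    frag_pos: list[tuple[float, Optional[str]]] = []
    if config.layout == "strata":
        ml = config.map_length
        frag_pos += [(x, None) for x in np.arange(2.5, ml, 5.0)]
        frag_pos += [(x, None) for x in np.arange(60.0, 90.0, 1.0)]
        contig_starts = np.linspace(82.0, 92.0, 5)
        for ci, start in enumerate(contig_starts, 1):
            for fj in range(5):
                frag_pos.append((start + 0.15 * fj, f"Contig{ci}"))
        mean_sites = config.n_sites / len(frag_pos) - 1.0
        sizes = 1 + rng.poisson(max(mean_sites, 0.1), size=len(frag_pos))
    else:
        n_frag = max(1, int(round(config.n_sites / 4)))
        frag_pos = [(x, None) for x in np.sort(rng.uniform(0, config.map_length, n_frag))]
        sizes = _chunk_sizes(config.n_sites, n_frag, rng)
    cm, frags, contigs = [], [], []
    for (pos, contig), size in sorted(zip(frag_pos, sizes), key=lambda t: t[0][0]):
        fid = f"TD{len(set(frags)) + 1:03d}"
        for _ in range(int(size)):
            cm.append(pos)
            frags.append(fid)
            contigs.append(contig)
    return np.array(cm), frags, contigs


def _chunk_sizes(total: int, n_chunks: int, rng: np.random.Generator) -> np.ndarray:
    sizes = np.ones(n_chunks, dtype=int)
    extra = rng.multinomial(max(total - n_chunks, 0), np.ones(n_chunks) / n_chunks)
    return sizes + extra


def _physical_positions(cm: np.ndarray, profile, rng: np.random.Generator) -> np.ndarray:
    """Map cM to bp through a piecewise kb/cM profile; intra-fragment sites
    (equal cM) are offset by ~120 bp steps."""
    bp = np.zeros_like(cm)
    for start, end, ratio in profile:
        seg = np.clip(cm, start, end) - start
        bp += seg * ratio * 1000.0
    bp = bp + 1.0
    out = bp.copy()
    for j in range(1, len(cm)):
        if out[j] <= out[j - 1]:
            out[j] = out[j - 1] + rng.integers(80, 200)
    return np.asarray(np.round(out), dtype=int)


def _founder_haplotypes(pool_freqs, cm, config, rng):
    """Founder panels with Markov allele correlation along the map.

    A founder haplotype is a thresholded Gaussian AR chain: correlation
    between adjacent sites exp(-switch_rate * d) so founder-panel LD decays
    on the same scale as the mosaic switching.
    """
    F, L = config.n_founder_haplotypes, len(cm)
    d = np.diff(cm, prepend=cm[0])
    r = np.exp(-config.switch_rate * d)
    r[0] = 0.0
    founders = np.empty((2, F, L), dtype=np.int8)
    for pool in range(2):
        z = norm.ppf(pool_freqs[pool])
        x = np.empty((F, L))
        x[:, 0] = rng.standard_normal(F)
        noise = rng.standard_normal((F, L))
        for l in range(1, L):
            x[:, l] = r[l] * x[:, l - 1] + np.sqrt(1.0 - r[l] ** 2) * noise[:, l]
        founders[pool] = (x < z).astype(np.int8)
    return founders


def _mosaic_haplotypes(founders, cm, q, config, rng):
    """Sample one haplotype per row of ``q`` by mosaic copying over founders.

    At each inter-site gap the copied founder switches with probability
    1 - exp(-switch_rate * d); at a switch the source pool is redrawn from
    the individual's ancestry q (probability q of the cultivated pool).
    """
    n = len(q)
    F, L = founders.shape[1], founders.shape[2]
    d = np.diff(cm, prepend=cm[0])
    p_switch = 1.0 - np.exp(-config.switch_rate * d)
    p_switch[0] = 1.0
    pool = np.zeros(n, dtype=np.intp)
    fidx = np.zeros(n, dtype=np.intp)
    haps = np.empty((n, L), dtype=np.int8)
    for l in range(L):
        sw = rng.random(n) < p_switch[l]
        if sw.any():
            pool[sw] = (rng.random(sw.sum()) < q[sw]).astype(np.intp)
            fidx[sw] = rng.integers(0, F, size=sw.sum())
        haps[:, l] = founders[pool, fidx, l]
    return haps


def simulate_panel(config: SimConfig) -> SimOutput:
    """Generate a full panel: genotypes, annotations, true Q, phenotypes, truth.

    Fully reproducible from ``config.seed`` (numpy PCG64 generator).
    """
    rng = np.random.default_rng(config.seed)
    cm, frags, contigs = _site_positions(config, rng)
    config = _reconcile_site_count(config, len(cm))
    _, pool_freqs = simulate_ancestral_freqs(config, rng, positions_cm=cm)
    for entry in config.qtl_spec:
        site = entry[0]
        if not 0 <= site < config.n_sites:
            raise ValueError(f"qtl_spec site index {site} out of range")
        # QTL sites segregate in both pools so the planted signal is not a
        # pure structure proxy (and survives the bottleneck)
        pool_freqs[:, site] = 0.5
    bp = _physical_positions(cm, config.kb_per_cm_profile, rng)

    founders = _founder_haplotypes(pool_freqs, cm, config, rng)

    # ancestry: q = cultivated-pool proportion
    q_cult = np.ones(config.n_cultivated)
    n_intro = min(config.n_introgressed_cultivated, config.n_cultivated)
    q_cult[:n_intro] = config.introgression_q
    q = np.concatenate([
        np.zeros(config.n_wild),
        rng.beta(config.admixture_alpha, config.admixture_beta, config.n_admixed),
        q_cult,
    ])
    h1 = _mosaic_haplotypes(founders, cm, q, config, rng)
    h2 = _mosaic_haplotypes(founders, cm, q, config, rng)
    calls = (h1 + h2).astype(np.int8)

    # selfing: each heterozygous call resolves to a homozygote with
    # probability 1 - (1/2)^selfing_generations. The resolved allele follows
    # a Markov haplotype choice along the map (switching between the two
    # parental haplotypes at the mosaic switch rate): marginally a fair coin
    # per site, but linked sites co-resolve as they do under real selfing,
    # so residual LD is not erased by the homozygosity drive.
    het = calls == 1
    resolve = het & (rng.random(calls.shape) < 1.0 - 0.5 ** config.selfing_generations)
    d_gap = np.diff(cm, prepend=cm[0])
    p_sw = 1.0 - np.exp(-config.switch_rate * d_gap)
    n_acc = calls.shape[0]
    choice = np.empty(calls.shape, dtype=bool)
    choice[:, 0] = rng.random(n_acc) < 0.5
    for l in range(1, calls.shape[1]):
        flip = rng.random(n_acc) < p_sw[l]
        choice[:, l] = np.where(flip, rng.random(n_acc) < 0.5, choice[:, l - 1])
    resolved_allele = np.where(choice, h2, h1)
    calls[resolve] = (2 * resolved_allele[resolve]).astype(np.int8)

    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = -1

    accessions = (
        [f"WILD{i+1:03d}" for i in range(config.n_wild)]
        + [f"ADMX{i+1:03d}" for i in range(config.n_admixed)]
        + [f"CULT{i+1:03d}" for i in range(config.n_cultivated)]
    )
    groups = (
        [GROUP_LABELS[0]] * config.n_wild
        + [GROUP_LABELS[1]] * config.n_admixed
        + [GROUP_LABELS[2]] * config.n_cultivated
    )
    sites = _annotate_sites(cm, bp, frags, contigs, config, rng)
    genotypes = GenotypeMatrix(accessions, groups, sites, calls)
    true_q = QMatrix(accessions, np.column_stack([1.0 - q, q]), source="estimated")

    phenotypes, truth = _simulate_phenotypes(genotypes, q, config, rng)
    truth["seed"] = config.seed
    return SimOutput(genotypes, sites, true_q, phenotypes, truth, config)


def _reconcile_site_count(config: SimConfig, realized: int) -> SimConfig:
    if realized == config.n_sites:
        return config
    cfg = SimConfig(**{**asdict(config), "n_sites": realized})
    return cfg


def _annotate_sites(cm, bp, frags, contigs, config, rng):
    bases = np.array(list("ACGT"))
    sites = []
    frag_offsets: dict[str, int] = {}
    for j in range(len(cm)):
        off = frag_offsets.get(frags[j], 0) + rng.integers(20, 140)
        frag_offsets[frags[j]] = off
        is_indel = rng.random() < config.indel_fraction
        ref, alt = rng.choice(bases, 2, replace=False)
        sites.append(
            SiteAnnotation(
                site_id=f"{frags[j]}-{off}",
                chromosome="SL2.40ch02",
                genetic_pos=float(cm[j]),
                physical_pos=int(bp[j]),
                region_class="coding" if rng.random() < config.coding_fraction else "noncoding",
                variant_class="indel" if is_indel else "SNP",
                fragment_id=frags[j],
                contig_id=contigs[j],
                ref=str(ref),
                alt="-" if is_indel else str(alt),
            )
        )
    return sites


def _simulate_phenotypes(genotypes: GenotypeMatrix, q, config: SimConfig, rng):
    """Trait values on the analysis scale (log for FW/LCN, raw for SSC),
    stored on the natural scale; returns (PhenotypeTable, truth dict)."""
    n = genotypes.n_accessions
    dose = genotypes.dosage()
    col_mean = np.nanmean(dose, axis=0)
    dose = np.where(np.isnan(dose), col_mean, dose)

    # correlated polygenic backgrounds for FW and SSC
    bg = {t: np.zeros(n) for t in ("FW", "LCN", "SSC")}
    sd = {t: config.background_sd.get(t, 0.0) for t in ("FW", "LCN", "SSC")}
    z1, z2, z3 = rng.standard_normal((3, n))
    rho = config.background_corr_fw_ssc
    bg["FW"] = sd["FW"] * z1
    bg["SSC"] = sd["SSC"] * (rho * z1 + np.sqrt(max(1 - rho**2, 0.0)) * z2)
    bg["LCN"] = sd["LCN"] * z3

    genetic = {}
    for trait in ("FW", "LCN", "SSC"):
        g = np.full(n, config.trait_means.get(trait, 0.0)) + bg[trait]
        g = g + config.structure_effect.get(trait, 0.0) * q
        for entry in config.qtl_spec:
            site, qtrait, effect = entry
            if qtrait == trait:
                g = g + effect * dose[:, site]
        genetic[trait] = g

    h2 = config.target_h2
    records = []
    truth_var = {}
    n_cells = config.n_years * config.n_reps
    for trait in ("FW", "LCN", "SSC"):
        g = genetic[trait]
        var_g = float(np.var(g))
        sigma_e = np.sqrt(var_g * (1.0 - h2) / h2) if var_g > 0 else 1.0
        year_eff = rng.normal(0.0, config.year_sd_frac * np.sqrt(var_g) if var_g > 0 else 0.1,
                              size=config.n_years)
        noise = rng.normal(0.0, sigma_e, size=(n, config.n_years, config.n_reps))
        values = g[:, None, None] + year_eff[None, :, None] + noise
        realized = values.reshape(n, n_cells).mean(axis=1)
        truth_var[trait] = {
            "var_genetic": var_g,
            "sigma_e2": float(sigma_e**2),
            "expected_h2": var_g / (var_g + sigma_e**2) if var_g > 0 else 0.0,
            "qtl": [
                {
                    "site_index": int(site),
                    "site_id": genotypes.sites[site].site_id,
                    "effect": float(eff),
                    "realized_r2": float(
                        np.corrcoef(dose[:, site], realized)[0, 1] ** 2
                    ),
                }
                for site, qtrait, eff in config.qtl_spec
                if qtrait == trait
            ],
        }
        for y in range(config.n_years):
            for r in range(config.n_reps):
                for i, acc in enumerate(genotypes.accessions):
                    v = values[i, y, r]
                    if trait in ("FW", "LCN"):
                        v = float(np.exp(v))
                        if trait == "LCN":
                            v = max(v, 1.0)
                    else:
                        v = max(float(v), 0.0)
                    records.append(
                        {"accession": acc, "trait": trait, "year": 2007 + y,
                         "rep": r + 1, "value": v}
                    )
    phenos = PhenotypeTable(pd.DataFrame.from_records(records))
    truth = {"traits": truth_var, "qtl_spec": [list(map(str, e)) for e in config.qtl_spec],
             "ancestry": list(map(float, q))}
    return phenos, truth


# ---------------------------------------------------------------------------
# presets

def preset_config(preset: str, seed: int = 0) -> SimConfig:
    """Named study conditions.

    ``paper_like``: 90 accessions (10 wild / 63 admixed / 17 cultivated),
    ~350 sites on one chromosome in three marker-density strata, LD calibrated
    so the fitted decay crosses r^2 ~ 0.3 near 1 cM, one large locule-number
    QTL (marker R^2 ~ 0.44), structure-confounded fruit-weight and sugar
    means, broad-sense h^2 0.95.

    ``tiny``: 12 accessions x 30 sites for unit tests.
    """
    if preset == "paper_like":
        return SimConfig(
            layout="strata",
            qtl_spec=(
                (190, "LCN", 0.295),
                (190, "SSC", -0.57),
                (120, "FW", 0.23),
                (260, "FW", 0.16),
            ),
            structure_effect={"FW": 0.61, "LCN": 0.25, "SSC": -1.04},
            background_sd={"FW": 0.34, "LCN": 0.32, "SSC": 0.98},
            missing_rate=0.01,
            seed=seed,
        )
    if preset == "tiny":
        return SimConfig(
            n_wild=3, n_admixed=6, n_cultivated=3, n_sites=30,
            map_length=50.0, qtl_spec=((5, "FW", 0.4),),
            structure_effect={"FW": 0.5}, background_sd={"FW": 0.2},
            seed=seed,
        )
    raise ValueError(f"unknown preset {preset!r}")


def make_fixture(preset: str, seed: int = 0, outdir: Optional[str] = None) -> SimOutput:
    """Simulate a preset panel and (optionally) write it to ``outdir`` in the
    pipeline's tsv/VCF formats."""
    config = preset_config(preset, seed)
    out = simulate_panel(config)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        _io.write_genotypes(out.genotypes, os.path.join(outdir, "genotypes.tsv"))
        _io.write_genotypes(out.genotypes, os.path.join(outdir, "genotypes.vcf"), format="vcf")
        _io.write_annotations(out.annotations, os.path.join(outdir, "annotations.tsv"))
        _io.write_phenotypes(out.phenotypes, os.path.join(outdir, "phenotypes_raw.tsv"))
        _io.write_qmatrix(out.true_q, os.path.join(outdir, "true_q.tsv"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(out.truth, fh, indent=1)
    return out
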