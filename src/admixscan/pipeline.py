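"""End-to-end orchestration: run the diversity -> LD -> structure/kinship ->
association stages from one config, with a reproducible manifest."""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from . import diversity as _div
from . import ld as _ld
from . import structure as _struct
from . import phenotypes as _phen
from . import association as _assoc
from .datatypes import GenotypeMatrix, PhenotypeTable
from .simulate import make_fixture, preset_config, simulate_panel


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (simulate a preset or load files)."""

    outdir: str = "admixscan_out"
    simulate_preset: Optional[str] = "paper_like"
    seed: int = 1
    genotypes: Optional[str] = None
    annotations: Optional[str] = None
    phenotypes: Optional[str] = None
    q_matrix: Optional[str] = None
    kinship: Optional[str] = None
    stages: Sequence[str] = ("diversity", "ld", "structure", "assoc")
    maf_threshold: float = 0.05
    ld_subset: Optional[str] = "cerasiforme"
    n_permutations: int = 0
    decay_units: Sequence[str] = ("cM",)
    k_range: Sequence[int] = (1, 2, 3, 4)
    k_replicates: int = 3
    assoc_models: Sequence[str] = ("GLM", "Q", "KQ")
    mlm_method: str = "p3d"
    traits: Sequence[str] = ("FW", "LCN", "SSC")
    thresholds: tuple = (0.005, 0.05)
    coding_length: float = 13827.0
    noncoding_length: float = 30396.0
    reference_accession: Optional[str] = None

    def validate(self) -> None:
        if self.simulate_preset is None:
            for path in (self.genotypes, self.phenotypes):
                if path is None or not os.path.exists(path):
                    raise ValueError(f"input path missing or nonexistent: {path}")
        if "assoc" in self.stages and any(m in ("Q", "KQ") for m in self.assoc_models):
            if "structure" not in self.stages and self.q_matrix is None:
                raise ValueError(
                    "Q/KQ association models need the structure stage or an "
                    "imported Q matrix"
                )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out (< 2^31)."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the output manifest."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "stages": {},
        "outputs": [],
        "input_hashes": {},
    }

    def emit(name: str, writer) -> str:
        path = os.path.join(config.outdir, name)
        writer(path)
        manifest["outputs"].append(name)
        return path

    # -- inputs ------------------------------------------------------------
    t0 = time.time()
    if config.simulate_preset is not None:
        sim = make_fixture(config.simulate_preset, stage_seed(config.seed, "simulate"),
                           outdir=os.path.join(config.outdir, "simulated"))
        genotypes, phenos_raw = sim.genotypes, sim.phenotypes
        manifest["outputs"].extend(
            os.path.join("simulated", f) for f in sorted(os.listdir(
                os.path.join(config.outdir, "simulated")))
        )
    else:
        genotypes = _io.read_genotypes(config.genotypes, format="tsv",
                                       annotations=config.annotations)
        phenos_raw = _io.read_phenotypes(config.phenotypes)
        for key in ("genotypes", "annotations", "phenotypes", "q_matrix", "kinship"):
            path = getattr(config, key)
            if path:
                manifest["input_hashes"][key] = _sha256(path)
    manifest["stages"]["load"] = {"seconds": round(time.time() - t0, 3),
                                  "n_accessions": genotypes.n_accessions,
                                  "n_sites": genotypes.n_sites}

    filtered = _div.filter_by_maf(genotypes, config.maf_threshold)

    # -- phenotype preprocessing (needed by assoc) -------------------------
    means = {}
    herit = {}
    has_years = "year" in phenos_raw.frame.columns and phenos_raw.frame["year"].nunique() > 1
    for trait in config.traits:
        adj = _phen.adjusted_means(phenos_raw, trait)
        means[trait] = adj.adjusted_series(trait)
        if has_years:
            an = _phen.two_factor_anova(phenos_raw, trait)
            div = _phen.replicate_divisor(phenos_raw, trait)
            herit[trait] = _phen.heritability(an, div)
    means_frame = pd.DataFrame(means)
    emit("adjusted_means.tsv",
         lambda p: means_frame.rename_axis("accession").reset_index()
         .to_csv(p, sep="\t", index=False, float_format="%.6g"))
    corr = _phen.trait_correlations(means_frame)
    emit("trait_correlations.tsv",
         lambda p: corr.rename_axis("trait").reset_index()
         .to_csv(p, sep="\t", index=False, float_format="%.6g"))

    # -- diversity ---------------------------------------------------------
    if "diversity" in config.stages:
        t0 = time.time()
        rows = []
        for group in sorted(set(genotypes.groups)):
            mask = genotypes.accession_mask(group)
            if mask.sum() < 2:
                continue
            summary = _div.diversity_summary(
                filtered, group,
                total_length=config.coding_length + config.noncoding_length,
                coding_length=config.coding_length,
                noncoding_length=config.noncoding_length,
            )
            rows.append(vars(summary) | {"shared_counts": ""})
        emit("diversity.tsv",
             lambda p: _io.write_results(pd.DataFrame(rows).drop(columns=["shared_counts"]), p))
        spec_rows = []
        for group in sorted(set(genotypes.groups)):
            hist = _div.maf_spectrum(genotypes, genotypes.accession_mask(group),
                                     overall_prefilter=config.maf_threshold)
            hist.insert(0, "group", group)
            spec_rows.append(hist)
        emit("maf_spectrum.tsv",
             lambda p: _io.write_results(pd.concat(spec_rows, ignore_index=True), p))
        manifest["stages"]["diversity"] = {"seconds": round(time.time() - t0, 3),
                                           "n_sites_retained": filtered.n_sites}

    # -- LD ----------------------------------------------------------------
    if "ld" in config.stages:
        t0 = time.time()
        subset = config.ld_subset if config.ld_subset in set(genotypes.groups) else None
        pairs = _ld.ld_matrix(genotypes, subset=subset,
                              maf_threshold=config.maf_threshold)
        emit("ld_pairs.tsv", lambda p: _io.write_results(pairs, p))
        fits = []
        for unit in config.decay_units:
            col = {"cM": "d_cm", "kb": "d_kb"}[unit]
            usable = pairs[pairs[col].notna() & (pairs[col] > 0)]
            if len(usable) >= 10:
                fit = _ld.fit_ld_decay(usable, distance_unit=unit)
                fits.append(vars(fit))
        emit("ld_decay.tsv", lambda p: _io.write_results(pd.DataFrame(fits), p))
        frag_sites = _ld.representative_sites(genotypes)
        anns = sorted((genotypes.sites[j] for j in frag_sites),
                      key=lambda s: s.genetic_pos)
        hot = _ld.hotspot_ratio_scan(anns, threshold=100.0)
        emit("hotspots.tsv", lambda p: _io.write_results(hot, p))
        manifest["stages"]["ld"] = {"seconds": round(time.time() - t0, 3),
                                    "n_pairs": len(pairs)}

    # -- structure & kinship ----------------------------------------------
    q = None
    kin = None
    if config.q_matrix:
        q = _io.read_qmatrix(config.q_matrix)
    if config.kinship:
        kin = _io.read_kinship(config.kinship)
    if "structure" in config.stages:
        t0 = time.time()
        sseed = stage_seed(config.seed, "structure")
        runs = _struct.structure_runs(filtered, config.k_range,
                                      n_replicates=config.k_replicates, seed=sseed)
        emit("structure_runs.tsv", lambda p: _io.write_structure_runs(runs, p))
        best_k = 2
        if len(config.k_range) >= 3:
            table, chosen = _struct.evanno_delta_k(runs)
            emit("evanno.tsv", lambda p: _io.write_results(table, p))
            best_k = chosen or 2
        if q is None:
            q = _struct.estimate_admixture(filtered, best_k, seed=sseed)
        emit("q_matrix.tsv", lambda p: _io.write_qmatrix(q, p))
        labels = _struct.classify_admixed(q, threshold=0.8)
        emit("structure_labels.tsv",
             lambda p: _io.write_results(
                 pd.DataFrame({"accession": q.accessions, "label": labels}), p))
        if kin is None:
            kin = _struct.ritland_kinship(filtered)
        emit("kinship.tsv", lambda p: _io.write_kinship(kin, p))
        coords, var_frac = _struct.pca_axes(filtered, n_axes=4)
        pca_df = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(coords.shape[1])])
        pca_df.insert(0, "accession", genotypes.accessions)
        emit("pca.tsv", lambda p: _io.write_results(pca_df, p))
        manifest["stages"]["structure"] = {
            "seconds": round(time.time() - t0, 3), "chosen_k": best_k,
            "n_admixed": labels.count("admixed"),
            "pca_variance_fractions": [float(v) for v in var_frac],
        }

    # -- association -------------------------------------------------------
    if "assoc" in config.stages:
        t0 = time.time()
        pvals_by_model: dict[str, list] = {}
        n_tested = 0
        for model in config.assoc_models:
            tables = []
            for trait in config.traits:
                tab = _assoc.run_scan(
                    genotypes, means[trait], trait, model=model, q=q,
                    kinship=kin, structure_source="STS",
                    maf_threshold=config.maf_threshold,
                    mlm_method=config.mlm_method,
                    reference_accession=config.reference_accession,
                    thresholds=config.thresholds,
                )
                tables.append(tab)
            allt = pd.concat(tables, ignore_index=True)
            emit(f"assoc_{model.lower()}.tsv", lambda p, t=allt: _io.write_results(t, p))
            pvals_by_model[model] = list(allt["p_value"])
            n_tested = max(n_tested, len(allt))
        diags = _assoc.pvalue_cdf_diagnostic(
            {m: p for m, p in pvals_by_model.items() if p})
        emit("calibration.tsv",
             lambda p: _io.write_results(pd.DataFrame(
                 [{"model": d.model, "max_deviation": d.max_deviation}
                  for d in diags]), p))
        manifest["stages"]["assoc"] = {"seconds": round(time.time() - t0, 3),
                                       "n_tests_per_model": n_tested}

    if herit:
        manifest["heritability"] = {t: vars(h) for t, h in herit.items()}
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
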