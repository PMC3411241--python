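"""Readers and writers for the pipeline's tabular and VCF formats.

All on-disk formats are plain text: tab-separated genotype / annotation /
phenotype / result tables and biallelic VCF (GT field only). Floats are
written with >= 6 significant digits so write -> read round-trips exactly at
that precision.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    GROUPS,
    MISSING,
    GenotypeMatrix,
    KinshipMatrix,
    PhenotypeTable,
    QMatrix,
    SiteAnnotation,
)

_MISSING_TOKENS = {".", "NA", "", "nan", "-1"}

ANNOTATION_COLUMNS = [
    "site_id", "chromosome", "genetic_pos", "physical_pos", "region_class",
    "variant_class", "fragment_id", "contig_id", "ref", "alt",
]


def read_annotations(path: str) -> list[SiteAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation sheet missing columns {sorted(missing)}")
    sites = []
    for _, row in df.iterrows():
        phys = row.get("physical_pos")
        sites.append(
            SiteAnnotation(
                site_id=row["site_id"],
                chromosome=row["chromosome"],
                genetic_pos=float(row["genetic_pos"]),
                physical_pos=None if pd.isna(phys) or phys == "" else int(float(phys)),
                region_class=row.get("region_class", "noncoding"),
                variant_class=row.get("variant_class", "SNP"),
                fragment_id=row.get("fragment_id", "") or "",
                contig_id=None if pd.isna(row.get("contig_id")) else row.get("contig_id"),
                ref=row.get("ref", "A") or "A",
                alt=row.get("alt", "T") or "T",
            )
        )
    return sites


def write_annotations(sites: Sequence[SiteAnnotation], path: str) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "chromosome": s.chromosome,
            "genetic_pos": repr(s.genetic_pos),
            "physical_pos": "" if s.physical_pos is None else s.physical_pos,
            "region_class": s.region_class,
            "variant_class": s.variant_class,
            "fragment_id": s.fragment_id,
            "contig_id": s.contig_id or "",
            "ref": s.ref,
            "alt": s.alt,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_call(token: str, accession: str, site_id: str) -> int:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return MISSING
    try:
        value = int(token)
    except ValueError:
        raise ValueError(
            f"call {token!r} for accession {accession!r} at site {site_id!r} "
            "is not an integer dosage"
        ) from None
    if value not in (0, 1, 2):
        raise ValueError(
            f"call {value} outside {{0,1,2}} for accession {accession!r} "
            f"at site {site_id!r}"
        )
    return value


def read_genotypes(
    path: str,
    format: str = "tsv",
    annotations: Optional[str | Sequence[SiteAnnotation]] = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from tsv (accessions as rows) or biallelic VCF.

    The tsv dialect is ``accession<TAB>group<TAB><site ids...>`` with dosage
    codes 0/1/2 and ``.``/``NA`` for missing. ``annotations`` (a path or
    parsed list) supplies the site metadata; for VCF it is optional and
    defaults to record-derived annotations.
    """
    if format not in ("tsv", "vcf"):
        raise ValueError(f"unknown genotype format {format!r}")
    if isinstance(annotations, str):
        annotations = read_annotations(annotations)
    if format == "tsv":
        return _read_genotypes_tsv(path, annotations)
    return _read_genotypes_vcf(path, annotations)


def _read_genotypes_tsv(path, annotations) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "accession" or header[1] != "group":
            raise ValueError(
                f"{path}:1: malformed genotype header; expected "
                "'accession\\tgroup\\t<site ids...>'"
            )
        site_ids = header[2:]
        accessions, groups, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            accessions.append(parts[0])
            groups.append(parts[1] if parts[1] in GROUPS else "other")
            rows.append([_parse_call(t, parts[0], s) for t, s in zip(parts[2:], site_ids)])
    sites = _match_annotations(site_ids, annotations)
    return GenotypeMatrix(accessions, groups, sites, np.array(rows, dtype=np.int8))


def _match_annotations(site_ids, annotations) -> list[SiteAnnotation]:
    if annotations is None:
        return [
            SiteAnnotation(site_id=s, chromosome="chr", genetic_pos=0.0,
                           region_class="noncoding")
            for s in site_ids
        ]
    by_id = {s.site_id: s for s in annotations}
    missing = [s for s in site_ids if s not in by_id]
    if missing:
        raise ValueError(f"annotation sheet lacks sites: {missing[:5]}")
    return [by_id[s] for s in site_ids]


def _read_genotypes_vcf(path, annotations) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    accessions = list(vcf.samples)
    sites, columns = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} not supported; "
                "split it upstream"
            )
        # gt_types with gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        col = np.asarray(rec.gt_types, dtype=np.int8).copy()
        col[col == 3] = MISSING
        columns.append(col)
        var_class = "SNP" if len(rec.REF) == 1 and len(rec.ALT[0]) == 1 else "indel"
        sid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}-{rec.POS}"
        sites.append(
            SiteAnnotation(
                site_id=sid, chromosome=rec.CHROM, genetic_pos=0.0,
                physical_pos=rec.POS, region_class="noncoding",
                variant_class=var_class, ref=rec.REF, alt=rec.ALT[0],
            )
        )
    calls = np.column_stack(columns) if columns else np.zeros((len(accessions), 0), np.int8)
    if annotations is not None:
        by_id = {s.site_id: s for s in annotations}
        sites = [by_id.get(s.site_id, s) for s in sites]
    groups = ["other"] * len(accessions)
    return GenotypeMatrix(accessions, groups, sites, calls)


def write_genotypes(genotypes: GenotypeMatrix, path: str, format: str = "tsv") -> None:
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("accession\tgroup\t" + "\t".join(genotypes.site_ids) + "\n")
            for i, (acc, grp) in enumerate(zip(genotypes.accessions, genotypes.groups)):
                tokens = ["." if c == MISSING else str(c) for c in genotypes.calls[i]]
                fh.write(f"{acc}\t{grp}\t" + "\t".join(tokens) + "\n")
        return
    if format != "vcf":
        raise ValueError(f"unknown genotype format {format!r}")
    _write_vcf(genotypes, path)


def _write_vcf(genotypes: GenotypeMatrix, path: str) -> None:
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({s.chromosome for s in genotypes.sites})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.accessions) + "\n"
        )
        order = sorted(
            range(genotypes.n_sites),
            key=lambda j: (genotypes.sites[j].chromosome,
                           genotypes.sites[j].physical_pos or j + 1),
        )
        for j in order:
            s = genotypes.sites[j]
            pos = s.physical_pos or j + 1
            gts = "\t".join(gt_map[int(c)] for c in genotypes.calls[:, j])
            fh.write(
                f"{s.chromosome}\t{pos}\t{s.site_id}\t{s.ref}\t{s.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phenotypes(path: str) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    return PhenotypeTable(df)


def write_phenotypes(phenos: PhenotypeTable, path: str) -> None:
    phenos.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_results(results: pd.DataFrame, path: str) -> None:
    """Write a result table as tsv with >= 6 significant digits for floats."""
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_qmatrix(q: QMatrix, path: str) -> None:
    df = pd.DataFrame(q.proportions, columns=[f"Q{k+1}" for k in range(q.k)])
    df.insert(0, "accession", q.accessions)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_qmatrix(path: str, source: str = "imported") -> QMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    props = df.drop(columns=["accession"]).to_numpy(float)
    # renormalize away round-trip noise; imported Structure output is often
    # printed at 3 decimals
    props = props / props.sum(axis=1, keepdims=True)
    return QMatrix(list(df["accession"]), props, source=source)


def write_kinship(k: KinshipMatrix, path: str) -> None:
    df = pd.DataFrame(k.values, columns=k.accessions)
    df.insert(0, "accession", k.accessions)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_kinship(path: str) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    return KinshipMatrix(list(df["accession"]), df.drop(columns=["accession"]).to_numpy(float))


def write_structure_runs(runs: dict[int, list[float]], path: str) -> None:
    rows = [
        {"K": k, "replicate": i + 1, "log_likelihood": ll}
        for k in sorted(runs) for i, ll in enumerate(runs[k])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_structure_runs(path: str) -> dict[int, list[float]]:
    df = pd.read_csv(path, sep="\t")
    return {int(k): list(g["log_likelihood"]) for k, g in df.groupby("K")}
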