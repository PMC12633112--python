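"""Readers and writers for the on-disk formats.

Formats: minimal GT-only VCF (biallelic, diploid; 1-based coordinates),
PLINK-style FAM pedigree, phenotype TSV (FID IID phenotype cov1..covK),
the fixed-column sumstats TSV of :mod:`famgwas.fgwas`, ground-truth and
weights TSVs, and YAML pipeline configuration.  Dosages count the A1
(effect) allele, so VCF records are written with REF = A2 and ALT = A1.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from famgwas.fgwas import SUMSTATS_COLUMNS
from famgwas.simulate import FamilyDataset

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_fam",
    "read_fam",
    "write_phenotypes",
    "read_phenotypes",
    "write_truth",
    "write_sumstats",
    "read_sumstats",
    "write_dataset",
    "read_dataset",
    "write_imputed_records",
    "file_sha256",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(dataset: FamilyDataset, path: str | Path) -> Path:
    """Write genotyped individuals as a minimal GT-only VCF."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.iids)
            + "\n"
        )
        G = dataset.genotypes
        for li, row in enumerate(dataset.snps.itertuples()):
            calls = []
            for g in G[:, li]:
                calls.append("./." if not np.isfinite(g) else _GT[int(g)])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp}\t{row.a2}\t{row.a1}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )
    return path


def read_vcf(path: str | Path):
    """Read a biallelic GT VCF into (dosages, snp metadata, sample ids, n_skipped).

    Multi-allelic records are skipped and counted; a malformed data line
    raises with its line number.  Dosages count the ALT (= A1) allele;
    missing calls become NaN.
    """
    try:
        return _read_vcf_cyvcf2(str(path))
    except ImportError:
        return _read_vcf_text(path)


def _read_vcf_cyvcf2(path: str):
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, meta = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gt = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dos)
        meta.append((var.CHROM, var.POS, var.ID, var.ALT[0], var.REF))
    snps = pd.DataFrame(meta, columns=["chrom", "pos", "snp", "a1", "a2"])
    G = np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return G, snps, samples, skipped


def _read_vcf_text(path):
    samples, rows, meta = [], [], []
    skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"malformed VCF line {ln}: expected >=10 fields")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                skipped += 1
                continue
            dos = []
            for call in fields[9:]:
                gt = call.split(":")[0].replace("|", "/")
                if gt in (".", "./."):
                    dos.append(np.nan)
                else:
                    try:
                        a, b = gt.split("/")
                        dos.append(float(int(a) + int(b)))
                    except ValueError as exc:
                        raise ValueError(f"malformed genotype {call!r} on line {ln}") from exc
            rows.append(dos)
            meta.append((chrom, int(pos), vid, alt, ref))
    snps = pd.DataFrame(meta, columns=["chrom", "pos", "snp", "a1", "a2"])
    G = np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return G, snps, samples, skipped


def write_fam(dataset: FamilyDataset, path: str | Path) -> Path:
    path = Path(path)
    dataset.pedigree_frame().to_csv(path, sep="\t", header=False, index=False)
    return path


def read_fam(path: str | Path) -> pd.DataFrame:
    fam = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["FID", "IID", "father", "mother", "sex", "phenotype"],
        dtype={"FID": str, "IID": str, "father": str, "mother": str},
    )
    return fam


def write_phenotypes(dataset: FamilyDataset, path: str | Path) -> Path:
    path = Path(path)
    cols = {"FID": dataset.fids, "IID": dataset.iids, "phenotype": dataset.phenotype}
    if dataset.phenotype2 is not None:
        cols["phenotype2"] = dataset.phenotype2
    if dataset.covariates is not None:
        for k in range(dataset.covariates.shape[1]):
            cols[f"cov{k + 1}"] = dataset.covariates[:, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str}, na_values=["NA"])


def write_truth(dataset: FamilyDataset, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "SNP": dataset.snp_ids,
            "true_delta": dataset.truth.get("true_delta", np.full(dataset.n_snps, np.nan)),
            "true_alpha": dataset.truth.get("true_alpha", np.full(dataset.n_snps, np.nan)),
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def write_sumstats(sumstats: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in SUMSTATS_COLUMNS if c in sumstats.columns]
    cols += [c for c in sumstats.columns if c not in cols]
    sumstats[cols].to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_sumstats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_imputed_records(records: list[dict], path: str | Path) -> Path:
    """Imputed-parent TSV: FID, SNP, kind, expectation, posterior entries."""
    rows = []
    for rec in records:
        rows.append(
            {
                "FID": rec["fid"],
                "SNP": rec["snp"],
                "kind": rec["record"].kind,
                "expectation": rec["record"].expectation,
                "posterior": ";".join(
                    f"{k}:{v:.6g}" for k, v in sorted(rec["record"].posterior.items())
                ),
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)
    return Path(path)


def write_dataset(dataset: FamilyDataset, prefix: str | Path) -> dict[str, Path]:
    """Write VCF + FAM + phenotype TSV (+ truth TSV when simulated)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    out = {
        "vcf": write_vcf(dataset, prefix.with_suffix(".vcf")),
        "fam": write_fam(dataset, prefix.with_suffix(".fam")),
        "pheno": write_phenotypes(dataset, prefix.with_suffix(".pheno.tsv")),
    }
    if "true_delta" in dataset.truth:
        out["truth"] = write_truth(dataset, prefix.with_suffix(".truth.tsv"))
    return out


def read_dataset(
    vcf_path: str | Path,
    fam_path: str | Path,
    pheno_path: str | Path | None = None,
) -> FamilyDataset:
    """Assemble a FamilyDataset from VCF + FAM (+ phenotype TSV).

    Roles are inferred from the pedigree: an individual listed as another
    sample's father/mother gets that role; everyone else is an offspring.
    A parent id absent from the samples means the parent is ungenotyped
    (not an error).  Allele frequencies are estimated from parental rows
    when any exist, otherwise from all samples, floored at 1/(2n + 2).
    """
    G, snps, samples, _ = read_vcf(vcf_path)
    fam = read_fam(fam_path).set_index("IID")
    fam = fam.loc[[s for s in samples if s in fam.index]]
    if len(fam) != len(samples):
        missing = set(samples) - set(fam.index)
        raise ValueError(f"samples missing from FAM: {sorted(missing)[:5]}...")

    fathers = set(fam["father"]) - {"0"}
    mothers = set(fam["mother"]) - {"0"}
    role = np.array(
        [
            "father" if s in fathers else ("mother" if s in mothers else "offspring")
            for s in samples
        ]
    )

    pheno = np.full(len(samples), np.nan)
    covariates = None
    if pheno_path is not None:
        ph = read_phenotypes(pheno_path).set_index("IID")
        cov_cols = [c for c in ph.columns if c.startswith("cov")]
        if cov_cols:
            covariates = np.full((len(samples), len(cov_cols)), np.nan)
        for i, s in enumerate(samples):
            if s in ph.index:
                pheno[i] = ph.loc[s, "phenotype"]
                if cov_cols:
                    covariates[i] = ph.loc[s, cov_cols].to_numpy(dtype=float)

    parent_mask = role != "offspring"
    basis = G[parent_mask] if parent_mask.any() else G
    n = basis.shape[0]
    floor = 1.0 / (2 * n + 2)
    with np.errstate(invalid="ignore"):
        freqs = np.nanmean(basis, axis=0) / 2.0
    freqs = np.clip(np.nan_to_num(freqs, nan=0.5), floor, 1 - floor)

    snps = snps.copy()
    snps["pos"] = snps["pos"].astype(int)
    return FamilyDataset(
        genotypes=G,
        fids=fam["FID"].to_numpy(),
        iids=np.asarray(samples),
        father_ids=fam["father"].to_numpy(),
        mother_ids=fam["mother"].to_numpy(),
        sex=fam["sex"].to_numpy(),
        role=role,
        phenotype=pheno,
        covariates=covariates,
        snps=snps,
        freqs=freqs,
    )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
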