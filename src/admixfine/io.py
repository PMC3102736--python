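"""Readers and writers for the pipeline's file formats.

Genotypes travel either as VCF (``GT`` for typed variants, ``DS`` dosage
field for imputed ones, imputation quality under INFO key ``RSQ``) or as a
TSV dosage dialect: one row per variant with columns ``variant_id, chrom,
pos, risk_allele, other_allele, typed, rsq`` followed by one dosage column
per sample (``NA`` = missing).  Dosages always count copies of the declared
risk allele; positions are 1-based.

Phenotypes: TSV with ``sample_id, status, age, study, family_history,
severity, sex`` (``NA`` for unknown family history / severity).  Local
ancestry: long TSV ``sample_id, variant_id, pop1_chromosomes``.  Risk-region
configuration: TSV ``region_name, chrom, start, end, index_variants``
(comma-separated ids).  Ground truth is serialized as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    DataError,
    DosageMatrix,
    LocalAncestryTrack,
    RiskRegion,
    validate_sample_table,
)


# ----------------------------------------------------------------------
# dosage TSV dialect
# ----------------------------------------------------------------------


def write_dosage_tsv(dosages: DosageMatrix, path: str | Path) -> None:
    meta = dosages.variants
    with open(path, "w") as fh:
        header = ["variant_id", "chrom", "pos", "risk_allele", "other_allele",
                  "typed", "rsq"] + list(dosages.samples)
        fh.write("\t".join(header) + "\n")
        for j in range(dosages.n_variants):
            row = meta.iloc[j]
            vals = [
                "NA" if np.isnan(d) else format(d, ".6g")
                for d in dosages.dosages[:, j]
            ]
            fh.write(
                "\t".join(
                    [
                        str(row["variant_id"]), str(row["chrom"]), str(int(row["pos"])),
                        str(row["risk_allele"]), str(row["other_allele"]),
                        "1" if row["typed"] else "0", format(float(row["rsq"]), ".6g"),
                    ]
                    + vals
                )
                + "\n"
            )


def read_dosage_tsv(path: str | Path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    fixed = ["variant_id", "chrom", "pos", "risk_allele", "other_allele", "typed", "rsq"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise DataError(f"dosage TSV missing columns: {missing}")
    samples = [c for c in df.columns if c not in fixed]
    variants = df[fixed].copy()
    variants["typed"] = variants["typed"].astype(int).astype(bool)
    dosages = df[samples].to_numpy(dtype=float).T
    return DosageMatrix(dosages, samples, variants)


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------


def write_vcf(dosages: DosageMatrix, path: str | Path) -> None:
    """Plain-text VCF 4.2; REF is the other allele, ALT the risk allele, so
    GT/DS count risk alleles directly."""
    meta = dosages.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=RSQ,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Hard genotype calls">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Risk allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t")
        fh.write("FORMAT\t" + "\t".join(dosages.samples) + "\n")
        gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(dosages.n_variants):
            row = meta.iloc[j]
            typed = bool(row["typed"])
            info = f"RSQ={float(row['rsq']):.4g}" + (";TYPED" if typed else "")
            if typed:
                calls = [
                    "./." if np.isnan(d) else gt_code[float(d)]
                    for d in dosages.dosages[:, j]
                ]
                fmt = "GT"
            else:
                calls = [format(d, ".4f") for d in dosages.dosages[:, j]]
                fmt = "DS"
            fh.write(
                "\t".join(
                    [
                        str(row["chrom"]), str(int(row["pos"])), str(row["variant_id"]),
                        str(row["other_allele"]), str(row["risk_allele"]),
                        ".", "PASS", info, fmt,
                    ]
                    + calls
                )
                + "\n"
            )


def read_vcf(
    path: str | Path, risk_alleles: dict[str, str] | None = None
) -> DosageMatrix:
    """Read genotypes/dosages from a VCF via cyvcf2.

    By default the ALT allele is taken as the risk allele; pass
    ``risk_alleles`` (variant id -> allele) to orient dosages explicitly —
    a variant whose declared risk allele matches REF is flipped, and a
    mismatch with both alleles raises an error naming the variant.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, recs = [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        ref, alt = var.REF, var.ALT[0] if var.ALT else "."
        risk, other, flip = alt, ref, False
        if risk_alleles and vid in risk_alleles:
            declared = risk_alleles[vid]
            if declared == alt:
                pass
            elif declared == ref:
                risk, other, flip = ref, alt, True
            else:
                raise DataError(
                    f"variant {vid}: declared risk allele {declared!r} matches "
                    f"neither REF={ref} nor ALT={alt}"
                )
        try:
            ds = var.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
            typed = False
        else:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = var.gt_types
            dos = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
            typed = True
        if flip:
            dos = 2.0 - dos
        rsq = var.INFO.get("RSQ")
        rows.append(
            {
                "variant_id": vid,
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "risk_allele": risk,
                "other_allele": other,
                "typed": typed,
                "rsq": float(rsq) if rsq is not None else (1.0 if typed else np.nan),
            }
        )
        recs.append(dos)
    if not rows:
        raise DataError(f"no records in VCF: {path}")
    return DosageMatrix(np.column_stack(recs), samples, pd.DataFrame(rows))


def read_genotypes(
    path: str | Path, fmt: str | None = None, risk_alleles: dict[str, str] | None = None
) -> DosageMatrix:
    """Dispatch on format ('vcf' or 'tsv'; inferred from the suffix)."""
    fmt = fmt or ("vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv")
    if fmt == "vcf":
        return read_vcf(path, risk_alleles)
    if fmt == "tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {fmt}")


# ----------------------------------------------------------------------
# phenotype / ancestry / regions / truth
# ----------------------------------------------------------------------


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    validate_sample_table(table)
    out = table.copy()
    for col in ("family_history", "severity"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return validate_sample_table(df)


def write_local_ancestry(track: LocalAncestryTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tvariant_id\tpop1_chromosomes\n")
        for i, sid in enumerate(track.samples):
            for j, vid in enumerate(track.variant_ids):
                fh.write(f"{sid}\t{vid}\t{track.values[i, j]:.6g}\n")


def read_local_ancestry(path: str | Path) -> LocalAncestryTrack:
    df = pd.read_csv(path, sep="\t")
    wide = df.pivot(index="sample_id", columns="variant_id", values="pop1_chromosomes")
    return LocalAncestryTrack(
        wide.to_numpy(dtype=float), list(wide.index), list(wide.columns)
    )


def write_regions(regions: list[RiskRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region_name\tchrom\tstart\tend\tindex_variants\n")
        for r in regions:
            fh.write(
                f"{r.name}\t{r.chrom}\t{r.start}\t{r.end}\t{','.join(r.index_variants)}\n"
            )


def read_regions(path: str | Path) -> list[RiskRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for _, row in df.iterrows():
        idx = (
            tuple(str(row["index_variants"]).split(","))
            if pd.notna(row["index_variants"]) and str(row["index_variants"])
            else ()
        )
        out.append(
            RiskRegion(str(row["region_name"]), str(row["chrom"]),
                       int(row["start"]), int(row["end"]), idx)
        )
    return out


def write_truth(truth, path: str | Path) -> None:
    """Ground-truth JSON (scalars and per-variant summaries; phased
    haplotypes stay in memory only)."""
    payload = {
        "seed": truth.seed,
        "causal": [{"variant_id": c.variant_id, "log_or": c.log_or} for c in truth.causal],
        "relationships": truth.relationships,
        "variant_ids": truth.variant_ids,
        "typed": truth.typed.astype(int).tolist(),
        "rsq_target": np.round(truth.rsq_target, 6).tolist(),
        "rsq_realized": [None if not np.isfinite(v) else round(float(v), 6)
                         for v in truth.rsq_realized],
        "theta_mean": float(truth.theta.mean()),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


__all__ = [
    "read_dosage_tsv",
    "read_genotypes",
    "read_local_ancestry",
    "read_phenotypes",
    "read_regions",
    "read_vcf",
    "write_dosage_tsv",
    "write_local_ancestry",
    "write_phenotypes",
    "write_regions",
    "write_truth",
    "write_vcf",
]
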