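"""Readers, writers and validation for the pipeline's text formats.

Everything is plain TSV except genotypes (VCF or matrix TSV, read via
cyvcf2), gene models (BED, 0-based half-open, or GFF3, 1-based
inclusive; both are normalised to 1-based inclusive internally) and the
optional popoolation-style sync export of pooled allele counts.
Validation distinguishes hard errors (missing required columns,
non-positive life spans, an H pool without its C counterpart) from
warnings, and reports record locations.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .gwa import GenotypeMatrix

__all__ = [
    "ValidationError",
    "validate_lifespan",
    "validate_pooled_counts",
    "read_lifespan_tsv",
    "write_lifespan_tsv",
    "read_microenv_tsv",
    "write_microenv_tsv",
    "read_genotype_matrix_tsv",
    "write_genotype_matrix_tsv",
    "read_vcf_genotypes",
    "write_vcf_genotypes",
    "read_pooled_counts_tsv",
    "write_pooled_counts_tsv",
    "write_sync",
    "read_sync",
    "read_bed_genes",
    "read_gff3_genes",
    "read_go_annotations",
    "read_covariates_tsv",
]

LIFESPAN_COLUMNS = ["line", "sex", "temperature", "vial", "lifespan_days"]


class ValidationError(ValueError):
    """Input failed validation; ``errors`` lists the hard failures."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def validate_lifespan(df: pd.DataFrame) -> list[str]:
    """Hard errors for a life span table (empty list = valid)."""
    errors = []
    for col in LIFESPAN_COLUMNS:
        if col not in df.columns:
            errors.append(f"missing required column '{col}'")
    if errors:
        return errors
    vals = pd.to_numeric(df["lifespan_days"], errors="coerce")
    bad = df.index[vals.isna() | (vals <= 0)]
    for i in bad[:10]:
        errors.append(f"non-positive or non-numeric life span at record {i}")
    if len(bad) > 10:
        errors.append(f"... and {len(bad) - 10} more bad life span records")
    return errors


def read_lifespan_tsv(path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if validate:
        errors = validate_lifespan(df)
        if errors:
            raise ValidationError(errors)
    return df


def write_lifespan_tsv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_microenv_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_microenv_tsv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------- genotypes

META_COLS = ["variant_id", "chrom", "pos", "ref", "alt"]


def write_genotype_matrix_tsv(geno: GenotypeMatrix, path) -> None:
    """Variants as rows: metadata columns then one dosage column per line."""
    out = geno.meta.copy()
    out = pd.concat([out.reset_index(drop=True), geno.dosage.T.reset_index(drop=True)], axis=1)
    out.columns = META_COLS + list(geno.dosage.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def read_genotype_matrix_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise ValidationError([f"missing required column '{c}'" for c in missing])
    meta = df[META_COLS].copy()
    dosage = df.drop(columns=META_COLS).T
    dosage.columns = meta["variant_id"]
    dosage.index.name = "line"
    return GenotypeMatrix(dosage.astype(float), meta)


def write_vcf_genotypes(geno: GenotypeMatrix, path) -> None:
    """Minimal GT-only VCF (1-based positions; inbred 0/0 / 1/1 calls)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        lines = list(geno.dosage.index)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(map(str, lines)) + "\n")
        D = geno.dosage.to_numpy(float)
        for j, row in enumerate(geno.meta.itertuples(index=False)):
            calls = []
            for d in D[:, j]:
                calls.append("./." if np.isnan(d) else ("1/1" if d == 2 else "0/0"))
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf_genotypes(path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into inbred dosages.

    Homozygous ref -> 0, homozygous alt -> 2; heterozygous or missing
    calls in inbred lines are treated as missing dosage.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = vcf.samples
    meta_rows, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        meta_rows.append(
            {
                "variant_id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM, "pos": var.POS, "ref": var.REF, "alt": var.ALT[0],
            }
        )
        gt = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        d = np.where(gt == 0, 0.0, np.where(gt == 3, 2.0, np.nan))
        cols.append(d)
    meta = pd.DataFrame(meta_rows)
    dosage = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(lines, name="line"),
        columns=meta["variant_id"],
    )
    return GenotypeMatrix(dosage, meta)


# ------------------------------------------------------------ pooled counts

def _pool_id(row) -> str:
    return f"{row.sex}_{row.temperature}_rep{row.replicate}_{row.pool_type}"


_POOL_RE = re.compile(r"^(?P<sex>[^_]+)_(?P<temp>[^_]+)_rep(?P<rep>\d+)_(?P<type>[HC])$")


def write_pooled_counts_tsv(counts: pd.DataFrame, path, seed: int | None = None) -> None:
    out = counts.copy()
    out["pool_id"] = [
        f"{s}_{t}_rep{r}_{p}"
        for s, t, r, p in zip(out["sex"], out["temperature"], out["replicate"], out["pool_type"])
    ]
    cols = ["chrom", "pos", "ref", "alt", "variant_id", "pool_id", "ref_reads", "alt_reads", "pool_size"]
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out[cols].to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_pooled_counts_tsv(path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"chrom", "pos", "ref", "alt", "pool_id", "ref_reads", "alt_reads"}
    missing = need - set(df.columns)
    if missing:
        raise ValidationError([f"missing required column '{c}'" for c in sorted(missing)])
    parsed = df["pool_id"].astype(str).str.extract(_POOL_RE)
    if parsed.isna().any(axis=None):
        bad = df.index[parsed.isna().any(axis=1)][:5].tolist()
        raise ValidationError([f"malformed pool_id at record(s) {bad}"])
    df["sex"] = parsed["sex"]
    df["temperature"] = parsed["temp"]
    df["replicate"] = parsed["rep"].astype(int)
    df["pool_type"] = parsed["type"]
    if "variant_id" not in df.columns:
        df["variant_id"] = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    if "pool_size" not in df.columns:
        df["pool_size"] = 96
    if validate:
        errors = validate_pooled_counts(df)
        if errors:
            raise ValidationError(errors)
    return df


def validate_pooled_counts(df: pd.DataFrame) -> list[str]:
    """Hard errors: negative counts, or an H pool without its C pool."""
    errors = []
    if (df["ref_reads"] < 0).any() or (df["alt_reads"] < 0).any():
        errors.append("negative read counts present")
    have = df.groupby(["sex", "temperature", "replicate"], observed=True)["pool_type"].agg(set)
    for ctx, types in have.items():
        if types != {"H", "C"}:
            errors.append(f"context {ctx} lacks a complete H/C pool pair")
    return errors


_NUCS = ["A", "T", "C", "G", "N", "del"]


def write_sync(counts: pd.DataFrame, path) -> None:
    """Popoolation-style sync export: A:T:C:G:N:del per pool column.

    Pool order is recorded on a leading comment line.
    """
    pools = sorted(
        {_pool_id(r) for r in counts.itertuples(index=False)}
    )
    wide_ref = counts.pivot_table(
        index=["chrom", "pos", "ref", "alt"],
        columns=counts.apply(_pool_id, axis=1), values="ref_reads", observed=True,
    )
    wide_alt = counts.pivot_table(
        index=["chrom", "pos", "ref", "alt"],
        columns=counts.apply(_pool_id, axis=1), values="alt_reads", observed=True,
    )
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\t" + "\t".join(pools) + "\n")
        for (chrom, pos, ref, alt) in wide_ref.index:
            cells = []
            for p in pools:
                cnt = dict.fromkeys(_NUCS, 0)
                cnt[ref] = int(wide_ref.loc[(chrom, pos, ref, alt), p])
                cnt[alt] = int(wide_alt.loc[(chrom, pos, ref, alt), p])
                cells.append(":".join(str(cnt[n]) for n in _NUCS))
            fh.write(f"{chrom}\t{pos}\t{ref}\t" + "\t".join(cells) + "\n")


def read_sync(path) -> pd.DataFrame:
    """Read a sync file written by :func:`write_sync` back into long counts."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.startswith("#"):
        raise ValidationError(["sync file lacks the pool-order header line"])
    pools = header.lstrip("#").split("\t")[3:]
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "pos", "ref"] + pools)
    rows = []
    for rec in df.itertuples(index=False):
        for p in pools:
            m = _POOL_RE.match(p)
            counts = dict(zip(_NUCS, map(int, getattr(rec, p).split(":"))))
            ref_n = counts.pop(rec.ref)
            alt_nuc, alt_n = max(counts.items(), key=lambda kv: kv[1])
            rows.append(
                {
                    "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alt_nuc,
                    "variant_id": f"{rec.chrom}:{rec.pos}",
                    "sex": m["sex"], "temperature": m["temp"],
                    "replicate": int(m["rep"]), "pool_type": m["type"],
                    "ref_reads": ref_n, "alt_reads": alt_n, "pool_size": 96,
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- gene models

def read_bed_genes(path) -> pd.DataFrame:
    """BED (0-based half-open) -> gene table (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 4:
        raise ValidationError(["BED file needs at least 4 columns (chrom, start, end, name)"])
    out = pd.DataFrame(
        {
            "gene_id": df[3],
            "chrom": df[0],
            "start": df[1].astype(int) + 1,
            "end": df[2].astype(int),
        }
    )
    out["length"] = out["end"] - out["start"] + 1
    if (out["length"] < 1).any():
        raise ValidationError(["gene with end < start in BED file"])
    return out


_GFF_ID = re.compile(r"(?:^|;)(?:ID|gene_id)=([^;]+)")


def read_gff3_genes(path, feature: str = "gene") -> pd.DataFrame:
    """GFF3 (1-based inclusive) gene records -> gene table."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
    )
    df = df[df["type"] == feature]
    ids = df["attrs"].astype(str).str.extract(_GFF_ID)[0]
    out = pd.DataFrame(
        {
            "gene_id": ids.fillna("unknown"),
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
        }
    ).reset_index(drop=True)
    out["length"] = out["end"] - out["start"] + 1
    return out


def read_go_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValidationError(["GO annotation TSV needs 2 columns (gene, term)"])
    df.columns = ["gene_id", "term"] + list(df.columns[2:])
    return df[["gene_id", "term"]]


def read_covariates_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "line" not in df.columns:
        raise ValidationError(["covariate TSV needs a 'line' column"])
    return df.set_index("line")
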