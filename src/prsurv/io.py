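"""Readers and writers for the pipeline's plain-text formats.

Formats: VCF (GT:AD:GQ calls), summary-statistics TSV, dense LD matrix TSV,
PGS-style scoring TSV, phenotype CSV, lab-series CSV and a BED-like gene
table (converted to 1-based closed coordinates on read). Every table is
written with a header and a provenance footer comment (config hash and
seed); readers skip comment lines, so each writer's output round-trips
through its reader.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .assoc import LDMatrix, SUMSTAT_COLUMNS
from .prscore import SCORING_COLUMNS, ScoreWeights
from .synthpop import LabSeries
from .vqc import MISSING, GenotypeCallMatrix

__all__ = [
    "write_vcf", "read_vcf",
    "write_table", "read_table",
    "write_sumstats", "read_sumstats",
    "write_ld_matrix", "read_ld_matrix",
    "write_scoring_file", "read_scoring_file",
    "write_lab_series", "read_lab_series",
    "read_gene_table",
]

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _footer(provenance: dict | None) -> str:
    if not provenance:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in sorted(provenance.items()))
    return f"# prsurv {parts}\n"


def write_table(df: pd.DataFrame, path, sep: str = "\t",
                provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        df.to_csv(fh, sep=sep, index=False, float_format="%.10g")
        fh.write(_footer(provenance))


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def write_sumstats(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    write_table(df[SUMSTAT_COLUMNS], path, provenance=provenance)


def read_sumstats(path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics file missing columns: {missing}")
    return df


def write_ld_matrix(ld: LDMatrix, path, provenance: dict | None = None) -> None:
    df = pd.DataFrame(ld.R, columns=ld.variant_ids)
    write_table(df, path, provenance=provenance)


def read_ld_matrix(path) -> LDMatrix:
    df = read_table(path)
    return LDMatrix(list(df.columns), df.to_numpy(float))


def write_scoring_file(weights: ScoreWeights, path,
                       provenance: dict | None = None) -> None:
    cols = SCORING_COLUMNS + [c for c in ("signal", "effect_allele_freq")
                              if c in weights.table.columns]
    write_table(weights.table[cols], path, provenance=provenance)


def read_scoring_file(path) -> ScoreWeights:
    return ScoreWeights(table=read_table(path))


def write_lab_series(series: list[LabSeries], path,
                     provenance: dict | None = None) -> None:
    rows = []
    for s in series:
        for d, v in zip(s.days, s.tsh):
            rows.append((s.patient_id, float(d), float(v), "", ""))
        for cls, day in s.symptomatic_days.items():
            rows.append((s.patient_id, float(day), np.nan, cls, "symptomatic"))
    df = pd.DataFrame(rows, columns=["patient_id", "day", "tsh", "event_class", "kind"])
    write_table(df, path, sep=",", provenance=provenance)


def read_lab_series(path) -> list[LabSeries]:
    df = read_table(path, sep=",")
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        labs = grp[grp["kind"] != "symptomatic"].sort_values("day")
        sym = grp[grp["kind"] == "symptomatic"]
        out.append(LabSeries(
            patient_id=str(pid),
            days=labs["day"].to_numpy(float),
            tsh=labs["tsh"].to_numpy(float),
            symptomatic_days={str(r["event_class"]): float(r["day"])
                              for _, r in sym.iterrows()},
        ))
    return out


def read_gene_table(path) -> pd.DataFrame:
    """Gene table with columns chrom, tss, strand, name.

    A BED-like 0-based ``tss`` column named ``tss0`` is converted to the
    1-based closed convention used everywhere else.
    """
    df = read_table(path)
    if "tss0" in df.columns:
        df = df.rename(columns={"tss0": "tss"})
        df["tss"] = df["tss"].astype(int) + 1
    need = {"chrom", "tss", "name"}
    if not need <= set(df.columns):
        raise ValueError(f"gene table must have columns {sorted(need)}")
    return df


def write_vcf(
    path,
    variants: pd.DataFrame,
    gt: np.ndarray,
    sample_ids: list[str],
    ad_ref: np.ndarray | None = None,
    ad_alt: np.ndarray | None = None,
    gq: np.ndarray | None = None,
) -> None:
    """Write biallelic SNV calls with GT:AD:GQ per sample.

    Depths default to an idealised 15/15 het, 30/0 hom profile and GQ to 99
    when not supplied (synthetic genotypes carry no read-level data).
    """
    n, m = gt.shape
    if len(sample_ids) != n or len(variants) != m:
        raise ValueError("shape mismatch between genotypes, samples and variants")
    contigs = list(dict.fromkeys(variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j in range(m):
            v = variants.iloc[j]
            calls = []
            for i in range(n):
                g = int(gt[i, j])
                if ad_ref is not None:
                    ar, aa = int(ad_ref[i, j]), int(ad_alt[i, j])
                else:
                    ar, aa = {0: (30, 0), 1: (15, 15), 2: (0, 30)}.get(g, (0, 0))
                q = int(gq[i, j]) if gq is not None else 99
                calls.append(f"{_GT_STR[g]}:{ar},{aa}:{q}")
            fh.write(f"{v['chrom']}\t{int(v['pos'])}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                     f"\t.\tPASS\t.\tGT:AD:GQ\t" + "\t".join(calls) + "\n")


def read_vcf(path) -> tuple[GenotypeCallMatrix, pd.DataFrame]:
    """Read biallelic SNV calls into a call matrix plus a variant table."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    gts, ars, aas, gqs, rows = [], [], [], [], []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        rows.append((rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}",
                     rec.REF, alt))
        g = np.array([a + b if (a >= 0 and b >= 0) else MISSING
                      for a, b, *_ in rec.genotypes], dtype=np.int8)
        ad = rec.format("AD")
        gq = rec.format("GQ")
        gts.append(g)
        ars.append(ad[:, 0] if ad is not None else np.zeros(len(samples), int))
        aas.append(ad[:, 1] if ad is not None else np.zeros(len(samples), int))
        gqs.append(gq.reshape(-1) if gq is not None else np.full(len(samples), 99))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    calls = GenotypeCallMatrix(
        gt=np.column_stack(gts).astype(np.int8),
        ad_ref=np.column_stack(ars).astype(int),
        ad_alt=np.column_stack(aas).astype(int),
        gq=np.column_stack(gqs).astype(int),
        variant_ids=list(variants["id"]),
        sample_ids=samples,
    )
    return calls, variants
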