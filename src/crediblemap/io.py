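"""File formats: VCF v4.2 genotypes and tab-separated stage tables.

Reading goes through cyvcf2; writing emits minimal VCF v4.2 text with GT
(hard calls) or DS (dosage) FORMAT fields.  All tabular stage outputs are
TSV with a header row, optionally preceded by ``# key=value`` comment
lines stamping the run configuration.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_table",
    "write_table",
]


def read_vcf(
    path: str | Path,
    dosage: bool = False,
    strict_biallelic: bool = True,
) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into a `GenotypeMatrix`.

    GT is parsed to {0, 1, 2, NaN}; with ``dosage`` the DS FORMAT field is
    used instead.  Multiallelic records are rejected under
    ``strict_biallelic`` (naming the record) and skipped otherwise.  A
    per-variant imputation quality is picked up from the INFO ``R2`` key
    when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.array(vcf.samples, dtype=object)
    columns, ids, positions, chroms, refs, alts, r2s = [], [], [], [], [], [], []
    any_r2 = False
    for rec in vcf:
        if len(rec.ALT) != 1:
            if strict_biallelic:
                raise ValueError(
                    f"multiallelic record at {rec.CHROM}:{rec.POS} "
                    f"({rec.ID or '.'}); split or drop it first"
                )
            continue
        if dosage:
            try:
                ds = rec.format("DS")
            except KeyError:
                ds = None
            if ds is None:
                raise ValueError(
                    f"record at {rec.CHROM}:{rec.POS} has no DS field"
                )
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = np.asarray(rec.gt_types, dtype=float)
            col = np.choose(gt.astype(int), [0.0, 1.0, np.nan, 2.0])
        columns.append(col)
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        positions.append(rec.POS)
        chroms.append(rec.CHROM)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        r2 = rec.INFO.get("R2")
        r2s.append(np.nan if r2 is None else float(r2))
        any_r2 = any_r2 or r2 is not None
    vcf.close()
    if not columns:
        raise ValueError(f"no usable biallelic records in {path}")
    return GenotypeMatrix(
        genotypes=np.column_stack(columns),
        variant_ids=np.array(ids, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        sample_ids=sample_ids,
        chrom=np.array(chroms, dtype=object),
        info_r2=np.array(r2s, dtype=float) if any_r2 else None,
        dosage=dosage,
    )


_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path, dosage: bool = False) -> None:
    """Write a `GenotypeMatrix` as VCF v4.2 text (GT, or DS when ``dosage``)."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation r2">\n')
    if dosage:
        buf.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
    else:
        buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for contig in pd.unique(g.chrom):
        buf.write(f"##contig=<ID={contig}>\n")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    buf.write("\t".join(header_cols + [str(s) for s in g.sample_ids]) + "\n")
    fmt = "DS" if dosage else "GT"
    for j in range(g.n_variants):
        info = "."
        if g.info_r2 is not None and not np.isnan(g.info_r2[j]):
            info = f"R2={g.info_r2[j]:g}"
        fields = [
            str(g.chrom[j]),
            str(int(g.positions[j])),
            str(g.variant_ids[j]),
            str(g.ref[j]),
            str(g.alt[j]),
            ".",
            "PASS",
            info,
            fmt,
        ]
        col = g.genotypes[:, j]
        if dosage:
            calls = ["." if np.isnan(x) else f"{x:g}" for x in col]
        else:
            calls = ["./." if np.isnan(x) else _GT_CODES[float(x)] for x in col]
        buf.write("\t".join(fields + calls) + "\n")
    path.write_text(buf.getvalue())


def write_table(
    df: pd.DataFrame, path: str | Path, header_meta: dict | None = None
) -> None:
    """TSV with a header row, preceded by ``# key=value`` stamp lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
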