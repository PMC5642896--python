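"""File interchange: VCF genotypes, sample sheets, panel configs.

Genotypes travel as VCF 4.2 with GT fields; the counted (dosage) allele is
written as ALT, so a dosage of 2 becomes ``1/1`` and missing becomes
``./.``.  Reading uses cyvcf2 and counts ALT copies.  Sample sheets are
tab-separated with the header ``sample_id sex ethnicity status grade age``.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import MISSING, GenotypeMatrix, SampleRecord, VariantRecord, frame_to_samples, samples_to_frame

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write the matrix as a minimal VCF 4.2 with GT genotypes."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgxvalidity\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if any(v.gene for v in matrix.variants):
            fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
        seen: list[str] = []
        for v in matrix.variants:
            if v.chrom not in seen:
                seen.append(v.chrom)
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, v in enumerate(matrix.variants):
            info = f"GENE={v.gene}" if v.gene else "."
            gts = "\t".join(_GT[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.other_allele}\t{v.counted_allele}"
                f"\t.\t.\t{info}\tGT\t{gts}\n"
            )
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, counting ALT-allele copies."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else None
        if alt is None or len(alt) != 1 or len(rec.REF) != 1:
            continue  # biallelic SNVs only
        gene = rec.INFO.get("GENE")
        variants.append(
            VariantRecord(
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                counted_allele=alt,
                other_allele=rec.REF,
                gene=gene,
            )
        )
        col = np.full(len(sample_ids), MISSING, dtype=np.int16)
        for i, g in enumerate(rec.genotypes):
            alleles = [a for a in g[:-1] if a >= 0]
            if len(alleles) == 2:
                col[i] = sum(1 for a in alleles if a == 1)
        columns.append(col)
    vcf.close()
    calls = np.column_stack(columns) if columns else np.empty((len(sample_ids), 0), dtype=np.int16)
    return GenotypeMatrix(sample_ids, variants, calls)


def write_sample_sheet(samples: list[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    samples_to_frame(samples).to_csv(path, sep="\t", index=False)
    return path


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "sex", "ethnicity", "status", "grade", "age"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return frame_to_samples(frame)


def write_yaml(obj, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path


def read_yaml(path: str | Path):
    with Path(path).open() as fh:
        return yaml.safe_load(fh)
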