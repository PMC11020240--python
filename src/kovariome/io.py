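"""Reading and writing the on-disk formats: VCF 4.2 (GT + AD), TSV tables."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .cohort import MISSING, GenotypeMatrix


def write_vcf(
    genotypes: GenotypeMatrix,
    path: str | os.PathLike,
    read_counts: tuple[np.ndarray, np.ndarray] | None = None,
) -> None:
    """Write genotypes (and optional per-call AD/DP) as an uncompressed VCF.

    ``read_counts`` is a pair of ``(ref_reads, alt_reads)`` arrays shaped
    like the dosage matrix.
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if read_counts is not None:
        header.add_line(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">'
        )
        header.add_line(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
        )
    meta = genotypes.variant_meta
    for chrom in pd.unique(meta["chrom"].astype(str)):
        maxpos = int(meta.loc[meta["chrom"].astype(str) == chrom, "pos"].max())
        header.contigs.add(chrom, length=maxpos + 1000)
    for sid in genotypes.sample_ids:
        header.add_sample(sid)

    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(genotypes.n_variants):
            row = meta.iloc[j]
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]) - 1 + len(row["ref"]),
                alleles=(str(row["ref"]), str(row["alt"])),
                id=(str(row["id"]) if "id" in row and pd.notna(row["id"]) else None),
            )
            for i, sid in enumerate(genotypes.sample_ids):
                g = int(genotypes.dosages[i, j])
                rec.samples[sid]["GT"] = gt_codes[g]
                if read_counts is not None:
                    ref_r = int(read_counts[0][i, j])
                    alt_r = int(read_counts[1][i, j])
                    rec.samples[sid]["AD"] = (ref_r, alt_r)
                    rec.samples[sid]["DP"] = ref_r + alt_r
            out.write(rec)


def read_vcf(
    path: str | os.PathLike, with_read_counts: bool = False
) -> GenotypeMatrix | tuple[GenotypeMatrix, tuple[np.ndarray, np.ndarray]]:
    """Load a biallelic-record VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are split implicitly by cyvcf2 only if normalized
    upstream; records with more than one ALT raise.
    """
    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    rows = []
    dosage_cols = []
    ref_cols: list[np.ndarray] = []
    alt_cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"non-biallelic record at {rec.CHROM}:{rec.POS}")
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "id": rec.ID,
            }
        )
        gt = rec.gt_types.astype(np.int8)  # 0,1,2 and 3=missing under gts012
        gt[gt == 3] = MISSING
        dosage_cols.append(gt)
        if with_read_counts:
            ad = rec.format("AD")
            if ad is None:
                raise ValueError("VCF lacks AD field required for read counts")
            ad = np.where(ad < 0, 0, ad)
            ref_cols.append(ad[:, 0].astype(np.int32))
            alt_cols.append(ad[:, 1].astype(np.int32))
    vcf.close()
    gm = GenotypeMatrix(
        np.column_stack(dosage_cols).astype(np.int8),
        pd.DataFrame(rows),
        sample_ids,
    )
    if with_read_counts:
        return gm, (np.column_stack(ref_cols), np.column_stack(alt_cols))
    return gm


def write_trait_table(traits: pd.DataFrame, path: str | os.PathLike) -> None:
    traits.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_trait_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
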