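"""Biallelic SNP genotype container and VCF v4.2 I/O (GT subfield only)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """0/1/2 alt-allele dosages, one row per sample, one column per variant.

    Missing genotypes are NaN.  ``variants`` has columns chrom, pos (1-based),
    id, ref, alt with non-decreasing positions within each chromosome.
    """

    samples: list
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage matrix shape mismatch with samples/variants")
        for _, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be non-decreasing within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per variant from non-missing dosages."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        v = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            [self.samples[i] for i in s],
            self.variants.iloc[v].reset_index(drop=True),
            self.dosages[np.ix_(s, v)],
        )


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a plain-text VCF v4.2 with GT-only genotype fields."""
    contigs = list(dict.fromkeys(gm.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lactgwas\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in gm.samples)
            + "\n"
        )
        D = gm.dosages
        for j, v in enumerate(gm.variants.itertuples(index=False)):
            gts = "\t".join(
                "./." if np.isnan(D[i, j]) else _GT_CODE[D[i, j]]
                for i in range(gm.n_samples)
            )
            fh.write(
                f"{v.chrom}\t{int(v.pos)}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0,1,2 dosage; 3 unknown
    samples = [int(s) if s.isdigit() else s for s in vcf.samples]
    rows = []
    dosages = []
    for var in vcf:
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID if var.ID else f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
        gt = var.gt_types.astype(float)
        gt[gt == 3] = np.nan
        dosages.append(gt)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    D = np.array(dosages).T if dosages else np.zeros((len(samples), 0))
    return GenotypeMatrix(samples, variants, D)
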