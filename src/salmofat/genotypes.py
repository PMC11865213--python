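"""Sample x SNP dosage container with map metadata and VCF/TSV round-trips.

Dosages are coded 0 = AA, 1 = AB|BA, 2 = BB on the second (B) allele and
stored as floats with ``NaN`` marking missing calls.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

_ALLOWED = np.array([0.0, 1.0, 2.0])


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x SNPs) plus a SNP map.

    ``snp_map`` carries one row per SNP with at least ``snp_id``, ``chrom``,
    ``pos`` (1-based), ``a1``, ``a2``; extra columns (e.g. the simulator's
    truth labels) travel along untouched. ``founder_dosages`` is populated by
    the simulator so pedigree-transmission invariants remain checkable.
    """

    sample_ids: np.ndarray
    dosages: np.ndarray  # (n_samples, n_snps) float, NaN = missing
    snp_map: pd.DataFrame
    founder_ids: np.ndarray | None = None
    founder_dosages: np.ndarray | None = None
    _freq_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_map)):
            raise AlignmentError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_map)} SNPs"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, _ALLOWED).all():
            raise FormatError("dosages must be in {0, 1, 2} or NaN")
        if self.snp_map["snp_id"].duplicated().any():
            raise FormatError("snp_ids must be unique")
        if (self.snp_map["pos"] < 1).any():
            raise FormatError("positions must be >= 1 (1-based)")
        self.snp_map = self.snp_map.reset_index(drop=True)

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["snp_id"].to_numpy()

    def allele_freq(self) -> np.ndarray:
        """Frequency of the second (B) allele per SNP over non-missing calls."""
        if self._freq_cache is None:
            with np.errstate(invalid="ignore"):
                self._freq_cache = np.nanmean(self.dosages, axis=0) / 2.0
        return self._freq_cache

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    # -- subsetting --------------------------------------------------------

    def subset_samples(self, ids) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise AlignmentError(f"samples not in genotype matrix: {missing[:5]}")
        rows = np.array([index[s] for s in ids])
        return GenotypeMatrix(
            np.asarray(list(ids), dtype=object),
            self.dosages[rows],
            self.snp_map.copy(),
        )

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            keep = self.snp_map["snp_id"].isin(mask).to_numpy()
        else:
            keep = mask
        return GenotypeMatrix(
            self.sample_ids.copy(),
            self.dosages[:, keep],
            self.snp_map.loc[keep].reset_index(drop=True),
        )

    # -- I/O: dosage TSV ---------------------------------------------------

    def to_tsv(self, prefix: str) -> None:
        """Write ``<prefix>.dosage.tsv`` (samples x SNPs, NA = missing) and
        ``<prefix>.map.tsv``."""
        df = pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)
        df.index.name = "individual_id"
        df.to_csv(prefix + ".dosage.tsv", sep="\t", na_rep="NA")
        self.snp_map.to_csv(prefix + ".map.tsv", sep="\t", index=False)

    @classmethod
    def from_tsv(cls, prefix: str) -> "GenotypeMatrix":
        df = pd.read_csv(prefix + ".dosage.tsv", sep="\t", index_col=0)
        snp_map = pd.read_csv(prefix + ".map.tsv", sep="\t")
        if list(df.columns) != list(snp_map["snp_id"]):
            raise FormatError("dosage columns and map rows disagree")
        return cls(df.index.to_numpy(object), df.to_numpy(float), snp_map)

    # -- I/O: VCF ----------------------------------------------------------

    def to_vcf(self, path: str) -> None:
        """Write an unphased diploid GT-only VCF (uncompressed text)."""
        p = self.allele_freq()
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in pd.unique(self.snp_map["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, self.sample_ids))
                + "\n"
            )
            gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            for j, row in self.snp_map.iterrows():
                calls = [
                    "./." if np.isnan(d) else gt_codes[d] for d in self.dosages[:, j]
                ]
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                    f"{row.get('a1', 'A')}\t{row.get('a2', 'B')}\t.\t.\t.\tGT\t"
                    + "\t".join(calls)
                    + "\n"
                )
        del p

    @classmethod
    def from_vcf(cls, path: str) -> "GenotypeMatrix":
        from cyvcf2 import VCF

        if not os.path.exists(path):
            raise FormatError(f"no such VCF: {path}")
        vcf = VCF(path)
        samples = np.asarray(vcf.samples, dtype=object)
        rows, dosage_cols = [], []
        for variant in vcf:
            gts = np.asarray(variant.gt_types, dtype=float)
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            dos = np.where(gts == 3, 2.0, gts)
            dos[gts == 2] = np.nan
            dosage_cols.append(dos)
            rows.append(
                {
                    "snp_id": variant.ID,
                    "chrom": variant.CHROM,
                    "pos": variant.POS,
                    "a1": variant.REF,
                    "a2": variant.ALT[0] if variant.ALT else ".",
                }
            )
        if not rows:
            raise FormatError(f"VCF {path} contains no variants")
        return cls(samples, np.column_stack(dosage_cols), pd.DataFrame(rows))
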