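"""Genotype container and plain-text genotype I/O.

Genotypes are held as additive minor-allele dosages (0/1/2, NaN for a
missing call) in a samples x SNPs matrix, with per-SNP metadata
(chromosome, position, alleles) alongside.  This is the in-memory shape
every downstream stage (QC, LD, interaction testing) operates on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix with missingness.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2}`` and ``NaN`` marking missing calls.
    sample_ids
        Sample identifiers, one per row.
    snps
        Per-SNP metadata frame with columns ``snp_id, chrom, pos, ref, alt``;
        one row per dosage column, in column order.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    snps: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length must match dosage rows")
        if len(self.snps) != self.dosages.shape[1]:
            raise ValueError("snps metadata must match dosage columns")
        missing_cols = [c for c in SNP_META_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"snps metadata missing columns: {missing_cols}")
        self.snps = self.snps.reset_index(drop=True)
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy(dtype=object)

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(f"unknown SNP id: {snp_id!r}")
        return int(idx[0])

    def dosage_vector(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]

    # ------------------------------------------------------------- statistics
    def call_rate_per_snp(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def call_rate_per_sample(self) -> np.ndarray:
        """Fraction of non-missing calls per sample."""
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP coded-allele frequency f = mean(dosage) / 2 over calls.

        SNPs with zero non-missing calls get NaN.
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Folded minor allele frequency min(f, 1 - f)."""
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(n_hom_major, n_het, n_hom_minor)-style counts by dosage 0/1/2."""
        g = self.dosage_vector(snp_id)
        return (
            int(np.nansum(g == 0)),
            int(np.nansum(g == 1)),
            int(np.nansum(g == 2)),
        )

    # --------------------------------------------------------------- indexing
    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Subset by boolean mask or sample-ID array (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            rows = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            rows = np.array([pos[s] for s in keep], dtype=int)
        return GenotypeMatrix(
            self.dosages[rows], self.sample_ids[rows], self.snps.copy()
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Subset by boolean mask or SNP-ID array (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            cols = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.snp_ids)}
            cols = np.array([pos[s] for s in keep], dtype=int)
        return GenotypeMatrix(
            self.dosages[:, cols],
            self.sample_ids,
            self.snps.iloc[cols].reset_index(drop=True),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(), self.sample_ids.copy(), self.snps.copy()
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.dosages, other.dosages, equal_nan=True)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and self.snps.equals(other.snps)
        )


# ---------------------------------------------------------------------- I/O
def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write genotypes as a minimal plain-text VCF 4.2 with GT fields.

    The coded (dosage-counted) allele is written as ALT, so dosage equals
    the ALT-allele count of the GT field.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = [
            "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
            "FORMAT",
        ]
        header += [str(s) for s in G.sample_ids]
        fh.write("\t".join(header) + "\n")
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, row in G.snps.iterrows():
            calls = [
                "./." if np.isnan(d) else gt_codes[d] for d in G.dosages[:, j]
            ]
            rec = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(row["snp_id"]),
                str(row["ref"]),
                str(row["alt"]),
                ".",
                ".",
                ".",
                "GT",
            ] + calls
            fh.write("\t".join(rec) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (ALT-allele dosages from GT)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = np.array(vcf.samples, dtype=object)
    dosage_cols, meta = [], []
    for rec in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(float)
        d = np.where(gt == 3, 2.0, gt)
        d[gt == 2] = np.nan
        dosage_cols.append(d)
        meta.append(
            (rec.ID, rec.CHROM, rec.POS, rec.REF, rec.ALT[0] if rec.ALT else ".")
        )
    vcf.close()
    snps = pd.DataFrame(meta, columns=SNP_META_COLUMNS)
    dosages = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.empty((len(sample_ids), 0))
    )
    return GenotypeMatrix(dosages, sample_ids, snps)


def write_dosage_tsv(G: GenotypeMatrix, path: str) -> None:
    """Rectangular dosage TSV: rows = samples, header = SNP IDs."""
    df = pd.DataFrame(G.dosages, columns=G.snp_ids, index=G.sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path: str, snps: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a rectangular dosage TSV; SNP metadata optional.

    Without a metadata frame, chromosome/position/allele columns are
    filled with placeholders (chrom '0', positions in column order).
    """
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values="NA")
    if snps is None:
        snps = pd.DataFrame(
            {
                "snp_id": df.columns,
                "chrom": "0",
                "pos": np.arange(1, df.shape[1] + 1),
                "ref": "A",
                "alt": "B",
            }
        )
    return GenotypeMatrix(
        df.to_numpy(dtype=float), df.index.to_numpy(dtype=object), snps
    )


def snp_meta_frame(
    snp_ids, chrom="1", pos=None, ref="A", alt="B"
) -> pd.DataFrame:
    """Convenience constructor for the SNP metadata frame."""
    snp_ids = list(snp_ids)
    if pos is None:
        pos = np.arange(1, len(snp_ids) + 1)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": np.broadcast_to(np.asarray(chrom, dtype=object), len(snp_ids)).copy(),
            "pos": np.asarray(pos, dtype=int),
            "ref": np.broadcast_to(np.asarray(ref, dtype=object), len(snp_ids)).copy(),
            "alt": np.broadcast_to(np.asarray(alt, dtype=object), len(snp_ids)).copy(),
        }
    )


def to_stream_tsv(df: pd.DataFrame) -> str:
    """Deterministic TSV rendering used by the CLI writers."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, na_rep="NA")
    return buf.getvalue()
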