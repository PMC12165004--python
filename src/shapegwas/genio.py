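"""Genotype container and PLINK1/VCF input-output.

Dosages are additive minor/alt-allele counts in {0, 1, 2}; missing calls are
NaN and must be removed by QC before association.  The PLINK1 binary triple
(.bed/.bim/.fam) is read and written directly: the .bed payload is the
standard SNP-major 2-bit encoding (magic bytes 0x6c 0x1b, mode 0x01).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_plink", "write_plink", "read_vcf"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> dosage of the A1 (minor) allele
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class GenotypeMatrix:
    """N individuals x P variants of additive dosages with variant metadata.

    Attributes
    ----------
    dosage : (n, p) float array with entries in {0, 1, 2} or NaN (missing).
    variants : DataFrame with columns chrom, pos, id, ref, alt (one row per
        variant, aligned with dosage columns).
    sample_ids : length-n list of individual identifiers.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-dimensional")
        if len(self.variants) != self.dosage.shape[1]:
            raise ValueError(
                f"variant table has {len(self.variants)} rows but dosage has "
                f"{self.dosage.shape[1]} columns"
            )
        if not self.sample_ids:
            self.sample_ids = [f"ind{i}" for i in range(self.dosage.shape[0])]
        if len(self.sample_ids) != self.dosage.shape[0]:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Per-variant frequency of the counted (alt) allele, ignoring missing."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=0)

    def take_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[:, mask],
            variants=self.variants.loc[np.asarray(mask)].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a .bed/.bim/.fam triple (SNP-major PLINK1 layout)."""
    prefix = Path(prefix)
    n, p = g.dosage.shape

    bim = pd.DataFrame(
        {
            "chrom": g.variants["chrom"],
            "id": g.variants["id"],
            "cm": 0,
            "pos": g.variants["pos"],
            "a1": g.variants["alt"],
            "a2": g.variants["ref"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": g.sample_ids,
            "iid": g.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    # dosage of A1 -> 2-bit codes: 0 copies -> 0b11, 1 -> 0b10, 2 -> 0b00,
    # missing -> 0b01
    codes = np.full((p, n), 0b01, dtype=np.uint8)
    d = g.dosage.T
    codes[d == 0] = 0b11
    codes[d == 1] = 0b10
    codes[d == 2] = 0b00
    n_bytes = (n + 3) // 4
    padded = np.zeros((p, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shaped = padded.reshape(p, n_bytes, 4)
    packed = (
        shaped[:, :, 0]
        | (shaped[:, :, 1] << 2)
        | (shaped[:, :, 2] << 4)
        | (shaped[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a .bed/.bim/.fam triple into a GenotypeMatrix (A1 dosage)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK1 .bed file")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if len(body) != p * n_bytes:
        raise ValueError(f"{prefix}.bed: unexpected payload size")
    body = body.reshape(p, n_bytes)
    # unpack 2-bit fields, little-endian within each byte
    codes = np.empty((p, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosage = _BED_DECODE[codes[:, :n]].T
    variants = pd.DataFrame(
        {
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "id": bim["id"],
            "ref": bim["a2"],
            "alt": bim["a1"],
        }
    )
    return GenotypeMatrix(
        dosage=dosage, variants=variants, sample_ids=list(fam["iid"])
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic variants from a VCF; dosage = alt-allele count from GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(np.float64)
        d = np.where(gt == 3, 2.0, gt)
        d[gt == 2] = np.nan
        rows.append(d)
        meta.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    if not rows:
        raise ValueError(f"{path}: no biallelic variants found")
    return GenotypeMatrix(
        dosage=np.column_stack(rows),
        variants=pd.DataFrame(meta),
        sample_ids=samples,
    )
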