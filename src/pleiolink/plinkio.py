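"""Minimal PLINK 1.9 .bed/.bim/.fam writer/reader plus TSV side files.

Only biallelic markers (neutral SNPs and QTNs) are representable;
continuum-of-alleles QTL are exported to a separate TSV. The .bed payload is
SNP-major (magic bytes 0x6c 0x1b 0x01): per SNP, individuals are packed four
to a byte, two bits each, with codes 00 = homozygous A1 (dosage 2 of the
minor allele A1), 10 = heterozygous, 11 = homozygous A2, 01 = missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .gwaa import GenotypeSample

__all__ = ["export_plink", "export_qtl_values", "read_plink", "load_sample"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# dosage of A1 -> 2-bit code
_CODE_OF_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11}
_DOSAGE_OF_CODE = {0b00: 2, 0b10: 1, 0b11: 0}


def _pack_bed(dosage: np.ndarray) -> bytes:
    """Pack an (n, M) dosage matrix into SNP-major .bed payload bytes."""
    n, M = dosage.shape
    nbytes = (n + 3) // 4
    out = np.zeros((M, nbytes), dtype=np.uint8)
    codes = np.zeros_like(dosage, dtype=np.uint8)
    for d, c in _CODE_OF_DOSAGE.items():
        codes[dosage == d] = c
    for i in range(n):
        out[:, i // 4] |= codes[i, :] << np.uint8(2 * (i % 4))
    return out.tobytes()


def _unpack_bed(payload: bytes, n: int, M: int) -> np.ndarray:
    raw = np.frombuffer(payload, dtype=np.uint8).reshape(M, (n + 3) // 4)
    dosage = np.zeros((n, M), dtype=np.int8)
    for i in range(n):
        code = (raw[:, i // 4] >> (2 * (i % 4))) & 0b11
        if np.any(code == 0b01):
            raise ValueError("missing genotypes are not supported")
        col = np.zeros(M, dtype=np.int8)
        for c, d in _DOSAGE_OF_CODE.items():
            col[code == c] = d
        dosage[i] = col
    return dosage


def export_plink(sample: GenotypeSample, prefix) -> None:
    """Write <prefix>.bed/.bim/.fam plus phenotype and truth TSVs.

    Dosages must be 0/1/2 minor-allele counts (A1 = minor allele). Raises if
    the sample carries no biallelic markers.
    """
    prefix = Path(prefix)
    G = np.asarray(sample.genotypes)
    if G.size == 0 or G.shape[1] == 0:
        raise ValueError(
            "no biallelic markers to export; continuum-of-alleles QTL are "
            "written to the qtl_values TSV instead"
        )
    if not np.isin(G, [0, 1, 2]).all():
        raise ValueError("dosages must be 0/1/2; multiallelic loci are not exportable")
    n, M = G.shape
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(_pack_bed(G))
    bim = pd.DataFrame(
        {
            "chrom": sample.marker_map["chrom"].to_numpy() + 1,
            "id": sample.marker_map["marker"],
            "cM": sample.marker_map["cM"],
            "bp": (sample.marker_map["cM"] * 1e4).round().astype(int) + 1,
            "a1": "A",
            "a2": "T",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": np.arange(n),
            "iid": np.arange(n),
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    pheno = pd.DataFrame(
        {
            "FID": np.arange(n),
            "IID": np.arange(n),
            "trait1": sample.phenotypes[:, 0],
            "trait2": sample.phenotypes[:, 1],
        }
    )
    pheno.to_csv(str(prefix) + ".pheno.tsv", sep="\t", index=False)
    sample.truth.to_csv(str(prefix) + ".truth.tsv", sep="\t", index=False)


def export_qtl_values(sample: GenotypeSample, path) -> None:
    """Write continuum-of-alleles QTL haplotype values as a long-format TSV.

    These loci are multiallelic real-valued and cannot be represented in
    PLINK files; columns: IID, haplotype (0/1), locus id, effect_trait1,
    effect_trait2.
    """
    if sample.qtl_values is None or sample.qtl_map is None:
        raise ValueError("sample carries no haplotype-level QTL values")
    n, _, L, _ = sample.qtl_values.shape
    iid = np.repeat(np.arange(n), 2 * L)
    hap = np.tile(np.repeat([0, 1], L), n)
    locus = np.tile(sample.qtl_map["id"].to_numpy(), 2 * n)
    flat = sample.qtl_values.reshape(-1, 2)
    pd.DataFrame(
        {
            "IID": iid,
            "haplotype": hap,
            "locus": locus,
            "effect_trait1": flat[:, 0],
            "effect_trait2": flat[:, 1],
        }
    ).to_csv(path, sep="\t", index=False)


def read_plink(prefix):
    """Read a .bed/.bim/.fam triplet -> (dosage (n, M) int8, bim, fam)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cM", "bp", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    with open(prefix.with_suffix(".bed"), "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError("not a SNP-major PLINK .bed file")
        payload = fh.read()
    return _unpack_bed(payload, len(fam), len(bim)), bim, fam


def load_sample(prefix) -> GenotypeSample:
    """Load an exported sample (PLINK triplet + phenotype/truth TSVs).

    Lets the association stage run standalone on externally simulated data;
    haplotype-level arrays are unavailable, so LD metrics against
    continuum QTL are skipped for such samples.
    """
    prefix = Path(prefix)
    dosage, bim, fam = read_plink(prefix)
    pheno = pd.read_csv(str(prefix) + ".pheno.tsv", sep="\t")
    truth = pd.read_csv(str(prefix) + ".truth.tsv", sep="\t")
    marker_map = pd.DataFrame(
        {
            "marker": bim["id"],
            "chrom": bim["chrom"] - 1,
            "cM": bim["cM"],
            "role": "neutral",
        }
    )
    return GenotypeSample(
        genotypes=dosage,
        phenotypes=pheno[["trait1", "trait2"]].to_numpy(),
        marker_map=marker_map,
        truth=truth,
    )
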