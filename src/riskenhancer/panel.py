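"""Phased haplotype panels and linkage disequilibrium from haplotype counts.

A panel stores one population's phased alleles as a (2n_samples, n_variants)
0/1 matrix together with variant metadata.  r-squared between two variants is
computed by direct haplotype counting,

    r2 = D^2 / (pA (1-pA) pB (1-pB)),   D = p_AB - pA * pB,

which is exact for phased data and needs no EM step.  Unphased input is
rejected on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


class MonomorphicVariantError(ValueError):
    """LD is undefined for a variant with no allelic variation."""


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes (rows) by variants (columns) for one population.

    ``variants`` is a DataFrame with columns id, chrom, pos (1-based), ref,
    alt; ``haplotypes`` has shape (2 * n_samples, n_variants); 0 codes the
    reference allele.
    """

    population: str
    variants: pd.DataFrame
    haplotypes: np.ndarray
    sample_names: list[str] | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes, dtype=np.int8)
        if h.ndim != 2 or h.shape[0] % 2:
            raise ValueError("haplotypes must be a (2n, m) matrix")
        if not np.isin(h, (0, 1)).all():
            raise ValueError("haplotypes must be coded 0/1 (biallelic)")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        if len(self.variants) != h.shape[1]:
            raise ValueError("variant table and haplotype matrix disagree on size")
        if self.variants["id"].duplicated().any():
            raise ValueError("variant ids must be unique within a panel")
        self.haplotypes = h
        self.variants = self.variants.reset_index(drop=True)
        self._index = {v: i for i, v in enumerate(self.variants["id"])}

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.haplotypes[:, self._index[variant_id]]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel {self.population!r}")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def allele_frequency(self, variant_id: str) -> float:
        return float(self.column(variant_id).mean())


def r2_from_columns(a: np.ndarray, b: np.ndarray) -> float:
    """r-squared between two phased 0/1 haplotype columns by counting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("haplotype columns differ in length")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise MonomorphicVariantError("r2 undefined for a monomorphic variant")
    pab = np.mean(a * b)
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def pairwise_r2(panel: HaplotypePanel, a: str, b: str) -> float:
    """LD between two variants of a panel; symmetric, in [0, 1]."""
    return r2_from_columns(panel.column(a), panel.column(b))


# ---------------------------------------------------------------------------
# VCF IO (one file per population; phased GT required)
# ---------------------------------------------------------------------------

def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as a minimal phased VCF (GT only)."""
    n = panel.n_samples
    samples = panel.sample_names or [f"{panel.population}_s{i}" for i in range(n)]
    chroms = panel.variants["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=riskenhancer (population {panel.population})\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        h = panel.haplotypes
        for j, row in panel.variants.iterrows():
            gts = "\t".join(f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(n))
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path, population: str) -> HaplotypePanel:
    """Read a phased VCF into a panel; unphased genotypes are rejected."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    columns = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic site at {var.CHROM}:{var.POS}; split first")
        gts = np.asarray(var.genotype.array())
        if gts.shape[1] < 3 or not np.all(gts[:, 2]):
            raise ValueError(
                f"unphased genotype at {var.CHROM}:{var.POS}: phased GT required "
                "for haplotype-counting LD"
            )
        alleles = gts[:, :2]
        if np.any(alleles < 0):
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        columns.append(alleles.reshape(-1))
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    hap = (np.column_stack(columns) if columns
           else np.empty((2 * len(samples), 0), dtype=np.int8))
    return HaplotypePanel(population, variants, hap, sample_names=samples)
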