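"""Data containers and text-format I/O.

Read counts come either from a VCF with a per-sample AD field (via cyvcf2,
optional) or from a TSV matrix with columns ``snp_id  contig  bp`` followed
by one ``ref:alt`` pair per sample.  Sample tables and habitat surveys are
CSV; the linkage map is a TSV with columns ``contig  bp  lg  cm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import LinkageMap
from .exceptions import ConfigurationError

__all__ = [
    "SnpReadMatrix",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_vcf_ad",
    "read_samples_csv",
    "read_habitat_csv",
    "read_map_tsv",
]


@dataclass
class SnpReadMatrix:
    """Per-individual (ref, alt) read depths for biallelic SNPs."""

    snp_id: np.ndarray  # (n_snps,) str
    contig: np.ndarray  # (n_snps,) str
    bp: np.ndarray  # (n_snps,) int, 1-based
    ref: np.ndarray  # (n_snps, n_ind) int
    alt: np.ndarray  # (n_snps, n_ind) int
    samples: list = field(default_factory=list)
    lg: np.ndarray | None = None
    cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        if self.ref.shape != self.alt.shape:
            raise ConfigurationError("ref/alt matrices must have equal shape")
        if np.any(self.ref < 0) or np.any(self.alt < 0):
            raise ConfigurationError("read depths must be non-negative")

    @property
    def n_snps(self) -> int:
        return self.ref.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.ref.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    def subset(self, snp_mask) -> "SnpReadMatrix":
        m = np.asarray(snp_mask)
        return SnpReadMatrix(
            snp_id=self.snp_id[m], contig=self.contig[m], bp=self.bp[m],
            ref=self.ref[m], alt=self.alt[m], samples=self.samples,
            lg=None if self.lg is None else self.lg[m],
            cm=None if self.cm is None else self.cm[m],
        )

    def site_table(self) -> pd.DataFrame:
        df = pd.DataFrame({"snp_id": self.snp_id, "contig": self.contig,
                           "bp": self.bp})
        if self.lg is not None:
            df["lg"] = self.lg
            df["cm"] = self.cm
        return df


def read_counts_tsv(path) -> SnpReadMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "snp_id": str})
    meta = ["snp_id", "contig", "bp"]
    samples = [c for c in df.columns if c not in meta]
    pairs = df[samples].astype(str).to_numpy()
    split = np.char.split(pairs.astype(str), ":")
    ref = np.array([[int(p[0]) for p in row] for row in split])
    alt = np.array([[int(p[1]) for p in row] for row in split])
    return SnpReadMatrix(
        snp_id=df["snp_id"].to_numpy(), contig=df["contig"].to_numpy(),
        bp=df["bp"].to_numpy(int), ref=ref, alt=alt, samples=samples,
    )


def write_counts_tsv(mat: SnpReadMatrix, path) -> None:
    cols = {"snp_id": mat.snp_id, "contig": mat.contig, "bp": mat.bp}
    body = np.char.add(np.char.add(mat.ref.astype(str), ":"),
                       mat.alt.astype(str))
    samples = mat.samples or [f"ind{i}" for i in range(mat.n_individuals)]
    for j, s in enumerate(samples):
        cols[s] = body[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_vcf_ad(path) -> SnpReadMatrix:
    """Read biallelic SNPs with a per-sample AD field from a VCF."""
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ConfigurationError("cyvcf2 is required for VCF input") from e
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, contigs, bps, refs, alts = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ad = var.format("AD")
        if ad is None:
            continue
        ad = np.maximum(ad, 0)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        contigs.append(var.CHROM)
        bps.append(var.POS)
        refs.append(ad[:, 0])
        alts.append(ad[:, 1])
    return SnpReadMatrix(
        snp_id=np.array(ids), contig=np.array(contigs),
        bp=np.array(bps, dtype=int), ref=np.array(refs, dtype=int),
        alt=np.array(alts, dtype=int), samples=samples,
    )


def read_samples_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns or "x" not in df.columns or "y" not in df.columns:
        raise ConfigurationError("sample CSV needs at least id, x, y columns")
    return df


def read_habitat_csv(path):
    from .transect import HabitatSurvey

    df = pd.read_csv(path)
    if "habitat" not in df.columns:
        raise ConfigurationError("habitat CSV needs a habitat column")
    return HabitatSurvey(points_xy=df[["x", "y"]].to_numpy(float),
                         labels=df["habitat"].to_numpy())


def read_map_tsv(path) -> LinkageMap:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    return LinkageMap(df)
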