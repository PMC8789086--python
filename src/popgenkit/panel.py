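"""Core data model: genotype panels, genetic maps, QC reports.

A :class:`GenotypePanel` holds a diploid biallelic SNP matrix (samples x
SNPs, ALT-allele dosage 0/1/2 with ``-1`` as the missing sentinel), an
optional phased haplotype matrix (2*samples x SNPs, 0/1), a per-SNP table
(chromosome, bp, cM, alleles, id) and a per-sample metadata table
(population, major group, coordinates, filter flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SNP_COLUMNS = ["chrom", "pos", "cm", "ref", "alt", "id"]
SAMPLE_COLUMNS = ["id", "population", "major_group", "lat", "lon"]


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass
class GenotypePanel:
    """Samples x SNPs diploid genotype matrix with map and metadata.

    Parameters
    ----------
    genotypes
        int8/int16 array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2, MISSING}`` counting ALT alleles.
    snp_table
        DataFrame with columns ``chrom, pos, cm, ref, alt, id``; rows sorted
        by (chrom, pos) and cM non-decreasing within a chromosome.
    sample_table
        DataFrame with at least an ``id`` column; optional ``population``,
        ``major_group``, ``lat``, ``lon``, ``admixed``, ``related`` columns.
    haplotypes
        Optional phased binary matrix of shape ``(2*n_samples, n_snps)``.
        Rows ``2i`` and ``2i+1`` are the two haplotypes of sample ``i``.
    """

    genotypes: np.ndarray
    snp_table: pd.DataFrame
    sample_table: pd.DataFrame
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise PanelError("genotypes must be a 2-D samples x SNPs matrix")
        n, s = self.genotypes.shape
        if len(self.sample_table) != n:
            raise PanelError(
                f"sample_table has {len(self.sample_table)} rows for {n} samples"
            )
        if len(self.snp_table) != s:
            raise PanelError(f"snp_table has {len(self.snp_table)} rows for {s} SNPs")
        if self.sample_table["id"].duplicated().any():
            raise PanelError("duplicate sample ids")
        self.validate()

    # -- properties ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_table["id"])

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def validate(self) -> None:
        """Check structural invariants; raise :class:`PanelError` on violation."""
        g = self.genotypes
        ok = (g == MISSING) | ((g >= 0) & (g <= 2))
        if not ok.all():
            raise PanelError("genotype values must be in {0,1,2} or MISSING")
        if self.haplotypes is not None:
            h = np.asarray(self.haplotypes)
            if h.shape != (2 * self.n_samples, self.n_snps):
                raise PanelError("haplotypes must have shape (2*n_samples, n_snps)")
            sums = h[0::2] + h[1::2]
            nonmiss = ~self.missing_mask
            if not np.array_equal(sums[nonmiss], g[nonmiss]):
                raise PanelError("haplotype pair sums disagree with genotypes")
        st = self.snp_table
        for chrom, sub in st.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise PanelError(f"snp_table not sorted by bp on chrom {chrom}")
            cm = sub["cm"].to_numpy(dtype=float)
            if np.any(np.diff(cm) < -1e-12):
                raise PanelError(f"cM not non-decreasing on chrom {chrom}")

    # -- views -----------------------------------------------------------
    def take_samples(self, index: np.ndarray | list[int]) -> "GenotypePanel":
        """Subset samples by positional index, preserving haplotype pairing."""
        index = np.asarray(index, dtype=int)
        hap = None
        if self.haplotypes is not None:
            hap_idx = np.stack([2 * index, 2 * index + 1], axis=1).ravel()
            hap = self.haplotypes[hap_idx]
        return GenotypePanel(
            genotypes=self.genotypes[index],
            snp_table=self.snp_table.reset_index(drop=True),
            sample_table=self.sample_table.iloc[index].reset_index(drop=True),
            haplotypes=hap,
        )

    def take_snps(self, index: np.ndarray | list[int]) -> "GenotypePanel":
        """Subset SNPs by positional index (must preserve sort order)."""
        index = np.asarray(index, dtype=int)
        hap = self.haplotypes[:, index] if self.haplotypes is not None else None
        return GenotypePanel(
            genotypes=self.genotypes[:, index],
            snp_table=self.snp_table.iloc[index].reset_index(drop=True),
            sample_table=self.sample_table.reset_index(drop=True),
            haplotypes=hap,
        )

    def select_samples(self, ids: list[str]) -> "GenotypePanel":
        """Subset samples by id, in the given order."""
        lookup = {sid: i for i, sid in enumerate(self.sample_table["id"])}
        try:
            idx = [lookup[s] for s in ids]
        except KeyError as exc:
            raise PanelError(f"unknown sample id {exc.args[0]!r}") from None
        return self.take_samples(idx)

    def allele_frequency(self) -> np.ndarray:
        """Pooled ALT allele frequency per SNP (NaN where all missing)."""
        g = np.where(self.missing_mask, 0, self.genotypes).astype(float)
        n = 2.0 * (~self.missing_mask).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, g.sum(axis=0) / n, np.nan)

    def sample_missingness(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    def snp_missingness(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)


@dataclass
class GeneticMap:
    """Piecewise-linear bp -> cM map, one anchor list per chromosome.

    ``anchors[chrom]`` is a list of ``(bp, cm)`` points strictly increasing
    in bp and non-decreasing in cM. Queries outside the anchored range take
    the boundary cM value (constant extrapolation).
    """

    anchors: dict[str | int, list[tuple[int, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, pts in self.anchors.items():
            bps = np.array([p[0] for p in pts])
            cms = np.array([p[1] for p in pts], dtype=float)
            if np.any(np.diff(bps) <= 0):
                raise PanelError(f"map anchors not strictly increasing in bp ({chrom})")
            if np.any(np.diff(cms) < 0):
                raise PanelError(f"map anchors decreasing in cM ({chrom})")

    def interpolate(self, chrom, bp) -> float | np.ndarray:
        """Interpolate genetic position (cM) at ``bp`` on ``chrom``."""
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        pts = self.anchors[chrom]
        bps = np.array([p[0] for p in pts], dtype=float)
        cms = np.array([p[1] for p in pts], dtype=float)
        # np.interp clamps to boundary values outside the anchor range
        out = np.interp(np.asarray(bp, dtype=float), bps, cms)
        return float(out) if np.isscalar(bp) else out


def interpolate_cm(gmap: GeneticMap, chrom, bp):
    """Genetic position in cM at ``bp``; constant beyond the anchor range."""
    return gmap.interpolate(chrom, bp)


@dataclass
class QCReport:
    """Per-rule removal counts from :func:`popgenkit.qc.qc_filter`."""

    n_snps_in: int = 0
    n_samples_in: int = 0
    snps_removed_missing: int = 0
    snps_removed_triallelic: int = 0
    snps_removed_hwe: int = 0
    snps_removed_arm_trim: int = 0
    samples_removed_missing: int = 0
    rare_allele_fraction: float = 0.0
    n_snps_out: int = 0
    n_samples_out: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)
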