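"""Allele-frequency f-statistics with block-jackknife uncertainty.

Per-SNP moments (a, b, c, d are population ALT frequencies):

* ``f2(A,B)   = (a-b)^2``       minus the finite-sample heterozygosity
  corrections ``a(1-a)/(n_a-1) + b(1-b)/(n_b-1)`` (n = haplotype counts),
* ``f3(C;A,B) = (c-a)(c-b)``    minus ``c(1-c)/(n_c-1)``,
* ``f4(A,B;C,D) = (a-b)(c-d)``  (unbiased as is),

averaged over SNPs with non-missing frequencies in every argument
population. Standard errors come from a weighted delete-one block
jackknife over contiguous genetic-map blocks (default 5 cM), with block
weights proportional to their SNP counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


@dataclass
class FrequencyTable:
    """Per-population ALT frequencies and haplotype counts per SNP."""

    populations: list[str]
    freqs: np.ndarray  # (n_pops, n_snps), NaN where count 0
    counts: np.ndarray  # (n_pops, n_snps) observed haplotype counts
    snp_table: pd.DataFrame

    def __post_init__(self) -> None:
        ok = np.isnan(self.freqs) | ((self.freqs >= 0) & (self.freqs <= 1))
        if not ok.all():
            raise ValueError("frequencies must be in [0,1] or NaN")
        if ((self.counts == 0) != np.isnan(self.freqs)).any():
            raise ValueError("count 0 must coincide with missing frequency")

    def index(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"population {pop!r} not in table") from None


@dataclass
class FStatResult:
    kind: str
    pops: tuple[str, ...]
    estimate: float
    se: float
    n_blocks: int
    n_snps: int

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se > 0 else float("inf")


def allele_frequencies(
    panel: GenotypePanel, grouping: dict[str, str] | None = None
) -> FrequencyTable:
    """Per-population ALT frequency table.

    ``grouping`` maps sample id -> population; by default the panel's
    ``population`` column is used. Pass ``{sid: sid}`` to treat each
    individual as a population of one.
    """
    if grouping is None:
        grouping = dict(
            zip(panel.sample_table["id"], panel.sample_table["population"])
        )
    ids = panel.sample_ids
    missing_samples = [s for s in grouping if s not in set(ids)]
    if missing_samples:
        raise KeyError(f"grouped samples not in panel: {missing_samples[:5]}")
    pops = sorted(set(grouping.values()))
    n_pops, n_snps = len(pops), panel.n_snps
    freqs = np.full((n_pops, n_snps), np.nan)
    counts = np.zeros((n_pops, n_snps))
    pop_index = {p: i for i, p in enumerate(pops)}
    g = panel.genotypes
    nonmiss = g != MISSING
    for p in pops:
        rows = [i for i, sid in enumerate(ids) if grouping.get(sid) == p]
        if not rows:
            raise ValueError(f"population {p!r} has no samples")
        sub = g[rows]
        ok = nonmiss[rows]
        n = 2.0 * ok.sum(axis=0)
        tot = np.where(ok, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop_index[p]] = np.where(n > 0, tot / n, np.nan)
        counts[pop_index[p]] = n
    return FrequencyTable(pops, freqs, counts, panel.snp_table)


def map_blocks(snp_table: pd.DataFrame, block_size_cm: float) -> np.ndarray:
    """Assign each SNP to a contiguous genetic-map block id."""
    snp_table = snp_table.reset_index(drop=True)
    block = np.zeros(len(snp_table), dtype=int)
    offset = 0
    for _, sub in snp_table.groupby("chrom", sort=False):
        cm = sub["cm"].to_numpy(dtype=float)
        rel = np.floor((cm - cm[0]) / block_size_cm).astype(int)
        block[sub.index] = offset + rel
        offset += rel.max() + 1
    # renumber to consecutive ids
    _, block = np.unique(block, return_inverse=True)
    return block


def _weighted_block_jackknife(
    per_snp: np.ndarray, blocks: np.ndarray
) -> tuple[float, float, int]:
    """Weighted delete-one-block jackknife mean and SE (Busing et al.)."""
    n = len(per_snp)
    est = per_snp.mean()
    ids = np.unique(blocks)
    g = len(ids)
    if g < 2:
        raise ValueError("need at least 2 jackknife blocks")
    total = per_snp.sum()
    theta_del = np.empty(g)
    m = np.empty(g)
    for j, b in enumerate(ids):
        sel = blocks == b
        m[j] = sel.sum()
        theta_del[j] = (total - per_snp[sel].sum()) / (n - m[j])
    h = n / m
    theta_jack = g * est - np.sum((1.0 - m / n) * theta_del)
    tau = h * est - (h - 1.0) * theta_del
    var = np.sum((tau - theta_jack) ** 2 / (h - 1.0)) / g
    return float(est), float(np.sqrt(var)), g


def f_statistic(
    freqs: FrequencyTable,
    kind: str,
    pops: tuple[str, ...],
    block_size_cm: float = 5.0,
    bias_correction: bool = True,
) -> FStatResult:
    """Estimate f2/f3/f4 with block-jackknife SE.

    SNPs enter only when the frequency is non-missing in every argument
    population (listwise complete cases).
    """
    expect = {"f2": 2, "f3": 3, "f4": 4}
    if kind not in expect:
        raise ValueError(f"kind must be f2/f3/f4, got {kind!r}")
    if len(pops) != expect[kind]:
        raise ValueError(f"{kind} takes {expect[kind]} populations")
    idx = [freqs.index(p) for p in pops]
    f = freqs.freqs[idx]
    n = freqs.counts[idx]
    usable = ~np.isnan(f).any(axis=0)
    if usable.sum() == 0:
        raise ValueError("no SNPs with complete frequencies across arguments")
    f = f[:, usable]
    n = n[:, usable]

    def het_corr(i: int) -> np.ndarray:
        ni = n[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = f[i] * (1.0 - f[i]) / np.maximum(ni - 1.0, 1e-12)
        return np.where(ni > 1, corr, 0.0)

    if kind == "f2":
        per_snp = (f[0] - f[1]) ** 2
        if bias_correction:
            per_snp = per_snp - het_corr(0) - het_corr(1)
    elif kind == "f3":
        c, a, b = f[0], f[1], f[2]
        per_snp = (c - a) * (c - b)
        if bias_correction:
            per_snp = per_snp - het_corr(0)
    else:
        per_snp = (f[0] - f[1]) * (f[2] - f[3])

    blocks = map_blocks(freqs.snp_table, block_size_cm)[usable]
    est, se, g = _weighted_block_jackknife(per_snp, blocks)
    return FStatResult(kind, tuple(pops), est, se, g, int(usable.sum()))


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    units: str = "other"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def outgroup_f3_matrix(
    freqs: FrequencyTable,
    outgroup: str,
    units: str = "one_minus",
    block_size_cm: float = 5.0,
) -> DistanceMatrix:
    """Pairwise outgroup-f3 (or 1 - f3) matrix over non-outgroup populations."""
    if units not in ("raw", "one_minus"):
        raise ValueError("units must be 'raw' or 'one_minus'")
    freqs.index(outgroup)
    others = [p for p in freqs.populations if p != outgroup]
    k = len(others)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r = f_statistic(
                freqs, "f3", (outgroup, others[i], others[j]), block_size_cm
            )
            v = 1.0 - r.estimate if units == "one_minus" else r.estimate
            mat[i, j] = mat[j, i] = v
    return DistanceMatrix(others, mat, units="1-f3" if units == "one_minus" else "f3")


def summarize_f4_affinity(
    results: list[FStatResult], z_threshold: float = 4.0
) -> pd.DataFrame:
    """Count strongly significant f4(O, X; Y, Z) tests by (X, Z) over Y.

    All results must be f4 statistics sharing a common first (outgroup)
    argument; a result contributes to cell (X, Z) when its Z score
    strictly exceeds ``z_threshold``.
    """
    if not results:
        return pd.DataFrame(columns=["X", "Z", "n_significant"])
    outgroups = {r.pops[0] for r in results}
    if len(outgroups) != 1:
        raise ValueError(f"mixed outgroups in f4 summary: {sorted(outgroups)}")
    if any(r.kind != "f4" for r in results):
        raise ValueError("summarize_f4_affinity requires f4 results only")
    counts: dict[tuple[str, str], int] = {}
    for r in results:
        _, x, _, z_pop = r.pops
        key = (x, z_pop)
        counts.setdefault(key, 0)
        if r.z > z_threshold:
            counts[key] += 1
    rows = [(x, z_pop, c) for (x, z_pop), c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["X", "Z", "n_significant"])
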