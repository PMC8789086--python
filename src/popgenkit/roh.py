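"""Runs of homozygosity and the F_ROH inbreeding coefficient.

ROH calling mirrors the classic sliding-window scan: 50-SNP windows
tolerate at most one heterozygote and five missing calls; a SNP's
homozygosity score is the fraction of spanning windows that pass;
candidate runs where the score clears the overlap threshold are then
subjected to gap, density and minimum-length filters. F_ROH is the
summed ROH length divided by the genomic span covered by the SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, GenotypePanel

ROH_COLUMNS = ["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"]


@dataclass
class ROHSet:
    table: pd.DataFrame  # ROH_COLUMNS

    def for_sample(self, sid: str) -> pd.DataFrame:
        return self.table[self.table["sample"] == sid]


def call_roh(
    panel: GenotypePanel,
    window_snps: int = 50,
    max_het_per_window: int = 1,
    max_miss_per_window: int = 5,
    min_overlap_frac: float = 0.05,
    min_snp_density_kb: float = 50.0,
    max_gap_kb: float = 100.0,
    min_length_kb: float = 500.0,
) -> ROHSet:
    """Sliding-window ROH scan over every sample and chromosome.

    Windows lie fully inside the chromosome; terminal SNPs spanned by
    fewer windows are scored over the available ones. Candidate runs are
    split at inter-SNP gaps above ``max_gap_kb`` and must satisfy the
    minimum length and the average SNP density (one SNP per
    ``min_snp_density_kb`` kb or denser).
    """
    rows = []
    chroms = panel.snp_table["chrom"].to_numpy()
    pos = panel.snp_table["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        sl = np.flatnonzero(chroms == chrom)
        cpos = pos[sl]
        if np.any(np.diff(cpos) < 0):
            raise ValueError(f"SNPs unsorted on chromosome {chrom}")
        for i, sid in enumerate(panel.sample_ids):
            g = panel.genotypes[i, sl]
            runs = _scan_sample(
                g,
                cpos,
                window_snps,
                max_het_per_window,
                max_miss_per_window,
                min_overlap_frac,
                max_gap_kb * 1000.0,
            )
            for s, e in runs:
                # a reported segment starts and ends on a homozygous call
                while s <= e and g[s] not in (0, 2):
                    s += 1
                while e >= s and g[e] not in (0, 2):
                    e -= 1
                if e < s:
                    continue
                length = int(cpos[e] - cpos[s] + 1)
                n_snps = e - s + 1
                if length < min_length_kb * 1000.0:
                    continue
                if length / n_snps > min_snp_density_kb * 1000.0:
                    continue
                rows.append((sid, chrom, int(cpos[s]), int(cpos[e]), n_snps, length))
    return ROHSet(pd.DataFrame(rows, columns=ROH_COLUMNS))


def _scan_sample(
    g: np.ndarray,
    pos: np.ndarray,
    window: int,
    max_het: int,
    max_miss: int,
    min_frac: float,
    max_gap_bp: float,
) -> list[tuple[int, int]]:
    n = len(g)
    het = (g == 1).astype(int)
    miss = (g == MISSING).astype(int)
    if n < window:
        window = max(n, 1)
    n_win = n - window + 1
    chet = np.concatenate([[0], np.cumsum(het)])
    cmiss = np.concatenate([[0], np.cumsum(miss)])
    win_het = chet[window:] - chet[:-window]
    win_miss = cmiss[window:] - cmiss[:-window]
    passes = ((win_het <= max_het) & (win_miss <= max_miss)).astype(int)
    cpass = np.concatenate([[0], np.cumsum(passes)])
    score = np.empty(n)
    for k in range(n):
        lo = max(0, k - window + 1)
        hi = min(k, n_win - 1)
        if hi < lo:
            score[k] = 0.0
        else:
            score[k] = (cpass[hi + 1] - cpass[lo]) / (hi - lo + 1)
    in_run = score >= min_frac
    runs = []
    k = 0
    while k < n:
        if not in_run[k]:
            k += 1
            continue
        start = k
        while k + 1 < n and in_run[k + 1] and (pos[k + 1] - pos[k]) <= max_gap_bp:
            k += 1
        runs.append((start, k))
        k += 1
    return runs


@dataclass
class FrohTable:
    per_sample: pd.DataFrame  # id, population, froh
    per_population: pd.DataFrame  # population, mean_froh, n


def covered_span(panel: GenotypePanel) -> int:
    """Total genomic span (bp) covered by the panel's SNPs."""
    total = 0
    for _, sub in panel.snp_table.groupby("chrom", sort=False):
        total += int(sub["pos"].max() - sub["pos"].min() + 1)
    return total


def froh(rohs: ROHSet, covered_bp: int, panel: GenotypePanel) -> FrohTable:
    """Per-sample F_ROH = total ROH bp / covered bp, with population means."""
    if covered_bp <= 0:
        raise ValueError("covered_bp must be positive")
    sums = rohs.table.groupby("sample")["length_bp"].sum()
    if len(sums) and sums.max() > covered_bp:
        raise ValueError("ROH total exceeds the covered genomic span")
    st = panel.sample_table
    per_sample = pd.DataFrame(
        {
            "id": st["id"],
            "population": st.get("population", pd.Series(["?"] * len(st))),
            "froh": [float(sums.get(s, 0.0)) / covered_bp for s in st["id"]],
        }
    )
    per_pop = (
        per_sample.groupby("population")["froh"]
        .agg(mean_froh="mean", n="count")
        .reset_index()
    )
    return FrohTable(per_sample, per_pop)


@dataclass
class FrohGeography:
    spearman_r: float
    spearman_p: float
    wilcoxon_stat: float | None = None
    wilcoxon_p: float | None = None


def froh_geography(
    froh_table: FrohTable,
    coords: pd.DataFrame,
    axis: str = "lon",
    region_labels: pd.Series | None = None,
) -> FrohGeography:
    """Spearman correlation of population-mean F_ROH with a coordinate.

    ``coords`` maps population -> (lat, lon). If ``region_labels`` gives a
    two-level region per population, a Wilcoxon rank-sum test between the
    two regions' F_ROH values is added (exact for n <= 20 per side,
    normal approximation with continuity correction otherwise).
    """
    merged = froh_table.per_population.merge(coords, on="population")
    if len(merged) < 3:
        raise ValueError("need at least 3 populations")
    x = merged[axis].to_numpy(dtype=float)
    y = merged["mean_froh"].to_numpy(dtype=float)
    if np.std(x) <= 1e-12 * max(1.0, np.abs(x).max()) or np.std(y) <= 1e-12 * max(
        1.0, np.abs(y).max()
    ):
        raise ValueError("constant input to Spearman correlation")
    r, p = stats.spearmanr(x, y)
    result = FrohGeography(float(r), float(p))
    if region_labels is not None:
        lab = merged["population"].map(region_labels)
        groups = lab.dropna().unique()
        if len(groups) != 2:
            raise ValueError("region_labels must define exactly two regions")
        a = y[(lab == groups[0]).to_numpy()]
        b = y[(lab == groups[1]).to_numpy()]
        method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
        u = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        result.wilcoxon_stat = float(u.statistic)
        result.wilcoxon_p = float(u.pvalue)
    return result
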