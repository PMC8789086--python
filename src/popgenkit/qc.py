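"""Panel quality control and LD pruning.

The QC filter applies, in order: per-SNP missingness, per-sample
missingness, triallelic-site removal (sites whose REF/ALT pair conflicts
with observed alleles are assumed pre-removed by the readers; the hook
here removes sites flagged in the snp_table), Hardy-Weinberg exact-test
filtering, and optional trimming of SNPs near chromosome-arm ends.

LD pruning is a greedy left-to-right scan over bp-denominated sliding
windows: within each window any pair with squared dosage correlation
above the cutoff loses its later (higher-bp) member.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .panel import MISSING, GenotypePanel, PanelError, QCReport


def hwe_exact_midp(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Mid-p exact test for Hardy-Weinberg proportions.

    Conditions on the minor-allele count and sums the probabilities of
    heterozygote counts as or less likely than observed, counting the
    observed outcome with weight one half (mid-p correction).
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if rare == 0:
        return 1.0
    # recurrence over possible heterozygote counts with fixed rare count
    het_min = rare % 2
    hets = np.arange(het_min, rare + 1, 2)
    probs = np.zeros(len(hets))
    # start from the mode and fill outwards to avoid underflow
    mid = len(hets) // 2
    probs[mid] = 1.0
    for i in range(mid, len(hets) - 1):
        h = hets[i]
        r_hom = (rare - h) // 2
        c_hom = n - r_hom - h
        # P(h+2)/P(h) = 4*r_hom*c_hom / ((h+1)(h+2))
        probs[i + 1] = probs[i] * 4.0 * r_hom * c_hom / ((h + 1.0) * (h + 2.0))
    for i in range(mid, 0, -1):
        h = hets[i]
        r_hom = (rare - h) // 2
        c_hom = n - r_hom - h
        # P(h-2)/P(h) = h(h-1) / (4*(r_hom+1)*(c_hom+1))
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (r_hom + 1.0) * (c_hom + 1.0))
    probs /= probs.sum()
    obs_idx = (n_het - het_min) // 2
    p_obs = probs[obs_idx]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum() - 0.5 * p_obs
    return float(min(1.0, max(p, 0.0)))


def qc_filter(
    panel: GenotypePanel,
    snp_missing_max: float = 0.05,
    ind_missing_max: float = 0.10,
    maf_rare_threshold: float = 0.01,
    hwe_p_min: float | None = None,
    arm_trim_bp: int | None = None,
    arm_table: dict | None = None,
) -> tuple[GenotypePanel, QCReport]:
    """Filter a panel by missingness, HWE, and chromosome-arm proximity.

    Parameters
    ----------
    snp_missing_max, ind_missing_max
        Maximum tolerated missing fraction per SNP / per sample; strictly
        greater is removed.
    maf_rare_threshold
        SNPs with minor allele frequency strictly below this are *counted*
        (reported as the rare-allele fraction), not removed.
    hwe_p_min
        If given, SNPs with mid-p exact-test p <= this value are removed.
    arm_trim_bp, arm_table
        If both given, SNPs within ``arm_trim_bp`` of any arm boundary are
        removed. ``arm_table`` maps chromosome -> list of (arm_start_bp,
        arm_end_bp) intervals.

    Returns
    -------
    (filtered panel, QCReport)
    """
    for name, v in [
        ("snp_missing_max", snp_missing_max),
        ("ind_missing_max", ind_missing_max),
        ("maf_rare_threshold", maf_rare_threshold),
    ]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {v}")
    report = QCReport(n_snps_in=panel.n_snps, n_samples_in=panel.n_samples)

    # SNP missingness
    keep_snp = panel.snp_missingness() <= snp_missing_max
    report.snps_removed_missing = int((~keep_snp).sum())
    panel = panel.take_snps(np.flatnonzero(keep_snp))

    # sample missingness (after SNP removal, matching the sequential pipeline)
    keep_ind = panel.sample_missingness() <= ind_missing_max
    report.samples_removed_missing = int((~keep_ind).sum())
    panel = panel.take_samples(np.flatnonzero(keep_ind))

    # arm trimming
    if arm_trim_bp is not None and arm_table:
        pos = panel.snp_table["pos"].to_numpy()
        chroms = panel.snp_table["chrom"].to_numpy()
        near = np.zeros(panel.n_snps, dtype=bool)
        for chrom, arms in arm_table.items():
            on = chroms == chrom
            for start, end in arms:
                near |= on & (
                    (np.abs(pos - start) < arm_trim_bp)
                    | (np.abs(pos - end) < arm_trim_bp)
                )
        report.snps_removed_arm_trim = int(near.sum())
        panel = panel.take_snps(np.flatnonzero(~near))

    # HWE exact test on pooled samples
    if hwe_p_min is not None:
        g = panel.genotypes
        het = (g == 1).sum(axis=0)
        hom_ref = (g == 0).sum(axis=0)
        hom_alt = (g == 2).sum(axis=0)
        pvals = np.array(
            [
                hwe_exact_midp(int(h), int(r), int(a))
                for h, r, a in zip(het, hom_ref, hom_alt)
            ]
        )
        keep = pvals > hwe_p_min
        report.snps_removed_hwe = int((~keep).sum())
        panel = panel.take_snps(np.flatnonzero(keep))

    if panel.n_snps == 0 or panel.n_samples == 0:
        raise PanelError("panel empty after QC filtering")

    freq = panel.allele_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    with np.errstate(invalid="ignore"):
        report.rare_allele_fraction = float(np.nanmean(maf < maf_rare_threshold))
    report.n_snps_out = panel.n_snps
    report.n_samples_out = panel.n_samples
    return panel, report


def ld_prune(
    panel: GenotypePanel,
    r2_max: float = 0.2,
    window_bp: int = 50_000,
    step_bp: int = 10_000,
) -> GenotypePanel:
    """Greedy LD pruning on dosage correlation within bp sliding windows.

    Windows of ``window_bp`` advance by ``step_bp`` along each chromosome;
    inside a window, for every pair with r^2 > ``r2_max`` the SNP at the
    higher bp position is dropped. Deterministic for a given panel.
    """
    if panel.n_snps < 2:
        raise PanelError("ld_prune requires at least 2 SNPs")
    g = panel.genotypes.astype(float)
    g[panel.genotypes == MISSING] = np.nan
    pos = panel.snp_table["pos"].to_numpy()
    chroms = panel.snp_table["chrom"].to_numpy()
    keep = np.ones(panel.n_snps, dtype=bool)
    for chrom in pd_unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        cpos = pos[idx]
        start = int(cpos.min())
        stop = int(cpos.max())
        w = start
        while w <= stop:
            in_win = idx[(cpos >= w) & (cpos < w + window_bp)]
            in_win = in_win[keep[in_win]]
            if len(in_win) >= 2:
                sub = g[:, in_win]
                r2 = _pairwise_complete_r2(sub)
                # greedy: later SNP of any offending pair is dropped
                for a in range(len(in_win)):
                    if not keep[in_win[a]]:
                        continue
                    for b in range(a + 1, len(in_win)):
                        if keep[in_win[b]] and r2[a, b] > r2_max:
                            keep[in_win[b]] = False
            w += step_bp
    return panel.take_snps(np.flatnonzero(keep))


def _pairwise_complete_r2(x: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between columns, pairwise-complete rows."""
    m = x.shape[1]
    r2 = np.zeros((m, m))
    mask = ~np.isnan(x)
    for a in range(m):
        for b in range(a + 1, m):
            ok = mask[:, a] & mask[:, b]
            if ok.sum() < 2:
                continue
            xa, xb = x[ok, a], x[ok, b]
            sa, sb = xa.std(), xb.std()
            if sa == 0 or sb == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            r2[a, b] = r2[b, a] = r * r
    return r2


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Order-preserving unique (first occurrence order)."""
    import pandas as pd

    return pd.unique(values)
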