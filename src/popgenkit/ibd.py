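"""IBD/HBD segment detection, masking, time classification and networks.

The detector runs on phased haplotypes. Each site of a haplotype pair
scores ``log10 P(obs | IBD) / P(obs | background)``: matches score
against the allele-frequency-expected identity rate ``p^2 + q^2``,
mismatches are genotyping errors at the configured tolerance against the
background mismatch rate ``2pq``. All maximal positive-scoring
subsegments (Ruzzo-Tompa) longer than the length cutoff and with support
above the LOD cutoff are emitted; HBD is the same scan over an
individual's own two haplotypes.

Segment ages follow the expectation E[generations] = 3 / (2 I) with I
the length in morgans, converted to years at 28 years per generation,
and the three sharing periods split at 8.4 cM (pre-Columbian/colonial)
and 28 cM (colonial/recent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

SEGMENT_COLUMNS = [
    "sample1", "hap1", "sample2", "hap2", "chrom",
    "start_bp", "end_bp", "start_cm", "end_cm", "length_cm", "lod", "ancestry",
]

PRECOLUMBIAN_MAX_CM = 8.4
COLONIAL_MAX_CM = 28.0
YEARS_PER_GENERATION = 28.0


@dataclass
class IBDSegmentSet:
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SEGMENT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"segment table missing columns {missing}")

    @property
    def n_segments(self) -> int:
        return len(self.table)

    def hbd(self) -> "IBDSegmentSet":
        t = self.table
        return IBDSegmentSet(t[t["sample1"] == t["sample2"]].reset_index(drop=True))


# --------------------------------------------------------------------------
# detection


def detect_ibd(
    panel: GenotypePanel,
    min_cm: float = 2.0,
    min_support: float = 3.0,
    error_tolerance: float = 0.002,
    include_hbd: bool = True,
    sample_pairs: list[tuple[str, str]] | None = None,
) -> IBDSegmentSet:
    """Scan all haplotype pairs for IBD segments.

    Emits maximal segments with map length strictly greater than
    ``min_cm`` and LOD support strictly greater than ``min_support``.
    ``sample_pairs`` restricts the scan (pairs of sample ids; use
    ``(s, s)`` for HBD only).
    """
    if not panel.phased:
        raise ValueError("detect_ibd requires a phased panel")
    hap = panel.haplotypes
    ids = panel.sample_ids
    n = len(ids)
    freq = panel.allele_frequency()
    chroms = panel.snp_table["chrom"].to_numpy()
    cms = panel.snp_table["cm"].to_numpy(dtype=float)
    bps = panel.snp_table["pos"].to_numpy()
    miss = panel.missing_mask

    eps = max(error_tolerance, 1e-6)
    p = np.clip(freq, 1e-6, 1 - 1e-6)
    match_bg = p**2 + (1 - p) ** 2
    s_match = np.log10((1.0 - eps) / match_bg)
    s_mismatch = np.log10(eps / (1.0 - match_bg))

    if sample_pairs is None:
        pairs = [(i, j) for i in range(n) for j in range(i, n)]
        if not include_hbd:
            pairs = [(i, j) for i, j in pairs if i != j]
    else:
        idx = {s: i for i, s in enumerate(ids)}
        pairs = [(idx[a], idx[b]) for a, b in sample_pairs]

    rows = []
    chrom_slices = [
        (chrom, np.flatnonzero(chroms == chrom)) for chrom in pd.unique(chroms)
    ]
    for i, j in pairs:
        hap_pairs = (
            [(0, 1)] if i == j else [(0, 0), (0, 1), (1, 0), (1, 1)]
        )
        for h1, h2 in hap_pairs:
            a = hap[2 * i + h1]
            b = hap[2 * j + h2]
            valid = ~(miss[i] | miss[j])
            for chrom, sl in chrom_slices:
                ok = sl[valid[sl]]
                if len(ok) < 2:
                    continue
                scores = np.where(a[ok] == b[ok], s_match[ok], s_mismatch[ok])
                for s_idx, e_idx, lod in _max_scoring_segments(scores):
                    lo, hi = ok[s_idx], ok[e_idx]
                    length = cms[hi] - cms[lo]
                    if length > min_cm and lod > min_support:
                        rows.append(
                            (
                                ids[i], h1, ids[j], h2, chrom,
                                int(bps[lo]), int(bps[hi]),
                                float(cms[lo]), float(cms[hi]),
                                float(length), float(lod), None,
                            )
                        )
    return IBDSegmentSet(pd.DataFrame(rows, columns=SEGMENT_COLUMNS))


def _max_scoring_segments(scores: np.ndarray) -> list[tuple[int, int, float]]:
    """Ruzzo-Tompa all maximal positive-scoring subsequences."""
    out: list[list] = []  # [start, end, L_cum, R_cum]
    cum = 0.0
    for k, s in enumerate(scores):
        prev = cum
        cum += s
        if s <= 0:
            continue
        seg = [k, k, prev, cum]
        while True:
            # find rightmost previous segment with L < seg's L
            merged = False
            for m in range(len(out) - 1, -1, -1):
                if out[m][2] < seg[2]:
                    if out[m][3] < seg[3]:
                        seg = [out[m][0], seg[1], out[m][2], seg[3]]
                        del out[m:]
                        merged = True
                    break
            if not merged:
                break
        out.append(seg)
    return [(s, e, r - l) for s, e, l, r in out]


# --------------------------------------------------------------------------
# gap merging


def merge_gaps(
    segments: IBDSegmentSet,
    panel: GenotypePanel | None = None,
    max_gap_cm: float = 0.6,
    max_discordant_hom: int = 1,
) -> IBDSegmentSet:
    """Merge consecutive segments of the same haplotype pair across short gaps.

    A gap qualifies when it is at most ``max_gap_cm`` long and contains at
    most ``max_discordant_hom`` opposite-homozygote genotype sites between
    the two samples (counted on ``panel`` when given; assumed zero
    otherwise).
    """
    t = segments.table
    if t.empty:
        return IBDSegmentSet(t.copy())
    if panel is not None:
        idx = {s: i for i, s in enumerate(panel.sample_ids)}
        chroms = panel.snp_table["chrom"].to_numpy()
        cms = panel.snp_table["cm"].to_numpy(dtype=float)
    merged_rows = []
    keys = ["sample1", "hap1", "sample2", "hap2", "chrom"]
    for key, grp in t.groupby(keys, sort=False, dropna=False):
        grp = grp.sort_values("start_cm").reset_index(drop=True)
        cur = grp.iloc[0].copy()
        for _, nxt in grp.iloc[1:].iterrows():
            gap = nxt["start_cm"] - cur["end_cm"]
            n_disc = 0
            if panel is not None and gap > 0:
                i, j = idx[cur["sample1"]], idx[cur["sample2"]]
                in_gap = (
                    (chroms == cur["chrom"])
                    & (cms > cur["end_cm"])
                    & (cms < nxt["start_cm"])
                )
                gi = panel.genotypes[i, in_gap]
                gj = panel.genotypes[j, in_gap]
                both = (gi != MISSING) & (gj != MISSING)
                n_disc = int(np.sum(np.abs(gi[both] - gj[both]) == 2))
            if 0 <= gap <= max_gap_cm and n_disc <= max_discordant_hom:
                cur["end_cm"] = nxt["end_cm"]
                cur["end_bp"] = nxt["end_bp"]
                cur["lod"] = cur["lod"] + nxt["lod"]
            else:
                merged_rows.append(cur)
                cur = nxt.copy()
        merged_rows.append(cur)
    out = pd.DataFrame(merged_rows).reset_index(drop=True)
    out["length_cm"] = out["end_cm"] - out["start_cm"]
    return IBDSegmentSet(out[SEGMENT_COLUMNS])


# --------------------------------------------------------------------------
# local ancestry


@dataclass
class AncestryTracts:
    """Per-haplotype ancestry tracts tiling each chromosome."""

    table: pd.DataFrame  # sample, hap, chrom, start_cm, end_cm, ancestry, posterior
    inherited_windows: int = 0  # all-missing windows that copied a neighbour label

    def for_haplotype(self, sample: str, hap: int) -> pd.DataFrame:
        t = self.table
        return t[(t["sample"] == sample) & (t["hap"] == hap)]


def classify_local_ancestry(
    panel: GenotypePanel,
    reference_freqs,
    window_cm: float = 0.2,
    switch_prob: float = 0.01,
) -> AncestryTracts:
    """Windowed likelihood classification of haplotype ancestry.

    Each ``window_cm`` map window of a haplotype is scored by its
    log-likelihood under every source population's allele frequencies;
    window labels come from a Viterbi pass that penalizes ancestry
    switches between adjacent windows (``switch_prob`` per window),
    reflecting that true tracts span many windows. Posteriors are the
    pre-smoothing normalized window likelihoods. Windows with no usable
    site carry no emission and inherit their label through the smoothing
    (counted in ``inherited_windows``). Adjacent same-label windows merge
    into tracts.
    """
    if not panel.phased:
        raise ValueError("classify_local_ancestry requires a phased panel")
    sources = list(reference_freqs.populations)
    K = len(sources)
    if K < 2:
        raise ValueError("need at least 2 source populations")
    f = np.clip(reference_freqs.freqs, 1e-6, 1 - 1e-6)  # (K, S)
    logf = np.log(f)
    log1mf = np.log(1.0 - f)
    log_stay = np.log(1.0 - switch_prob)
    log_switch = np.log(switch_prob / (K - 1))
    chroms = panel.snp_table["chrom"].to_numpy()
    cms = panel.snp_table["cm"].to_numpy(dtype=float)
    hap = panel.haplotypes
    miss = panel.missing_mask
    ids = panel.sample_ids
    rows = []
    inherited = 0
    for chrom in pd.unique(chroms):
        sl = np.flatnonzero(chroms == chrom)
        c = cms[sl]
        lo, hi = c[0], c[-1]
        n_win = max(1, int(np.ceil((hi - lo) / window_cm)))
        edges = lo + window_cm * np.arange(n_win + 1)
        edges[-1] = max(edges[-1], hi + 1e-9)
        win_of = np.clip(np.searchsorted(edges, c, side="right") - 1, 0, n_win - 1)
        for hrow in range(hap.shape[0]):
            sample = ids[hrow // 2]
            alleles = hap[hrow, sl].astype(float)
            ok = ~miss[hrow // 2, sl]
            emit = np.zeros((n_win, K))
            posts = np.full(n_win, np.nan)
            for w in range(n_win):
                in_w = (win_of == w) & ok
                if not in_w.any():
                    inherited += 1
                    continue
                sites = sl[in_w]
                a = alleles[in_w]
                ll = logf[:, sites] @ a + log1mf[:, sites] @ (1.0 - a)
                emit[w] = ll - ll.max()
                lik = np.exp(emit[w])
                posts[w] = float(lik.max() / lik.sum())
            labels = _viterbi(emit, log_stay, log_switch)
            start = 0
            for w in range(1, n_win + 1):
                if w == n_win or labels[w] != labels[start]:
                    window_posts = posts[start:w]
                    seg_post = (
                        float(np.nanmean(window_posts))
                        if np.any(~np.isnan(window_posts))
                        else np.nan
                    )
                    rows.append(
                        (
                            sample, hrow % 2, chrom,
                            float(edges[start]), float(edges[w]),
                            sources[labels[start]], seg_post,
                        )
                    )
                    start = w
    table = pd.DataFrame(
        rows,
        columns=["sample", "hap", "chrom", "start_cm", "end_cm", "ancestry", "posterior"],
    )
    return AncestryTracts(table, inherited)


def _viterbi(emit: np.ndarray, log_stay: float, log_switch: float) -> np.ndarray:
    """Most probable label path; ties resolve to the lowest source index."""
    n, k = emit.shape
    score = emit[0].copy()
    back = np.zeros((n, k), dtype=int)
    for w in range(1, n):
        trans = score[None, :] + np.where(
            np.eye(k, dtype=bool), log_stay, log_switch
        )
        back[w] = np.argmax(trans, axis=1)
        score = emit[w] + trans[np.arange(k), back[w]]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(score))
    for w in range(n - 1, 0, -1):
        path[w - 1] = back[w, path[w]]
    return path


def mask_by_ancestry(
    segments: IBDSegmentSet,
    tracts: AncestryTracts,
    target_label: str,
    min_overlap_frac: float = 1.0,
) -> IBDSegmentSet:
    """Keep segments whose span is (mostly) of the target ancestry.

    A segment survives when at least ``min_overlap_frac`` of its cM length
    lies in target-labelled tracts on *both* participating haplotypes.
    """
    t = segments.table
    if t.empty:
        return IBDSegmentSet(t.copy())
    tt = tracts.table
    keep = []
    for row in t.itertuples(index=False):
        fracs = []
        for sample, hap in ((row.sample1, row.hap1), (row.sample2, row.hap2)):
            sub = tt[
                (tt["sample"] == sample)
                & (tt["hap"] == hap)
                & (tt["chrom"] == row.chrom)
            ]
            if sub.empty:
                raise KeyError(f"no ancestry tracts for {sample} hap {hap}")
            target = sub[sub["ancestry"] == target_label]
            ov = 0.0
            for tr in target.itertuples(index=False):
                lo = max(tr.start_cm, row.start_cm)
                hi = min(tr.end_cm, row.end_cm)
                ov += max(0.0, hi - lo)
            span = max(row.end_cm - row.start_cm, 1e-12)
            fracs.append(ov / span)
        keep.append(min(fracs) >= min_overlap_frac - 1e-12)
    out = t[np.array(keep, dtype=bool)].copy()
    out["ancestry"] = target_label
    return IBDSegmentSet(out.reset_index(drop=True))


# --------------------------------------------------------------------------
# time classification


def segment_age(
    length_cm: float, years_per_generation: float = YEARS_PER_GENERATION
) -> tuple[float, float]:
    """Expected age of an IBD segment: 3/(2 I) generations, I in morgans."""
    if length_cm <= 0:
        raise ValueError("segment length must be positive")
    generations = 3.0 / (2.0 * (length_cm / 100.0))
    return generations, generations * years_per_generation


def bin_to_period(length_cm: float) -> str:
    """Pre-Columbian (<= 8.4 cM), colonial ((8.4, 28] cM) or recent (> 28 cM)."""
    if length_cm <= 0:
        raise ValueError("segment length must be positive")
    if length_cm <= PRECOLUMBIAN_MAX_CM:
        return "precolumbian"
    if length_cm <= COLONIAL_MAX_CM:
        return "colonial"
    return "recent"


# --------------------------------------------------------------------------
# sharing networks and length spectra


@dataclass
class SharingNetwork:
    period: str
    edges: pd.DataFrame  # pop1, pop2, avg_count, avg_length_cm, n1, n2
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["pop1", "pop2", "avg_length_cm", "reason"]
        )
    )

    def edge(self, a: str, b: str) -> pd.Series:
        a, b = sorted([a, b])
        sub = self.edges[(self.edges["pop1"] == a) & (self.edges["pop2"] == b)]
        if sub.empty:
            raise KeyError(f"pair ({a}, {b}) not in network")
        return sub.iloc[0]


def sharing_network(
    segments: IBDSegmentSet,
    grouping: dict[str, str],
    period: str | None = None,
    min_avg_cm: float = 5.0,
    min_len_cm: float = 2.0,
) -> SharingNetwork:
    """Population-pair IBD sharing normalized by the sample-size product.

    For each population pair, avg_count = number of shared segments
    divided by n1*n2 and avg_length = summed cM divided by n1*n2 (the
    within-population diagonal also uses n*n for consistency with the
    product rule). Pairs whose avg_length does not exceed ``min_avg_cm``
    are excluded and recorded.
    """
    sizes: dict[str, int] = {}
    for sid, pop in grouping.items():
        sizes[pop] = sizes.get(pop, 0) + 1
    if not sizes or any(v == 0 for v in sizes.values()):
        raise ValueError("population of size 0")
    t = segments.table
    t = t[t["length_cm"] >= min_len_cm]
    if period is not None:
        t = t[[bin_to_period(x) == period for x in t["length_cm"]]]
    agg: dict[tuple[str, str], list] = {}
    for row in t.itertuples(index=False):
        p1 = grouping.get(row.sample1)
        p2 = grouping.get(row.sample2)
        if p1 is None or p2 is None:
            continue
        key = tuple(sorted([p1, p2]))
        agg.setdefault(key, [0, 0.0])
        agg[key][0] += 1
        agg[key][1] += row.length_cm
    pops = sorted(sizes)
    edge_rows, excl_rows = [], []
    for ai in range(len(pops)):
        for bi in range(ai, len(pops)):
            a, b = pops[ai], pops[bi]
            n1, n2 = sizes[a], sizes[b]
            count, total = agg.get((a, b), [0, 0.0])
            denom = n1 * n2
            avg_count = count / denom
            avg_len = total / denom
            if avg_len > min_avg_cm:
                edge_rows.append((a, b, avg_count, avg_len, n1, n2))
            else:
                excl_rows.append((a, b, avg_len, f"avg length <= {min_avg_cm} cM"))
    return SharingNetwork(
        period or "all",
        pd.DataFrame(
            edge_rows,
            columns=["pop1", "pop2", "avg_count", "avg_length_cm", "n1", "n2"],
        ),
        pd.DataFrame(excl_rows, columns=["pop1", "pop2", "avg_length_cm", "reason"]),
    )


LENGTH_BINS_CM = [(1.0, 2.0), (2.0, 4.0), (4.0, 8.0), (8.0, 16.0), (16.0, np.inf)]


def length_category_summary(
    segments: IBDSegmentSet,
    grouping: dict[str, str],
    pair_counts: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-population segment counts and mean lengths in five length bins.

    Bins are half-open [low, high) in cM: 1-2, 2-4, 4-8, 8-16, >16.
    Only intra-population segments (both samples in the same population)
    are summarized. ``pair_counts`` optionally normalizes counts (e.g.,
    by the number of sample pairs per population); default is raw counts.
    """
    pops = sorted(set(grouping.values()))
    rows = []
    t = segments.table
    for pop in pops:
        members = {s for s, p in grouping.items() if p == pop}
        sub = t[t["sample1"].isin(members) & t["sample2"].isin(members)]
        denom = (pair_counts or {}).get(pop, 1.0)
        for lo, hi in LENGTH_BINS_CM:
            sel = sub[(sub["length_cm"] >= lo) & (sub["length_cm"] < hi)]
            label = f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"
            rows.append(
                (
                    pop,
                    label,
                    len(sel) / denom,
                    float(sel["length_cm"].mean()) if len(sel) else 0.0,
                )
            )
    return pd.DataFrame(rows, columns=["population", "bin", "avg_count", "avg_length_cm"])
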