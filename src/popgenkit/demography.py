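"""Founder-event dating and effective-population-size history.

Founder events are inferred from the decay of allele-sharing correlation
with genetic distance: within a population that passed through a recent
bottleneck, pairs of sites at distance d morgans show excess correlation
proportional to exp(-2 * FA * d), FA the age of the event in
generations. The cross-population correlation against an outgroup is
subtracted to remove ancestral sharing. The fitted zero-distance
amplitude, in percent, is reported as the founder intensity (FI).

N_e history is fit from the IBD segment length spectrum. With a
piecewise-constant diploid trajectory N_g, a haplotype pair coalesces at
generation g with probability P(g) = (1/(2 N_g)) prod_{h<g}(1 - 1/(2 N_h)),
and conditional on g the expected number of maximal shared tracts longer
than u morgans in a genome of G morgans is (2 g G + 1) exp(-2 g u). The
fit minimizes the Poisson deviance of binned observed counts against
this forward model with a smoothness penalty on adjacent log-N_e epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .ibd import IBDSegmentSet
from .panel import MISSING, GenotypePanel


# --------------------------------------------------------------------------
# allele-sharing decay


@dataclass
class DecayCurve:
    bin_centers_cm: np.ndarray
    within: np.ndarray
    cross: np.ndarray
    corrected: np.ndarray
    # per-chromosome sums for block bootstrap: chrom -> (sum per bin, count per bin)
    per_chrom: dict = field(default_factory=dict)
    # per-chromosome per-sample-pair binned product sums, for the joint
    # chromosome x individual bootstrap: chrom -> (n_pairs, n_bins)
    pair_within: dict = field(default_factory=dict)
    pair_cross: dict = field(default_factory=dict)
    bin_counts: dict = field(default_factory=dict)  # chrom -> counts per bin
    within_pairs: list = field(default_factory=list)  # (focal_i, focal_j)
    cross_focal: list = field(default_factory=list)  # focal index per cross pair
    n_focal: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_centers_cm) <= 0):
            raise ValueError("bins must be increasing")


def _sharing_matrix(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Allele-sharing probability per site for a pair of diploids."""
    return (g1 * g2 + (2.0 - g1) * (2.0 - g2)) / 4.0


def allele_sharing_decay(
    panel: GenotypePanel,
    focal_population: str,
    outgroup_samples: list[str],
    max_cm: float = 30.0,
    bin_cm: float = 0.1,
) -> DecayCurve:
    """Binned allele-sharing correlation versus genetic distance.

    Within-focal sample pairs give the raw curve; focal-versus-outgroup
    pairs give the ancestral-sharing baseline subtracted to form the
    corrected curve. Requires more than 5 focal samples.
    """
    st = panel.sample_table
    focal_idx = np.flatnonzero((st["population"] == focal_population).to_numpy())
    if len(focal_idx) < 5:
        raise ValueError(
            f"focal population {focal_population!r} has {len(focal_idx)} samples; "
            "founder-event dating requires at least 5 unrelated samples"
        )
    id_to_row = {sid: i for i, sid in enumerate(st["id"])}
    out_idx = np.array([id_to_row[s] for s in outgroup_samples])

    g = panel.genotypes.astype(float)
    g[panel.genotypes == MISSING] = np.nan
    cms = panel.snp_table["cm"].to_numpy(dtype=float)
    chroms = panel.snp_table["chrom"].to_numpy()

    n_bins = int(np.ceil(max_cm / bin_cm))
    edges = bin_cm * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def centered_pair_matrix(rows_a, rows_b, same: bool) -> np.ndarray:
        cols = []
        for ai, a in enumerate(rows_a):
            for b in rows_b[ai + 1 :] if same else rows_b:
                cols.append(_sharing_matrix(g[a], g[b]))
        v = np.array(cols)  # (n_pairs, S)
        v = v - np.nanmean(v, axis=0, keepdims=True)
        return np.nan_to_num(v, nan=0.0)

    vw = centered_pair_matrix(focal_idx, focal_idx, same=True)
    vx = centered_pair_matrix(focal_idx, out_idx, same=False)
    n_focal = len(focal_idx)
    within_pairs = [
        (a, b) for a in range(n_focal) for b in range(a + 1, n_focal)
    ]
    cross_focal = [a for a in range(n_focal) for _ in out_idx]

    within_sum = np.zeros(n_bins)
    cross_sum = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    per_chrom: dict = {}
    pair_within: dict = {}
    pair_cross: dict = {}
    bin_counts: dict = {}
    for chrom in pd.unique(chroms):
        sl = np.flatnonzero(chroms == chrom)
        c = cms[sl]
        d = np.abs(c[:, None] - c[None, :])
        iu = np.triu_indices(len(sl), 1)
        dd = d[iu]
        sel = (dd > 0) & (dd <= max_cm)
        binidx = np.minimum((dd[sel] / bin_cm).astype(int), n_bins - 1)
        i_idx = sl[iu[0][sel]]
        j_idx = sl[iu[1][sel]]
        pw = np.empty((vw.shape[0], n_bins))
        for p in range(vw.shape[0]):
            pw[p] = np.bincount(
                binidx, weights=vw[p, i_idx] * vw[p, j_idx], minlength=n_bins
            )
        px = np.empty((vx.shape[0], n_bins))
        for p in range(vx.shape[0]):
            px[p] = np.bincount(
                binidx, weights=vx[p, i_idx] * vx[p, j_idx], minlength=n_bins
            )
        ws = pw.mean(axis=0)
        xs = px.mean(axis=0)
        ct = np.bincount(binidx, minlength=n_bins).astype(float)
        within_sum += ws
        cross_sum += xs
        counts += ct
        per_chrom[chrom] = (ws - xs, ct)
        pair_within[chrom] = pw
        pair_cross[chrom] = px
        bin_counts[chrom] = ct

    with np.errstate(invalid="ignore", divide="ignore"):
        within = np.where(counts > 0, within_sum / counts, np.nan)
        cross = np.where(counts > 0, cross_sum / counts, np.nan)
    return DecayCurve(
        centers, within, cross, within - cross, per_chrom,
        pair_within, pair_cross, bin_counts, within_pairs, cross_focal, n_focal,
    )


@dataclass
class FounderEvent:
    founder_age_gen: float
    founder_age_years: float
    founder_intensity_pct: float
    fa_ci: tuple[float, float]
    fi_ci: tuple[float, float]
    converged: bool = True
    fa_identifiable: bool = True
    diagnostics: dict = field(default_factory=dict)


def _fit_decay(centers_cm: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Fit y = A exp(-2 FA d) + c, d in morgans. Returns (A, FA, c)."""
    d = centers_cm / 100.0
    ok = np.isfinite(y)
    d, y = d[ok], y[ok]
    if len(y) < 20:
        raise ValueError("decay fit requires at least 20 populated bins")
    a0 = max(y[: max(3, len(y) // 20)].mean(), 1e-6)
    c0 = y[-max(3, len(y) // 10) :].mean()
    fa0 = 10.0
    popt, _ = optimize.curve_fit(
        lambda x, a, fa, c: a * np.exp(-2.0 * fa * x) + c,
        d,
        y,
        p0=[a0, fa0, c0],
        bounds=([0.0, 0.0, -1.0], [1.0, 500.0, 1.0]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])


def fit_founder_event(
    curve: DecayCurve,
    bootstrap_n: int = 100,
    seed: int = 0,
    years_per_generation: float = 28.0,
) -> FounderEvent:
    """Exponential-decay fit of the corrected curve: age and intensity.

    The 95% CI comes from a block bootstrap over chromosomes (bin-level
    resampling when the curve holds a single chromosome). An amplitude
    indistinguishable from zero flags the age as unidentifiable.
    """
    try:
        a, fa, c = _fit_decay(curve.bin_centers_cm, curve.corrected)
        converged = True
    except (RuntimeError, ValueError) as exc:
        return FounderEvent(
            float("nan"), float("nan"), 0.0, (float("nan"), float("nan")),
            (float("nan"), float("nan")), converged=False,
            fa_identifiable=False, diagnostics={"error": str(exc)},
        )
    rng = np.random.default_rng(seed)
    chrom_keys = list(curve.per_chrom)
    fas, fis = [], []
    pairs = np.array(curve.within_pairs) if curve.within_pairs else None
    cross_focal = np.array(curve.cross_focal) if curve.cross_focal else None
    for _ in range(bootstrap_n):
        if pairs is not None and len(chrom_keys) > 1:
            # joint bootstrap: chromosomes and focal individuals — the
            # individual resample propagates shared (genome-wide)
            # variance that a chromosome-only bootstrap cannot see
            pick = rng.choice(len(chrom_keys), size=len(chrom_keys), replace=True)
            m = np.bincount(
                rng.integers(0, curve.n_focal, curve.n_focal),
                minlength=curve.n_focal,
            )
            w_pairs = (m[pairs[:, 0]] * m[pairs[:, 1]]).astype(float)
            w_cross = m[cross_focal].astype(float)
            if w_pairs.sum() == 0 or w_cross.sum() == 0:
                continue
            s = np.zeros_like(curve.corrected)
            n = np.zeros_like(curve.corrected)
            for k in pick:
                ck = chrom_keys[k]
                s += (
                    w_pairs @ curve.pair_within[ck]
                ) / w_pairs.sum() - (w_cross @ curve.pair_cross[ck]) / w_cross.sum()
                n += curve.bin_counts[ck]
            with np.errstate(invalid="ignore", divide="ignore"):
                y = np.where(n > 0, s / n, np.nan)
            x = curve.bin_centers_cm
        elif len(chrom_keys) > 1:
            pick = rng.choice(len(chrom_keys), size=len(chrom_keys), replace=True)
            s = np.zeros_like(curve.corrected)
            n = np.zeros_like(curve.corrected)
            for k in pick:
                cs, ct = curve.per_chrom[chrom_keys[k]]
                s += cs
                n += ct
            with np.errstate(invalid="ignore", divide="ignore"):
                y = np.where(n > 0, s / n, np.nan)
            x = curve.bin_centers_cm
        else:
            ok = np.flatnonzero(np.isfinite(curve.corrected))
            pick = rng.choice(ok, size=len(ok), replace=True)
            x = curve.bin_centers_cm[pick]
            y = curve.corrected[pick]
            order = np.argsort(x)
            # jitter duplicate centers to keep bins increasing for the fit
            x = x[order] + 1e-9 * np.arange(len(order))
            y = y[order]
        try:
            ab, fab, _ = _fit_decay(x, y)
            fas.append(fab)
            fis.append(100.0 * ab)
        except (RuntimeError, ValueError):
            continue
    fa_ci = (
        tuple(np.percentile(fas, [2.5, 97.5])) if fas else (float("nan"), float("nan"))
    )
    fi_ci = (
        tuple(np.percentile(fis, [2.5, 97.5])) if fis else (float("nan"), float("nan"))
    )
    # FA is identifiable only when the exponential term beats a flat curve
    # decisively (F-test of the 2 extra parameters)
    d = curve.bin_centers_cm / 100.0
    ok = np.isfinite(curve.corrected)
    y_obs = curve.corrected[ok]
    fit_vals = a * np.exp(-2.0 * fa * d[ok]) + c
    sse_exp = float(np.sum((y_obs - fit_vals) ** 2))
    sse_const = float(np.sum((y_obs - y_obs.mean()) ** 2))
    n_fit = len(y_obs)
    f_stat = (
        ((sse_const - sse_exp) / 2.0) / (sse_exp / max(n_fit - 3, 1))
        if sse_exp > 0
        else np.inf
    )
    identifiable = bool(np.isfinite(fa) and f_stat > 10.0)
    return FounderEvent(
        founder_age_gen=fa,
        founder_age_years=fa * years_per_generation,
        founder_intensity_pct=100.0 * a,
        fa_ci=fa_ci,
        fi_ci=fi_ci,
        converged=converged,
        fa_identifiable=identifiable,
        diagnostics={
            "amplitude": a,
            "baseline": c,
            "n_bootstrap_ok": len(fas),
            "f_vs_constant": f_stat,
        },
    )


# --------------------------------------------------------------------------
# IBD length spectrum and Ne history


@dataclass
class NeTrajectory:
    ne: np.ndarray  # diploid Ne per generation, index 0 = 1 generation ago
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.ne) <= 0):
            raise ValueError("Ne must be positive")

    def at(self, generation: int) -> float:
        if not 1 <= generation <= len(self.ne):
            raise IndexError(f"generation {generation} outside horizon")
        return float(self.ne[generation - 1])


def coalescent_probabilities(ne: np.ndarray) -> np.ndarray:
    """P(pair coalesces exactly at generation g), g = 1..len(ne)."""
    haz = 1.0 / (2.0 * np.asarray(ne, dtype=float))
    surv = np.concatenate([[1.0], np.cumprod(1.0 - haz[:-1])])
    return surv * haz


def expected_ibd_spectrum(
    traj: NeTrajectory,
    genome_morgans: float,
    length_bins_cm: np.ndarray,
    warn_mass: float = 0.01,
) -> np.ndarray:
    """Expected maximal-segment counts per haplotype pair per length bin.

    ``length_bins_cm`` are bin edges (increasing, cM); the return has one
    entry per bin [edge_i, edge_i+1). Counts longer than u from
    coalescence at g: (2 g G + 1) exp(-2 g u); bins by differencing.
    Warns when more than ``warn_mass`` coalescent probability lies beyond
    the trajectory horizon.
    """
    edges_m = np.asarray(length_bins_cm, dtype=float) / 100.0
    if np.any(np.diff(edges_m) <= 0):
        raise ValueError("length bin edges must be increasing")
    p = coalescent_probabilities(traj.ne)
    tail = 1.0 - p.sum()
    if tail > warn_mass:
        warnings.warn(
            f"{100 * tail:.1f}% of coalescent mass beyond the trajectory horizon",
            stacklevel=2,
        )
    g = np.arange(1, len(p) + 1, dtype=float)
    # exceed[i, j] = E[# maximal tracts > edge_j | coalescence at g_i]:
    # Poisson breakpoints at rate 2g on a line of length G give
    # (2 g (G - u) + 1) exp(-2 g u) intervals longer than u (0 for u >= G)
    rem = np.clip(genome_morgans - edges_m[None, :], 0.0, None)
    exceed = np.where(
        edges_m[None, :] < genome_morgans,
        (2.0 * g[:, None] * rem + 1.0) * np.exp(-2.0 * g[:, None] * edges_m[None, :]),
        0.0,
    )
    per_bin = exceed[:, :-1] - exceed[:, 1:]
    return p @ per_bin


def _segment_lengths_cm(segments) -> np.ndarray:
    if isinstance(segments, IBDSegmentSet):
        return segments.table["length_cm"].to_numpy(dtype=float)
    return np.asarray(segments, dtype=float)


def fit_ne_history(
    segments,
    n_pairs: int,
    genome_morgans: float,
    horizon_generations: int = 100,
    n_epochs: int = 10,
    min_len_cm: float = 2.0,
    bootstrap_n: int = 100,
    seed: int = 0,
    smoothness: float = 1.0,
    filter_related: bool = True,
) -> NeTrajectory:
    """Piecewise-constant Ne trajectory from an IBD length spectrum.

    ``segments`` is an :class:`IBDSegmentSet` or an array of segment
    lengths in cM; ``n_pairs`` the number of haplotype pairs scanned.
    Epoch boundaries are log-spaced over the horizon; the fit minimizes
    Poisson deviance of geometric length-bin counts with a quadratic
    smoothness penalty on adjacent log10-Ne. The CI is a bootstrap over
    segments. With ``filter_related=False`` a warning records that the
    most recent generations are biased by retained related pairs.
    """
    lengths = _segment_lengths_cm(segments)
    lengths = lengths[lengths >= min_len_cm]
    flags: dict = {}
    if not filter_related:
        warnings.warn(
            "related pairs retained: estimates for the most recent generations "
            "are expected to be particularly biased",
            stacklevel=2,
        )
        flags["related_retained"] = True
    if len(lengths) < 50:
        flags["low_confidence"] = f"only {len(lengths)} segments"

    top = max(lengths.max() + 1.0, 30.0) if len(lengths) else 30.0
    bin_edges = np.geomspace(min_len_cm, top, 16)
    obs, _ = np.histogram(lengths, bins=bin_edges)

    bounds_g = np.unique(
        np.round(np.geomspace(1, horizon_generations, n_epochs + 1)).astype(int)
    )
    n_ep = len(bounds_g) - 1

    def expand(log10_ne: np.ndarray) -> np.ndarray:
        ne = np.empty(horizon_generations)
        for e in range(n_ep):
            ne[bounds_g[e] - 1 : bounds_g[e + 1]] = 10.0 ** log10_ne[e]
        ne[bounds_g[-1] - 1 :] = 10.0 ** log10_ne[-1]
        return ne

    def objective(log10_ne: np.ndarray, observed: np.ndarray) -> float:
        ne = expand(log10_ne)
        exp_counts = n_pairs * expected_ibd_spectrum(
            NeTrajectory(ne), genome_morgans, bin_edges, warn_mass=1.1
        )
        exp_counts = np.maximum(exp_counts, 1e-9)
        dev = 2.0 * np.sum(
            exp_counts
            - observed
            + np.where(observed > 0, observed * np.log(observed / exp_counts), 0.0)
        )
        pen = smoothness * np.sum(np.diff(log10_ne) ** 2)
        return dev + pen

    def fit_once(observed: np.ndarray, x0: np.ndarray) -> np.ndarray:
        res = optimize.minimize(
            objective,
            x0,
            args=(observed,),
            method="L-BFGS-B",
            bounds=[(0.5, 8.0)] * n_ep,
        )
        return res.x

    x0 = np.full(n_ep, 3.0)
    x_hat = fit_once(obs, x0)
    ne_hat = expand(x_hat)

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(bootstrap_n):
        res_lengths = rng.choice(lengths, size=len(lengths), replace=True)
        ob, _ = np.histogram(res_lengths, bins=bin_edges)
        boot.append(expand(fit_once(ob, x_hat)))
    if boot:
        arr = np.array(boot)
        lo = np.percentile(arr, 2.5, axis=0)
        hi = np.percentile(arr, 97.5, axis=0)
    else:
        lo = hi = None
    if hi is not None and np.any(hi / np.maximum(lo, 1e-12) > 1e4):
        flags["wide_ci"] = "trajectory poorly constrained in some epochs"
    return NeTrajectory(ne_hat, lo, hi, flags)


def trajectory_change(traj: NeTrajectory, from_gen: int, to_gen: int) -> float:
    """Percent reduction of Ne between two generations (growth is negative)."""
    n_from = traj.at(from_gen)
    n_to = traj.at(to_gen)
    return 100.0 * (n_from - n_to) / n_from
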