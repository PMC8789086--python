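"""Synthetic-truth validation experiments.

Each function runs a self-contained experiment against planted or
simulated ground truth and returns the summary quantities a user would
check before trusting the pipeline on real data: detector exactness on
clean fixtures, null calibration of f4 and AMOVA tests, parameter
recovery for founder events and Ne trajectories, the closed-form IBD
spectrum against its generative oracle, and the serial-founder F_ROH
gradient. All randomness derives from the single seed argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .amova import amova
from .demography import (
    NeTrajectory,
    allele_sharing_decay,
    expected_ibd_spectrum,
    fit_founder_event,
    fit_ne_history,
)
from .fstats import allele_frequencies, f_statistic
from .graphs import AdmixtureGraph, expected_f_stats
from .ibd import detect_ibd, merge_gaps, segment_age
from .panel import GenotypePanel
from .roh import call_roh, covered_span, froh, froh_geography
from .simulate import (
    Bottleneck,
    Chromosome,
    Deme,
    DemographicModel,
    Split,
    plant_fixtures,
    simulate_ibd_segments,
    simulate_panel,
)

YEARS_PER_GENERATION = 28.0


def _subseed(seed: int, stream: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# time conversions


def time_conversions() -> dict[str, float]:
    """Segment-length ages and generation/year conversions."""
    gen_84, years_84 = segment_age(8.4)
    gen_28, years_28 = segment_age(28.0)
    return {
        "generations_at_8p4_cm": gen_84,
        "years_at_8p4_cm": years_84,
        "generations_at_28_cm": gen_28,
        "years_at_28_cm": years_28,
        "years_bp_at_8_generations": 8 * YEARS_PER_GENERATION,
        "years_bp_at_37_generations": 37 * YEARS_PER_GENERATION,
        "years_bp_at_75_generations": 75 * YEARS_PER_GENERATION,
    }


# --------------------------------------------------------------------------
# detector exactness on clean constructive fixtures


def _complementary_panel(n_snps: int, spacing_cm: float, seed: int) -> GenotypePanel:
    """Two samples whose cross-sample haplotypes mismatch at every site."""
    rng = np.random.default_rng(seed)
    r1 = rng.integers(0, 2, n_snps).astype(np.int8)
    r2 = rng.integers(0, 2, n_snps).astype(np.int8)
    hap = np.array([r1, r2, 1 - r1, 1 - r2], dtype=np.int8)
    cm = np.arange(n_snps) * spacing_cm
    pos = (cm * 1e6).astype(np.int64) + np.arange(n_snps) + 1
    snp = pd.DataFrame(
        {"chrom": "1", "pos": pos, "cm": cm, "ref": "A", "alt": "T",
         "id": [f"v{i}" for i in range(n_snps)]}
    )
    st = pd.DataFrame(
        {"id": ["s0", "s1"], "population": "P", "major_group": "P",
         "lat": 0.0, "lon": 0.0}
    )
    return GenotypePanel(hap[0::2] + hap[1::2], snp, st, hap)


def ibd_roh_exactness(seed: int) -> dict[str, float]:
    """Planted IBD and ROH recovery on clean fixtures.

    Returns detection precision and recall over planted segments and the
    worst truth-boundary error in SNPs for both detectors.
    """
    spacing = 100.0 / 3000
    panel = _complementary_panel(3000, spacing, _subseed(seed, 1))
    plants = [
        {"kind": "ibd", "sample1": "s0", "hap1": 0, "sample2": "s1", "hap2": 0,
         "chrom": "1", "start_cm": a, "end_cm": b}
        for a, b in ((10.0, 13.0), (30.0, 35.0), (60.0, 70.0))
    ]
    planted, truth = plant_fixtures(panel, plants, seed=_subseed(seed, 2))
    segs = merge_gaps(detect_ibd(planted, include_hbd=False), planted)
    cms = planted.snp_table["cm"].to_numpy()

    def snp_index(cm_val):
        return int(np.argmin(np.abs(cms - cm_val)))

    matched = np.zeros(len(truth.ibd), dtype=bool)
    n_spurious = 0
    max_err = 0
    for row in segs.table.itertuples(index=False):
        hit = None
        for t_i, tr in enumerate(truth.ibd.itertuples(index=False)):
            same_haps = (
                row.sample1 == tr.sample1 and row.sample2 == tr.sample2
                and row.hap1 == tr.hap1 and row.hap2 == tr.hap2
            )
            overlap = min(row.end_cm, tr.end_cm) - max(row.start_cm, tr.start_cm)
            if same_haps and overlap > 0:
                hit = t_i
                err = max(
                    abs(snp_index(row.start_cm) - snp_index(tr.start_cm)),
                    abs(snp_index(row.end_cm) - snp_index(tr.end_cm)),
                )
                max_err = max(max_err, err)
                break
        if hit is None:
            n_spurious += 1
        else:
            matched[hit] = True
    precision = (
        (len(segs.table) - n_spurious) / len(segs.table) if len(segs.table) else 0.0
    )
    recall = matched.mean() if len(truth.ibd) else 0.0

    # ROH: all-heterozygous background, planted homozygous runs
    rng = np.random.default_rng(_subseed(seed, 3))
    n = 3000
    h0 = rng.integers(0, 2, (2, n)).astype(np.int8)
    hap = np.empty((4, n), dtype=np.int8)
    hap[0::2] = h0
    hap[1::2] = 1 - h0
    pos = np.arange(n, dtype=np.int64) * 3000 + 1
    snp = pd.DataFrame(
        {"chrom": "1", "pos": pos, "cm": pos / 1e6, "ref": "A", "alt": "T",
         "id": [f"v{i}" for i in range(n)]}
    )
    st = pd.DataFrame(
        {"id": ["s0", "s1"], "population": "P", "major_group": "P",
         "lat": 0.0, "lon": 0.0}
    )
    het_panel = GenotypePanel(hap[0::2] + hap[1::2], snp, st, hap)
    planted_roh, truth_roh = plant_fixtures(
        het_panel,
        [{"kind": "roh", "sample": "s0", "chrom": "1", "start_cm": 2.0,
          "end_cm": 2.8},
         {"kind": "roh", "sample": "s1", "chrom": "1", "start_cm": 5.0,
          "end_cm": 6.5}],
        seed=_subseed(seed, 4),
    )
    rohs = call_roh(planted_roh)
    roh_err = 0
    roh_found = 0
    for tr in truth_roh.roh.itertuples(index=False):
        mine = rohs.table[
            (rohs.table["sample"] == tr.sample)
            & (rohs.table["end_bp"] > tr.start_bp)
            & (rohs.table["start_bp"] < tr.end_bp)
        ]
        if len(mine) == 1:
            roh_found += 1
            row = mine.iloc[0]
            roh_err = max(
                roh_err,
                int(round(abs(row.start_bp - tr.start_bp) / 3000)),
                int(round(abs(row.end_bp - tr.end_bp) / 3000)),
            )
    return {
        "ibd_precision": float(precision),
        "ibd_recall": float(recall),
        "ibd_boundary_err_snps": float(max_err),
        "roh_recall": roh_found / len(truth_roh.roh),
        "roh_boundary_err_snps": float(roh_err),
        "roh_spurious": float(len(rohs.table) - roh_found),
    }


# --------------------------------------------------------------------------
# f-statistics: graph oracle and null calibration


def _enumerate_edge_usage(graph: AdmixtureGraph, leaf: str) -> dict:
    """Brute-force path enumeration (independent of the mass propagation)."""
    usage: dict = {}

    def walk(node, prob):
        for p in graph.g.predecessors(node):
            w = graph.g.edges[p, node]["weight"]
            usage[(p, node)] = usage.get((p, node), 0.0) + prob * w
            walk(p, prob * w)

    walk(leaf, 1.0)
    return usage


def graph_oracle_max_error(seed: int, n_graphs: int = 20) -> float:
    """Worst |prediction - path-enumeration oracle| over random small graphs."""
    rng = np.random.default_rng(_subseed(seed, 10))
    worst = 0.0
    for k in range(n_graphs):
        g = AdmixtureGraph()
        if k % 2 == 0:
            g.add_edge("R", "x", rng.uniform(0.01, 0.1))
            g.add_edge("R", "C", rng.uniform(0.01, 0.1))
            g.add_edge("x", "A", rng.uniform(0.01, 0.1))
            g.add_edge("x", "B", rng.uniform(0.01, 0.1))
        else:
            g.add_edge("R", "x", rng.uniform(0.01, 0.1))
            g.add_edge("R", "y", rng.uniform(0.01, 0.1))
            g.add_edge("x", "A", rng.uniform(0.01, 0.1))
            g.add_edge("y", "B", rng.uniform(0.01, 0.1))
            g.add_admixture("x", "y", "C", w1=rng.uniform(0.2, 0.8))
        leaves = g.leaves
        edges = list(g.g.edges)
        lengths = np.array([g.g.edges[e]["length"] for e in edges])
        for i in range(len(leaves)):
            for j in range(i + 1, len(leaves)):
                a, b = leaves[i], leaves[j]
                pred = expected_f_stats(g, [("f2", (a, b))])[("f2", (a, b))]
                ua = _enumerate_edge_usage(g, a)
                ub = _enumerate_edge_usage(g, b)
                oracle = float(
                    np.sum(
                        lengths
                        * np.array(
                            [ua.get(e, 0.0) - ub.get(e, 0.0) for e in edges]
                        )
                        ** 2
                    )
                )
                worst = max(worst, abs(pred - oracle))
    return worst


def f4_null_calibration(seed: int, n_replicates: int = 100) -> dict[str, float]:
    """|Z| of f4 over arbitrary splits of one panmictic deme.

    The deme is large (2,000 diploids) so that the 24 sampled individuals
    are essentially unrelated; close kin would shift f4 genome-wide and
    is a real (not numerical) violation of the null.
    """
    n_ok = 0
    zs = []
    for rep in range(n_replicates):
        model = DemographicModel(
            demes=[Deme("P", 2000)],
            generations=1,
            chromosomes=[Chromosome("1", 100.0, 1500)],
        )
        panel, _ = simulate_panel(model, 24, seed=_subseed(seed, 100 + rep))
        grouping = {
            sid: f"G{i % 4}" for i, sid in enumerate(panel.sample_ids)
        }
        freqs = allele_frequencies(panel, grouping)
        z = abs(f_statistic(freqs, "f4", ("G0", "G1", "G2", "G3")).z)
        zs.append(z)
        n_ok += z < 3.0
    return {
        "frac_abs_z_lt_3": n_ok / n_replicates,
        "mean_abs_z": float(np.mean(zs)),
        "n": n_replicates,
    }


# --------------------------------------------------------------------------
# founder-event recovery


def founder_age_coverage(
    seed: int, n_replicates: int = 50, true_age: float = 10.0
) -> dict[str, float]:
    """Bottleneck (25 diploids for 2 generations, ~10 generations ago)
    planted in a deme of 800; fraction of replicates whose 95% bootstrap
    CI covers the true age."""
    covered = 0
    ages = []
    for rep in range(n_replicates):
        model = DemographicModel(
            demes=[Deme("F", 800, bn_f=0.02), Deme("O", 800, bn_f=0.02)],
            generations=15,
            bottlenecks=[
                Bottleneck("F", start_gen=int(true_age) + 1, duration=2,
                           reduced_size=25)
            ],
            chromosomes=[Chromosome(str(c), 50.0, 600) for c in range(8)],
        )
        panel, _ = simulate_panel(
            model, {"F": 12, "O": 15}, seed=_subseed(seed, 200 + rep)
        )
        curve = allele_sharing_decay(
            panel, "F", [f"O_{i}" for i in range(15)]
        )
        ev = fit_founder_event(curve, bootstrap_n=40, seed=_subseed(seed, 300 + rep))
        ages.append(ev.founder_age_gen)
        lo, hi = ev.fa_ci
        if np.isfinite(lo) and lo <= true_age <= hi:
            covered += 1
    return {
        "ci_coverage": covered / n_replicates,
        "median_age": float(np.median(ages)),
        "n": n_replicates,
    }


# --------------------------------------------------------------------------
# Ne trajectory recovery and spectrum oracle


def ne_recovery(seed: int) -> dict[str, float]:
    """Constant-Ne recovery and detection of a 10-fold recent crash."""
    ne_const = np.full(100, 1000.0)
    lengths = simulate_ibd_segments(
        ne_const, 30_000, 30.0, 0.02, seed=_subseed(seed, 400)
    )
    traj = fit_ne_history(
        lengths * 100.0, n_pairs=30_000, genome_morgans=30.0,
        bootstrap_n=0, seed=_subseed(seed, 401),
    )
    const_median = float(np.median(traj.ne))

    ne_crash = np.concatenate([np.full(20, 500.0), np.full(80, 5000.0)])
    lengths2 = simulate_ibd_segments(
        ne_crash, 60_000, 30.0, 0.02, seed=_subseed(seed, 402)
    )
    traj2 = fit_ne_history(
        lengths2 * 100.0, n_pairs=60_000, genome_morgans=30.0,
        bootstrap_n=0, seed=_subseed(seed, 403),
    )
    recent = float(np.median(traj2.ne[:15]))
    old = float(np.median(traj2.ne[30:80]))
    return {
        "constant_ne_median": const_median,
        "crash_fold_decline": old / recent,
    }


def spectrum_oracle_max_rel_error(seed: int) -> dict[str, float]:
    """Closed-form bin counts vs the generative segment simulation."""
    out = {}
    bins = np.array([2.0, 4.0, 8.0, 16.0, 30.0])
    for name, ne in (
        ("constant", np.full(100, 1000.0)),
        ("two_epoch", np.concatenate([np.full(20, 300.0), np.full(80, 3000.0)])),
    ):
        n_pairs = 120_000
        exp = expected_ibd_spectrum(NeTrajectory(ne), 30.0, bins) * n_pairs
        lengths = simulate_ibd_segments(
            ne, n_pairs, 30.0, 0.015, seed=_subseed(seed, 500 + len(name))
        )
        obs, _ = np.histogram(lengths * 100.0, bins=bins)
        populated = exp >= 20
        out[name] = float(
            np.max(np.abs(obs[populated] / exp[populated] - 1.0))
        )
    return out


# --------------------------------------------------------------------------
# AMOVA null calibration


def amova_type1(
    seed: int, n_runs: int = 200, alpha: float = 0.05, n_perm: int = 99
) -> dict[str, float]:
    """Rejection rates of the permutation tests on label-randomized
    panmictic data (all hierarchy levels truly null)."""
    rng = np.random.default_rng(_subseed(seed, 600))
    n_pops, per_pop, n_snps = 4, 6, 200
    rej = {"among_populations": 0, "among_individuals": 0}
    for r in range(n_runs):
        p = rng.uniform(0.2, 0.8, n_snps)
        g = (
            (rng.random((n_pops * per_pop, n_snps, 2)) < p[None, :, None])
            .sum(-1)
            .astype(np.int8)
        )
        snp = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(n_snps) * 1000 + 1,
             "cm": np.arange(n_snps) * 0.01, "ref": "A", "alt": "T",
             "id": [f"v{i}" for i in range(n_snps)]}
        )
        pops = [f"p{k // per_pop}" for k in range(n_pops * per_pop)]
        st = pd.DataFrame(
            {"id": [f"s{i}" for i in range(n_pops * per_pop)],
             "population": pops,
             "major_group": [f"g{int(x[1:]) % 2}" for x in pops],
             "lat": 0.0, "lon": 0.0}
        )
        panel = GenotypePanel(g, snp, st)
        res = amova(panel, n_perm=n_perm, seed=_subseed(seed, 700 + r))
        for k in rej:
            if res.p_values.get(k, 1.0) <= alpha:
                rej[k] += 1
    return {
        "among_populations_rate": rej["among_populations"] / n_runs,
        "among_individuals_rate": rej["among_individuals"] / n_runs,
        "n": n_runs,
    }


# --------------------------------------------------------------------------
# serial-founder F_ROH gradient


def serial_founder_gradient(seed: int) -> dict[str, float]:
    """Five demes founded eastward in sequence, each through a 25-diploid
    bottleneck; F_ROH should rise strictly along the chain."""
    demes = [
        Deme(f"d{k}", 250, bn_f=0.02, lon=-75.0 + 10 * k) for k in range(5)
    ]
    splits = [
        Split(f"d{k}", [f"d{k + 1}"], generation=40 - 8 * k) for k in range(4)
    ]
    bots = [
        Bottleneck(f"d{k + 1}", start_gen=40 - 8 * k, duration=3, reduced_size=25)
        for k in range(4)
    ]
    model = DemographicModel(
        demes=demes, generations=45, splits=splits, bottlenecks=bots,
        chromosomes=[Chromosome(str(c), 80.0, 4000) for c in range(4)],
    )
    panel, _ = simulate_panel(model, 12, seed=_subseed(seed, 800))
    rohs = call_roh(panel)
    ftab = froh(rohs, covered_span(panel), panel)
    values = (
        ftab.per_population.sort_values("population")["mean_froh"].to_numpy()
    )
    coords = (
        panel.sample_table.groupby("population")[["lat", "lon"]]
        .first()
        .reset_index()
    )
    res = froh_geography(ftab, coords, axis="lon")
    return {
        "strictly_increasing": float(np.all(np.diff(values) > 0)),
        "spearman_r": res.spearman_r,
        "spearman_p": res.spearman_p,
        "froh_westmost": float(values[0]),
        "froh_eastmost": float(values[-1]),
    }
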