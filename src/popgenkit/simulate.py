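"""Synthetic genotype panels with known truth.

Two generators:

* :func:`simulate_panel` — a discrete-generation Wright-Fisher forward
  simulation of structured demes. Founder haplotypes are drawn site-wise
  from Balding-Nichols per-deme allele frequencies around shared ancestral
  frequencies; recombination is modelled as Poisson crossovers on the cM
  map (no interference); splits, admixture pulses, bottlenecks and
  symmetric migration are supported. Output is fully phased, with
  per-haplotype ancestry tracts tracked exactly through every meiosis.

* :func:`plant_fixtures` — constructive edits of an existing phased panel
  that create IBD/HBD/ROH segments and pedigree relatives with exactly
  known coordinates, for detector unit tests.

Both are deterministic under their seed. A third helper,
:func:`simulate_ibd_segments`, draws IBD segment lengths generatively
from an effective-population-size trajectory (coalescence time per
haplotype pair, Poisson crossover breakpoints, maximal shared tracts);
it serves as the independent check for closed-form segment-count
predictions and as a fast segment source for trajectory-fitting tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel

DEFAULT_BP_PER_CM = 1_000_000


@dataclass
class Chromosome:
    name: str
    length_cm: float
    n_snps: int


@dataclass
class Deme:
    """A simulated population.

    ``size`` is the constant diploid size; ``bn_f`` the Balding-Nichols
    divergence of its founder allele frequencies from the shared ancestral
    frequencies (pairwise Hudson F_ST between two demes is approximately
    the mean of their ``bn_f`` values). ``lat``/``lon`` feed the sample
    metadata for geography analyses. ``founded_by`` marks demes created by
    a split event rather than present from the simulation start.
    """

    name: str
    size: int
    bn_f: float = 0.0
    lat: float = 0.0
    lon: float = 0.0
    group: str | None = None
    founded_by: str | None = None

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError(f"deme {self.name}: diploid size must be >= 2")


@dataclass
class Bottleneck:
    deme: str
    start_gen: int  # generations before present at which the bottleneck begins
    duration: int
    reduced_size: int


@dataclass
class AdmixturePulse:
    source: str
    target: str
    fraction: float
    generation: int  # generations before present

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("admixture fraction must be in (0,1)")


@dataclass
class Split:
    parent: str
    children: list[str]
    generation: int  # child demes founded this many generations before present


@dataclass
class DemographicModel:
    """Full specification of a forward simulation."""

    demes: list[Deme]
    generations: int = 20
    chromosomes: list[Chromosome] = field(
        default_factory=lambda: [Chromosome("1", 100.0, 5000)]
    )
    bottlenecks: list[Bottleneck] = field(default_factory=list)
    pulses: list[AdmixturePulse] = field(default_factory=list)
    splits: list[Split] = field(default_factory=list)
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    # Balding-Nichols divergence of each major group's frequencies from the
    # shared ancestral ones; demes then diverge by their own bn_f around
    # their group's frequencies (hierarchical structure for AMOVA-style data)
    group_bn_f: dict[str, float] = field(default_factory=dict)
    bp_per_cm: int = DEFAULT_BP_PER_CM

    def deme_names(self) -> list[str]:
        return [d.name for d in self.demes]

    def size_at(self, deme: str, gens_ago: int) -> int:
        base = next(d.size for d in self.demes if d.name == deme)
        for b in self.bottlenecks:
            if b.deme == deme and b.start_gen >= gens_ago > b.start_gen - b.duration:
                return b.reduced_size
        return base


@dataclass
class TruthSet:
    """Planted / tracked ground truth accompanying a synthetic panel.

    All tables use sample ids, haplotype indices in {0,1}, 1-based
    inclusive bp coordinates and cM map coordinates.
    """

    ibd: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "sample1", "hap1", "sample2", "hap2", "chrom",
                "start_bp", "end_bp", "start_cm", "end_cm",
            ]
        )
    )
    roh: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample", "chrom", "start_bp", "end_bp", "start_cm", "end_cm"]
        )
    )
    tracts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample", "hap", "chrom", "start_cm", "end_cm", "ancestry"]
        )
    )
    pedigree: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample1", "sample2", "relation", "expected_pi_hat"]
        )
    )


# --------------------------------------------------------------------------
# genome helpers


def _snp_positions(model: DemographicModel, rng: np.random.Generator):
    """Place SNPs uniformly at random (sorted) along each chromosome."""
    chroms, cms = [], []
    for ch in model.chromosomes:
        u = np.sort(rng.uniform(0.0, ch.length_cm, ch.n_snps))
        chroms.append(np.full(ch.n_snps, ch.name, dtype=object))
        cms.append(u)
    chrom_arr = np.concatenate(chroms)
    cm_arr = np.concatenate(cms)
    bp_arr = np.maximum(1, np.round(cm_arr * model.bp_per_cm)).astype(np.int64)
    # enforce strictly increasing bp within chromosome
    for ch in model.chromosomes:
        sl = chrom_arr == ch.name
        bp = bp_arr[sl]
        bp = np.maximum.accumulate(bp + np.arange(len(bp)) * 0)  # already sorted
        for i in range(1, len(bp)):
            if bp[i] <= bp[i - 1]:
                bp[i] = bp[i - 1] + 1
        bp_arr[sl] = bp
    return chrom_arr, bp_arr, cm_arr


def _chrom_slices(model: DemographicModel) -> list[tuple[int, int, float]]:
    out, start = [], 0
    for ch in model.chromosomes:
        out.append((start, start + ch.n_snps, ch.length_cm))
        start += ch.n_snps
    return out


def _meiosis(
    rng: np.random.Generator,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    anc_a: np.ndarray,
    anc_b: np.ndarray,
    slices: list[tuple[int, int, float]],
    cm: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: Poisson crossovers per chromosome on the cM map."""
    gam = np.empty_like(hap_a)
    ganc = np.empty_like(anc_a)
    for s, e, length_cm in slices:
        n_x = rng.poisson(length_cm / 100.0)
        phase = rng.integers(0, 2)
        if n_x == 0:
            src_h = hap_a if phase == 0 else hap_b
            src_a = anc_a if phase == 0 else anc_b
            gam[s:e] = src_h[s:e]
            ganc[s:e] = src_a[s:e]
            continue
        cuts = np.sort(rng.uniform(0.0, length_cm, n_x))
        seg = np.searchsorted(cuts, cm[s:e], side="right")
        use_b = ((seg + phase) % 2).astype(bool)
        gam[s:e] = np.where(use_b, hap_b[s:e], hap_a[s:e])
        ganc[s:e] = np.where(use_b, anc_b[s:e], anc_a[s:e])
    return gam, ganc


# --------------------------------------------------------------------------
# forward simulation


def simulate_panel(
    model: DemographicModel,
    n_samples_per_deme: int | dict[str, int],
    seed: int,
) -> tuple[GenotypePanel, TruthSet]:
    """Forward-simulate a structured panel and return it fully phased.

    Sampled individuals are drawn (without replacement) from the final
    generation of each deme. Ancestry labels are the founding deme of each
    chromosome stretch, propagated exactly through every recombination;
    they become the ``tracts`` table of the returned :class:`TruthSet`.
    """
    rng = np.random.default_rng(seed)
    chrom_arr, bp_arr, cm_arr = _snp_positions(model, rng)
    slices = _chrom_slices(model)
    n_snps = len(cm_arr)
    names = model.deme_names()
    name_to_label = {n: i for i, n in enumerate(names)}

    # ancestral frequencies shared by all demes
    lo, hi = model.ancestral_freq_range
    p0 = rng.uniform(lo, hi, n_snps)

    founded_at = {d.name: model.generations for d in model.demes}
    for sp in model.splits:
        for c in sp.children:
            founded_at[c] = sp.generation

    def bn_draw(base: np.ndarray, f: float) -> np.ndarray:
        if f <= 0:
            return base
        pb = np.clip(base, 1e-4, 1 - 1e-4)
        return rng.beta(pb * (1.0 - f) / f, (1.0 - pb) * (1.0 - f) / f)

    group_freqs: dict[str, np.ndarray] = {}
    for d in model.demes:
        if d.group is not None and d.group not in group_freqs:
            group_freqs[d.group] = bn_draw(p0, model.group_bn_f.get(d.group, 0.0))

    def founder_pool(deme: Deme, n_hap: int) -> tuple[np.ndarray, np.ndarray]:
        base = group_freqs.get(deme.group, p0) if deme.group else p0
        p = bn_draw(base, deme.bn_f)
        hap = (rng.random((n_hap, n_snps)) < p).astype(np.int8)
        anc = np.full((n_hap, n_snps), name_to_label[deme.name], dtype=np.int8)
        return hap, anc

    haps: dict[str, np.ndarray] = {}
    ancs: dict[str, np.ndarray] = {}
    for d in model.demes:
        if d.founded_by is None and founded_at[d.name] == model.generations:
            size = model.size_at(d.name, model.generations)
            if size <= 0:
                raise ValueError(f"deme {d.name} has size 0 at founding")
            haps[d.name], ancs[d.name] = founder_pool(d, 2 * size)

    mig = model.migration

    for gens_ago in range(model.generations - 1, -1, -1):
        # splits founding new demes this generation
        for sp in model.splits:
            if sp.generation == gens_ago + 1:
                for child in sp.children:
                    if child not in haps:
                        haps[child] = haps[sp.parent]
                        ancs[child] = ancs[sp.parent]
        new_haps: dict[str, np.ndarray] = {}
        new_ancs: dict[str, np.ndarray] = {}
        for deme in names:
            if deme not in haps:
                continue
            size = model.size_at(deme, gens_ago)
            if size <= 0:
                raise ValueError(f"deme {deme} has size 0 at generation {gens_ago}")
            pulse = next(
                (
                    p
                    for p in model.pulses
                    if p.target == deme and p.generation == gens_ago
                ),
                None,
            )
            child_h = np.empty((2 * size, n_snps), dtype=np.int8)
            child_a = np.empty((2 * size, n_snps), dtype=np.int8)
            for g in range(2 * size):
                src = deme
                if pulse is not None and rng.random() < pulse.fraction:
                    src = pulse.source
                else:
                    for (frm, to), rate in mig.items():
                        if to == deme and frm in haps and rng.random() < rate:
                            src = frm
                            break
                pool_h, pool_a = haps[src], ancs[src]
                parent = rng.integers(0, pool_h.shape[0] // 2)
                child_h[g], child_a[g] = _meiosis(
                    rng,
                    pool_h[2 * parent],
                    pool_h[2 * parent + 1],
                    pool_a[2 * parent],
                    pool_a[2 * parent + 1],
                    slices,
                    cm_arr,
                )
            new_haps[deme] = child_h
            new_ancs[deme] = child_a
        haps, ancs = new_haps, new_ancs

    # sample individuals
    if isinstance(n_samples_per_deme, int):
        n_per = {d: n_samples_per_deme for d in haps}
    else:
        n_per = dict(n_samples_per_deme)
    sample_rows = []
    hap_rows = []
    anc_rows = []
    for d in model.demes:
        if d.name not in n_per or d.name not in haps:
            continue
        k = n_per[d.name]
        n_avail = haps[d.name].shape[0] // 2
        if k > n_avail:
            raise ValueError(f"deme {d.name}: requested {k} samples from {n_avail}")
        chosen = rng.choice(n_avail, size=k, replace=False)
        for j, ind in enumerate(np.sort(chosen)):
            sid = f"{d.name}_{j}"
            sample_rows.append((sid, d.name, d.group or d.name, d.lat, d.lon))
            hap_rows.append(haps[d.name][2 * ind])
            hap_rows.append(haps[d.name][2 * ind + 1])
            anc_rows.append(ancs[d.name][2 * ind])
            anc_rows.append(ancs[d.name][2 * ind + 1])

    haplotypes = np.array(hap_rows, dtype=np.int8)
    genotypes = haplotypes[0::2] + haplotypes[1::2]
    snp_table = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": bp_arr,
            "cm": cm_arr,
            "ref": "A",
            "alt": "T",
            "id": [f"snp{i}" for i in range(n_snps)],
        }
    )
    sample_table = pd.DataFrame(
        sample_rows, columns=["id", "population", "major_group", "lat", "lon"]
    )
    panel = GenotypePanel(genotypes, snp_table, sample_table, haplotypes)

    truth = TruthSet()
    truth.tracts = _tracts_from_labels(
        np.array(anc_rows, dtype=np.int8), panel, {v: k for k, v in name_to_label.items()}
    )
    return panel, truth


def _tracts_from_labels(
    anc: np.ndarray, panel: GenotypePanel, label_to_name: dict[int, str]
) -> pd.DataFrame:
    rows = []
    chroms = panel.snp_table["chrom"].to_numpy()
    cms = panel.snp_table["cm"].to_numpy()
    ids = panel.sample_ids
    for h in range(anc.shape[0]):
        sid, hap = ids[h // 2], h % 2
        for chrom in pd.unique(chroms):
            sl = np.flatnonzero(chroms == chrom)
            labels = anc[h, sl]
            breaks = np.flatnonzero(np.diff(labels) != 0)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(sl) - 1]])
            for s, e in zip(starts, ends):
                rows.append(
                    (
                        sid,
                        hap,
                        chrom,
                        cms[sl[s]],
                        cms[sl[e]],
                        label_to_name[int(labels[s])],
                    )
                )
    return pd.DataFrame(
        rows, columns=["sample", "hap", "chrom", "start_cm", "end_cm", "ancestry"]
    )


# --------------------------------------------------------------------------
# constructive fixtures


def plant_fixtures(
    panel: GenotypePanel,
    requests: list[dict],
    seed: int,
    error_rate: float = 0.0,
) -> tuple[GenotypePanel, TruthSet]:
    """Plant IBD/ROH segments and relatives into a phased panel.

    Each request is a dict with a ``kind`` key:

    * ``{"kind": "ibd", "sample1", "hap1", "sample2", "hap2", "chrom",
      "start_cm", "end_cm"}`` — copy the stretch from haplotype
      (sample1, hap1) onto (sample2, hap2), creating exact IBD.
    * ``{"kind": "roh", "sample", "chrom", "start_cm", "end_cm"}`` — copy
      haplotype 0 over haplotype 1, creating an exactly homozygous run.
    * ``{"kind": "parent_offspring", "parent", "other_parent", "child"}``
      — replace the child's haplotypes by one recombinant gamete from each
      parent.
    * ``{"kind": "full_sibs", "parent1", "parent2", "child1", "child2"}``
      — regenerate both children from the same two parents.

    Contradictory requests (two plants writing the same haplotype
    interval) raise ``ValueError``. ``error_rate`` flips each planted-site
    allele independently after planting.
    """
    if not panel.phased:
        raise ValueError("plant_fixtures requires a phased panel")
    rng = np.random.default_rng(seed)
    hap = panel.haplotypes.copy()
    ids = panel.sample_ids
    idx_of = {s: i for i, s in enumerate(ids)}
    chroms = panel.snp_table["chrom"].to_numpy()
    cms = panel.snp_table["cm"].to_numpy()
    bps = panel.snp_table["pos"].to_numpy()
    written: dict[int, list[tuple[int, int]]] = {}
    truth = TruthSet()
    ibd_rows, roh_rows, ped_rows = [], [], []

    def snp_range(chrom, start_cm, end_cm) -> np.ndarray:
        sl = np.flatnonzero(
            (chroms == chrom) & (cms >= start_cm) & (cms <= end_cm)
        )
        if len(sl) == 0:
            raise ValueError(f"no SNPs in {chrom}:{start_cm}-{end_cm} cM")
        return sl

    def claim(hrow: int, sl: np.ndarray) -> None:
        lo, hi = int(sl[0]), int(sl[-1])
        for a, b in written.get(hrow, []):
            if lo <= b and a <= hi:
                raise ValueError("overlapping contradictory plant requests")
        written.setdefault(hrow, []).append((lo, hi))

    # map-aware gamete for pedigree planting
    chrom_info = []
    for chrom in pd.unique(chroms):
        sl = np.flatnonzero(chroms == chrom)
        chrom_info.append((sl[0], sl[-1] + 1, float(cms[sl[-1]] - cms[sl[0]])))

    def gamete(parent_idx: int) -> np.ndarray:
        a, b = hap[2 * parent_idx], hap[2 * parent_idx + 1]
        out = np.empty_like(a)
        for s, e, length_cm in chrom_info:
            n_x = rng.poisson(max(length_cm, 0.0) / 100.0)
            phase = rng.integers(0, 2)
            cuts = np.sort(rng.uniform(cms[s], cms[e - 1], n_x)) if n_x else np.array([])
            seg = np.searchsorted(cuts, cms[s:e], side="right")
            use_b = ((seg + phase) % 2).astype(bool)
            out[s:e] = np.where(use_b, b[s:e], a[s:e])
        return out

    for req in requests:
        kind = req["kind"]
        if kind == "ibd":
            s1, h1 = idx_of[req["sample1"]], req["hap1"]
            s2, h2 = idx_of[req["sample2"]], req["hap2"]
            sl = snp_range(req["chrom"], req["start_cm"], req["end_cm"])
            claim(2 * s2 + h2, sl)
            hap[2 * s2 + h2, sl] = hap[2 * s1 + h1, sl]
            ibd_rows.append(
                (
                    req["sample1"], h1, req["sample2"], h2, req["chrom"],
                    int(bps[sl[0]]), int(bps[sl[-1]]),
                    float(cms[sl[0]]), float(cms[sl[-1]]),
                )
            )
        elif kind in ("roh", "hbd"):
            s = idx_of[req["sample"]]
            sl = snp_range(req["chrom"], req["start_cm"], req["end_cm"])
            claim(2 * s + 1, sl)
            hap[2 * s + 1, sl] = hap[2 * s, sl]
            roh_rows.append(
                (
                    req["sample"], req["chrom"],
                    int(bps[sl[0]]), int(bps[sl[-1]]),
                    float(cms[sl[0]]), float(cms[sl[-1]]),
                )
            )
        elif kind == "parent_offspring":
            p1 = idx_of[req["parent"]]
            p2 = idx_of[req["other_parent"]]
            c = idx_of[req["child"]]
            claim(2 * c, np.arange(hap.shape[1]))
            claim(2 * c + 1, np.arange(hap.shape[1]))
            hap[2 * c] = gamete(p1)
            hap[2 * c + 1] = gamete(p2)
            ped_rows.append((req["parent"], req["child"], "parent_offspring", 0.5))
        elif kind == "full_sibs":
            p1, p2 = idx_of[req["parent1"]], idx_of[req["parent2"]]
            c1, c2 = idx_of[req["child1"]], idx_of[req["child2"]]
            for c in (c1, c2):
                claim(2 * c, np.arange(hap.shape[1]))
                claim(2 * c + 1, np.arange(hap.shape[1]))
                hap[2 * c] = gamete(p1)
                hap[2 * c + 1] = gamete(p2)
            ped_rows.append((req["child1"], req["child2"], "full_sibs", 0.5))
        else:
            raise ValueError(f"unknown plant kind {kind!r}")

    if error_rate > 0:
        flips = rng.random(hap.shape) < error_rate
        hap = np.where(flips, 1 - hap, hap).astype(np.int8)

    genotypes = (hap[0::2] + hap[1::2]).astype(np.int8)
    out = GenotypePanel(
        genotypes, panel.snp_table.copy(), panel.sample_table.copy(), hap
    )
    truth.ibd = pd.DataFrame(ibd_rows, columns=truth.ibd.columns)
    truth.roh = pd.DataFrame(roh_rows, columns=truth.roh.columns)
    truth.pedigree = pd.DataFrame(ped_rows, columns=truth.pedigree.columns)
    return out, truth


# --------------------------------------------------------------------------
# generative IBD-segment draw from an Ne trajectory


def simulate_ibd_segments(
    ne_per_generation: np.ndarray,
    n_pairs: int,
    genome_morgans: float,
    min_morgans: float,
    seed: int,
    max_generation: int | None = None,
) -> np.ndarray:
    """Draw maximal IBD segment lengths (morgans) for haplotype pairs.

    For each of ``n_pairs`` haplotype pairs a single coalescence time ``g``
    is drawn from the per-generation coalescent probability implied by the
    diploid trajectory ``ne_per_generation`` (index 0 = one generation
    ago). Crossover breakpoints accumulated over the ``2 g`` meioses are
    Poisson along the genome; the maximal tracts between breakpoints are
    the shared segments, and those longer than ``min_morgans`` are
    returned. Pairs whose coalescence falls beyond the trajectory horizon
    contribute nothing (their segments are shorter than any practical
    cutoff for long horizons).
    """
    rng = np.random.default_rng(seed)
    ne = np.asarray(ne_per_generation, dtype=float)
    horizon = len(ne) if max_generation is None else min(len(ne), max_generation)
    haz = 1.0 / (2.0 * ne[:horizon])
    surv = np.concatenate([[1.0], np.cumprod(1.0 - haz)])
    pcoal = surv[:-1] * haz  # P(coalesce exactly at generation g+1)
    gdraw = rng.random(n_pairs)
    cum = np.cumsum(pcoal)
    out: list[np.ndarray] = []
    for u in gdraw:
        gi = int(np.searchsorted(cum, u))
        if gi >= horizon:
            continue  # coalesces beyond horizon
        g = gi + 1
        n_breaks = rng.poisson(2.0 * g * genome_morgans)
        if n_breaks == 0:
            lengths = np.array([genome_morgans])
        else:
            cuts = np.sort(rng.uniform(0.0, genome_morgans, n_breaks))
            edges = np.concatenate([[0.0], cuts, [genome_morgans]])
            lengths = np.diff(edges)
        out.append(lengths[lengths > min_morgans])
    if not out:
        return np.array([])
    return np.concatenate(out)
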