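"""Hierarchical analysis of molecular variance (AMOVA).

Genotypes are decomposed to allele copies (two per individual per
locus), and squared allele-value differences summed over loci give the
classic sums of squares for a four-level nested hierarchy: among
linguistic groups, among populations within groups, among individuals
within populations, and within individuals. Variance components use the
standard unequal-size nested ANOVA expectations; each level's
significance comes from its own permutation scheme (whole populations
among groups; individuals among populations within their group; allele
copies among individuals within their population), with
p = (exceedances + 1) / (n_perm + 1).

Loci with missing genotypes in any analyzed sample are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

LEVELS = [
    "among_groups",
    "among_populations",
    "among_individuals",
    "within_individuals",
]


@dataclass
class AmovaResult:
    variance_components: dict[str, float]
    percent_variation: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    df: dict[str, int]
    untestable: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in LEVELS:
            rows.append(
                (
                    level,
                    self.df.get(level, np.nan),
                    self.variance_components.get(level, np.nan),
                    self.percent_variation.get(level, np.nan),
                    self.p_values.get(level, np.nan),
                )
            )
        return pd.DataFrame(
            rows, columns=["level", "df", "variance", "percent", "p_value"]
        )


def _allele_matrix(panel: GenotypePanel) -> np.ndarray:
    """2n x S allele-value matrix; het genotypes contribute one 1 and one 0."""
    g = panel.genotypes
    keep = ~(g == MISSING).any(axis=0)
    g = g[:, keep].astype(float)
    n, s = g.shape
    x = np.empty((2 * n, s))
    x[0::2] = np.where(g >= 1, 1.0, 0.0)  # first allele
    x[1::2] = np.where(g == 2, 1.0, 0.0)  # second allele
    return x


def _components(
    x: np.ndarray, ind_pop: np.ndarray, ind_group: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Variance components and df for the four levels.

    ``x`` is the 2n x S allele matrix; ``ind_pop``/``ind_group`` give the
    population and group index per individual.
    """
    n_ind = len(ind_pop)
    pops = np.unique(ind_pop)
    groups = np.unique(ind_group)
    allele_pop = np.repeat(ind_pop, 2)
    allele_group = np.repeat(ind_group, 2)
    n_alleles = 2 * n_ind

    grand = x.mean(axis=0)
    ind_mean = 0.5 * (x[0::2] + x[1::2])
    ss_wi = np.sum((x[0::2] - ind_mean) ** 2 + (x[1::2] - ind_mean) ** 2)

    pop_mean = np.empty((len(pops), x.shape[1]))
    pop_sizes = np.empty(len(pops))
    for k, p in enumerate(pops):
        sel = allele_pop == p
        pop_sizes[k] = sel.sum()
        pop_mean[k] = x[sel].mean(axis=0)
    group_mean = np.empty((len(groups), x.shape[1]))
    group_sizes = np.empty(len(groups))
    for k, gr in enumerate(groups):
        sel = allele_group == gr
        group_sizes[k] = sel.sum()
        group_mean[k] = x[sel].mean(axis=0)

    pop_of_ind = np.searchsorted(pops, ind_pop)
    ss_ai = np.sum(2.0 * (ind_mean - pop_mean[pop_of_ind]) ** 2)
    group_of_pop = np.empty(len(pops), dtype=int)
    for k, p in enumerate(pops):
        group_of_pop[k] = np.searchsorted(
            groups, ind_group[ind_pop == p][0]
        )
    ss_ap = np.sum(
        pop_sizes[:, None] * (pop_mean - group_mean[group_of_pop]) ** 2
    )
    ss_ag = np.sum(group_sizes[:, None] * (group_mean - grand) ** 2)

    df = np.array(
        [len(groups) - 1, len(pops) - len(groups), n_ind - len(pops), n_ind]
    )
    ms = np.full(4, np.nan)
    ss = np.array([ss_ag, ss_ap, ss_ai, ss_wi])
    for i in range(4):
        if df[i] > 0:
            ms[i] = ss[i] / df[i]

    # expected-MS coefficients for unequal sizes (allele counts per pop/group)
    s1 = np.sum(pop_sizes**2)
    s2 = np.sum(group_sizes**2)
    within_group_sq = np.zeros(len(groups))
    for k in range(len(pops)):
        within_group_sq[group_of_pop[k]] += pop_sizes[k] ** 2
    t = np.sum(within_group_sq / group_sizes)
    n1 = (n_alleles - t) / max(df[1], 1)
    n2 = (t - s1 / n_alleles) / max(df[0], 1)
    n3 = (n_alleles - s2 / n_alleles) / max(df[0], 1)

    sig_wi = ms[3]
    sig_ai = (ms[2] - sig_wi) / 2.0 if df[2] > 0 else 0.0
    sig_ap = (ms[1] - ms[2]) / n1 if df[1] > 0 else 0.0
    sig_ag = (
        (ms[0] - ms[2] - n2 * sig_ap) / n3 if df[0] > 0 else 0.0
    )
    return np.array([sig_ag, sig_ap, sig_ai, sig_wi]), df


def amova(
    panel: GenotypePanel,
    hierarchy: dict[str, tuple[str, str]] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Four-level AMOVA with level-appropriate permutation p-values.

    ``hierarchy`` maps sample id -> (population, group); by default the
    panel's ``population`` and ``major_group`` columns are used.
    """
    if hierarchy is None:
        hierarchy = {
            r.id: (r.population, r.major_group)
            for r in panel.sample_table.itertuples(index=False)
        }
    ids = panel.sample_ids
    pops_raw = np.array([hierarchy[s][0] for s in ids])
    groups_raw = np.array([hierarchy[s][1] for s in ids])
    _, ind_pop = np.unique(pops_raw, return_inverse=True)
    _, ind_group = np.unique(groups_raw, return_inverse=True)
    if len(np.unique(ind_group)) < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    # group of each population (hierarchy must nest cleanly)
    for p in np.unique(ind_pop):
        if len(np.unique(ind_group[ind_pop == p])) != 1:
            raise ValueError("a population spans multiple groups")

    x = _allele_matrix(panel)
    sig, df = _components(x, ind_pop, ind_group)
    total = np.sum(np.clip(sig, 0.0, None))
    pct = {
        lvl: 100.0 * max(s, 0.0) / total if total > 0 else 0.0
        for lvl, s in zip(LEVELS, sig)
    }
    sig_ag, sig_ap, sig_ai, sig_wi = sig
    tot_raw = max(sig_ag, 0) + max(sig_ap, 0) + max(sig_ai, 0) + max(sig_wi, 0)
    phi = {
        "phi_ct": max(sig_ag, 0) / tot_raw if tot_raw > 0 else 0.0,
        "phi_sc": max(sig_ap, 0) / max(sig_ap + sig_ai + sig_wi, 1e-300),
        "phi_st": (max(sig_ag, 0) + max(sig_ap, 0)) / tot_raw if tot_raw > 0 else 0.0,
        "phi_is": max(sig_ai, 0) / max(sig_ai + sig_wi, 1e-300),
    }

    rng = np.random.default_rng(seed)
    untestable: list[str] = []
    p_values: dict[str, float] = {}

    pops = np.unique(ind_pop)
    group_of_pop = np.array(
        [ind_group[ind_pop == p][0] for p in pops]
    )

    # among groups: permute whole populations among groups
    if df[0] > 0 and len(pops) > len(np.unique(ind_group)):
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(group_of_pop)
            g_perm = perm[np.searchsorted(pops, ind_pop)]
            s, _ = _components(x, ind_pop, g_perm)
            if s[0] >= sig_ag - 1e-15:
                exceed += 1
        p_values["among_groups"] = (exceed + 1) / (n_perm + 1)
    else:
        untestable.append("among_groups")

    # among populations within groups: permute individuals among pops in group
    counts = np.bincount(group_of_pop)
    if df[1] > 0 and np.any(counts >= 2):
        exceed = 0
        for _ in range(n_perm):
            pop_perm = ind_pop.copy()
            for gr in np.unique(ind_group):
                sel = np.flatnonzero(ind_group == gr)
                pop_perm[sel] = pop_perm[sel][rng.permutation(len(sel))]
            s, _ = _components(x, pop_perm, ind_group)
            if s[1] >= sig_ap - 1e-15:
                exceed += 1
        p_values["among_populations"] = (exceed + 1) / (n_perm + 1)
    else:
        untestable.append("among_populations")

    # among individuals within populations: permute allele copies among a
    # population's allele slots, independently per locus (per-locus
    # exchangeability; whole-row shuffles would be confounded by the
    # het-allele slot coding)
    if df[2] > 0:
        exceed = 0
        allele_pop = np.repeat(ind_pop, 2)
        n_loci = x.shape[1]
        for _ in range(n_perm):
            xp = x.copy()
            for p in pops:
                sel = np.flatnonzero(allele_pop == p)
                order = np.argsort(rng.random((len(sel), n_loci)), axis=0)
                xp[sel] = x[sel][order, np.arange(n_loci)]
            s, _ = _components(xp, ind_pop, ind_group)
            if s[2] >= sig_ai - 1e-15:
                exceed += 1
        p_values["among_individuals"] = (exceed + 1) / (n_perm + 1)
    else:
        untestable.append("among_individuals")

    return AmovaResult(
        variance_components=dict(zip(LEVELS, sig)),
        percent_variation=pct,
        phi=phi,
        p_values=p_values,
        n_permutations=n_perm,
        df=dict(zip(LEVELS, (int(d) for d in df))),
        untestable=untestable,
    )
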