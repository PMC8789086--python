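"""Pairwise relatedness and unrelated-subset selection.

PI_HAT follows the genome-wide method-of-moments IBD estimator: observed
IBS counts per pair are compared with their expectations under IBD
states 0/1/2 given sample allele frequencies, solved state by state,
truncated to [0,1] and renormalized; PI_HAT = P(IBD=2) + 0.5 P(IBD=1).
The small-sample allele-frequency bias factors of the original tool are
omitted (documented); planted-pair tests anchor calibration instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    table: pd.DataFrame  # columns: id1, id2, p_ibd0, p_ibd1, p_ibd2, pi_hat

    def pi_hat(self, id1: str, id2: str) -> float:
        if id1 == id2:
            return 1.0
        a, b = sorted([id1, id2])
        row = self.table[(self.table["id1"] == a) & (self.table["id2"] == b)]
        if row.empty:
            raise KeyError(f"pair ({id1}, {id2}) not in kinship table")
        return float(row["pi_hat"].iloc[0])


def pairwise_pi_hat(panel: GenotypePanel, warn_unpruned: bool = True) -> KinshipMatrix:
    """Method-of-moments IBD-state probabilities for all sample pairs.

    Assumes approximately independent markers; run on an LD-pruned panel
    (a warning is emitted otherwise, controlled by ``warn_unpruned``).
    """
    if panel.n_snps < 50:
        raise ValueError("pairwise_pi_hat needs at least 50 SNPs")
    if warn_unpruned:
        warnings.warn(
            "pairwise_pi_hat assumes near-independent SNPs; LD-prune first",
            stacklevel=2,
        )
    g = panel.genotypes.astype(np.int16)
    miss = panel.missing_mask
    p = panel.allele_frequency()
    q = 1.0 - p
    usable = ~np.isnan(p) & (p > 0) & (p < 1)
    g = g[:, usable]
    miss = miss[:, usable]
    p, q = p[usable], q[usable]

    # per-SNP conditional IBS expectations
    e_ibs0_ibd0 = 2.0 * p**2 * q**2
    e_ibs1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e_ibs2_ibd0 = p**4 + q**4 + 4.0 * p**2 * q**2
    e_ibs1_ibd1 = 2.0 * p**2 * q + 2.0 * p * q**2
    e_ibs2_ibd1 = p**2 + q**2

    ids = panel.sample_ids
    n = len(ids)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            if ok.sum() < 50:
                raise ValueError(f"pair ({ids[i]}, {ids[j]}): <50 shared SNPs")
            diff = np.abs(g[i, ok] - g[j, ok])
            n0 = int((diff == 2).sum())
            n1 = int((diff == 1).sum())
            n2 = int((diff == 0).sum())
            e00 = e_ibs0_ibd0[ok].sum()
            e10 = e_ibs1_ibd0[ok].sum()
            e20 = e_ibs2_ibd0[ok].sum()
            e11 = e_ibs1_ibd1[ok].sum()
            e21 = e_ibs2_ibd1[ok].sum()
            nt = float(ok.sum())
            p0 = n0 / e00 if e00 > 0 else 0.0
            p1 = (n1 - p0 * e10) / e11 if e11 > 0 else 0.0
            p2 = (n2 - p0 * e20 - p1 * e21) / nt
            probs = np.clip([p0, p1, p2], 0.0, None)
            s = probs.sum()
            probs = probs / s if s > 0 else np.array([1.0, 0.0, 0.0])
            pi = probs[2] + 0.5 * probs[1]
            rows.append((ids[i], ids[j], *probs, pi))
    table = pd.DataFrame(
        rows, columns=["id1", "id2", "p_ibd0", "p_ibd1", "p_ibd2", "pi_hat"]
    )
    return KinshipMatrix(ids, table)


def max_unrelated_set(
    kinship: KinshipMatrix, threshold: float = 0.375
) -> tuple[list[str], str]:
    """Largest sample subset with no pair's PI_HAT above ``threshold``.

    Exact (branch-and-bound maximum independent set) on connected
    components of the related-pair graph with <= 30 vertices; greedy
    highest-degree removal on larger components. Returns the subset
    (sorted) and the mode used ("exact", "greedy", or "mixed"). Ties are
    broken toward the lexicographically smallest id set.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    related = kinship.table[kinship.table["pi_hat"] > threshold]
    adj: dict[str, set[str]] = {s: set() for s in kinship.sample_ids}
    for r in related.itertuples(index=False):
        adj[r.id1].add(r.id2)
        adj[r.id2].add(r.id1)

    keep: list[str] = [s for s in kinship.sample_ids if not adj[s]]
    modes = set()
    seen: set[str] = set(keep)
    for start in sorted(adj):
        if start in seen or not adj[start]:
            continue
        comp = _component(start, adj)
        seen |= comp
        if len(comp) <= 30:
            keep += _exact_mis(comp, adj)
            modes.add("exact")
        else:
            keep += _greedy_mis(comp, adj)
            modes.add("greedy")
    mode = "mixed" if len(modes) > 1 else (modes.pop() if modes else "exact")
    return sorted(keep), mode


def _component(start: str, adj: dict[str, set[str]]) -> set[str]:
    comp, stack = {start}, [start]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in comp:
                comp.add(nb)
                stack.append(nb)
    return comp


def _exact_mis(nodes: set[str], adj: dict[str, set[str]]) -> list[str]:
    """Branch and bound on (include u / exclude u) for the max-degree vertex."""

    def solve(active: frozenset) -> tuple[int, tuple[str, ...]]:
        if not active:
            return 0, ()
        degs = {v: len(adj[v] & active) for v in active}
        if max(degs.values()) == 0:
            return len(active), tuple(sorted(active))
        u = min((v for v in active if degs[v] == max(degs.values()))),
        u = u[0]
        # exclude u
        size_ex, set_ex = solve(active - {u})
        # include u: drop its neighbours
        size_in, set_in = solve(active - {u} - adj[u])
        size_in += 1
        set_in = tuple(sorted(set_in + (u,)))
        if size_in > size_ex or (size_in == size_ex and set_in < set_ex):
            return size_in, set_in
        return size_ex, set_ex

    return list(solve(frozenset(nodes))[1])


def _greedy_mis(nodes: set[str], adj: dict[str, set[str]]) -> list[str]:
    active = set(nodes)
    local = {v: set(adj[v]) & active for v in active}
    while any(local[v] for v in active):
        worst = max(active, key=lambda v: (len(local[v]), v))
        active.remove(worst)
        for nb in local[worst]:
            local[nb].discard(worst)
        del local[worst]
    return sorted(active)
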