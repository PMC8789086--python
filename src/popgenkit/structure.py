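"""Ancestry proportions and ordination.

Supervised ancestry estimation maximizes, per sample, the binomial
likelihood of its genotypes under a mixture of fixed reference allele
frequencies (the supervised-mode clustering model), by EM on the simplex.
PCA operates on centered, sqrt(p(1-p))-scaled dosages; classical MDS is
Torgerson double-centering of squared distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fstats import DistanceMatrix, FrequencyTable
from .panel import MISSING, GenotypePanel

_EPS = 1e-6


@dataclass
class AncestryProportions:
    sample_ids: list[str]
    components: list[str]
    q: np.ndarray  # (n_samples, K), rows on the simplex
    log_likelihood: float

    def __post_init__(self) -> None:
        if np.any(self.q < -1e-9) or not np.allclose(self.q.sum(axis=1), 1.0):
            raise ValueError("ancestry proportions must lie on the simplex")

    def admixed_flags(self, focal: str, max_other: float = 0.01) -> np.ndarray:
        """True where the non-focal components sum to more than ``max_other``."""
        k = self.components.index(focal)
        other = 1.0 - self.q[:, k]
        return other > max_other

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, columns=self.components)
        df.insert(0, "id", self.sample_ids)
        return df


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coords: np.ndarray  # (n, k)
    eigenvalues: np.ndarray
    method: str

    @property
    def variance_explained(self) -> np.ndarray:
        pos = np.clip(self.eigenvalues, 0.0, None)
        tot = pos.sum()
        return pos[: self.coords.shape[1]] / tot if tot > 0 else pos


def supervised_ancestry(
    panel: GenotypePanel,
    reference_freqs: FrequencyTable,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> AncestryProportions:
    """EM for per-sample ancestry fractions given K source frequencies.

    The likelihood treats each of a sample's ``2 - missing`` allele draws
    at SNP j as coming from source k with probability ``q_k``, ALT with
    probability ``f_kj``. Reference frequencies of exactly 0/1 are clipped
    to [eps, 1-eps]. Deterministic from the uniform start; the
    log-likelihood is non-decreasing across iterations.
    """
    K = len(reference_freqs.populations)
    if K < 2:
        raise ValueError("need at least 2 reference components")
    f = reference_freqs.freqs
    usable = ~np.isnan(f).any(axis=0)
    if usable.sum() == 0:
        raise ValueError("no SNPs with complete reference frequencies")
    f = np.clip(f[:, usable], _EPS, 1.0 - _EPS)  # (K, S)
    g = panel.genotypes[:, usable].astype(float)
    miss = g == MISSING
    g[miss] = 0.0
    n_alt = g  # ALT allele count per sample x SNP
    n_ref = np.where(miss, 0.0, 2.0 - g)

    n = panel.n_samples
    q = np.full((n, K), 1.0 / K)
    total_ll = 0.0
    for i in range(n):
        qi = q[i]
        prev_ll = -np.inf
        ai, ri = n_alt[i], n_ref[i]
        for _ in range(max_iter):
            # responsibilities for ALT and REF draws at each SNP
            alt_mix = qi[:, None] * f  # (K, S)
            ref_mix = qi[:, None] * (1.0 - f)
            alt_tot = alt_mix.sum(axis=0)
            ref_tot = ref_mix.sum(axis=0)
            ll = float(np.sum(ai * np.log(alt_tot) + ri * np.log(ref_tot)))
            expected = (alt_mix / alt_tot) @ ai + (ref_mix / ref_tot) @ ri
            qi = expected / expected.sum()
            if abs(ll - prev_ll) < tol * max(abs(ll), 1.0):
                prev_ll = ll
                break
            prev_ll = ll
        q[i] = qi
        total_ll += prev_ll
    return AncestryProportions(
        panel.sample_ids, list(reference_freqs.populations), q, total_ll
    )


def pca(panel: GenotypePanel, n_components: int = 10) -> OrdinationResult:
    """PCA of genotype dosages, centered and scaled by sqrt(p(1-p)).

    Missing dosages are mean-imputed per SNP. Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    if panel.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    g = panel.genotypes.astype(float)
    miss = panel.missing_mask
    g[miss] = np.nan
    if np.isnan(g).all(axis=0).any():
        raise ValueError("all-missing SNP in PCA input")
    mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), mean, g)
    p = mean / 2.0
    scale = np.sqrt(np.clip(p * (1.0 - p), 1e-12, None))
    x = (g - mean) / scale
    x = x[:, scale.ravel() > 1e-6]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    eig = s**2 / (panel.n_samples - 1)
    coords = u[:, :k] * s[:k]
    # sign convention from the loadings
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            coords[:, j] *= -1.0
    return OrdinationResult(panel.sample_ids, coords, eig, "pca")


def classical_mds(dist: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Torgerson classical scaling of a distance matrix.

    Negative eigenvalues (non-Euclidean input) are reported but their
    axes are dropped; requesting more dimensions than there are positive
    eigenvalues is an error.
    """
    d = dist.matrix
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int(np.sum(eigval > 1e-10))
    if k > n_pos:
        raise ValueError(f"requested {k} dimensions but only {n_pos} are positive")
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    return OrdinationResult(list(dist.labels), coords, eigval, "classical_mds")
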