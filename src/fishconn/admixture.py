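"""Bayesian admixture clustering of multilocus genotypes.

The model: K clusters, each with its own Dirichlet(1)-distributed allele
frequencies per locus; every individual carries a membership vector q_i
over clusters; each gene copy is assigned to a cluster with probability
proportional to q_ik times that cluster's frequency of the observed
allele. A Gibbs sampler alternates cluster assignments of gene copies,
cluster allele frequencies, individual memberships, and a Metropolis step
on the shared Dirichlet concentration alpha (uniform(0, 10) prior).

Model support for a given K is summarized by the standard estimator
lnP(K) = mean(lnL) - var(lnL)/2 over post-burn-in samples; the number of
clusters across a K range is selected by Evanno's delta-K, the SD-scaled
absolute second difference of mean lnP(K). Replicate runs are aligned by
an optimal column permutation before averaging memberships.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .datatypes import MISSING, GenotypeDataset
from ._kernels import admixture_gibbs


@dataclass
class QMatrix:
    """Posterior-mean membership proportions, one row per individual."""

    individual_id: np.ndarray
    q: np.ndarray
    K: int
    seed: int

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        if self.q.shape != (len(self.individual_id), self.K):
            raise ValueError("q shape mismatch")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("q rows must sum to 1")


@dataclass
class AdmixtureFit:
    q: QMatrix
    freqs: np.ndarray  # (K, L, A) posterior-mean cluster allele frequencies
    lnl_trace: np.ndarray
    ln_pk: float
    alpha_mean: float


def _encode(g: GenotypeDataset) -> tuple[np.ndarray, np.ndarray, int]:
    """Map allele codes to dense 0-based indices; missing stays -1."""
    codes = np.unique(g.calls[g.calls != MISSING])
    lut = {int(a): i for i, a in enumerate(codes)}
    enc = np.full_like(g.calls, -1)
    it = np.nditer(g.calls, flags=["multi_index"])
    for v in it:
        if int(v) != MISSING:
            enc[it.multi_index] = lut[int(v)]
    return enc, codes, len(codes)


def fit_admixture(
    g: GenotypeDataset,
    K: int,
    burn_in: int = 2000,
    n_iters: int = 8000,
    seed: int = 0,
) -> AdmixtureFit:
    """Run the admixture Gibbs sampler for a fixed K.

    ``n_iters`` is the total number of sweeps; the first ``burn_in`` are
    discarded when averaging Q, the frequencies, and the lnL trace used by
    the lnP(K) estimator. Missing gene copies are skipped in every update.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if g.n == 0:
        raise ValueError("empty dataset")
    if not burn_in < n_iters:
        raise ValueError("burn_in must be < n_iters")
    enc, _, A = _encode(g)
    q_mean, p_mean, lnl, alpha_mean = admixture_gibbs(
        enc.astype(np.int64), K, A, n_iters, burn_in, int(seed) % (2**31)
    )
    q_mean = q_mean / q_mean.sum(axis=1, keepdims=True)
    ln_pk = float(np.mean(lnl) - np.var(lnl) / 2.0)
    return AdmixtureFit(
        QMatrix(g.individual_id, q_mean, K, seed), p_mean, lnl, ln_pk, alpha_mean
    )


def align_replicates(runs: list[QMatrix]) -> list[QMatrix]:
    """Resolve label switching across replicate runs.

    Each run's columns are permuted to maximize the sum of column-wise dot
    products with the first run (solved exactly as a linear assignment),
    so memberships can be averaged across replicates.
    """
    if not runs:
        return []
    ref = runs[0]
    aligned = [ref]
    for run in runs[1:]:
        if run.q.shape != ref.q.shape:
            raise ValueError("replicates have mismatched shapes")
        score = ref.q.T @ run.q  # score[i, j]: ref col i vs run col j
        rows, cols = linear_sum_assignment(-score)
        perm = np.empty(run.K, dtype=int)
        perm[rows] = cols
        aligned.append(QMatrix(run.individual_id, run.q[:, perm], run.K, run.seed))
    return aligned


def brute_force_alignment_score(ref: np.ndarray, q: np.ndarray) -> float:
    """Best alignment score by exhaustive permutation search (oracle, small K)."""
    K = ref.shape[1]
    return max(
        float(sum(np.dot(ref[:, i], q[:, p[i]]) for i in range(K)))
        for p in permutations(range(K))
    )


def mean_q(aligned: list[QMatrix]) -> QMatrix:
    """Average of aligned replicate memberships (rows renormalized)."""
    q = np.mean([r.q for r in aligned], axis=0)
    q /= q.sum(axis=1, keepdims=True)
    return QMatrix(aligned[0].individual_id, q, aligned[0].K, aligned[0].seed)


@dataclass
class KSelectionTable:
    table: pd.DataFrame  # index K; columns mean_lnpk, sd_lnpk, delta_k
    best_k: int


def evanno(lnpk: dict[int, list[float]]) -> KSelectionTable:
    """Evanno delta-K over a contiguous K range with replicate lnP(K).

    delta-K(K) = |L(K+1) - 2 L(K) + L(K-1)| / SD(L(K)) using replicate
    means; undefined at the endpoints. Interior K with zero replicate SD
    are flagged infinite and excluded from the argmax.
    """
    ks = sorted(lnpk)
    if len(ks) < 3:
        raise ValueError("need >= 3 contiguous K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be contiguous")
    if any(len(lnpk[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicates per K")
    means = {k: float(np.mean(lnpk[k])) for k in ks}
    sds = {k: float(np.std(lnpk[k], ddof=1)) for k in ks}
    dk: dict[int, float] = {}
    for k in ks[1:-1]:
        second = abs(means[k + 1] - 2 * means[k] + means[k - 1])
        dk[k] = second / sds[k] if sds[k] > 0 else np.inf
    finite = {k: v for k, v in dk.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("all interior K have zero replicate SD")
    best = max(finite, key=lambda k: (finite[k], -k))
    table = pd.DataFrame(
        {
            "mean_lnpk": [means[k] for k in ks],
            "sd_lnpk": [sds[k] for k in ks],
            "delta_k": [dk.get(k, np.nan) for k in ks],
        },
        index=pd.Index(ks, name="K"),
    )
    return KSelectionTable(table, best)


def select_k(
    g: GenotypeDataset,
    k_min: int = 1,
    k_max: int = 7,
    replicates: int = 20,
    burn_in: int = 2000,
    n_iters: int = 8000,
    seed: int = 0,
) -> tuple[KSelectionTable, dict[int, list[AdmixtureFit]]]:
    """Fit the admixture model over a K range and select K by delta-K."""
    rng = np.random.default_rng(seed)
    fits: dict[int, list[AdmixtureFit]] = {}
    lnpk: dict[int, list[float]] = {}
    for k in range(k_min, k_max + 1):
        fits[k] = [
            fit_admixture(g, k, burn_in, n_iters, int(rng.integers(2**31)))
            for _ in range(replicates)
        ]
        lnpk[k] = [f.ln_pk for f in fits[k]]
    return evanno(lnpk), fits
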