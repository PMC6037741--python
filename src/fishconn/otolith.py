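"""Infinite Gaussian mixture analysis of otolith near-core chemistry.

The number of natal sources contributing to a mixed collection of fish is
unknown, so the clustering model is a Dirichlet process mixture of
multivariate Gaussians: a Chinese-restaurant-process prior over partitions
with a conjugate Normal-inverse-Wishart (NIW) base measure, sampled by
collapsed Gibbs (component means/covariances integrated out analytically).
The DP concentration alpha carries a Gamma hyperprior and is resampled by
the Escobar-West auxiliary-variable scheme. Posterior summaries are the
pairwise co-assignment matrix, the modal number of occupied clusters, and
an average-linkage consensus dendrogram; non-metric MDS provides the
companion ordination view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from sklearn.manifold import MDS

from .datatypes import ELEMENT_RATIO_COLUMNS, OtolithMatrix


def standardize_chemistry(x: OtolithMatrix) -> np.ndarray:
    """Natural-log element:Ca ratios, then z-score every column.

    Element:Ca ratios are strictly positive and right-skewed, so they are
    log-transformed before centring; the delta values (d13C, d18O) are
    already on an interval scale and stay linear. Columns are z-scored
    with the n-1 (sample) SD.
    """
    if x.n < 2:
        raise ValueError("need n >= 2 to standardize")
    out = np.empty((x.n, len(x.columns)))
    for j, col in enumerate(x.columns):
        v = x.values[col].to_numpy(dtype=float)
        if col in ELEMENT_RATIO_COLUMNS:
            v = np.log(v)
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance column: {col}")
        out[:, j] = (v - v.mean()) / sd
    return out


@dataclass
class DPMPrior:
    """Gamma hyperprior on alpha plus the NIW base measure.

    Defaults are weakly informative on z-scored inputs: flat location
    (kappa0 = 0.01), identity scale, nu0 = p + 2 so E[Sigma] exists.
    """

    alpha_shape: float = 1.0
    alpha_rate: float = 1.0
    niw_mu0: np.ndarray | None = None
    niw_kappa0: float = 0.01
    niw_nu0: float | None = None
    niw_psi0: np.ndarray | None = None
    fixed_alpha: float | None = None

    def resolved(self, p: int) -> "DPMPrior":
        mu0 = np.zeros(p) if self.niw_mu0 is None else np.asarray(self.niw_mu0, float)
        nu0 = float(p + 2) if self.niw_nu0 is None else float(self.niw_nu0)
        psi0 = np.eye(p) if self.niw_psi0 is None else np.asarray(self.niw_psi0, float)
        if self.alpha_shape <= 0 or self.alpha_rate <= 0 or self.niw_kappa0 <= 0:
            raise ValueError("hyperparameters must be positive")
        if nu0 <= p - 1:
            raise ValueError("niw_nu0 must exceed p - 1")
        if not np.allclose(psi0, psi0.T) or np.linalg.eigvalsh(psi0).min() <= 0:
            raise ValueError("niw_psi0 must be symmetric positive-definite")
        return DPMPrior(
            self.alpha_shape, self.alpha_rate, mu0, self.niw_kappa0, nu0, psi0,
            self.fixed_alpha,
        )


@dataclass
class PartitionTrace:
    """Stored Gibbs samples: (n_stored, n) labels and the alpha trace."""

    assignments: np.ndarray
    alpha_trace: np.ndarray
    n_iters: int
    thin: int
    seed: int

    @property
    def n_stored(self) -> int:
        return self.assignments.shape[0]

    def occupied_counts(self, burn_in: int = 0) -> np.ndarray:
        """Number of occupied clusters at each stored iteration after burn-in."""
        if burn_in >= self.n_stored:
            raise ValueError("burn_in >= stored iterations")
        return np.array(
            [len(np.unique(row)) for row in self.assignments[burn_in:]]
        )


@dataclass
class CoassignmentMatrix:
    m: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, float)
        assert np.allclose(self.m, self.m.T)


@dataclass
class OrdinationResult:
    coords: np.ndarray
    stress: float
    seed: int
    converged: bool


class _Cluster:
    """Sufficient statistics and cached posterior-predictive pieces."""

    __slots__ = ("n", "s", "ss", "_cache")

    def __init__(self, p: int):
        self.n = 0
        self.s = np.zeros(p)
        self.ss = np.zeros((p, p))
        self._cache = None

    def add(self, x: np.ndarray) -> None:
        self.n += 1
        self.s += x
        self.ss += np.outer(x, x)
        self._cache = None

    def remove(self, x: np.ndarray) -> None:
        self.n -= 1
        self.s -= x
        self.ss -= np.outer(x, x)
        self._cache = None

    def predictive(self, prior: DPMPrior, p: int):
        """Cached pieces of the Student-t posterior predictive.

        Returns (df, mu, inverse Cholesky of the scale matrix, constant
        part of the log density).
        """
        if self._cache is None:
            k0, nu0, mu0, psi0 = (
                prior.niw_kappa0,
                prior.niw_nu0,
                prior.niw_mu0,
                prior.niw_psi0,
            )
            kn = k0 + self.n
            nun = nu0 + self.n
            if self.n:
                xbar = self.s / self.n
                mun = (k0 * mu0 + self.s) / kn
                scatter = self.ss - self.n * np.outer(xbar, xbar)
                dev = xbar - mu0
                psin = psi0 + scatter + (k0 * self.n / kn) * np.outer(dev, dev)
            else:
                mun = mu0
                psin = psi0
            df = nun - p + 1
            sigma = psin * (kn + 1) / (kn * df)
            chol = np.linalg.cholesky(sigma)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            const = float(
                gammaln((df + p) / 2)
                - gammaln(df / 2)
                - 0.5 * p * np.log(df * np.pi)
                - 0.5 * logdet
            )
            self._cache = (df, mun, np.linalg.inv(chol), const)
        return self._cache


def _niw_log_marginal(xs: np.ndarray, prior: DPMPrior) -> float:
    """Log marginal likelihood of a data block under the NIW base measure."""
    xs = np.atleast_2d(xs)
    n, p = xs.shape
    k0, nu0, mu0, psi0 = (
        prior.niw_kappa0,
        prior.niw_nu0,
        prior.niw_mu0,
        prior.niw_psi0,
    )
    kn = k0 + n
    nun = nu0 + n
    xbar = xs.mean(axis=0)
    dev = xs - xbar
    scatter = dev.T @ dev
    d0 = xbar - mu0
    psin = psi0 + scatter + (k0 * n / kn) * np.outer(d0, d0)
    _, ld0 = np.linalg.slogdet(psi0)
    _, ldn = np.linalg.slogdet(psin)
    mvg = sum(
        gammaln((nun + 1 - j) / 2) - gammaln((nu0 + 1 - j) / 2)
        for j in range(1, p + 1)
    )
    return float(
        -0.5 * n * p * np.log(np.pi)
        + 0.5 * p * (np.log(k0) - np.log(kn))
        + 0.5 * nu0 * ld0
        - 0.5 * nun * ldn
        + mvg
    )


def _t_logpdf(
    x: np.ndarray, df: float, mu: np.ndarray, chol_inv: np.ndarray, const: float
) -> float:
    z = chol_inv @ (x - mu)
    maha = float(z @ z)
    return const - 0.5 * (df + len(x)) * np.log1p(maha / df)


def _sams_move(
    x: np.ndarray,
    z: np.ndarray,
    clusters: dict[int, _Cluster],
    next_id: int,
    alpha: float,
    prior: DPMPrior,
    rng: np.random.Generator,
) -> int:
    """One sequentially-allocated split-merge Metropolis-Hastings attempt.

    Single-site Gibbs moves cannot carry a whole group between clusters,
    so the chain is metastable across partitions differing in occupied-K;
    this move (Jain-Neal style, with Dahl's sequential allocation as the
    proposal) restores mixing. Returns the possibly-advanced next_id.
    """
    n, p = x.shape
    i, j = rng.choice(n, size=2, replace=False)

    k0 = prior.niw_kappa0
    nu0 = prior.niw_nu0
    mu0 = prior.niw_mu0
    psi0_diag = np.diag(prior.niw_psi0)

    def diag_logpred(nb, s, ss, xt):
        """Per-axis Student-t log predictive from diagonal sufficient stats.

        Used only to build the allocation proposal (and its probability);
        the accept/reject step uses the exact full-covariance marginals,
        so the approximation costs proposal quality, not correctness.
        """
        kn = k0 + nb
        nun = nu0 + nb
        xbar = s / nb
        mun = (k0 * mu0 + s) / kn
        scatter = ss - nb * xbar**2
        psin = psi0_diag + scatter + (k0 * nb / kn) * (xbar - mu0) ** 2
        df = nun - p + 1
        var = psin * (kn + 1) / (kn * df)
        z2 = (xt - mun) ** 2 / var
        return float(
            p * (gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi))
            - 0.5 * np.log(var).sum()
            - 0.5 * (df + 1) * np.log1p(z2 / df).sum()
        )

    def seq_alloc(rest, forced_in_i=None):
        """Allocate `rest` to the two seed clusters; return members and logq."""
        ni, nj = 1, 1
        si, sj = x[i].copy(), x[j].copy()
        ssi, ssj = x[i] ** 2, x[j] ** 2
        members_i, members_j = [i], [j]
        logq = 0.0
        for t in rng.permutation(rest):
            li = np.log(ni) + diag_logpred(ni, si, ssi, x[t])
            lj = np.log(nj) + diag_logpred(nj, sj, ssj, x[t])
            tot = np.logaddexp(li, lj)
            if forced_in_i is None:
                to_i = np.log(rng.random()) < li - tot
            else:
                to_i = forced_in_i[t]
            if to_i:
                logq += li - tot
                ni += 1
                si = si + x[t]
                ssi = ssi + x[t] ** 2
                members_i.append(t)
            else:
                logq += lj - tot
                nj += 1
                sj = sj + x[t]
                ssj = ssj + x[t] ** 2
                members_j.append(t)
        return members_i, members_j, logq

    if z[i] == z[j]:  # propose a split
        block = np.flatnonzero(z == z[i])
        rest = block[(block != i) & (block != j)]
        mem_i, mem_j, logq = seq_alloc(rest)
        log_prior = (
            np.log(alpha) + gammaln(len(mem_i)) + gammaln(len(mem_j))
            - gammaln(len(block))
        )
        log_lik = (
            _niw_log_marginal(x[mem_i], prior)
            + _niw_log_marginal(x[mem_j], prior)
            - _niw_log_marginal(x[block], prior)
        )
        if np.log(rng.random()) < log_prior + log_lik - logq:
            ci, cj = _Cluster(p), _Cluster(p)
            for t in mem_i:
                ci.add(x[t])
            for t in mem_j:
                cj.add(x[t])
            clusters[z[i]] = ci
            clusters[next_id] = cj
            z[mem_j] = next_id
            return next_id + 1
        return next_id
    # propose a merge of the two clusters
    zi, zj = z[i], z[j]
    block_i = np.flatnonzero(z == zi)
    block_j = np.flatnonzero(z == zj)
    both = np.concatenate([block_i, block_j])
    rest = both[(both != i) & (both != j)]
    forced = {int(t): z[t] == zi for t in rest}
    _, _, logq = seq_alloc(rest, forced_in_i=forced)
    log_prior = (
        np.log(alpha)
        + gammaln(len(block_i))
        + gammaln(len(block_j))
        - gammaln(len(both))
    )
    log_lik = (
        _niw_log_marginal(x[block_i], prior)
        + _niw_log_marginal(x[block_j], prior)
        - _niw_log_marginal(x[both], prior)
    )
    if np.log(rng.random()) < -(log_prior + log_lik) + logq:
        merged = _Cluster(p)
        for t in both:
            merged.add(x[t])
        clusters[zi] = merged
        del clusters[zj]
        z[block_j] = zi
    return next_id


def fit_dpm(
    x: np.ndarray,
    n_iters: int = 2000,
    thin: int = 1,
    seed: int = 0,
    prior: DPMPrior | None = None,
    split_merge_moves: int = 3,
) -> PartitionTrace:
    """Collapsed Gibbs sampling of the DP Gaussian mixture partition.

    Each sweep reassigns every individual by CRP-weighted marginal
    likelihoods — weight n_k times the cluster's Student-t posterior
    predictive for occupied clusters, alpha times the prior predictive for
    a new cluster — then attempts ``split_merge_moves`` split-merge
    Metropolis moves, and finally resamples alpha (Escobar-West) unless
    the prior fixes it. The trace stores the label vector every ``thin``
    sweeps.
    """
    x = np.atleast_2d(np.asarray(x, float))
    if not np.isfinite(x).all():
        raise ValueError("non-finite data")
    if n_iters < 2:
        raise ValueError("n_iters must be >= 2")
    n, p = x.shape
    prior = (prior or DPMPrior()).resolved(p)
    rng = np.random.default_rng(seed)

    # singleton initialization: one cluster per point, so the chain reaches
    # the posterior by coalescence (nucleating a new cluster from a single
    # point is a low-probability move under a diffuse base measure)
    alpha = prior.fixed_alpha if prior.fixed_alpha is not None else 1.0
    z = np.arange(n, dtype=int)
    clusters: dict[int, _Cluster] = {}
    for i in range(n):
        clusters[i] = _Cluster(p)
        clusters[i].add(x[i])
    next_id = n
    empty = _Cluster(p)  # prior predictive (never mutated)

    stored_z = []
    stored_alpha = []
    for sweep in range(n_iters):
        for i in range(n):
            ci = clusters[z[i]]
            ci.remove(x[i])
            if ci.n == 0:
                del clusters[z[i]]
            keys = list(clusters)
            logw = np.empty(len(keys) + 1)
            for j, k in enumerate(keys):
                c = clusters[k]
                logw[j] = np.log(c.n) + _t_logpdf(x[i], *c.predictive(prior, p))
            logw[-1] = np.log(alpha) + _t_logpdf(x[i], *empty.predictive(prior, p))
            logw -= logw.max()
            w = np.cumsum(np.exp(logw))
            choice = int(np.searchsorted(w, rng.random() * w[-1]))
            if choice == len(keys):
                clusters[next_id] = _Cluster(p)
                z[i] = next_id
                next_id += 1
            else:
                z[i] = keys[choice]
            clusters[z[i]].add(x[i])
        if n >= 2:
            for _ in range(split_merge_moves):
                next_id = _sams_move(x, z, clusters, next_id, alpha, prior, rng)
        if prior.fixed_alpha is None:
            k_occ = len(clusters)
            a, b = prior.alpha_shape, prior.alpha_rate
            eta = rng.beta(alpha + 1.0, n)
            rate = b - np.log(eta)
            odds = (a + k_occ - 1.0) / (n * rate)
            shape = a + k_occ if rng.random() < odds / (1.0 + odds) else a + k_occ - 1.0
            alpha = rng.gamma(shape, 1.0 / rate)
        if sweep % thin == 0:
            stored_z.append(z.copy())
            stored_alpha.append(alpha)
    return PartitionTrace(
        np.array(stored_z), np.array(stored_alpha), n_iters, thin, seed
    )


def coassignment(
    trace: PartitionTrace, burn_in: int, ids: np.ndarray | None = None
) -> CoassignmentMatrix:
    """Posterior probability that two fish share a mixture component."""
    if burn_in >= trace.n_stored:
        raise ValueError("burn_in >= stored iterations")
    kept = trace.assignments[burn_in:]
    same = kept[:, :, None] == kept[:, None, :]
    m = same.mean(axis=0)
    np.fill_diagonal(m, 1.0)
    n = m.shape[0]
    if ids is None:
        ids = np.arange(n)
    return CoassignmentMatrix(m, np.asarray(ids))


def most_probable_k(trace: PartitionTrace, burn_in: int) -> int:
    """Posterior mode of the occupied-cluster count; ties go to smaller K."""
    counts = trace.occupied_counts(burn_in)
    vals, freq = np.unique(counts, return_counts=True)
    return int(vals[np.argmax(freq)])  # np.unique sorts, argmax takes first max


def k_posterior(trace: PartitionTrace, burn_in: int) -> pd.DataFrame:
    counts = trace.occupied_counts(burn_in)
    vals, freq = np.unique(counts, return_counts=True)
    return pd.DataFrame({"k": vals, "frequency": freq / freq.sum()})


def consensus_tree(m: CoassignmentMatrix) -> str:
    """Average-linkage dendrogram on 1 - co-assignment, as newick text."""
    n = m.m.shape[0]
    if n < 2:
        raise ValueError("need n >= 2 for a tree")
    d = np.clip(1.0 - m.m, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    link = sch.linkage(squareform(d, checks=False), method="average")
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(link, [str(i) for i in m.ids])
    return str(tree).strip()


def nmds(
    x: np.ndarray, seed: int = 0, n_starts: int = 20
) -> OrdinationResult:
    """Two-dimensional non-metric MDS of the standardized chemistry.

    Euclidean distances; best (lowest Kruskal stress-1) of ``n_starts``
    random SMACOF initializations. Exactly duplicated rows are embedded
    once and share coordinates.
    """
    x = np.asarray(x, float)
    if x.shape[0] < 4:
        raise ValueError("need n >= 4 for NMDS")
    uniq, inverse = np.unique(x, axis=0, return_inverse=True)
    d = squareform(pdist(uniq))
    model = MDS(
        n_components=2,
        metric_mds=False,
        metric="precomputed",
        n_init=n_starts,
        init="random",
        max_iter=500,
        eps=1e-9,
        random_state=seed,
        normalized_stress=True,
    )
    coords_u = model.fit_transform(d)
    coords = coords_u[inverse]
    return OrdinationResult(coords, float(model.stress_), seed, True)
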