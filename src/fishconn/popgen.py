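"""Microsatellite diversity and differentiation statistics.

Per-locus and multilocus diversity (allele counts, observed and Nei
unbiased expected heterozygosity, Weir-Cockerham f, rarefied allelic
richness), pairwise Weir-Cockerham theta with a permutation test,
Hardy-Weinberg exact tests (complete enumeration on small problems,
Guo-Thompson Markov chain otherwise), a Brookfield null-allele estimate,
Mantel isolation-by-distance, and principal coordinates analysis.

Missing genotypes are handled pairwise-complete per locus: an individual
with a missing call is excluded from that locus only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import MISSING, DistanceMatrixInput, GenotypeDataset

__all__ = [
    "allele_frequencies",
    "diversity_table",
    "pairwise_fst",
    "hwe_exact",
    "null_allele_estimate",
    "mantel",
    "pcoa",
    "DiversityTable",
    "PairwiseFstMatrix",
    "MantelResult",
    "PcoaResult",
]


def _locus_calls(g: GenotypeDataset, population: str, locus: str) -> np.ndarray:
    if population not in g.populations:
        raise KeyError(f"unknown population: {population}")
    if locus not in g.loci:
        raise KeyError(f"unknown locus: {locus}")
    l = g.loci.index(locus)
    calls = g.population_calls(population)[:, l, :]
    return calls[calls[:, 0] != MISSING]


def allele_frequencies(
    g: GenotypeDataset, population: str, locus: str
) -> tuple[pd.Series, int]:
    """Allele frequencies over non-missing gene copies, plus the 2n count."""
    calls = _locus_calls(g, population, locus)
    if len(calls) == 0:
        raise ValueError(f"no typed individuals for ({population}, {locus})")
    copies = calls.ravel()
    vals, counts = np.unique(copies, return_counts=True)
    freqs = pd.Series(counts / counts.sum(), index=vals, name="frequency")
    return freqs, int(counts.sum())


# --- Weir-Cockerham variance components --------------------------------------


def _wc_components(
    counts: np.ndarray, hets: np.ndarray, n: np.ndarray
) -> tuple[float, float, float]:
    """Summed a, b, c over alleles for one locus.

    ``counts``: (r, A) allele-copy counts per population; ``hets``: (r, A)
    counts of heterozygous individuals carrying the allele; ``n``: (r,)
    typed individuals per population. Closed-form diploid components.
    """
    r = len(n)
    nbar = n.mean()
    ntot = n.sum()
    if r > 1:
        nc = (ntot - (n**2).sum() / ntot) / (r - 1)
    else:
        nc = np.nan
    a_sum = b_sum = c_sum = 0.0
    for aidx in range(counts.shape[1]):
        p_i = counts[:, aidx] / (2 * n)
        pbar = counts[:, aidx].sum() / (2 * ntot)
        hbar = hets[:, aidx].sum() / ntot
        if r > 1:
            s2 = (n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        else:
            a = 0.0
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _locus_arrays(calls: np.ndarray, alleles: np.ndarray):
    """Per-population allele-copy counts, het-carrier counts, typed n."""
    typed = calls[calls[:, 0] != MISSING]
    n = len(typed)
    counts = np.array(
        [(typed == a).sum() for a in alleles], dtype=float
    )
    hets = np.array(
        [
            ((typed[:, 0] != typed[:, 1]) & ((typed == a).any(axis=1))).sum()
            for a in alleles
        ],
        dtype=float,
    )
    return counts, hets, n


def wc_fis(calls: np.ndarray) -> float:
    """Weir-Cockerham f for a single population at one locus.

    ``calls``: (n, 2) allele codes, missing rows excluded by the caller.
    Returns NaN for monomorphic or single-individual input.
    """
    alleles = np.unique(calls)
    if len(alleles) < 2 or len(calls) < 2:
        return np.nan
    counts, hets, n = _locus_arrays(calls, alleles)
    _, b, c = _wc_components(
        counts[None, :], hets[None, :], np.array([float(n)])
    )
    denom = b + c
    return 1.0 - c / denom if denom > 0 else np.nan


def multilocus_theta(g: GenotypeDataset, pops: list[str] | None = None) -> float:
    """Multilocus Weir-Cockerham theta: sum(a) / sum(a + b + c) over loci."""
    pops = pops or g.populations
    pop_calls = [g.population_calls(p) for p in pops]
    num = den = 0.0
    for l in range(len(g.loci)):
        locus_calls = [pc[:, l, :] for pc in pop_calls]
        typed = [c[c[:, 0] != MISSING] for c in locus_calls]
        ns = np.array([float(len(t)) for t in typed])
        if (ns < 1).any() or ns.sum() < 2:
            continue
        alleles = np.unique(np.concatenate([t.ravel() for t in typed]))
        if len(alleles) < 2:
            continue
        counts = np.empty((len(pops), len(alleles)))
        hets = np.empty((len(pops), len(alleles)))
        for i, t in enumerate(typed):
            counts[i], hets[i], _ = _locus_arrays(t, alleles)
        a, b, c = _wc_components(counts, hets, ns)
        num += a
        den += a + b + c
    return num / den if den != 0 else np.nan


# --- diversity table ---------------------------------------------------------


def _log_comb(n: float, k: float) -> float:
    if k < 0 or k > n:
        return -np.inf
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(copy_counts: np.ndarray, g: int) -> float:
    """Hurlbert rarefaction: expected allele count in a draw of g copies."""
    two_n = copy_counts.sum()
    if g > two_n:
        raise ValueError("rarefaction size exceeds gene-copy count")
    total = 0.0
    for c in copy_counts:
        total += 1.0 - np.exp(_log_comb(two_n - c, g) - _log_comb(two_n, g))
    return float(total)


@dataclass
class DiversityTable:
    """Per-(population, locus) diversity with multilocus summary rows."""

    per_locus: pd.DataFrame  # MultiIndex (population, locus)
    multilocus: pd.DataFrame  # index population; columns incl. N
    rarefaction_g: dict  # locus -> g used


def diversity_table(
    g: GenotypeDataset, rarefaction_g: int | None = None
) -> DiversityTable:
    """Compute N_A, Ho, He (Nei unbiased), FIS (Weir-Cockerham f) and AR.

    AR standardizes each locus to ``rarefaction_g`` gene copies, or, by
    default, to the smallest typed gene-copy count across populations at
    that locus. Multilocus rows are arithmetic means over loci with data;
    cells where rarefaction is impossible are left NaN and excluded.
    """
    pops = g.populations
    if not pops:
        raise ValueError("no populations")
    rows = []
    g_used: dict[str, int] = {}
    for locus in g.loci:
        two_ns = []
        for pop in pops:
            calls = _locus_calls(g, pop, locus)
            if len(calls):
                two_ns.append(2 * len(calls))
        if two_ns:
            g_used[locus] = rarefaction_g if rarefaction_g else min(two_ns)
    for pop in pops:
        for locus in g.loci:
            calls = _locus_calls(g, pop, locus)
            n_typed = len(calls)
            if n_typed == 0:
                rows.append(
                    dict(population=pop, locus=locus, N_A=np.nan, Ho=np.nan,
                         He=np.nan, FIS=np.nan, AR=np.nan, n_typed=0)
                )
                continue
            copies = calls.ravel()
            vals, counts = np.unique(copies, return_counts=True)
            p = counts / counts.sum()
            two_n = counts.sum()
            ho = float((calls[:, 0] != calls[:, 1]).mean())
            he = (
                (two_n / (two_n - 1)) * (1.0 - (p**2).sum()) if two_n > 1 else np.nan
            )
            fis = wc_fis(calls)
            gg = g_used.get(locus)
            ar = (
                rarefied_richness(counts, gg)
                if gg is not None and gg <= two_n
                else np.nan
            )
            rows.append(
                dict(population=pop, locus=locus, N_A=len(vals), Ho=ho,
                     He=float(he), FIS=fis, AR=ar, n_typed=n_typed)
            )
    per_locus = pd.DataFrame(rows).set_index(["population", "locus"])
    multi = multilocus_means(per_locus)
    multi["N"] = [int((g.population == p).sum()) for p in multi.index]
    return DiversityTable(per_locus, multi, g_used)


def multilocus_means(per_locus: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic means over loci with data, per population.

    Loci with no typed individuals (n_typed = 0) and cells flagged NaN are
    excluded from the mean of each statistic.
    """
    typed = per_locus[per_locus["n_typed"] > 0]
    return typed.groupby(level="population", sort=False)[
        ["N_A", "Ho", "He", "FIS", "AR"]
    ].mean()


# --- pairwise theta with permutation test ------------------------------------


@dataclass
class PairwiseFstMatrix:
    labels: list[str]
    theta: np.ndarray
    p: np.ndarray
    alpha_adj: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.labels, columns=self.labels)


def pairwise_fst(
    g: GenotypeDataset, n_perm: int = 999, seed: int = 0, alpha: float = 0.05
) -> PairwiseFstMatrix:
    """Pairwise multilocus Weir-Cockerham theta with permutation p-values.

    For each pair, individuals are shuffled between the two populations;
    p = (#{theta_perm >= theta_obs} + 1) / (n_perm + 1). The Bonferroni
    threshold alpha / n_pairs is reported alongside the raw p-values.
    """
    pops = g.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    k = len(pops)
    theta = np.zeros((k, k))
    pmat = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            mask = (g.population == pops[i]) | (g.population == pops[j])
            sub = g.subset(mask)
            obs = multilocus_theta(sub)
            count = 0
            labels = sub.population.copy()
            for _ in range(n_perm):
                perm = rng.permutation(labels)
                permuted = GenotypeDataset(
                    sub.individual_id, perm, sub.loci, sub.calls
                )
                if multilocus_theta(permuted, pops=[pops[i], pops[j]]) >= obs:
                    count += 1
            theta[i, j] = theta[j, i] = obs
            pmat[i, j] = pmat[j, i] = (count + 1) / (n_perm + 1)
    return PairwiseFstMatrix(pops, theta, pmat, alpha / (k * (k - 1) / 2))


# --- Hardy-Weinberg exact test -----------------------------------------------


def _log_table_prob(table: dict, n: int, allele_counts: np.ndarray) -> float:
    """Log conditional probability of a genotype table given allele counts."""
    h = sum(c for (a, b), c in table.items() if a != b)
    lp = (
        gammaln(n + 1)
        + sum(gammaln(c + 1) for c in allele_counts)
        + h * np.log(2)
        - gammaln(2 * n + 1)
        - sum(gammaln(c + 1) for c in table.values())
    )
    return float(lp)


def _enumerate_tables(allele_counts: np.ndarray):
    """All genotype tables consistent with the given allele counts (<=3 alleles)."""
    A = len(allele_counts)
    c = allele_counts

    def hets(A):
        return [(i, j) for i in range(A) for j in range(i + 1, A)]

    pairs = hets(A)
    # iterate over heterozygote counts; homozygote counts follow by parity
    ranges = [range(int(min(c[i], c[j])) + 1) for i, j in pairs]
    import itertools

    for combo in itertools.product(*ranges):
        used = np.zeros(A, dtype=int)
        for (i, j), m in zip(pairs, combo):
            used[i] += m
            used[j] += m
        rem = c - used
        if (rem < 0).any() or (rem % 2).any():
            continue
        table = {}
        for (i, j), m in zip(pairs, combo):
            if m:
                table[(i, j)] = m
        for i in range(A):
            if rem[i]:
                table[(i, i)] = rem[i] // 2
        yield table


def _genotype_table(calls: np.ndarray) -> tuple[dict, np.ndarray, np.ndarray]:
    alleles = np.unique(calls)
    index = {a: i for i, a in enumerate(alleles)}
    table: dict = {}
    for a1, a2 in calls:
        i, j = sorted((index[a1], index[a2]))
        table[(i, j)] = table.get((i, j), 0) + 1
    counts = np.zeros(len(alleles), dtype=int)
    for (i, j), m in table.items():
        counts[i] += m
        counts[j] += m
    return table, counts, alleles


def hwe_exact(
    g: GenotypeDataset,
    population: str,
    locus: str,
    mc_dememorization: int = 1000,
    mc_steps: int = 100_000,
    seed: int = 0,
    method: str = "auto",
) -> float:
    """Exact test of Hardy-Weinberg proportions given allele counts.

    Small problems (<= 3 alleles and <= 30 typed individuals) are solved
    by complete enumeration of genotype tables with a probability-ordered
    rejection region; larger ones by the Guo-Thompson Markov chain with
    the given dememorization and chain length. ``method`` forces one
    route ("enumeration" or "mc").
    """
    calls = _locus_calls(g, population, locus)
    if len(calls) < 2:
        raise ValueError("need >= 2 typed individuals")
    table, counts, alleles = _genotype_table(calls)
    if len(alleles) < 2:
        raise ValueError("monomorphic locus: HWE p undefined")
    n = len(calls)
    if method == "enumeration" or (
        method == "auto" and len(alleles) <= 3 and n <= 30
    ):
        if len(alleles) > 3:
            raise ValueError("enumeration supports <= 3 alleles")
        return _hwe_enumerate(table, counts, n)
    return _hwe_markov_chain(calls, mc_dememorization, mc_steps, seed)


def _hwe_enumerate(table: dict, counts: np.ndarray, n: int) -> float:
    lp_obs = _log_table_prob(table, n, counts)
    total = 0.0
    tail = 0.0
    for t in _enumerate_tables(counts):
        lp = _log_table_prob(t, n, counts)
        pr = np.exp(lp)
        total += pr
        if lp <= lp_obs + 1e-9:
            tail += pr
    return float(tail / total)


def _hwe_markov_chain(
    calls: np.ndarray, dememorization: int, steps: int, seed: int
) -> float:
    """Markov-chain estimate of the exact conditional p.

    The chain swaps two gene copies in the flat 2n arrangement each step
    and always accepts: the uniform distribution over labelled
    arrangements induces exactly the conditional distribution over
    genotype tables given allele counts, so no Hastings correction is
    needed. p is the fraction of post-dememorization states whose table
    is no more probable than the observed one.
    """
    rng = np.random.default_rng(seed)
    flat = calls.ravel().copy()
    table, counts, alleles = _genotype_table(calls)
    idx = {int(a): i for i, a in enumerate(alleles)}
    cnt: dict = dict(table)

    def key(a1, a2):
        i, j = sorted((idx[int(a1)], idx[int(a2)]))
        return (i, j)

    lp_obs = _log_table_prob(cnt, len(calls), counts)
    lp_cur = lp_obs
    # incremental piece of log prob: het*log2 - sum log n_g!; the rest of
    # _log_table_prob is constant given allele counts
    below = 0
    two_n = len(flat)
    log2 = np.log(2)
    for step in range(dememorization + steps):
        i1, i2 = rng.integers(0, two_n, size=2)
        g1, g2 = i1 // 2, i2 // 2
        if g1 != g2 and flat[i1] != flat[i2]:
            old1 = key(flat[2 * g1], flat[2 * g1 + 1])
            old2 = key(flat[2 * g2], flat[2 * g2 + 1])
            flat[i1], flat[i2] = flat[i2], flat[i1]
            new1 = key(flat[2 * g1], flat[2 * g1 + 1])
            new2 = key(flat[2 * g2], flat[2 * g2 + 1])
            delta = 0.0
            for k_old in (old1, old2):
                c = cnt[k_old]
                delta += np.log(c)
                cnt[k_old] = c - 1
                if k_old[0] != k_old[1]:
                    delta -= log2
            for k_new in (new1, new2):
                c = cnt.get(k_new, 0)
                delta -= np.log(c + 1)
                cnt[k_new] = c + 1
                if k_new[0] != k_new[1]:
                    delta += log2
            lp_cur += delta
        if step >= dememorization and lp_cur <= lp_obs + 1e-9:
            below += 1
    return below / steps


def null_allele_estimate(ho: float, he: float) -> tuple[float, bool]:
    """Brookfield estimator r = (He - Ho) / (1 + He).

    Returns (estimate, excess_heterozygosity_flag); a negative raw value
    (Ho > He) is reported as 0 with the flag set.
    """
    if not (0 <= ho <= 1 and 0 <= he <= 1):
        raise ValueError("heterozygosities must lie in [0, 1]")
    r = (he - ho) / (1 + he)
    if r < 0:
        return 0.0, True
    return float(r), False


# --- Mantel test and PCoA ----------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int


def mantel(
    d1: DistanceMatrixInput,
    d2: DistanceMatrixInput,
    n_perm: int = 1000,
    seed: int = 0,
) -> MantelResult:
    """Mantel matrix correlation with a permutation test.

    r is the Pearson correlation of the upper-triangle entries; the null
    distribution comes from simultaneous row/column permutations of the
    second matrix, with the add-one rule p = (#{r_perm >= r_obs}+1)/(n+1).
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices have mismatched labels")
    n = d1.n
    if n < 3:
        raise ValueError("need >= 3 populations")
    iu = np.triu_indices(n, k=1)
    x = d1.d[iu]

    def corr(mat):
        y = mat[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(d2.d)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(d2.d[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r_obs, (count + 1) / (n_perm + 1), n_perm, seed)


@dataclass
class PcoaResult:
    coords: np.ndarray
    pct_variance: np.ndarray
    eigenvalues: np.ndarray


def pcoa(d: DistanceMatrixInput) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower double-centering of -d^2/2, eigendecomposition, coordinates for
    positive eigenvalues scaled by sqrt(eigenvalue); percentage of
    variation is relative to the sum of positive eigenvalues. Negative
    eigenvalues are reported but contribute no axes.
    """
    if d.n < 3:
        raise ValueError("need >= 3 points")
    a = -0.5 * d.d**2
    n = d.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10 * abs(evals).max(), 1e-12)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pct = 100.0 * evals[pos] / evals[pos].sum()
    return PcoaResult(coords, pct, evals)
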