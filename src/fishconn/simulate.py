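"""Synthetic data with the statistical structure the pipeline assumes.

Otolith chemistry is drawn source-wise from multivariate Gaussians on the
analysis scale (post log-transform), so the generator controls the
separation between natal sources directly. Microsatellite genotypes come
from the F-model: ancestral allele frequencies from a flat Dirichlet, and
per-population frequencies from Dirichlet(p_anc * (1-F)/F), which makes
Wright's F the expected fixation index against the ancestral pool and
hence a clean recovery target for the Weir-Cockerham estimator. An
optional admixture mode mixes each individual's gene copies across
populations, and a cline mode tilts allele frequencies monotonically along
a 1-D habitat axis to create isolation by distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import (
    CHEMISTRY_COLUMNS,
    DistanceMatrixInput,
    GenotypeDataset,
    OtolithMatrix,
)


@dataclass
class ChemistrySourceSpec:
    """K Gaussian natal sources in chemistry space.

    ``means`` is (K, p) on the analysis scale; element:Ca columns are
    exponentiated on output so the stored matrix satisfies the positivity
    invariant. ``covariances`` may be a single shared (p, p) matrix or one
    per source.
    """

    n_sources: int
    means: np.ndarray
    covariances: np.ndarray
    n_per_source: list[int]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        cov = np.asarray(self.covariances, dtype=float)
        if cov.ndim == 2:
            cov = np.repeat(cov[None], self.n_sources, axis=0)
        self.covariances = cov
        if self.means.shape[0] != self.n_sources:
            raise ValueError("means rows != n_sources")
        if any(n < 1 for n in self.n_per_source):
            raise ValueError("n_per_source must be >= 1")
        for k in range(self.n_sources):
            c = self.covariances[k]
            if not np.allclose(c, c.T):
                raise ValueError("covariance not symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError("covariance not positive-definite")
        if self.labels is None:
            self.labels = [f"S{k + 1}" for k in range(self.n_sources)]

    @property
    def p(self) -> int:
        return self.means.shape[1]


def separated_sources_spec(
    n_sources: int = 2,
    n_per_source: int = 30,
    separation: float = 6.0,
    p: int = 6,
) -> ChemistrySourceSpec:
    """Equidistant unit-covariance sources along the diagonal direction.

    ``separation`` is the Euclidean distance between adjacent source means
    in pooled within-source SD units, loaded equally on every variable
    (natal-source chemistry differences involve several elements and
    isotopes at once, and per-variable standardization treats the
    variables symmetrically, so the isotropic orientation is the neutral
    choice).
    """
    offsets = (np.arange(n_sources) - (n_sources - 1) / 2) * separation
    means = np.outer(offsets, np.ones(p) / np.sqrt(p))
    return ChemistrySourceSpec(
        n_sources, means, np.eye(p), [n_per_source] * n_sources
    )


def two_source_spec(
    n_per_source: int = 30,
    separation: float = 6.0,
    p: int = 6,
) -> ChemistrySourceSpec:
    """Two unit-covariance sources ``separation`` pooled SDs apart."""
    return separated_sources_spec(2, n_per_source, separation, p)


def simulate_otolith(
    spec: ChemistrySourceSpec, seed: int
) -> tuple[OtolithMatrix, np.ndarray]:
    """Draw an :class:`OtolithMatrix` source-wise from the spec's Gaussians.

    Returns the matrix and the true per-fish source labels (indices into
    ``spec.labels``) for recovery tests. Chemistry columns reuse the six
    standard names; simulated element:Ca draws are exponentiated so the
    stored ratios are strictly positive and log-normal per source.
    """
    rng = np.random.default_rng(seed)
    cols = list(CHEMISTRY_COLUMNS[: spec.p])
    if spec.p > len(CHEMISTRY_COLUMNS):
        cols += [f"var{j}" for j in range(len(CHEMISTRY_COLUMNS), spec.p)]
    rows = []
    labels = []
    for k in range(spec.n_sources):
        x = rng.multivariate_normal(
            spec.means[k], spec.covariances[k], size=spec.n_per_source[k]
        )
        rows.append(x)
        labels.extend([k] * spec.n_per_source[k])
    x = np.vstack(rows)
    labels = np.array(labels)
    values = pd.DataFrame(x, columns=cols)
    for j, c in enumerate(cols):
        if c in CHEMISTRY_COLUMNS[:4]:  # element:Ca -> positive scale
            values[c] = np.exp(values[c])
    n = len(labels)
    fish_id = np.array([f"F{i + 1:04d}" for i in range(n)], dtype=object)
    location = np.array([spec.labels[k] for k in labels], dtype=object)
    cohort = np.full(n, 2009)
    return OtolithMatrix(fish_id, location, cohort, values), labels


@dataclass
class FModelSpec:
    """F-model for drifted population allele frequencies.

    ``F`` is the per-population drift against a common ancestral pool,
    0 < F < 1; the expected Weir-Cockerham theta between two populations
    drifted independently at this F is approximately F. ``admixture_alpha``
    switches on per-individual Dirichlet membership mixing;
    ``cline_slope`` is the per-distance-unit logit drift used by
    :func:`simulate_ibd_cline`.
    """

    n_pops: int
    F: float
    n_loci: int
    alleles_per_locus: int
    n_per_pop: list[int] | int
    admixture_alpha: float | None = None
    cline_slope: float | None = None
    pop_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.F < 1):
            raise ValueError("F must lie in (0, 1)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.alleles_per_locus < 2:
            raise ValueError("alleles_per_locus must be >= 2")
        if isinstance(self.n_per_pop, int):
            self.n_per_pop = [self.n_per_pop] * self.n_pops
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop length != n_pops")
        if self.pop_labels is None:
            self.pop_labels = [f"P{k + 1}" for k in range(self.n_pops)]


def _pop_frequencies(spec: FModelSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-population frequencies, shapes (L, A) and (P, L, A)."""
    L, A, P = spec.n_loci, spec.alleles_per_locus, spec.n_pops
    p_anc = rng.dirichlet(np.ones(A), size=L)
    scale = (1.0 - spec.F) / spec.F
    p_pop = np.empty((P, L, A))
    for k in range(P):
        for l in range(L):
            p_pop[k, l] = rng.dirichlet(np.maximum(p_anc[l] * scale, 1e-9))
    return p_anc, p_pop


def _draw_dataset(
    spec: FModelSpec, p_pop: np.ndarray, rng: np.random.Generator
) -> GenotypeDataset:
    P, L, A = p_pop.shape
    ids, pops, rows = [], [], []
    counter = 1
    for k in range(P):
        nk = spec.n_per_pop[k]
        if spec.admixture_alpha is not None:
            # membership ~ Dirichlet(own-pop weight 1 + alpha/P everywhere):
            # alpha -> 0 gives pure individuals, alpha -> inf a single pool
            conc = np.full(P, spec.admixture_alpha / P)
            conc[k] += 1.0
            w = rng.dirichlet(conc, size=nk)
        for i in range(nk):
            calls = np.empty((L, 2), dtype=np.int64)
            for l in range(L):
                for c in range(2):
                    src = (
                        rng.choice(P, p=w[i])
                        if spec.admixture_alpha is not None
                        else k
                    )
                    calls[l, c] = rng.choice(A, p=p_pop[src, l]) + 1
            ids.append(f"I{counter:04d}")
            counter += 1
            pops.append(spec.pop_labels[k])
            rows.append(calls)
    return GenotypeDataset(
        np.array(ids, dtype=object),
        np.array(pops, dtype=object),
        [f"Loc{l + 1:02d}" for l in range(L)],
        np.array(rows, dtype=np.int64),
    )


def simulate_genotypes(
    spec: FModelSpec, seed: int
) -> tuple[GenotypeDataset, dict]:
    """Draw genotypes under the F-model.

    Returns the dataset and a truth dict with the ancestral and
    per-population allele frequencies so estimator recovery is assertable.
    """
    rng = np.random.default_rng(seed)
    p_anc, p_pop = _pop_frequencies(spec, rng)
    g = _draw_dataset(spec, p_pop, rng)
    return g, {"p_anc": p_anc, "p_pop": p_pop, "F": spec.F, "seed": seed}


def simulate_ibd_cline(
    spec: FModelSpec, positions: np.ndarray, seed: int
) -> tuple[GenotypeDataset, DistanceMatrixInput, dict]:
    """F-model genotypes with a monotone allele-frequency cline.

    After the F-model draw, the first allele's frequency at every locus is
    shifted on the logit scale by ``cline_slope * (position - mean)``,
    with the other alleles rescaled proportionally; the distance matrix is
    |position_i - position_j|. At slope 0 this reduces to the plain
    F-model (no systematic isolation by distance).
    """
    if spec.cline_slope is None:
        raise ValueError("cline_slope must be set on the spec")
    positions = np.asarray(positions, dtype=float)
    if spec.n_pops < 3:
        raise ValueError("need >= 3 populations for an IBD design")
    if len(positions) != spec.n_pops or (np.diff(positions) <= 0).any():
        raise ValueError("positions must be strictly increasing, one per population")
    rng = np.random.default_rng(seed)
    p_anc, p_pop = _pop_frequencies(spec, rng)
    centered = positions - positions.mean()
    eps = 1e-6
    for k in range(spec.n_pops):
        shift = spec.cline_slope * centered[k]
        for l in range(spec.n_loci):
            p1 = np.clip(p_pop[k, l, 0], eps, 1 - eps)
            p1 = expit(logit(p1) + shift)
            rest = p_pop[k, l, 1:]
            p_pop[k, l, 0] = p1
            p_pop[k, l, 1:] = rest * (1 - p1) / max(rest.sum(), eps)
    g = _draw_dataset(spec, p_pop, rng)
    d = np.abs(positions[:, None] - positions[None, :])
    dm = DistanceMatrixInput(list(spec.pop_labels), d)
    return g, dm, {"p_anc": p_anc, "p_pop": p_pop, "positions": positions}
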