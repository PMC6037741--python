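"""Core data containers shared across the pipeline.

Two marker types are carried through the analysis: per-fish otolith
near-core chemistry (continuous, multivariate) and diploid multi-locus
microsatellite genotypes (categorical allele calls grouped by sampling
location). Both are thin, validated wrappers around pandas/numpy objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: chemistry columns measured as element:Ca ratios (strictly positive,
#: log-transformed before standardization)
ELEMENT_RATIO_COLUMNS = ("MgCa", "MnCa", "SrCa", "BaCa")
#: stable-isotope columns in per-mil VPDB (interval scale, kept linear)
ISOTOPE_COLUMNS = ("d13C", "d18O")
CHEMISTRY_COLUMNS = ELEMENT_RATIO_COLUMNS + ISOTOPE_COLUMNS

#: sentinel for a missing allele call
MISSING = -1


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


@dataclass
class OtolithMatrix:
    """Per-fish otolith near-core chemistry.

    Parameters
    ----------
    fish_id : sequence of str
        Unique label per fish.
    location : sequence of str
        Sampling-location code per fish (e.g. NO, BAS, BAP, NS, BB, GS, PT).
    cohort : sequence of int
        Birth year per fish.
    values : DataFrame
        One row per fish; columns are a subset of the six chemistry
        variables (element:Ca ratios plus d13C/d18O), all numeric with no
        missing cells.
    """

    fish_id: np.ndarray
    location: np.ndarray
    cohort: np.ndarray
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.fish_id = np.asarray(self.fish_id, dtype=object)
        self.location = np.asarray(self.location, dtype=object)
        self.cohort = np.asarray(self.cohort, dtype=int)
        if len(set(self.fish_id)) != len(self.fish_id):
            raise ValidationError("duplicated fish_id")
        n = len(self.fish_id)
        if not (len(self.location) == len(self.cohort) == len(self.values) == n):
            raise ValidationError("field lengths disagree")
        if self.values.shape[1] < 2:
            raise ValidationError("need at least 2 chemistry variables")
        if self.values.isna().any().any():
            raise ValidationError("missing chemistry cells after validation")
        for col in self.values.columns:
            if col in ELEMENT_RATIO_COLUMNS and (self.values[col] <= 0).any():
                raise ValidationError(f"non-positive element:Ca ratio in {col}")

    @property
    def n(self) -> int:
        return len(self.fish_id)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GenotypeDataset:
    """Diploid multi-locus genotypes grouped by population.

    ``calls`` is an (n_individuals, n_loci, 2) integer array of allele
    codes; ``MISSING`` (-1) in both slots marks an untyped locus. Allele
    codes are opaque positive integers — only identity matters.
    """

    individual_id: np.ndarray
    population: np.ndarray
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.population = np.asarray(self.population, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n = len(self.individual_id)
        if len(set(self.individual_id)) != n:
            raise ValidationError("duplicated individual_id")
        if self.calls.shape != (n, len(self.loci), 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} != ({n}, {len(self.loci)}, 2)"
            )
        if len(self.population) != n:
            raise ValidationError("population length mismatch")
        if n and self.population.dtype == object and any(p == "" for p in self.population):
            raise ValidationError("empty population code")
        valid = (self.calls > 0) | (self.calls == MISSING)
        if not valid.all():
            raise ValidationError("allele codes must be positive or MISSING")
        # a half-missing diploid call is normalized to fully missing
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            self.calls[half] = MISSING

    @property
    def n(self) -> int:
        return len(self.individual_id)

    @property
    def populations(self) -> list[str]:
        """Population codes in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p, None)
        return list(seen)

    def subset(self, mask: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            self.individual_id[mask],
            self.population[mask],
            list(self.loci),
            self.calls[mask],
        )

    def population_calls(self, pop: str) -> np.ndarray:
        """Calls restricted to one population, shape (n_pop, n_loci, 2)."""
        return self.calls[self.population == pop]


@dataclass
class DistanceMatrixInput:
    """Pairwise waterway distances between sampling locations."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.labels)
        if self.d.shape != (k, k):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValidationError("distance matrix not symmetric")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-9:
            raise ValidationError("distance matrix diagonal not zero")
        if (self.d < -1e-12).any():
            raise ValidationError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)
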