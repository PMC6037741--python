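"""Shared fixtures: tiny genotype/chemistry datasets built in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fishconn import GenotypeDataset, OtolithMatrix

#: per-location sample sizes of the seven-location study design:
#: (otolith chemistry n, genotyped n, shared-individual n)
STUDY_DESIGN = {
    "NO": (10, 28, 10),
    "BAS": (13, 42, 13),
    "BAP": (18, 50, 18),
    "NS": (17, 50, 17),
    "BB": (13, 20, 13),
    "GS": (13, 61, 12),
    "PT": (18, 67, 16),
}


def make_genotypes(rows, loci=("L1", "L2")):
    """rows: list of (id, pop, calls) with calls shaped (n_loci, 2)."""
    ids = [r[0] for r in rows]
    pops = [r[1] for r in rows]
    calls = np.array([r[2] for r in rows], dtype=np.int64)
    return GenotypeDataset(
        np.array(ids, dtype=object), np.array(pops, dtype=object), list(loci), calls
    )


def single_locus_dataset(pop_genotypes: dict[str, list[tuple[int, int]]]):
    """One locus; pop_genotypes maps population -> list of allele pairs."""
    rows = []
    i = 0
    for pop, genos in pop_genotypes.items():
        for a1, a2 in genos:
            rows.append((f"i{i}", pop, [[a1, a2]]))
            i += 1
    return make_genotypes(rows, loci=("L1",))


@pytest.fixture
def two_pop_toy():
    """Single-locus pair used for the variance-components hand check."""
    return single_locus_dataset(
        {"P1": [(1, 1), (1, 1), (1, 2)], "P2": [(2, 2), (2, 2), (1, 2)]}
    )


@pytest.fixture
def chemistry_3x6():
    vals = pd.DataFrame(
        {
            "MgCa": [np.e, np.e**2, np.e**3],
            "MnCa": [1.0, 2.0, 3.0],
            "SrCa": [2.0, 2.5, 3.0],
            "BaCa": [0.1, 0.2, 0.3],
            "d13C": [-5.0, -6.0, -7.0],
            "d18O": [1.0, 0.0, -1.0],
        }
    )
    return OtolithMatrix(
        np.array(["a", "b", "c"], dtype=object),
        np.array(["NO", "NO", "NS"], dtype=object),
        np.array([2009, 2009, 2009]),
        vals,
    )


def study_design_files(rng: np.random.Generator) -> tuple[str, str]:
    """Chemistry CSV and Genepop text matching the study's sample sizes.

    Chemistry and genotype IDs overlap per location exactly at the shared
    count, so the reader + join path reproduces the combined-sample
    bookkeeping.
    """
    chem_rows = ["fish_id,location,cohort,MgCa,MnCa,SrCa,BaCa,d13C,d18O"]
    gen_lines = ["study-design fixture", "L1", "L2"]
    for loc, (n_oto, n_gen, n_combi) in STUDY_DESIGN.items():
        gen_lines.append("Pop")
        for j in range(1, n_gen + 1):
            a = rng.integers(1, 6, size=4)
            gen_lines.append(
                f"{loc}g{j} , {a[0]:02d}{a[1]:02d} {a[2]:02d}{a[3]:02d}"
            )
        for j in range(1, n_oto + 1):
            fid = f"{loc}g{j}" if j <= n_combi else f"{loc}x{j}"
            v = rng.lognormal(0, 0.2, size=4)
            iso = rng.normal(0, 1, size=2)
            chem_rows.append(
                f"{fid},{loc},2009,{v[0]:.4f},{v[1]:.4f},{v[2]:.4f},{v[3]:.4f},"
                f"{iso[0]:.3f},{iso[1]:.3f}"
            )
    return "\n".join(chem_rows) + "\n", "\n".join(gen_lines) + "\n"
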