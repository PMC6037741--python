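"""Readers and writers for the formats the pipeline touches.

Genepop is the interchange format for microsatellite genotypes; chemistry
and distance matrices travel as plain CSV. ``write_report`` dumps a result
bundle (any subset of the pipeline outputs) into a directory of CSV/newick
files plus a run log.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CHEMISTRY_COLUMNS,
    MISSING,
    DistanceMatrixInput,
    GenotypeDataset,
    OtolithMatrix,
)

logger = logging.getLogger("fishconn")


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _as_lines(source: str | Path | IO[str]) -> list[str]:
    if isinstance(source, Path):
        return source.read_text().splitlines()
    if isinstance(source, str):
        p = Path(source)
        if "\n" not in source and p.is_file():
            return p.read_text().splitlines()
        return source.splitlines()
    return source.read().splitlines()


def read_genepop(
    source: str | Path | IO[str],
    pop_names: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Parse a Genepop file into a :class:`GenotypeDataset`.

    Layout: a title line; locus names one per line or comma-separated on
    one line; blocks introduced by a line reading ``pop`` (any case), each
    block one individual per line as ``id , call call ...`` where a diploid
    call is two concatenated 2- or 3-digit allele codes. ``00``/``000``
    half-calls or all-zero whole calls decode to missing. The allele digit
    width is inferred from the file and must be consistent.

    Populations are named after the last individual id of each block
    (the classic convention) unless ``pop_names`` overrides them.
    """
    lines = _as_lines(source)
    if not lines:
        raise ParseError("empty Genepop file")
    # locus names: lines 2.. until first 'pop'
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if part:
            loci.extend(t.strip() for t in part.split(",") if t.strip())
        i += 1
    if i >= len(lines):
        raise ParseError("no Pop separator found (zero populations)")
    if not loci:
        raise ParseError("no locus names before first Pop line")

    blocks: list[list[tuple[int, str, list[str]]]] = []
    current: list[tuple[int, str, list[str]]] | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            current = []
            blocks.append(current)
            continue
        if current is None:
            raise ParseError(f"line {lineno + 1}: genotype line before first Pop")
        if "," not in raw:
            raise ParseError(f"line {lineno + 1}: expected 'id , genotypes'")
        ind_id, _, geno = raw.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"line {lineno + 1}: {len(tokens)} calls for {len(loci)} loci"
            )
        current.append((lineno + 1, ind_id.strip(), tokens))
    if not blocks or all(len(b) == 0 for b in blocks):
        raise ParseError("zero populations with individuals")

    # infer allele digit width: whole calls are 4 or 6 characters
    width = None
    for block in blocks:
        for lineno, _, tokens in block:
            for tok in tokens:
                if len(tok) == 4:
                    w = 2
                elif len(tok) == 6:
                    w = 3
                else:
                    raise ParseError(
                        f"line {lineno}: call '{tok}' has invalid width {len(tok)}"
                    )
                if width is None:
                    width = w
                elif width != w:
                    raise ParseError(
                        f"line {lineno}: inconsistent call width ({len(tok)} chars)"
                    )
    assert width is not None

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[list[int]]] = []
    labels: list[str] = []
    for b, block in enumerate(blocks):
        label = block[-1][1] if block else f"pop{b + 1}"
        labels.append(label)
    if pop_names is not None:
        if len(pop_names) != len(blocks):
            raise ParseError(
                f"{len(pop_names)} pop_names given for {len(blocks)} Pop blocks"
            )
        labels = list(pop_names)
    for label, block in zip(labels, blocks):
        for lineno, ind_id, tokens in block:
            calls = []
            for tok in tokens:
                a1 = int(tok[:width])
                a2 = int(tok[width:])
                if a1 == 0 or a2 == 0:
                    a1 = a2 = MISSING
                calls.append([a1, a2])
            ids.append(ind_id)
            pops.append(label)
            rows.append(calls)
    return GenotypeDataset(
        np.array(ids, dtype=object),
        np.array(pops, dtype=object),
        loci,
        np.array(rows, dtype=np.int64),
    )


def write_genepop(g: GenotypeDataset, title: str = "fishconn export") -> str:
    """Serialize a dataset back to Genepop text (3-digit allele codes)."""
    out = [title]
    out.extend(g.loci)
    for pop in g.populations:
        out.append("Pop")
        idx = np.flatnonzero(g.population == pop)
        for i in idx:
            toks = []
            for l in range(len(g.loci)):
                a1, a2 = g.calls[i, l]
                if a1 == MISSING:
                    toks.append("000000")
                else:
                    toks.append(f"{a1:03d}{a2:03d}")
            out.append(f"{g.individual_id[i]} , " + " ".join(toks))
    return "\n".join(out) + "\n"


def read_chemistry_csv(source: str | Path | IO[str]) -> tuple[OtolithMatrix, int]:
    """Read an otolith-chemistry table.

    Required columns: ``fish_id``, ``location``, ``cohort`` and the six
    chemistry variables. Rows with any missing chemistry cell are dropped;
    the dropped-row count is returned alongside the matrix and logged.
    """
    if isinstance(source, (str, Path)) and not (
        isinstance(source, str) and "\n" in source
    ):
        df = pd.read_csv(source)
    else:
        text = source if isinstance(source, str) else source.read()
        df = pd.read_csv(_io.StringIO(text))
    required = ["fish_id", "location", "cohort", *CHEMISTRY_COLUMNS]
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise ParseError(f"missing mandatory column(s): {', '.join(absent)}")
    chem = df[list(CHEMISTRY_COLUMNS)]
    for col in CHEMISTRY_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise ParseError(
                f"non-numeric value in column {col}, row {int(np.flatnonzero(bad)[0])}"
            )
    keep = chem.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d rows with missing chemistry cells", dropped)
    df = df[keep].reset_index(drop=True)
    mat = OtolithMatrix(
        df["fish_id"].astype(str).to_numpy(),
        df["location"].astype(str).to_numpy(),
        df["cohort"].to_numpy(),
        df[list(CHEMISTRY_COLUMNS)].astype(float),
    )
    return mat, dropped


def write_chemistry_csv(m: OtolithMatrix) -> str:
    df = pd.DataFrame(
        {"fish_id": m.fish_id, "location": m.location, "cohort": m.cohort}
    )
    df = pd.concat([df, m.values.reset_index(drop=True)], axis=1)
    return df.to_csv(index=False)


def read_distance_csv(source: str | Path | IO[str]) -> DistanceMatrixInput:
    """Read a labelled square distance matrix (labels in first column/header)."""
    if isinstance(source, (str, Path)) and not (
        isinstance(source, str) and "\n" in source
    ):
        df = pd.read_csv(source, index_col=0)
    else:
        text = source if isinstance(source, str) else source.read()
        df = pd.read_csv(_io.StringIO(text), index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError("distance matrix row/column labels disagree")
    return DistanceMatrixInput(list(df.index), df.to_numpy(dtype=float))


def write_distance_csv(d: DistanceMatrixInput) -> str:
    return pd.DataFrame(d.d, index=d.labels, columns=d.labels).to_csv()


# --- report bundle -----------------------------------------------------------

#: bundle key -> output file name for DataFrame-valued results
_TABLE_FILES = {
    "diversity": "diversity.csv",
    "pairwise_fst": "pairwise_fst.csv",
    "fst_pvalues": "fst_pvalues.csv",
    "q_matrix": "q_matrix.csv",
    "delta_k": "delta_k.csv",
    "coassignment": "coassignment.csv",
    "k_posterior": "k_posterior.csv",
    "nmds": "nmds_coords.csv",
    "pcoa": "pcoa_coords.csv",
    "combined": "combined_coordinates.csv",
}


def write_report(bundle: dict, out_dir: str | Path, params: dict | None = None) -> list[Path]:
    """Write a results bundle to ``out_dir``.

    ``bundle`` maps result names to pandas DataFrames (tables), a newick
    string under key ``"consensus_tree"``, or plain scalars collected into
    the run log. Returns the list of files written.
    """
    if not bundle:
        raise ValueError("nothing to write: empty results bundle")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    scalars: dict = {}
    for key, value in bundle.items():
        if key == "consensus_tree":
            path = out / "consensus_tree.nwk"
            path.write_text(value if value.endswith("\n") else value + "\n")
            written.append(path)
        elif isinstance(value, pd.DataFrame):
            path = out / _TABLE_FILES.get(key, f"{key}.csv")
            keep_index = not isinstance(value.index, pd.RangeIndex)
            value.to_csv(path, index=keep_index)
            written.append(path)
        else:
            scalars[key] = value
    log = out / "run_log.txt"
    with log.open("w") as fh:
        from . import __version__

        fh.write(f"fishconn {__version__}\n")
        for k, v in (params or {}).items():
            fh.write(f"param {k} = {v}\n")
        for k, v in scalars.items():
            fh.write(f"result {k} = {v}\n")
    written.append(log)
    return written
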