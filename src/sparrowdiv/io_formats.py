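"""Readers and writers for the external formats the pipeline touches.

GenePop (diploid microsatellites, 2- or 3-digit allele codes, ``000``/``00``
missing), delimited tables (phenotypes, localities, assay event logs,
reflectance spectra) and labeled symmetric matrices as TSV.
"""

from __future__ import annotations

import io
import os
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ARG_EVENTS,
    WAVELENGTHS,
    AssayEvent,
    AssayLog,
    Individual,
    LocalityTable,
    MicrosatDataset,
    PairwiseMatrix,
    PhenotypeTable,
    SpectrumTable,
    ValidationError,
)


class ParseError(ValueError):
    """Malformed input; message carries the offending line number."""


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _looks_like_genepop_text(source: str) -> bool:
    return "\n" in source


def read_genepop(source, region_of: dict[str, str] | None = None) -> MicrosatDataset:
    """Parse a GenePop file (path, text, or file-like) into a dataset.

    Population names are taken from the first individual label of each Pop
    block (text before the comma).  Both 2- and 3-digit allele encodings are
    accepted; ``00``/``000`` is a missing gene copy.  ``region_of`` optionally
    assigns populations to regions (default: empty region).
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, (str, os.PathLike)) and not _looks_like_genepop_text(str(source)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    lines = text.splitlines()
    if not lines:
        raise ParseError("line 1: empty GenePop input")

    # locus names: lines 2.. until first Pop; a single line may be comma-separated
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise ParseError(f"line {i + 1}: no locus names before first Pop")
    if i >= len(lines):
        raise ParseError(f"line {len(lines)}: no Pop block found")

    individuals: list[Individual] = []
    calls: list[list[tuple[int, int]]] = []
    pop_name = None
    block_size: int | None = None
    pop_sizes: dict[str, int] = {}
    width = None
    while i < len(lines):
        if _POP_RE.match(lines[i]):
            if block_size == 0:
                raise ParseError(f"line {i + 1}: empty Pop block before this line")
            pop_name = None  # named by the first individual of the block
            block_size = 0
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if "," not in line:
            raise ParseError(f"line {i + 1}: expected 'label , genotypes'")
        label, _, geno = line.partition(",")
        label = label.strip()
        fields = geno.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"line {i + 1}: {len(fields)} genotype fields for {len(loci)} loci"
            )
        if pop_name is None:
            pop_name = label if label else f"pop{len(pop_sizes) + 1}"
            if pop_name in pop_sizes:
                pop_name = f"{pop_name}_{len(pop_sizes) + 1}"
            pop_sizes[pop_name] = 0
        row = []
        for f in fields:
            if len(f) not in (4, 6) or not f.isdigit():
                raise ParseError(
                    f"line {i + 1}: malformed allele field {f!r} (need 2x2 or 2x3 digits)"
                )
            w = len(f) // 2
            if width is None:
                width = w
            elif w != width:
                raise ParseError(f"line {i + 1}: mixed allele widths in one file")
            row.append((int(f[:w]), int(f[w:])))
        region = (region_of or {}).get(pop_name, "")
        individuals.append(Individual(id=label, population=pop_name, region=region))
        pop_sizes[pop_name] += 1
        block_size = (block_size or 0) + 1
        calls.append(row)
        i += 1
    if block_size == 0:
        raise ParseError(f"line {len(lines)}: trailing empty Pop block")
    if not individuals:
        raise ParseError(f"line {len(lines)}: no individuals in any Pop block")

    arr = np.array(calls, dtype=np.int64)
    # a half-missing call is treated as fully missing
    half = (arr == 0).any(axis=2) & (arr != 0).any(axis=2)
    arr[half] = 0
    # store pairs unordered: canonical (low, high)
    arr = np.sort(arr, axis=2)
    return MicrosatDataset(individuals, loci, arr)


def write_genepop(dataset: MicrosatDataset, path=None, title: str = "sparrowdiv export") -> str:
    """Serialize a dataset in 3-digit GenePop encoding; returns the text."""
    if not dataset.loci:
        raise ValidationError("cannot write a GenePop file with no loci")
    if (dataset.calls >= 1000).any():
        raise ValidationError("allele codes must be < 1000 for 3-digit encoding")
    out = io.StringIO()
    out.write(title + "\n")
    for locus in dataset.loci:
        out.write(locus + "\n")
    for pop in dataset.populations:
        out.write("Pop\n")
        for i in dataset.indices_of(pop):
            pair_text = " ".join(
                f"{a:03d}{b:03d}" for a, b in np.sort(dataset.calls[i], axis=1)
            )
            out.write(f"{dataset.individuals[i].id}, {pair_text}\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def _read_delimited(path) -> pd.DataFrame:
    """CSV with tab auto-detect, UTF-8."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    header = text.splitlines()[0] if text else ""
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(io.StringIO(text), sep=sep)


def read_table(path, schema: str):
    """Read and validate one of the delimited-table schemas.

    schema in {"phenotype", "locality", "assay", "spectrum"}.
    """
    df = _read_delimited(path)
    if schema == "phenotype":
        return PhenotypeTable(df)
    if schema == "locality":
        return LocalityTable(df)
    if schema == "assay":
        return _assays_from_frame(df)
    if schema == "spectrum":
        return _spectra_from_frame(df)
    raise ValueError(f"unknown schema {schema!r}")


def _assays_from_frame(df: pd.DataFrame) -> list[AssayLog]:
    """Long event CSV -> AssayLogs.

    Columns: assay_id, bird_id, population, duration, decorated_perches
    (semicolon-separated ids, repeated per row), event_time, event_kind,
    event_arg (blank for simple events).  An assay with a blank event_kind
    row contributes no events (a bird that never moved).
    """
    needed = ["assay_id", "bird_id", "population", "duration",
              "event_time", "event_kind"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"assay table missing columns {missing}")
    logs = []
    for assay_id, grp in df.groupby("assay_id", sort=False):
        first = grp.iloc[0]
        decorated = frozenset(
            int(x) for x in str(first.get("decorated_perches", "1;2;3")).split(";") if x != ""
        )
        events = []
        for _, row in grp.sort_values("event_time").iterrows():
            kind = row["event_kind"]
            if pd.isna(kind) or kind == "":
                continue
            arg = row.get("event_arg")
            arg = None if pd.isna(arg) else int(arg)
            if kind in ARG_EVENTS and arg is None:
                raise ValidationError(f"assay {assay_id}: event {kind} needs an id")
            events.append(AssayEvent(float(row["event_time"]), str(kind), arg))
        logs.append(
            AssayLog(
                assay_id=str(assay_id),
                bird_id=str(first["bird_id"]),
                population=str(first["population"]),
                duration=float(first["duration"]),
                events=events,
                decorated_perches=decorated,
            )
        )
    return logs


def _spectra_from_frame(df: pd.DataFrame) -> SpectrumTable:
    wl_cols = [c for c in df.columns if re.fullmatch(r"(wl_?)?\d{3}", str(c))]
    got = [int(re.sub(r"\D", "", c)) for c in wl_cols]
    if sorted(got) != list(WAVELENGTHS):
        raise ValidationError(
            f"spectrum table needs exactly the 36 wavelength columns 380..730; got {len(got)}"
        )
    wl_cols = [c for _, c in sorted(zip(got, wl_cols))]
    samples = (
        df["sample"].astype(str).tolist()
        if "sample" in df.columns
        else [f"s{i}" for i in range(len(df))]
    )
    return SpectrumTable(samples, df[wl_cols].to_numpy(dtype=float))


def write_assay_table(logs: list[AssayLog], path=None) -> pd.DataFrame:
    rows = []
    for log in logs:
        meta = dict(
            assay_id=log.assay_id, bird_id=log.bird_id, population=log.population,
            duration=log.duration,
            decorated_perches=";".join(str(p) for p in sorted(log.decorated_perches)),
        )
        if not log.events:
            rows.append({**meta, "event_time": 0.0, "event_kind": "", "event_arg": None})
        for ev in log.events:
            rows.append({**meta, "event_time": ev.time, "event_kind": ev.kind,
                         "event_arg": ev.arg})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def write_spectrum_table(table: SpectrumTable, path=None) -> pd.DataFrame:
    df = pd.DataFrame(table.reflectance, columns=[f"wl_{w}" for w in WAVELENGTHS])
    df.insert(0, "sample", table.samples)
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# Labeled symmetric matrices
# ---------------------------------------------------------------------------

def read_matrix_tsv(path) -> PairwiseMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in df.index]
    if labels != [str(x) for x in df.columns]:
        raise ValidationError("matrix row and column labels differ")
    return PairwiseMatrix(labels, df.to_numpy(dtype=float))


def write_matrix_tsv(matrix: PairwiseMatrix, path) -> None:
    pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels).to_csv(
        path, sep="\t", float_format="%.6g"
    )
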