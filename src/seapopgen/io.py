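"""Readers and writers for the standard inputs and outputs of the pipeline.

No science lives here: FASTA alignments (via Biopython), GENEPOP genotype
files, labeled square CSV matrices, locality tables and the run
configuration.  All readers validate their invariants and compose with the
matching writers to identity on valid files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("seapopgen")

VALID_BASES = set("ACGTN-")

class InputError(ValueError):
    """Malformed or empty input file."""


class AlignmentError(InputError):
    """Sequences do not form a valid alignment (ragged lengths, bad symbols)."""


class FormatError(InputError):
    """File violates its format contract (GENEPOP digits, non-square CSV...)."""


class MatrixValidationError(InputError):
    """A matrix flagged symmetric is not."""


@dataclass
class SequenceAlignment:
    """Aligned haploid sequences with per-sample population labels."""

    ids: list[str]
    population: list[str]
    sites: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise AlignmentError("sample identifiers are not unique")
        if not (len(self.ids) == len(self.population) == len(self.sites)):
            raise AlignmentError("ids, population and sites differ in length")
        lengths = {len(s) for s in self.sites}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        if any(not p for p in self.population):
            raise AlignmentError("empty population label")
        for s in self.sites:
            bad = set(s) - VALID_BASES
            if bad:
                raise AlignmentError(f"invalid residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sites[0]) if self.sites else 0

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p)
        return list(seen)


@dataclass
class GenotypeTable:
    """Diploid codominant genotypes: allele sizes (repeat units) or missing.

    ``calls[i][l]`` is an unordered pair ``(a, b)`` of positive ints for
    individual ``i`` at locus ``l``, or ``None`` when missing.
    """

    ids: list[str]
    population: list[str]
    loci: list[str]
    calls: list[list[Optional[tuple[int, int]]]]

    def __post_init__(self) -> None:
        for row in self.calls:
            if len(row) != len(self.loci):
                raise InputError("genotype row length does not match loci")
            for call in row:
                if call is None:
                    continue
                a, b = call
                if a <= 0 or b <= 0:
                    raise InputError(f"non-positive allele value in {call}")
        for l, locus in enumerate(self.loci):
            if all(row[l] is None for row in self.calls):
                raise InputError(f"locus {locus} has no non-missing call")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p)
        return list(seen)

    def subset(self, pops: Sequence[str]) -> "GenotypeTable":
        keep = [i for i, p in enumerate(self.population) if p in set(pops)]
        return GenotypeTable(
            ids=[self.ids[i] for i in keep],
            population=[self.population[i] for i in keep],
            loci=list(self.loci),
            calls=[self.calls[i] for i in keep],
        )

    def alleles(self, locus: str, pop: Optional[str] = None) -> list[int]:
        """Flat list of gene copies at ``locus`` (optionally one population)."""
        l = self.loci.index(locus)
        out: list[int] = []
        for i, row in enumerate(self.calls):
            if pop is not None and self.population[i] != pop:
                continue
            if row[l] is not None:
                out.extend(row[l])
        return out


@dataclass
class LocalityTable:
    """Sampling localities with coordinates, group labels and habitat cells."""

    names: list[str]
    longitude: list[float]
    latitude: list[float]
    group: list[str]
    habitat_cells: list[list[tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise InputError("locality names are not unique")
        for lon, lat in zip(self.longitude, self.latitude):
            if not (-180.0 <= lon <= 360.0 and -90.0 <= lat <= 90.0):
                raise InputError(f"coordinate out of range: ({lon}, {lat})")


@dataclass
class MatrixTable:
    """Labeled square matrix of floats with an optional p-value matrix."""

    labels: list[str]
    values: np.ndarray
    pvalues: Optional[np.ndarray] = None
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if self.symmetric and not np.allclose(
            self.values, self.values.T, equal_nan=True
        ):
            raise MatrixValidationError("matrix flagged symmetric is asymmetric")
        if self.pvalues is not None:
            self.pvalues = np.asarray(self.pvalues, dtype=float)
            if self.pvalues.shape != (n, n):
                raise FormatError("p-value matrix shape mismatch")

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries in row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_alignment(
    path: str | Path,
    population_map: dict[str, str],
    unknown_policy: str = "error",
) -> SequenceAlignment:
    """Read an aligned FASTA file and attach population labels.

    ``unknown_policy`` is ``"error"`` (reject samples missing from the map)
    or ``"unknown"`` (assign the label ``UNKNOWN``).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    ids, pops, seqs = [], [], []
    for rec in records:
        if rec.id in population_map:
            pop = population_map[rec.id]
        elif unknown_policy == "unknown":
            pop = "UNKNOWN"
        else:
            raise InputError(f"sample {rec.id} has no population mapping")
        ids.append(rec.id)
        pops.append(pop)
        seqs.append(str(rec.seq).upper())
    aln = SequenceAlignment(ids=ids, population=pops, sites=seqs)
    logger.info("read %d aligned sequences (L=%d) from %s", aln.n_samples, aln.length, path)
    return aln


def write_fasta_alignment(aln: SequenceAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.sites)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GENEPOP

_GENEPOP_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _decode_genepop_call(tok: str, digits: int) -> Optional[tuple[int, int]]:
    a = int(tok[:digits])
    b = int(tok[digits:])
    if a == 0 or b == 0:
        return None
    return (a, b)


def read_genepop(path: str | Path) -> GenotypeTable:
    """Read a GENEPOP file (2- or 3-digit encoding, detected per file).

    Population labels are taken from the identifier of the *last* individual
    in each POP block (the conventional GENEPOP usage); ``000``/``00`` halves
    decode as missing.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise InputError(f"GENEPOP file {path} too short")
    body = lines[1:]  # first line is a title comment
    # locus names: either one comma-separated line or one per line before POP
    loci: list[str] = []
    i = 0
    while i < len(body) and not _GENEPOP_POP_RE.match(body[i]):
        loci.extend(t.strip() for t in body[i].split(",") if t.strip())
        i += 1
    if not loci or i == len(body):
        raise FormatError("no loci or no POP separator found")

    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] = []
    for line in body[i:]:
        if _GENEPOP_POP_RE.match(line):
            if current:
                blocks.append(current)
            current = []
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise FormatError(f"genotype line lacks comma: {line!r}")
        name, geno = line.split(",", 1)
        toks = geno.split()
        if len(toks) != len(loci):
            raise FormatError(
                f"individual {name.strip()!r} has {len(toks)} genotypes, expected {len(loci)}"
            )
        current.append((name.strip(), toks))
    if current:
        blocks.append(current)
    if not blocks:
        raise InputError("no individuals in GENEPOP file")

    widths = {len(t) for block in blocks for _, toks in block for t in toks}
    if len(widths) != 1 or widths.pop() not in (4, 6):
        raise FormatError(
            "mixed or invalid allele-code widths; expected uniform 2- or 3-digit coding"
        )
    digits = len(blocks[0][0][1][0]) // 2

    ids, pops, calls = [], [], []
    for block in blocks:
        pop_label = block[-1][0]
        for k, (name, toks) in enumerate(block):
            ids.append(f"{pop_label}_{k}" if name == pop_label else name)
            pops.append(pop_label)
            calls.append([_decode_genepop_call(t, digits) for t in toks])
    # ensure uniqueness (GENEPOP reuses names freely)
    if len(ids) != len(set(ids)):
        ids = [f"{p}_{k}" for k, p in enumerate(pops)]
    table = GenotypeTable(ids=ids, population=pops, loci=loci, calls=calls)
    logger.info(
        "read %d individuals x %d loci (%d populations) from %s",
        len(ids), len(loci), len(table.populations), path,
    )
    return table


def write_genepop(table: GenotypeTable, path: str | Path, digits: int = 3) -> None:
    fmt = f"%0{digits}d%0{digits}d"
    missing = "0" * (2 * digits)
    out = ["seapopgen genotypes", ", ".join(table.loci)]
    for pop in table.populations:
        out.append("POP")
        rows = [i for i, p in enumerate(table.population) if p == pop]
        for i in rows:
            toks = [
                fmt % call if (call := table.calls[i][l]) is not None else missing
                for l in range(len(table.loci))
            ]
            out.append(f"{pop}, " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV matrices and localities


def read_matrix_csv(path: str | Path, symmetric: bool = False) -> MatrixTable:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"matrix in {path} is {df.shape[0]}x{df.shape[1]}, not square")
    if list(df.index) != list(df.columns):
        raise FormatError("row labels differ from column labels")
    return MatrixTable(
        labels=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        symmetric=symmetric,
    )


def write_matrix_csv(table: MatrixTable, path: str | Path) -> None:
    df = pd.DataFrame(table.values, index=table.labels, columns=table.labels)
    df.to_csv(path, float_format="%.6g")
    if table.pvalues is not None:
        p = Path(path)
        pd.DataFrame(table.pvalues, index=table.labels, columns=table.labels).to_csv(
            p.with_name(p.stem + ".pvalues" + p.suffix), float_format="%.6g"
        )


def read_locality_csv(path: str | Path) -> LocalityTable:
    df = pd.read_csv(path)
    required = {"name", "longitude", "latitude", "group"}
    if not required <= set(df.columns):
        raise FormatError(f"locality CSV must contain columns {sorted(required)}")
    cells: list[list[tuple[int, int]]] = []
    if "habitat_cells" in df.columns:
        for spec in df["habitat_cells"]:
            if pd.isna(spec) or not str(spec).strip():
                cells.append([])
            else:
                cells.append(
                    [tuple(int(v) for v in c.split(":")) for c in str(spec).split(";")]
                )
    return LocalityTable(
        names=[str(n) for n in df["name"]],
        longitude=list(df["longitude"].astype(float)),
        latitude=list(df["latitude"].astype(float)),
        group=[str(g) for g in df["group"]],
        habitat_cells=cells,
    )


def write_locality_csv(table: LocalityTable, path: str | Path) -> None:
    cells = table.habitat_cells or [[] for _ in table.names]
    df = pd.DataFrame(
        {
            "name": table.names,
            "longitude": table.longitude,
            "latitude": table.latitude,
            "group": table.group,
            "habitat_cells": [
                ";".join(f"{i}:{j}" for i, j in cc) for cc in cells
            ],
        }
    )
    df.to_csv(path, index=False)
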