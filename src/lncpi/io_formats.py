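"""Readers and writers for the external representations of an LPI study.

Sequences arrive as FASTA (nucleotide for lncRNAs, amino acid for
proteins), the interaction network as a two-column edge-list TSV or a
dense 0/1 matrix, and predictions leave as a ranked five-column TSV.
All canonicalization of raw sequence text happens here, once, so the
encoders downstream can assume clean alphabets.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class Alphabet(enum.Enum):
    """Declared alphabet of a sequence collection."""

    NUCLEOTIDE = "nucleotide"
    PROTEIN = "protein"

    @property
    def letters(self) -> str:
        return NUCLEOTIDES if self is Alphabet.NUCLEOTIDE else AMINO_ACIDS


@dataclass(frozen=True)
class SequenceRecord:
    """One identified sequence over a declared alphabet."""

    id: str
    sequence: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        bad = set(self.sequence) - set(self.alphabet.letters)
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} outside "
                f"{self.alphabet.value} alphabet"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class InteractionMatrix:
    """Binary bipartite matrix Y: rows are lncRNAs, columns proteins.

    ``Y[i, j] == 1`` records a known interaction between ``lnc_ids[i]``
    and ``prot_ids[j]``; 0 is an unlabeled (presumed negative) pair.
    """

    lnc_ids: list[str]
    prot_ids: list[str]
    Y: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        if self.Y.shape != (len(self.lnc_ids), len(self.prot_ids)):
            raise ValueError(
                f"matrix shape {self.Y.shape} does not match id lists "
                f"({len(self.lnc_ids)}, {len(self.prot_ids)})"
            )
        if len(set(self.lnc_ids)) != len(self.lnc_ids):
            raise ValueError("duplicate lncRNA ids")
        if len(set(self.prot_ids)) != len(self.prot_ids):
            raise ValueError("duplicate protein ids")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")
        self.Y = self.Y.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.Y.shape

    def positive_pairs(self) -> list[tuple[str, str]]:
        """All (lnc_id, prot_id) pairs with a recorded interaction."""
        rows, cols = np.nonzero(self.Y)
        return [(self.lnc_ids[i], self.prot_ids[j]) for i, j in zip(rows, cols)]

    def zero_pairs(self) -> list[tuple[str, str]]:
        """All unlabeled (lnc_id, prot_id) pairs."""
        rows, cols = np.nonzero(self.Y == 0)
        return [(self.lnc_ids[i], self.prot_ids[j]) for i, j in zip(rows, cols)]


def canonicalize(raw: str, alphabet: Alphabet) -> tuple[str, int]:
    """Uppercase, map U->T for nucleotides, drop foreign characters.

    Returns the clean sequence and the number of characters discarded.
    """
    seq = raw.upper()
    if alphabet is Alphabet.NUCLEOTIDE:
        seq = seq.replace("U", "T")
    allowed = set(alphabet.letters)
    kept = [c for c in seq if c in allowed]
    return "".join(kept), len(seq) - len(kept)


def read_fasta(path: str | Path, alphabet: Alphabet) -> list[SequenceRecord]:
    """Parse a FASTA file into canonicalized :class:`SequenceRecord`s.

    Sequences are uppercased; for nucleotide input U is mapped to T and
    characters outside the declared alphabet are dropped with a logged
    count. Duplicate ids and records left empty after cleaning raise.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    dropped_total = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq, dropped = canonicalize(str(entry.seq), alphabet)
        dropped_total += dropped
        if not seq:
            raise ValueError(
                f"record {entry.id!r} in {path} is empty after canonicalization"
            )
        records.append(SequenceRecord(entry.id, seq, alphabet))
    if not records:
        raise ValueError(f"{path} contains no FASTA records")
    if dropped_total:
        logger.warning(
            "%s: discarded %d characters outside the %s alphabet",
            path,
            dropped_total,
            alphabet.value,
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_network(
    path: str | Path,
    lnc_ids: Sequence[str],
    prot_ids: Sequence[str],
    fmt: str = "auto",
) -> InteractionMatrix:
    """Read an interaction network as an edge list or a dense matrix.

    Edge-list mode: two tab-separated columns (lnc_id, prot_id), one
    positive interaction per line, no header. Matrix mode: first row is
    protein ids, first column lncRNA ids, entries 0/1. ``fmt="auto"``
    sniffs the format from the first line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    lnc_index = {x: i for i, x in enumerate(lnc_ids)}
    prot_index = {x: j for j, x in enumerate(prot_ids)}
    if fmt == "auto":
        # an edge-list line starts with a known lncRNA id; a matrix header
        # starts with a corner label and lists every protein id
        fmt = "edges"
        if lines:
            head = lines[0].rstrip("\n").split("\t")
            body = [t for t in head[1:] if t]
            if (
                head[0] not in lnc_index
                and body
                and set(body) == set(prot_ids)
                and len(lines) > 1
                and len(lines[1].rstrip("\n").split("\t")) == len(body) + 1
            ):
                fmt = "matrix"
    Y = np.zeros((len(lnc_ids), len(prot_ids)), dtype=np.int8)
    if fmt == "edges":
        for ln, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated fields")
            lnc, prot = parts
            if lnc not in lnc_index:
                raise ValueError(f"{path}:{ln}: unknown lncRNA id {lnc!r}")
            if prot not in prot_index:
                raise ValueError(f"{path}:{ln}: unknown protein id {prot!r}")
            Y[lnc_index[lnc], prot_index[prot]] = 1
    elif fmt == "matrix":
        if not lines:
            raise ValueError(f"{path}: empty matrix file")
        header = lines[0].rstrip("\n").split("\t")
        cols = [t for t in header[1:] if t]
        for prot in cols:
            if prot not in prot_index:
                raise ValueError(f"{path}: unknown protein id {prot!r}")
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            lnc = parts[0]
            if lnc not in lnc_index:
                raise ValueError(f"{path}:{ln}: unknown lncRNA id {lnc!r}")
            if len(parts) - 1 != len(cols):
                raise ValueError(f"{path}:{ln}: row width does not match header")
            for prot, tok in zip(cols, parts[1:]):
                if tok not in ("0", "1"):
                    raise ValueError(f"{path}:{ln}: non-binary entry {tok!r}")
                Y[lnc_index[lnc], prot_index[prot]] = int(tok)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    return InteractionMatrix(list(lnc_ids), list(prot_ids), Y)


def write_network(
    matrix: InteractionMatrix, path: str | Path, fmt: str = "edges"
) -> None:
    """Write a network as an edge list or a dense header-ed matrix."""
    path = Path(path)
    if fmt == "edges":
        with open(path, "w") as fh:
            for lnc, prot in matrix.positive_pairs():
                fh.write(f"{lnc}\t{prot}\n")
    elif fmt == "matrix":
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(matrix.prot_ids) + "\n")
            for i, lnc in enumerate(matrix.lnc_ids):
                row = "\t".join(str(int(v)) for v in matrix.Y[i])
                fh.write(f"{lnc}\t{row}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def write_predictions(
    pairs: Iterable[tuple[str, str, float, bool]], path: str | Path
) -> None:
    """Write scored pairs as a ranked TSV.

    Columns: rank, lnc_id, prot_id, score, known. Rows are sorted by
    score descending with ties broken by (lnc_id, prot_id) lexicographic
    order, so output is reproducible for equal scores.
    """
    rows = list(pairs)
    for lnc, prot, score, _known in rows:
        if not math.isfinite(score):
            raise ValueError(f"non-finite score for pair ({lnc!r}, {prot!r})")
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("rank\tlnc_id\tprot_id\tscore\tknown\n")
        for rank, (lnc, prot, score, known) in enumerate(rows, start=1):
            fh.write(f"{rank}\t{lnc}\t{prot}\t{score:.6g}\t{int(known)}\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored; keys are dotted paths
    (e.g. ``dnn.learning_rate``) interpreted by the pipeline config.
    """
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, value = stripped.split("=", 1)
        out[key.strip()] = value.strip()
    return out
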