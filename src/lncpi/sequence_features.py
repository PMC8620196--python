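"""Fixed-dimension sequence descriptors for lncRNAs and proteins.

Each lncRNA is encoded by 13 descriptor families (scalar composition
statistics, pseudo k-tuple composition, and seven k-gap families) into
a 14,891-dimensional vector; each protein by pseudo k-tuple composition
plus one k-gap family into a 10,420-dimensional vector. All k-mer and
k-gap features are raw occurrence counts; min-max scaling is applied
only after feature selection, on training data.

A k-gap feature counts a fixed head a-mer followed, after exactly g
wildcard positions, by a fixed tail b-mer, for g = 1..K. Families are
named by head/tail sizes (mono=1, di=2, tri=3), e.g. ``diTriKGap`` has
a=2, b=3.

Canonical ordering (required for reproducible selection): families in
the fixed order below; within a k-gap family gap ascending, then head
lexicographic, then tail lexicographic; within pseudoKNC, t ascending
then lexicographic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import Alphabet, SequenceRecord


@dataclass(frozen=True)
class DescriptorConfig:
    """Descriptor hyperparameters: maximum gap K and k-mer length."""

    k_gap: int = 5
    k_tuple: int = 3

    def __post_init__(self) -> None:
        if self.k_gap < 1 or self.k_tuple < 1:
            raise ValueError("k_gap and k_tuple must be >= 1")


#: (head length a, tail length b) for each k-gap family name.
KGAP_FAMILIES = {
    "diDiKGap": (2, 2),
    "diMonoKGap": (2, 1),
    "diTriKGap": (2, 3),
    "monoDiKGap": (1, 2),
    "monoMonoKGap": (1, 1),
    "monoTriKGap": (1, 3),
    "triMonoKGap": (3, 1),
    "triDiKGap": (3, 2),
}

#: lncRNA descriptor families in canonical (alphabetical) order.
LNCRNA_FAMILY_ORDER = (
    "atgcRatio",
    "cumulativeSkew",
    "diDiKGap",
    "diMonoKGap",
    "diTriKGap",
    "gcContent",
    "monoDiKGap",
    "monoMonoKGap",
    "monoTriKGap",
    "pseudoKNC",
    "triMonoKGap",
    "triDiKGap",
    "zCurve",
)

#: Protein descriptor families: k-tuple composition then one k-gap family.
PROTEIN_FAMILY_ORDER = ("pseudoKNC", "monoMonoKGap")


@dataclass
class FeatureMatrix:
    """Named feature columns over samples.

    ``feature_names`` are unique and fix the column order; sample ids
    keep row order but need not be unique (a pair listed twice encodes
    twice).
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.feature_names)})"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains NaN/inf")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self) -> dict[str, int]:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        if len(index) != len(self.sample_ids):
            raise ValueError("sample ids are not unique; cannot index rows")
        return index

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        """Restrict to the given columns, in the given order."""
        col = {f: j for j, f in enumerate(self.feature_names)}
        try:
            idx = [col[n] for n in names]
        except KeyError as exc:
            raise KeyError(f"unknown feature name {exc.args[0]!r}") from None
        return FeatureMatrix(
            list(self.sample_ids), list(names), self.values[:, idx].copy()
        )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Persist as TSV: header = feature names, first column = sample id."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(fm.feature_names) + "\n")
        for sid, row in zip(fm.sample_ids, fm.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty feature matrix file")
    names = lines[0].rstrip("\n").split("\t")[1:]
    sample_ids, rows = [], []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sample_ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    values = np.asarray(rows, dtype=np.float64).reshape(len(sample_ids), len(names))
    return FeatureMatrix(sample_ids, names, values)


# ---------------------------------------------------------------------------
# Low-level encoding


def _code_table(alphabet: Alphabet) -> np.ndarray:
    table = np.full(256, -1, dtype=np.int64)
    for i, c in enumerate(alphabet.letters):
        table[ord(c)] = i
    return table


_TABLES = {a: _code_table(a) for a in Alphabet}


def _codes(seq: str, alphabet: Alphabet) -> np.ndarray:
    codes = _TABLES[alphabet][np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(codes < 0)[0]})
        raise ValueError(f"characters {bad} outside the {alphabet.value} alphabet")
    return codes


def _rolling_codes(codes: np.ndarray, k: int, size: int) -> np.ndarray:
    """Integer code of every length-k window (base-`size` positional)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = out * size + codes[j : j + n]
    return out


@lru_cache(maxsize=None)
def _kmers(alphabet: Alphabet, k: int) -> tuple[str, ...]:
    return tuple("".join(p) for p in itertools.product(alphabet.letters, repeat=k))


def pseudoknc_names(alphabet: Alphabet, k_tuple: int) -> list[str]:
    """Canonical pseudoKNC feature names: t ascending, lexicographic."""
    return [
        f"pseudoKNC|{m}" for t in range(1, k_tuple + 1) for m in _kmers(alphabet, t)
    ]


def kgap_names(family: str, alphabet: Alphabet, max_gap: int) -> list[str]:
    """Canonical k-gap names: gap ascending, head then tail lexicographic."""
    a, b = KGAP_FAMILIES[family]
    return [
        f"{family}|{head}_g{g}_{tail}"
        for g in range(1, max_gap + 1)
        for head in _kmers(alphabet, a)
        for tail in _kmers(alphabet, b)
    ]


def encode_pseudoknc(seq: str, alphabet: Alphabet, k_tuple: int) -> np.ndarray:
    """Occurrence counts of every t-mer, t = 1..k_tuple, overlaps counted."""
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    codes = _codes(seq, alphabet)
    size = len(alphabet.letters)
    blocks = [
        np.bincount(_rolling_codes(codes, t, size), minlength=size**t)
        for t in range(1, k_tuple + 1)
    ]
    return np.concatenate(blocks).astype(np.float64)


def encode_kgap(
    seq: str, alphabet: Alphabet, head_len: int, tail_len: int, max_gap: int
) -> np.ndarray:
    """Counts of (head a-mer, gap g, tail b-mer) occurrences, g = 1..max_gap.

    Entry (H, T, g) counts positions i with seq[i:i+a] == H and
    seq[i+a+g : i+a+g+b] == T; windows running off the end contribute
    nothing, so sequences shorter than a+1+b give the zero vector.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    if head_len < 1 or tail_len < 1 or max_gap < 1:
        raise ValueError("head_len, tail_len and max_gap must be >= 1")
    codes = _codes(seq, alphabet)
    size = len(alphabet.letters)
    dim = size ** (head_len + tail_len)
    heads = _rolling_codes(codes, head_len, size)
    tails = _rolling_codes(codes, tail_len, size)
    blocks = []
    for g in range(1, max_gap + 1):
        n = len(seq) - (head_len + g + tail_len) + 1
        if n <= 0:
            blocks.append(np.zeros(dim, dtype=np.int64))
            continue
        idx = heads[:n] * size**tail_len + tails[head_len + g : head_len + g + n]
        blocks.append(np.bincount(idx, minlength=dim))
    return np.concatenate(blocks).astype(np.float64)


def encode_scalar_descriptors(seq: str) -> np.ndarray:
    """Whole-sequence composition statistics of a nucleotide sequence.

    Returns (zCurve x3, gcContent, atgcRatio, cumulativeSkew x2) where
    zCurve = ((A+G)-(C+T), (A+C)-(G+T), (A+T)-(G+C)) on letter totals,
    gcContent = (G+C)/len, atgcRatio = (A+T)/(G+C), and the skews are
    (G-C)/(G+C) and (A-T)/(A+T). Any 0/0 ratio is defined as 0.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    counts = np.bincount(_codes(seq, Alphabet.NUCLEOTIDE), minlength=4)
    na, nc, ng, nt = (float(x) for x in counts)

    def _ratio(num: float, den: float) -> float:
        return num / den if den else 0.0

    return np.array(
        [
            (na + ng) - (nc + nt),
            (na + nc) - (ng + nt),
            (na + nt) - (ng + nc),
            (ng + nc) / len(seq),
            _ratio(na + nt, ng + nc),
            _ratio(ng - nc, ng + nc),
            _ratio(na - nt, na + nt),
        ]
    )


# ---------------------------------------------------------------------------
# Full per-entity encoders


def _family_names(
    family: str, alphabet: Alphabet, config: DescriptorConfig
) -> list[str]:
    if family == "atgcRatio":
        return ["atgcRatio"]
    if family == "gcContent":
        return ["gcContent"]
    if family == "cumulativeSkew":
        return ["cumulativeSkew|GC", "cumulativeSkew|AT"]
    if family == "zCurve":
        return ["zCurve|RY", "zCurve|MK", "zCurve|WS"]
    if family == "pseudoKNC":
        return pseudoknc_names(alphabet, config.k_tuple)
    return kgap_names(family, alphabet, config.k_gap)


@lru_cache(maxsize=None)
def lncrna_feature_names(config: DescriptorConfig = DescriptorConfig()) -> tuple[str, ...]:
    """Canonical names of the full 13-family lncRNA vector (dim 14,891)."""
    names: list[str] = []
    for family in LNCRNA_FAMILY_ORDER:
        names.extend(_family_names(family, Alphabet.NUCLEOTIDE, config))
    return tuple(names)


@lru_cache(maxsize=None)
def protein_feature_names(config: DescriptorConfig = DescriptorConfig()) -> tuple[str, ...]:
    """Canonical names of the protein vector (dim 10,420)."""
    names: list[str] = []
    for family in PROTEIN_FAMILY_ORDER:
        names.extend(_family_names(family, Alphabet.PROTEIN, config))
    return tuple(names)


def encode_lncrna(seq: str, config: DescriptorConfig = DescriptorConfig()) -> np.ndarray:
    """Encode one nucleotide sequence with all 13 descriptor families."""
    scalars = encode_scalar_descriptors(seq)
    zcurve, gc, atgc, skew = scalars[:3], scalars[3], scalars[4], scalars[5:]
    blocks = {
        "atgcRatio": np.array([atgc]),
        "cumulativeSkew": skew,
        "gcContent": np.array([gc]),
        "zCurve": zcurve,
        "pseudoKNC": encode_pseudoknc(seq, Alphabet.NUCLEOTIDE, config.k_tuple),
    }
    for family in LNCRNA_FAMILY_ORDER:
        if family in blocks:
            continue
        a, b = KGAP_FAMILIES[family]
        blocks[family] = encode_kgap(seq, Alphabet.NUCLEOTIDE, a, b, config.k_gap)
    return np.concatenate([blocks[f] for f in LNCRNA_FAMILY_ORDER])


def encode_protein(seq: str, config: DescriptorConfig = DescriptorConfig()) -> np.ndarray:
    """Encode one amino-acid sequence (pseudoKNC + monoMonoKGap)."""
    knc = encode_pseudoknc(seq, Alphabet.PROTEIN, config.k_tuple)
    kgap = encode_kgap(seq, Alphabet.PROTEIN, 1, 1, config.k_gap)
    return np.concatenate([knc, kgap])


def encode_lncrna_set(
    records: Iterable[SequenceRecord], config: DescriptorConfig = DescriptorConfig()
) -> FeatureMatrix:
    records = list(records)
    names = list(lncrna_feature_names(config))
    values = np.empty((len(records), len(names)))
    for i, rec in enumerate(records):
        values[i] = encode_lncrna(rec.sequence, config)
    return FeatureMatrix([r.id for r in records], names, values)


def encode_protein_set(
    records: Iterable[SequenceRecord], config: DescriptorConfig = DescriptorConfig()
) -> FeatureMatrix:
    records = list(records)
    names = list(protein_feature_names(config))
    values = np.empty((len(records), len(names)))
    for i, rec in enumerate(records):
        values[i] = encode_protein(rec.sequence, config)
    return FeatureMatrix([r.id for r in records], names, values)


def build_pair_matrix(
    lnc_features: FeatureMatrix,
    prot_features: FeatureMatrix,
    pairs: Sequence[tuple[str, str]],
) -> FeatureMatrix:
    """Concatenate per-entity vectors into one row per (lncRNA, protein).

    Columns are the lncRNA block then the protein block, prefixed
    ``lnc:`` / ``prot:`` to keep names unique; sample id is
    ``"<lnc_id>|<prot_id>"``.
    """
    lnc_idx = lnc_features.row_index()
    prot_idx = prot_features.row_index()
    rows_l, rows_p, ids = [], [], []
    for lnc, prot in pairs:
        if lnc not in lnc_idx:
            raise KeyError(f"unknown lncRNA id {lnc!r}")
        if prot not in prot_idx:
            raise KeyError(f"unknown protein id {prot!r}")
        rows_l.append(lnc_idx[lnc])
        rows_p.append(prot_idx[prot])
        ids.append(f"{lnc}|{prot}")
    names = [f"lnc:{n}" for n in lnc_features.feature_names] + [
        f"prot:{n}" for n in prot_features.feature_names
    ]
    if not pairs:
        return FeatureMatrix([], names, np.empty((0, len(names))))
    values = np.hstack(
        [lnc_features.values[rows_l], prot_features.values[rows_p]]
    )
    return FeatureMatrix(ids, names, values)


# ---------------------------------------------------------------------------
# Min-max scaling (fit on training data, applied to held-out data)


@dataclass
class NormalizationParams:
    """Per-column min/max learned on a fitting set."""

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray


def min_max_normalize(fm: FeatureMatrix) -> tuple[FeatureMatrix, NormalizationParams]:
    """Map each column to (x - min) / (max - min) over the fitting set.

    Constant columns map to 0. The returned parameters reapply the same
    affine map to unseen data without clipping, so out-of-range values
    are allowed there.
    """
    if not len(fm.sample_ids):
        raise ValueError("cannot fit normalization on an empty matrix")
    mins = fm.values.min(axis=0)
    maxs = fm.values.max(axis=0)
    params = NormalizationParams(list(fm.feature_names), mins, maxs)
    return apply_normalization(params, fm), params


def apply_normalization(params: NormalizationParams, fm: FeatureMatrix) -> FeatureMatrix:
    """Apply previously learned min/max parameters to a feature matrix."""
    if list(fm.feature_names) != list(params.feature_names):
        raise ValueError("feature names do not match normalization parameters")
    span = params.maxs - params.mins
    safe = np.where(span == 0, 1.0, span)
    values = (fm.values - params.mins) / safe
    values[:, span == 0] = 0.0
    return FeatureMatrix(list(fm.sample_ids), list(fm.feature_names), values)
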