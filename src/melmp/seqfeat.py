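"""Sequence-derived feature encoders for moonlighting-protein prediction.

Four fixed-length views are computed per protein, each from a different
information source:

``Seq``
    Autocorrelation-compressed k-mer composition of the primary sequence.
    Counts of all 3-, 2- and 1-mers over the 20-letter amino-acid alphabet
    are concatenated into an 8420-dimensional ``rawkmers`` vector, which the
    autocorrelation coefficient function (Acf) compresses to ``m`` lags
    (default 400).
``PSSM``
    Evolutionary profile composition. A PSI-BLAST position-specific scoring
    matrix (L x 20 log-odds) is aggregated into a 20 x 20 matrix whose cell
    (i, k) is the length-normalised sum of profile column i over the
    positions occupied by residue k; flattened row-major to 400 values.
``AA``
    Physicochemical summary. Each retained AAindex property maps the
    sequence to a numeric series; its mean and population variance are
    concatenated, giving 2 values per property.
``SS``
    Eight-state secondary-structure composition: 3-, 2- and 1-mer counts
    over the SSpro8/DSSP alphabet {H,B,E,G,I,T,S,C}, 584 values.

Nonstandard residue policy: windows containing a code outside the 20-letter
alphabet are skipped by the k-mer counters; in the profile aggregation such
positions contribute to no cell but the division is still by the full
sequence length; in the physicochemical view they are dropped from the
series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import (
    DegenerateInputError,
    FormatError,
    InvalidSymbolError,
    MelmpError,
)

logger = logging.getLogger(__name__)

#: The 20 standard residues, alphabetical; also the column order of ProfileMatrix.
AA_ALPHABET: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Tolerated nonstandard residue codes (skipped, never counted).
NONSTANDARD_AA: frozenset[str] = frozenset("XBZUO")

#: Eight-state secondary-structure alphabet (SSpro8/DSSP), alphabetical.
SS_ALPHABET: tuple[str, ...] = tuple(sorted("HBEGITSC"))

RAWKMERS_LENGTH = 20**3 + 20**2 + 20  # 8420
SS_LENGTH = 8**3 + 8**2 + 8  # 584

VIEWS = ("Seq", "PSSM", "AA", "SS")


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise MelmpError("protein id must be nonempty")
        if len(self.residues) < 1:
            raise MelmpError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class AcfParams:
    """Lag count for the autocorrelation compression (default m=400)."""

    m: int = 400

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be a positive integer")


@dataclass
class ProfileMatrix:
    """An L x 20 position-specific scoring matrix with its sequence.

    Columns follow :data:`AA_ALPHABET` order regardless of the order in the
    source file.
    """

    scores: np.ndarray
    sequence: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise MelmpError(
                f"profile must be L x 20, got shape {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.sequence):
            raise MelmpError(
                f"profile has {self.scores.shape[0]} rows but sequence "
                f"length is {len(self.sequence)}"
            )


@dataclass
class PropertyTable:
    """Physicochemical property scales over the 20 standard residues.

    ``properties`` maps property id -> value per residue (AA_ALPHABET
    order); ``missing_ids`` lists input properties dropped because at least
    one residue value was missing.
    """

    properties: dict[str, np.ndarray] = field(default_factory=dict)
    missing_ids: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.properties)


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length numeric representation of one protein under one view."""

    view: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise MelmpError(f"unknown view {self.view!r}")


# ---------------------------------------------------------------------------
# k-mer counting


def count_kmers(seq: str, k: int, alphabet: tuple[str, ...] | str) -> np.ndarray:
    """Count all ``|alphabet|**k`` k-mers of ``seq``, lexicographic index.

    Windows containing a symbol outside ``alphabet`` are skipped. If the
    sequence is shorter than ``k`` the vector is all zero.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    alphabet = tuple(alphabet)
    if not alphabet:
        raise ValueError("alphabet must be nonempty")
    if len(seq) < 1:
        raise ValueError("sequence must be nonempty")

    a = len(alphabet)
    sym_index = {s: i for i, s in enumerate(alphabet)}
    idx = np.fromiter((sym_index.get(c, -1) for c in seq), dtype=np.int64)
    counts = np.zeros(a**k, dtype=np.int64)
    if len(seq) < k:
        return counts
    # rolling code over valid windows
    windows = np.lib.stride_tricks.sliding_window_view(idx, k)
    valid = (windows >= 0).all(axis=1)
    if valid.any():
        powers = a ** np.arange(k - 1, -1, -1, dtype=np.int64)
        codes = windows[valid] @ powers
        np.add.at(counts, codes, 1)
    return counts


def build_rawkmers(record: ProteinRecord | str) -> np.ndarray:
    """Concatenated (3-mer, 2-mer, 1-mer) counts; length 8420."""
    seq = record.residues if isinstance(record, ProteinRecord) else record
    parts = [count_kmers(seq, k, AA_ALPHABET) for k in (3, 2, 1)]
    out = np.concatenate(parts)
    assert out.shape[0] == RAWKMERS_LENGTH
    return out


# ---------------------------------------------------------------------------
# autocorrelation compression


def acf_transform(x: np.ndarray, params: AcfParams = AcfParams()) -> FeatureVector:
    """Centered autocorrelation coefficients r_1..r_m of a series.

    r_j = sum_{i=1..n-j} (x_i - xbar)(x_{i+j} - xbar) / sum_i (x_i - xbar)^2.

    A constant series has zero variance; the coefficients are then undefined
    and an all-zero vector is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    m = params.m
    if m >= n:
        raise ValueError(f"lag count m={m} must be smaller than series length n={n}")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        warnings.warn(
            "constant series: autocorrelation undefined, returning zeros",
            stacklevel=2,
        )
        return FeatureVector("Seq", np.zeros(m))
    r = np.empty(m)
    for j in range(1, m + 1):
        r[j - 1] = float(xc[: n - j] @ xc[j:]) / denom
    return FeatureVector("Seq", r)


def seq_features(record: ProteinRecord, params: AcfParams = AcfParams()) -> FeatureVector:
    """Primary-sequence view: Acf-compressed rawkmers (length ``params.m``)."""
    return acf_transform(build_rawkmers(record), params)


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII profile reading + aggregation


def read_ascii_pssm(path: str | Path) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII profile (``-out_ascii_pssm`` layout).

    Only the first 20 numeric columns (the log-odds block) are used. The
    residue-letter header line defines the source column order, which is
    remapped to alphabetical :data:`AA_ALPHABET` order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_cols: list[str] | None = None
    header_line_no = None
    rows: list[np.ndarray] = []
    residues: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if header_cols is None:
            if len(fields) >= 20 and all(
                len(f) == 1 and f in AA_ALPHABET for f in fields[:20]
            ):
                header_cols = fields[:20]
                header_line_no = lineno
            continue
        if not fields:
            continue
        if not fields[0].isdigit():
            break  # trailing statistics block
        if len(fields) < 22:
            raise FormatError(
                f"{path.name}:{lineno}: expected position, residue and 20 "
                f"log-odds columns, got {len(fields)} fields"
            )
        residue = fields[1]
        try:
            row = np.array([float(v) for v in fields[2:22]], dtype=float)
        except ValueError as exc:
            raise FormatError(f"{path.name}:{lineno}: non-numeric cell ({exc})") from None
        residues.append(residue)
        rows.append(row)

    if header_cols is None:
        raise FormatError(f"{path.name}: no residue-letter header line found")
    if not rows:
        raise FormatError(
            f"{path.name}: no profile rows after header at line {header_line_no}"
        )

    raw = np.vstack(rows)
    order = [header_cols.index(a) for a in AA_ALPHABET]
    return ProfileMatrix(scores=raw[:, order], sequence="".join(residues))


def pssm_aggregate(profile: ProfileMatrix, normalize: bool = True) -> FeatureVector:
    """Aggregate an L x 20 profile into the 400-dimensional PSSM view.

    Cell (i, k) of the 20 x 20 matrix sums profile column i over positions
    whose residue is tag k, divided by the full sequence length L. Positions
    with nonstandard residue codes contribute to no cell, but L keeps the
    full length. Flattening is row-major over i (profile column) then k
    (residue tag).
    """
    L = len(profile.sequence)
    tag_index = {a: t for t, a in enumerate(AA_ALPHABET)}
    M = np.zeros((20, 20))
    for j, res in enumerate(profile.sequence):
        t = tag_index.get(res)
        if t is None:
            continue
        M[:, t] += profile.scores[j, :]
    if normalize:
        M = M / L
    return FeatureVector("PSSM", M.reshape(-1))


# ---------------------------------------------------------------------------
# AAindex physicochemical properties

# AAindex1 "I" line layout: first value row is A R N D C Q E G H I,
# second row is L K M F P S T W Y V.
_AAINDEX_ROW1 = tuple("ARNDCQEGHI")
_AAINDEX_ROW2 = tuple("LKMFPSTWYV")


def read_property_table(path: str | Path) -> PropertyTable:
    """Parse an AAindex1 flat file, dropping properties with missing values.

    Each record starts with an ``H <accession>`` line; the ``I`` line is
    followed by two rows of 10 residue values ("NA" marks a missing value).
    Properties containing any missing value are recorded in
    ``missing_ids`` and excluded from the retained set.
    """
    path = Path(path)
    table = PropertyTable()
    current_id: str | None = None
    values: dict[str, float | None] = {}
    expecting: list[tuple[str, ...]] = []

    def _finish() -> None:
        nonlocal current_id, values
        if current_id is None:
            return
        if len(values) != 20:
            raise FormatError(
                f"property {current_id}: expected 20 residue values, got {len(values)}"
            )
        if any(v is None for v in values.values()):
            table.missing_ids.append(current_id)
        else:
            table.properties[current_id] = np.array(
                [values[a] for a in AA_ALPHABET], dtype=float
            )
        current_id, values = None, {}

    for line in path.read_text().splitlines():
        if line.startswith("H "):
            _finish()
            current_id = line[2:].strip()
            expecting = []
        elif line.startswith("I ") and current_id is not None:
            expecting = [_AAINDEX_ROW1, _AAINDEX_ROW2]
        elif expecting and line.startswith(" "):
            row = expecting.pop(0)
            fields = line.split()
            if len(fields) != len(row):
                raise FormatError(
                    f"property {current_id}: value row has {len(fields)} "
                    f"entries, expected {len(row)}"
                )
            for aa, f in zip(row, fields):
                values[aa] = None if f.upper() == "NA" else float(f)
        elif line.startswith("//"):
            _finish()
    _finish()
    return table


def aa_features(record: ProteinRecord, table: PropertyTable) -> FeatureVector:
    """Physicochemical view: (mean_1, var_1, ..., mean_P, var_P), length 2P.

    Each retained property digitizes the sequence (nonstandard residues
    dropped); the mean and population variance of the resulting series are
    reported.
    """
    if table.n_retained == 0:
        raise DegenerateInputError("property table retains no properties")
    idx = [AA_ALPHABET.index(c) for c in record.residues if c in AA_ALPHABET]
    if not idx:
        raise DegenerateInputError(
            f"protein {record.id!r}: no standard residues to digitize"
        )
    idx = np.asarray(idx)
    out = np.empty(2 * table.n_retained)
    for p, vals in enumerate(table.properties.values()):
        series = vals[idx]
        out[2 * p] = series.mean()
        out[2 * p + 1] = series.var()  # population variance
    return FeatureVector("AA", out)


# ---------------------------------------------------------------------------
# secondary-structure view


def ss_features(ss: str) -> FeatureVector:
    """Eight-state secondary-structure view: (3-mer, 2-mer, 1-mer), length 584."""
    if len(ss) < 1:
        raise InvalidSymbolError("empty secondary-structure string")
    bad = set(ss) - set(SS_ALPHABET)
    if bad:
        raise InvalidSymbolError(
            f"symbols {sorted(bad)} outside the 8-state alphabet {''.join(SS_ALPHABET)}"
        )
    parts = [count_kmers(ss, k, SS_ALPHABET) for k in (3, 2, 1)]
    out = np.concatenate(parts)
    assert out.shape[0] == SS_LENGTH
    return FeatureVector("SS", out.astype(float))


# ---------------------------------------------------------------------------
# record I/O


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped, multi-record) FASTA file."""
    records = [
        ProteinRecord(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{Path(path).name}: duplicate record ids")
    return records


def read_ss_file(path: str | Path) -> dict[str, str]:
    """Read FASTA-style secondary-structure strings (one entry per protein)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
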