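"""Hand-crafted per-residue feature priors.

Two fixed encodings complement the learned language-model embeddings:

* the five Atchley factors — standardized biophysical summaries (polarity,
  secondary-structure propensity, molecular volume, codon diversity,
  electrostatic charge) distilled from ~500 amino-acid attributes;
* the 20 substitution scores of a residue against the standard alphabet,
  taken from a log-odds substitution matrix (BLOSUM50 by default), which
  carry evolution-inspired priors about tolerated replacements.

Both tables ship as plain-text TSV resources.  ``logodds_from_counts``
exposes the log-odds construction score(A,B) = log2(f(A→B) / (f(A)·f(B)))
as a standalone constructor for toy matrices; the packaged BLOSUM50 is the
standard published matrix, not regenerated from counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .records import STANDARD_AA

#: letters treated as nonstandard: encoded as all-zero rows (neutral prior)
NONSTANDARD = set("XBZUOJ")


@dataclass(frozen=True)
class AtchleyTable:
    """The published 20x5 table of standardized amino-acid factors."""

    rows: dict  # letter -> np.ndarray shape (5,)
    factor_names: tuple = ()

    def __post_init__(self):
        if set(self.rows) != set(STANDARD_AA):
            raise ValueError("Atchley table must key exactly the 20 standard letters")
        for aa, v in self.rows.items():
            if np.asarray(v).shape != (5,) or not np.isfinite(v).all():
                raise ValueError(f"bad factor vector for {aa}")

    def __getitem__(self, aa: str) -> np.ndarray:
        return self.rows[aa]


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric log-odds substitution matrix over the 20 standard letters."""

    alphabet: str
    scores: np.ndarray  # (20, 20)
    name: str = "BLOSUM50"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.alphabet),) * 2:
            raise ValueError("score matrix shape does not match alphabet")
        if not np.isfinite(scores).all():
            raise ValueError("non-finite substitution scores")
        if not np.allclose(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.alphabet)})

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self._index[a], self._index[b]])

    def row(self, a: str) -> np.ndarray:
        return self.scores[self._index[a]]


def _read_resource(name: str) -> list[list[str]]:
    text = resources.files("nabind.data").joinpath(name).read_text()
    return [line.split("\t") for line in text.strip().split("\n")]


def load_atchley_table() -> AtchleyTable:
    """Load the packaged five-factor table."""
    rows = _read_resource("atchley_factors.tsv")
    header, body = rows[0], rows[1:]
    if len(body) != 20:
        raise OSError("corrupt Atchley resource: expected 20 rows")
    table = {r[0]: np.array([float(x) for x in r[1:]]) for r in body}
    return AtchleyTable(rows=table, factor_names=tuple(header[1:]))


_PACKAGED_MATRICES = {"BLOSUM50": "blosum50.tsv"}


def load_substitution_matrix(name: str = "BLOSUM50") -> SubstitutionMatrix:
    """Load a packaged substitution matrix by name (``BLOSUM50`` default)."""
    try:
        fname = _PACKAGED_MATRICES[name]
    except KeyError:
        raise KeyError(
            f"unknown substitution matrix {name!r}; packaged: {sorted(_PACKAGED_MATRICES)}"
        ) from None
    rows = _read_resource(fname)
    alphabet = "".join(rows[0][1:])
    scores = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    return SubstitutionMatrix(alphabet=alphabet, scores=scores, name=name)


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    return sequence.upper()


def encode_atchley(sequence: str, table: AtchleyTable | None = None) -> np.ndarray:
    """Per-residue 5-factor encoding; nonstandard letters map to zero rows."""
    sequence = _validate_sequence(sequence)
    if table is None:
        table = load_atchley_table()
    out = np.zeros((len(sequence), 5))
    for i, aa in enumerate(sequence):
        if aa in table.rows:
            out[i] = table.rows[aa]
    return out


def encode_substitution(sequence: str, matrix: SubstitutionMatrix | None = None) -> np.ndarray:
    """Per-residue 20-score encoding against the matrix alphabet order."""
    sequence = _validate_sequence(sequence)
    if matrix is None:
        matrix = load_substitution_matrix()
    out = np.zeros((len(sequence), len(matrix.alphabet)))
    for i, aa in enumerate(sequence):
        if aa in matrix._index:
            out[i] = matrix.row(aa)
    return out


def logodds_from_counts(
    pair_freq: np.ndarray,
    background: np.ndarray,
    alphabet: str | None = None,
    base: float = 2.0,
    floor: float = -30.0,
    name: str = "custom",
) -> SubstitutionMatrix:
    """Build a log-odds matrix score(A,B) = log_base(f(A→B) / (f(A)·f(B))).

    ``pair_freq`` is the symmetric joint substitution-probability table and
    ``background`` the letter frequencies.  Zero joint probabilities map to
    ``floor`` (default -30 in log2 units) instead of -inf.
    """
    pair_freq = np.asarray(pair_freq, dtype=float)
    background = np.asarray(background, dtype=float)
    n = background.shape[0]
    if pair_freq.shape != (n, n):
        raise ValueError("pair_freq shape must match background length")
    if not np.isclose(pair_freq.sum(), 1.0, atol=1e-8):
        raise ValueError("pair_freq must sum to 1")
    if not np.isclose(background.sum(), 1.0, atol=1e-8) or (background <= 0).any():
        raise ValueError("background must be strictly positive and sum to 1")
    if (pair_freq < 0).any():
        raise ValueError("pair_freq entries must be non-negative")
    expected = np.outer(background, background)
    with np.errstate(divide="ignore"):
        scores = np.log2(pair_freq / expected) / np.log2(base)
    scores = np.where(pair_freq > 0, scores, floor / np.log2(base))
    if alphabet is None:
        alphabet = STANDARD_AA[:n]
    # symmetrize exactly against floating asymmetry of symmetric inputs
    scores = (scores + scores.T) / 2.0
    return SubstitutionMatrix(alphabet=alphabet, scores=scores, name=name)
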