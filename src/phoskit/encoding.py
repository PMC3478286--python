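"""CKSAAP and binary one-hot encodings of site-centered sequence windows.

The composition of k-spaced amino acid pairs (CKSAAP) represents a window
of 2n+1 residues by, for each spacing k = 0..k_max, the count of every
ordered residue pair (a, b) occurring at positions (i, i+k+1).  The
alphabet has 21 letters: the 20 standard amino acids plus the padding
pseudo-residue ``O`` marking positions outside the protein, so each
spacing contributes 21 x 21 = 441 components and the default k_max = 5
yields a 6 x 441 = 2646-dimensional integer vector.

The binary encoding one-hot encodes every flank position (the central
S/T/Y is omitted, being constant within a model) as a 21-bit block in the
same alphabet order, giving 21 x (L-1) bits for a window of length L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: 21-letter alphabet: the 20 amino acids alphabetically, padding letter O last.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYO"
ALPHABET_SIZE = len(ALPHABET)
PAIRS_PER_SPACING = ALPHABET_SIZE * ALPHABET_SIZE  # 441

_RANK = {letter: i for i, letter in enumerate(ALPHABET)}

#: Default maximum spacing between the residues of a pair.
DEFAULT_K_MAX = 5

#: Character used to render the k intervening wildcard positions in labels.
GAP_CHAR = "×"  # multiplication sign, as in "S×S"


@dataclass(frozen=True)
class CKSAAPVector:
    """Integer pair-count vector for one window.

    ``values`` has length 441 x (k_max + 1), ordered by spacing k
    ascending, then first residue, then second residue in ALPHABET order.
    """

    values: np.ndarray
    k_max: int

    def count(self, a: str, b: str, k: int) -> float:
        """Count of the ordered pair (a, b) at spacing k."""
        return self.values[pair_index(a, b, k)]


@dataclass(frozen=True)
class BinaryVector:
    """One-hot flank encoding: 21 bits per non-central window position."""

    values: np.ndarray

    @property
    def n_set(self) -> int:
        return int(self.values.sum())


def pair_index(a: str, b: str, k: int) -> int:
    """0-based component index of the ordered pair (a, b) at spacing k.

    The bijection is ``k*441 + rank(a)*21 + rank(b)`` with ranks taken in
    ALPHABET order, so (A, A, 0) -> 0 and (O, O, 0) -> 440.
    """
    if a not in _RANK:
        raise ValueError(f"letter {a!r} outside the 21-letter alphabet")
    if b not in _RANK:
        raise ValueError(f"letter {b!r} outside the 21-letter alphabet")
    if k < 0:
        raise ValueError(f"spacing k must be non-negative, got {k}")
    return k * PAIRS_PER_SPACING + _RANK[a] * ALPHABET_SIZE + _RANK[b]


def feature_label(index: int, k_max: int = DEFAULT_K_MAX) -> str:
    """Human-readable label of a CKSAAP component, e.g. ``SP`` or ``S×S``.

    The label is the first letter, k gap characters, then the second
    letter; spacing 0 juxtaposes the two letters.
    """
    n_features = PAIRS_PER_SPACING * (k_max + 1)
    if not 0 <= index < n_features:
        raise ValueError(f"feature index {index} out of range [0, {n_features})")
    k, rest = divmod(index, PAIRS_PER_SPACING)
    a, b = divmod(rest, ALPHABET_SIZE)
    return ALPHABET[a] + GAP_CHAR * k + ALPHABET[b]


def label_to_index(label: str) -> int:
    """Inverse of :func:`feature_label` (accepts ``×`` or ``x`` gaps)."""
    if len(label) < 2:
        raise ValueError(f"malformed feature label {label!r}")
    a, gaps, b = label[0], label[1:-1], label[-1]
    if any(c not in (GAP_CHAR, "x", "X", ".") for c in gaps):
        raise ValueError(f"malformed feature label {label!r}")
    return pair_index(a, b, len(gaps))


def n_features(k_max: int = DEFAULT_K_MAX) -> int:
    """Total CKSAAP dimension: 441 x (k_max + 1)."""
    return PAIRS_PER_SPACING * (k_max + 1)


def cksaap_encode(
    window: str, k_max: int = DEFAULT_K_MAX, normalize: bool = False
) -> CKSAAPVector:
    """Encode a window as its k-spaced pair composition.

    For each spacing k <= k_max, every ordered pair
    ``(window[i], window[i+k+1])`` increments its component, so the 441
    counts of spacing k sum to L - k - 1.  Counts are raw occurrences;
    with ``normalize=True`` each spacing block is divided by its L - k - 1
    pair positions (off by default — the canonical encoding is counts).
    """
    L = len(window)
    if L <= k_max + 1:
        raise ValueError(
            f"window of length {L} too short for spacing k={k_max} "
            f"(needs length > {k_max + 1})"
        )
    try:
        ranks = np.array([_RANK[c] for c in window], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(
            f"letter {exc.args[0]!r} outside the 21-letter alphabet"
        ) from None
    values = np.zeros(n_features(k_max), dtype=np.int64)
    for k in range(k_max + 1):
        idx = k * PAIRS_PER_SPACING + ranks[: L - k - 1] * ALPHABET_SIZE + ranks[k + 1 :]
        np.add.at(values, idx, 1)
    if normalize:
        out = values.astype(np.float64)
        for k in range(k_max + 1):
            block = slice(k * PAIRS_PER_SPACING, (k + 1) * PAIRS_PER_SPACING)
            out[block] /= L - k - 1
        return CKSAAPVector(values=out, k_max=k_max)
    return CKSAAPVector(values=values, k_max=k_max)


def cksaap_matrix(
    windows: list[str], k_max: int = DEFAULT_K_MAX, normalize: bool = False
) -> np.ndarray:
    """Encode many windows into a (n_windows, 441*(k_max+1)) matrix."""
    if not windows:
        return np.zeros((0, n_features(k_max)), dtype=np.int64)
    return np.vstack(
        [cksaap_encode(w, k_max, normalize=normalize).values for w in windows]
    )


def binary_encode(window: str) -> BinaryVector:
    """One-hot encode the flanks of an odd-length window.

    The central residue (always the candidate S/T/Y) carries no
    information within one model and is skipped; each remaining position
    becomes a 21-bit block with a single set bit at its letter's rank.
    """
    L = len(window)
    if L % 2 == 0:
        raise ValueError(f"window length must be odd, got {L}")
    center = L // 2
    if window[center] not in "STY":
        raise ValueError(
            f"central residue must be S, T or Y, got {window[center]!r}"
        )
    flanks = window[:center] + window[center + 1 :]
    values = np.zeros(ALPHABET_SIZE * (L - 1), dtype=np.uint8)
    for i, c in enumerate(flanks):
        if c not in _RANK:
            raise ValueError(f"letter {c!r} outside the 21-letter alphabet")
        values[i * ALPHABET_SIZE + _RANK[c]] = 1
    return BinaryVector(values=values)


def binary_matrix(windows: list[str]) -> np.ndarray:
    """Binary-encode many equal-length windows into a 2D array."""
    return np.vstack([binary_encode(w).values for w in windows])


def write_feature_matrix(
    matrix: np.ndarray, path, k_max: int = DEFAULT_K_MAX, sparse: bool = False
) -> None:
    """Write a fragment x feature matrix as labelled text.

    Dense mode: TSV, one header row of feature labels, one row per
    fragment.  Sparse mode: a coordinate format — a header line
    ``#coo<TAB>nrows<TAB>ncols`` followed by the label header and
    ``row<TAB>col<TAB>value`` triples for nonzeros.
    """
    labels = [feature_label(j, k_max) for j in range(matrix.shape[1])]
    with open(path, "w", encoding="utf-8") as fh:
        if sparse:
            fh.write(f"#coo\t{matrix.shape[0]}\t{matrix.shape[1]}\n")
            fh.write("\t".join(labels) + "\n")
            rows, cols = np.nonzero(matrix)
            for r, c in zip(rows, cols):
                fh.write(f"{r}\t{c}\t{matrix[r, c]}\n")
        else:
            fh.write("\t".join(labels) + "\n")
            for row in matrix:
                fh.write("\t".join(str(v) for v in row) + "\n")


def read_feature_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a matrix written by :func:`write_feature_matrix`.

    Returns (matrix, feature labels); detects the sparse coordinate
    format by its ``#coo`` header line.
    """
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("#coo\t"):
            _, nrows, ncols = first.split("\t")
            labels = fh.readline().rstrip("\n").split("\t")
            matrix = np.zeros((int(nrows), int(ncols)), dtype=np.int64)
            for line in fh:
                r, c, v = line.split("\t")
                matrix[int(r), int(c)] = int(v)
            return matrix, labels
        labels = first.split("\t")
        rows = [
            [int(v) for v in line.rstrip("\n").split("\t")] for line in fh
        ]
        matrix = (
            np.array(rows, dtype=np.int64)
            if rows
            else np.zeros((0, len(labels)), dtype=np.int64)
        )
        return matrix, labels
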