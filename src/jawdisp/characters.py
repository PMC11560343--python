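"""Discrete character matrices: parsing, polymorphism handling, Gower
dissimilarity, and principal coordinate analysis.

Cells of a :class:`CharacterMatrix` are one of

* a single nominal state — a small non-negative ``int``;
* :data:`MISSING` (``None``) — unknown or inapplicable ("?" / "-");
* a polymorphic multiset — a sorted ``tuple`` of >= 2 ints with at least
  two distinct states. Multisets (e.g. ``(0, 0, 1)``) carry the frequency
  information that the majority resolution rule needs; plain two-state
  polymorphisms are ties and resolve to :data:`MISSING`.

All characters are treated as unordered nominal with equal weight; Gower
dissimilarity between two taxa is the mismatch fraction over characters
scored in both (pairwise-complete renormalization).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    CharacterParseError,
    InputError,
    NoComparableCharactersError,
)
from .ordination import Ordination

__all__ = [
    "MISSING",
    "CharacterMatrix",
    "DistanceMatrix",
    "read_characters",
    "resolve_polymorphisms",
    "gower_distance",
    "pcoa",
]

MISSING = None

Cell = "int | None | tuple[int, ...]"


def _check_cell(value, taxon: str, char: str):
    if value is MISSING:
        return MISSING
    if isinstance(value, (int, np.integer)):
        if value < 0:
            raise InputError(f"negative state {value} at ({taxon}, {char})")
        return int(value)
    if isinstance(value, tuple):
        if len(value) < 2 or len(set(value)) < 2:
            raise InputError(
                f"polymorphic cell at ({taxon}, {char}) needs >= 2 distinct states: {value}"
            )
        if any((not isinstance(s, (int, np.integer))) or s < 0 for s in value):
            raise InputError(f"invalid polymorphic states at ({taxon}, {char}): {value}")
        return tuple(sorted(int(s) for s in value))
    raise InputError(f"invalid cell value at ({taxon}, {char}): {value!r}")


@dataclass
class CharacterMatrix:
    """Rectangular taxa-by-characters table of nominal states."""

    taxa: list[str]
    characters: list[str]
    cells: list[list]  # row-major, taxa x characters

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise InputError("duplicate taxon labels")
        if len(self.cells) != len(self.taxa):
            raise InputError("cell row count does not match taxa")
        for t, row in zip(self.taxa, self.cells):
            if len(row) != len(self.characters):
                raise InputError(f"ragged row for taxon {t!r}")
        self.cells = [
            [_check_cell(v, t, c) for v, c in zip(row, self.characters)]
            for t, row in zip(self.taxa, self.cells)
        ]

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.taxa), len(self.characters)

    def cell(self, taxon: str, character: str):
        return self.cells[self.taxa.index(taxon)][self.characters.index(character)]

    def has_polymorphisms(self) -> bool:
        return any(isinstance(v, tuple) for row in self.cells for v in row)

    def to_frame(self) -> pd.DataFrame:
        """Object-dtype DataFrame view (handy for display/round-tripping)."""
        return pd.DataFrame(
            [list(row) for row in self.cells], index=self.taxa, columns=self.characters
        )


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise InputError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise InputError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise InputError("distance matrix has negative entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# parsing


def _parse_state_token(token: str, line: int | None = None):
    token = token.strip()
    if token in ("?", "-", ""):
        return MISSING
    if (token.startswith("{") and token.endswith("}")) or (
        token.startswith("(") and token.endswith(")")
    ):
        inner = token[1:-1].replace(",", "").replace(" ", "")
        if not inner.isdigit() or len(inner) < 2:
            raise CharacterParseError(f"bad polymorphic cell {token!r}", line)
        states = tuple(sorted(int(ch) for ch in inner))
        if len(set(states)) < 2:
            raise CharacterParseError(
                f"polymorphic cell {token!r} needs >= 2 distinct states", line
            )
        return states
    if token.isdigit():
        return int(token)
    raise CharacterParseError(f"unknown state token {token!r}", line)


def _read_csv_characters(path: Path) -> CharacterMatrix:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CharacterParseError("empty character file", 1) from None
        characters = [h.strip() for h in header[1:]]
        taxa: list[str] = []
        cells: list[list] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(characters) + 1:
                raise CharacterParseError(
                    f"expected {len(characters) + 1} columns, got {len(row)}", lineno
                )
            taxa.append(row[0].strip())
            cells.append([_parse_state_token(tok, lineno) for tok in row[1:]])
    if not taxa:
        raise CharacterParseError("no data rows", 2)
    return CharacterMatrix(taxa=taxa, characters=characters, cells=cells)


def _read_nexus_characters(path: Path) -> CharacterMatrix:
    import dendropy

    try:
        matrix = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises heterogeneous error types
        raise CharacterParseError(f"NEXUS parse failure: {exc}") from exc

    taxa: list[str] = []
    cells: list[list] = []
    n_char = None
    for taxon in matrix.taxon_namespace:
        # NEXUS unquoted labels map underscores to spaces; undo for ids
        taxa.append(taxon.label.replace(" ", "_"))
        row = []
        for state in matrix[taxon]:
            symbol = state.symbol
            members = state.member_states or []
            if symbol in ("?", "-"):
                row.append(MISSING)
            elif members and len(members) > 1:
                try:
                    parsed = tuple(sorted(int(s.symbol) for s in members))
                except (TypeError, ValueError):
                    raise CharacterParseError(
                        f"non-numeric state set for taxon {taxon.label!r}"
                    ) from None
                row.append(MISSING if "?" in {s.symbol for s in members} else parsed)
            else:
                try:
                    row.append(int(symbol))
                except (TypeError, ValueError):
                    raise CharacterParseError(
                        f"non-numeric state {symbol!r} for taxon {taxon.label!r}"
                    ) from None
        if n_char is None:
            n_char = len(row)
        elif len(row) != n_char:
            raise CharacterParseError(f"ragged row for taxon {taxon.label!r}")
        cells.append(row)
    characters = [f"char_{i + 1}" for i in range(n_char or 0)]
    return CharacterMatrix(taxa=taxa, characters=characters, cells=cells)


def read_characters(path, format: str | None = None) -> CharacterMatrix:
    """Read a character matrix from NEXUS or CSV.

    ``format`` is inferred from the file suffix when omitted (".nex"/
    ".nexus" vs ".csv"/".tsv" are recognized).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"character file not found: {path}")
    if format is None:
        format = "nexus" if path.suffix.lower() in (".nex", ".nexus") else "csv"
    format = format.lower()
    if format == "nexus":
        return _read_nexus_characters(path)
    if format == "csv":
        return _read_csv_characters(path)
    raise InputError(f"unknown character format {format!r}")


# ---------------------------------------------------------------------------
# polymorphism resolution


def resolve_polymorphisms(m: CharacterMatrix, mode: str = "majority") -> CharacterMatrix:
    """Return a copy with polymorphic cells resolved.

    ``majority`` keeps the most frequent state of the multiset and turns
    ties into :data:`MISSING`; ``missing`` blanks every polymorphic cell;
    ``keep`` passes the matrix through unchanged.
    """
    if mode not in ("majority", "missing", "keep"):
        raise InputError(f"unknown polymorphism mode {mode!r}")
    if mode == "keep":
        return CharacterMatrix(
            taxa=list(m.taxa),
            characters=list(m.characters),
            cells=[list(row) for row in m.cells],
        )

    def resolve(v):
        if not isinstance(v, tuple):
            return v
        if mode == "missing":
            return MISSING
        counts = Counter(v).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            return MISSING  # tied majority
        return counts[0][0]

    return CharacterMatrix(
        taxa=list(m.taxa),
        characters=list(m.characters),
        cells=[[resolve(v) for v in row] for row in m.cells],
    )


# ---------------------------------------------------------------------------
# Gower dissimilarity


def gower_distance(m: CharacterMatrix) -> DistanceMatrix:
    """Nominal Gower dissimilarity with pairwise-complete renormalization.

    d(i, j) = (# characters where i and j are both scored and differ) /
    (# characters where both are scored). Resolve polymorphisms first;
    set-valued cells are rejected. A pair with no shared scored character
    raises :class:`NoComparableCharactersError`.

    Output is bounded in [0, 1] but — as usual for missing-data Gower —
    not guaranteed to satisfy the triangle inequality.
    """
    if m.has_polymorphisms():
        raise InputError(
            "matrix still contains polymorphic cells; run resolve_polymorphisms first"
        )
    n_taxa, n_char = m.shape
    states = np.full((n_taxa, n_char), -1, dtype=int)
    for i, row in enumerate(m.cells):
        for j, v in enumerate(row):
            if v is not MISSING:
                states[i, j] = v
    present = states >= 0

    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            both = present[i] & present[j]
            n_comp = int(both.sum())
            if n_comp == 0:
                raise NoComparableCharactersError(m.taxa[i], m.taxa[j])
            mism = int((states[i, both] != states[j, both]).sum())
            d[i, j] = d[j, i] = mism / n_comp
    return DistanceMatrix(labels=list(m.taxa), d=d)


# ---------------------------------------------------------------------------
# principal coordinate analysis


def pcoa(
    dm: DistanceMatrix, axis_tol: float = 1e-8, correction: str | None = None
) -> Ordination:
    """Principal coordinate analysis (classic metric MDS).

    The squared-distance matrix is double-centered (B = -1/2 J D^2 J),
    eigendecomposed, and axes with eigenvalue > ``axis_tol`` times the
    largest eigenvalue are retained, each scaled by the square root of
    its eigenvalue. Negative eigenvalues — expected for missing-data
    Gower input — are dropped and variance proportions are computed over
    the positive eigenvalues only (``correction`` accepts "lingoes" or
    "cailliez" to make the input Euclidean first; default applies none).
    Axis signs are fixed by making the first nonzero coordinate of each
    axis positive.
    """
    d = dm.d
    if correction is not None:
        d = _correct_distances(d, correction)
    n = d.shape[0]
    if n < 2:
        raise InputError("PCoA needs at least 2 taxa")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2  # enforce exact symmetry before eigh
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    # stable order for (near-)equal eigenvalues: argsort is stable on the
    # reversed index, which preserves original decomposition order
    eigval, eigvec = eigval[order], eigvec[:, order]

    keep = eigval > axis_tol * max(eigval.max(), 0.0)
    eigval_pos = eigval[eigval > 0]
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    if eigval.size == 0:
        raise InputError("no positive PCoA eigenvalues; degenerate distance matrix")

    flip = np.empty(eigvec.shape[1])
    for k in range(eigvec.shape[1]):
        nz = np.flatnonzero(np.abs(eigvec[:, k]) > 1e-12)
        flip[k] = np.sign(eigvec[nz[0], k]) if nz.size else 1.0
    eigvec = eigvec * flip[None, :]

    scores = eigvec * np.sqrt(eigval)[None, :]
    axes = [f"PCo{i + 1}" for i in range(scores.shape[1])]
    return Ordination(
        scores=pd.DataFrame(scores, index=dm.labels, columns=axes),
        eigenvalues=eigval / (n - 1),
        proportion=eigval / eigval_pos.sum(),
        loadings=None,
        method="pcoa",
    )


def _correct_distances(d: np.ndarray, method: str) -> np.ndarray:
    """Lingoes / Cailliez corrections to make a dissimilarity Euclidean."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval = np.linalg.eigvalsh((b + b.T) / 2)
    if method == "lingoes":
        c = max(0.0, -eigval.min())
        if c == 0:
            return d
        d2 = d**2 + 2 * c
        np.fill_diagonal(d2, 0.0)
        return np.sqrt(d2)
    if method == "cailliez":
        zero = np.zeros((n, n))
        eye = np.eye(n)
        b1 = -0.5 * j @ d @ j
        special = np.block([[zero, 2 * b], [-eye, -4 * b1]])
        c = float(np.max(np.linalg.eigvals(special).real))
        if c <= 0:
            return d
        d2 = d + c
        np.fill_diagonal(d2, 0.0)
        return d2
    raise InputError(f"unknown PCoA correction {method!r}")
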