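"""Alignment I/O and empirical substitution-model data.

Handles FASTA / PHYLIP protein alignments, the bundled PAML-style ``.dat``
exchangeability files, generator-matrix construction, and the Grantham
amino-acid distance table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import (
    AA_INDEX,
    AMINO_ACIDS,
    GAP_CHARS,
    N_AA,
    PAML_TO_ALPHA,
)

DATA_DIR = Path(__file__).parent / "data"

BUNDLED_MODELS = (
    "Blosum62", "CpRev", "Dayhoff", "DayhoffDCMUT", "HIVb", "HIVw",
    "JTT", "JonesDCMUT", "LG", "Mtart", "Mtmam", "Mtrev24", "RtRev",
    "VT", "WAG",
)

_LEGAL_CHARS = frozenset(AMINO_ACIDS) | GAP_CHARS


class AlignmentError(ValueError):
    """Rows of unequal length or too few sequences."""


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class Alignment:
    """Equal-length amino-acid sequences with unique ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        if not self.rows:
            raise AlignmentError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal row lengths: {sorted(lengths)}")
        if self.l < 1:
            raise AlignmentError("alignment length must be >= 1")
        for i, row in enumerate(self.rows):
            for j, ch in enumerate(row):
                if ch not in _LEGAL_CHARS:
                    raise FormatError(
                        f"illegal character {ch!r} in row {i} column {j}"
                    )

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def l(self) -> int:
        return len(self.rows[0])

    def require_query(self) -> "Alignment":
        if self.n < 2:
            raise AlignmentError("a query alignment needs at least 2 sequences")
        return self

    def select_columns(self, columns) -> "Alignment":
        cols = list(columns)
        return Alignment(
            ids=list(self.ids),
            rows=["".join(r[c] for c in cols) for r in self.rows],
        )


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", "-")


def _read_fasta(text: str) -> Alignment:
    ids: list[str] = []
    rows: list[str] = []
    current: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current is not None:
                rows.append("".join(current))
            ids.append(line[1:].split()[0] if len(line) > 1 else "")
            current = []
        else:
            if current is None:
                raise FormatError("FASTA sequence data before first header")
            current.append(_normalize(line))
    if current is None:
        raise FormatError("no FASTA records found")
    rows.append("".join(current))
    return Alignment(ids=ids, rows=rows)


def _read_phylip(text: str) -> Alignment:
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty PHYLIP file")
    header = lines[0].split()
    if len(header) < 2 or not header[0].isdigit() or not header[1].isdigit():
        raise FormatError("bad PHYLIP header (expected '<n> <l>')")
    n, l = int(header[0]), int(header[1])
    body = lines[1:]
    if len(body) < n:
        raise FormatError("PHYLIP file truncated")
    ids: list[str] = []
    chunks: list[list[str]] = []
    for ln in body[:n]:
        parts = ln.split(None, 1)
        if len(parts) == 1:
            name, seq = parts[0], ""
        else:
            name, seq = parts
        ids.append(name)
        chunks.append([_normalize(seq.replace(" ", ""))])
    # interleaved continuation blocks
    extra = body[n:]
    idx = 0
    for ln in extra:
        chunks[idx % n].append(_normalize(ln.replace(" ", "")))
        idx += 1
    rows = ["".join(c) for c in chunks]
    if any(len(r) != l for r in rows):
        raise AlignmentError(
            f"PHYLIP rows do not match declared length {l}: "
            f"{sorted({len(r) for r in rows})}"
        )
    return Alignment(ids=ids, rows=rows)


def read_alignment(path, format: str = "auto") -> Alignment:
    """Read a protein alignment from FASTA or PHYLIP.

    Characters are upper-cased and '.' is normalized to '-'.  Record order
    is preserved.
    """
    text = Path(path).read_text()
    if format == "auto":
        stripped = text.lstrip()
        format = "fasta" if stripped.startswith(">") else "phylip"
    if format == "fasta":
        return _read_fasta(text)
    if format == "phylip":
        return _read_phylip(text)
    raise ValueError(f"unknown alignment format {format!r}")


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    path = Path(path)
    if format == "fasta":
        out = []
        for name, row in zip(aln.ids, aln.rows):
            out.append(f">{name}")
            out.append(row)
        path.write_text("\n".join(out) + "\n")
    elif format == "phylip":
        out = [f"{aln.n} {aln.l}"]
        width = max(len(i) for i in aln.ids) + 2
        for name, row in zip(aln.ids, aln.rows):
            out.append(f"{name:<{width}}{row}")
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


# ---------------------------------------------------------------------------
# Empirical substitution models
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalModel:
    """Reversible amino-acid model: exchangeabilities + frequencies.

    ``S`` and ``pi`` are indexed alphabetically by one-letter code.
    """

    name: str
    S: np.ndarray
    pi: np.ndarray
    gamma_shape: float | None = None
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.S.shape != (N_AA, N_AA):
            raise FormatError("S must be 20x20")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise FormatError("exchangeability matrix is not symmetric")
        if (self.S < 0).any():
            raise FormatError("negative exchangeability")
        if np.abs(np.diag(self.S)).max() > 0:
            raise FormatError("nonzero diagonal in exchangeability matrix")
        if self.pi.shape != (N_AA,):
            raise FormatError("pi must have 20 entries")
        if (self.pi <= 0).any():
            raise FormatError("frequencies must be positive")
        total = self.pi.sum()
        if abs(total - 1.0) > 1e-4:
            raise FormatError(f"frequencies sum to {total}, not 1")
        self.pi = self.pi / total
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must lie in [0, 1)")


def _parse_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    numbers = [
        float(tok)
        for tok in re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", text)
    ]
    if len(numbers) < 210:
        raise FormatError(
            f"PAML .dat file needs 190 rates + 20 frequencies, found {len(numbers)}"
        )
    rates, freqs = numbers[:190], numbers[190:210]
    S_paml = np.zeros((N_AA, N_AA))
    k = 0
    for i in range(1, N_AA):
        for j in range(i):
            S_paml[i, j] = S_paml[j, i] = rates[k]
            k += 1
    perm = PAML_TO_ALPHA
    S = np.zeros_like(S_paml)
    pi = np.zeros(N_AA)
    S[np.ix_(perm, perm)] = S_paml
    pi[perm] = freqs
    return S, pi


def load_empirical_model(
    name_or_path: str,
    gamma_shape: float | None = None,
    p_inv: float = 0.0,
) -> EmpiricalModel:
    """Load a bundled model by name, or any PAML-style .dat file by path."""
    if name_or_path in BUNDLED_MODELS:
        path = DATA_DIR / f"{name_or_path}.dat"
        name = name_or_path
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise LookupError(
                f"unknown model {name_or_path!r}; bundled models are: "
                + ", ".join(BUNDLED_MODELS)
            )
        name = path.stem
    S, pi = _parse_dat(path.read_text())
    return EmpiricalModel(name=name, S=S, pi=pi,
                          gamma_shape=gamma_shape, p_inv=p_inv)


def write_empirical_model(model: EmpiricalModel, path) -> None:
    """Write a model as a PAML .dat file (lower triangle + frequencies)."""
    perm = PAML_TO_ALPHA
    S = model.S[np.ix_(perm, perm)]
    pi = model.pi[perm]
    lines = []
    for i in range(1, N_AA):
        lines.append(" ".join(f"{S[i, j]:.6f}" for j in range(i)))
    lines.append("")
    lines.append(" ".join(f"{x:.6f}" for x in pi))
    Path(path).write_text("\n".join(lines) + "\n")


def build_rate_matrix(model: EmpiricalModel) -> np.ndarray:
    """GTR-style generator: Q_ij = S_ij pi_j, scaled to one expected
    substitution per site per unit branch length."""
    Q = model.S * model.pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(np.dot(model.pi, np.diag(Q)))
    return Q / rate


# ---------------------------------------------------------------------------
# Grantham distances
# ---------------------------------------------------------------------------

# Published per-residue composition (c), polarity (p), and volume (v)
# underlying the classical distance matrix.
GRANTHAM_PROPERTIES = {
    "A": (0.00, 8.1, 31), "C": (2.75, 5.5, 55), "D": (1.38, 13.0, 54),
    "E": (0.92, 12.3, 83), "F": (0.00, 5.2, 132), "G": (0.74, 9.0, 3),
    "H": (0.58, 10.4, 96), "I": (0.00, 5.2, 111), "K": (0.33, 11.3, 119),
    "L": (0.00, 4.9, 111), "M": (0.00, 5.7, 105), "N": (1.33, 11.6, 56),
    "P": (0.39, 8.0, 32.5), "Q": (0.89, 10.5, 85), "R": (0.65, 10.5, 124),
    "S": (1.42, 9.2, 32), "T": (0.71, 8.6, 61), "V": (0.00, 5.9, 84),
    "W": (0.13, 5.4, 170), "Y": (0.20, 6.2, 136),
}
GRANTHAM_ALPHA = 1.833
GRANTHAM_BETA = 0.1018
GRANTHAM_GAMMA = 0.000399
GRANTHAM_MEAN = 100.0  # normalization: mean off-diagonal distance


@dataclass
class GranthamTable:
    """Symmetric nonnegative amino-acid distance matrix, zero diagonal."""

    D: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.D is None:
            self.D = _compute_grantham_matrix()
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (N_AA, N_AA):
            raise FormatError("Grantham table must be 20x20")
        if not np.allclose(self.D, self.D.T):
            raise FormatError("Grantham table must be symmetric")
        if np.abs(np.diag(self.D)).max() > 0:
            raise FormatError("Grantham diagonal must be zero")
        if (self.D < 0).any():
            raise FormatError("Grantham distances must be nonnegative")


def _compute_grantham_matrix() -> np.ndarray:
    c = np.array([GRANTHAM_PROPERTIES[a][0] for a in AMINO_ACIDS])
    p = np.array([GRANTHAM_PROPERTIES[a][1] for a in AMINO_ACIDS])
    v = np.array([GRANTHAM_PROPERTIES[a][2] for a in AMINO_ACIDS])
    raw = np.sqrt(
        GRANTHAM_ALPHA * (c[:, None] - c[None, :]) ** 2
        + GRANTHAM_BETA * (p[:, None] - p[None, :]) ** 2
        + GRANTHAM_GAMMA * (v[:, None] - v[None, :]) ** 2
    )
    iu = np.triu_indices(N_AA, 1)
    rho = GRANTHAM_MEAN / raw[iu].mean()
    return rho * raw


def grantham_distance(a: str, b: str, table: GranthamTable | None = None) -> float:
    if a not in AA_INDEX or b not in AA_INDEX:
        raise ValueError(f"non-canonical amino acid in pair ({a!r}, {b!r})")
    if table is None:
        table = default_grantham_table()
    return float(table.D[AA_INDEX[a], AA_INDEX[b]])


_DEFAULT_GRANTHAM: GranthamTable | None = None


def default_grantham_table() -> GranthamTable:
    global _DEFAULT_GRANTHAM
    if _DEFAULT_GRANTHAM is None:
        _DEFAULT_GRANTHAM = GranthamTable()
    return _DEFAULT_GRANTHAM
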