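"""Folding-stability prediction on a representative structure.

A sequence threaded on the native contact map is scored against an
ensemble of gapless-threading decoy maps; the misfolded free energy uses
the random-energy-model estimate from the decoy energy mean and variance.
``dG < 0`` means the native state is stable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .alphabet import AA_INDEX, AMINO_ACIDS, MISSING_INDEX, N_AA, encode_seq
from .io_models import DATA_DIR, Alignment

DEFAULT_CUTOFF = 4.5
DEFAULT_S_MIN = 3
DEFAULT_TEMPERATURE = 1.0
DEFAULT_S_UNFOLD = 0.065
DEFAULT_N_DECOYS = 1000


class StructureError(ValueError):
    pass


class HomologyError(ValueError):
    """Alignment cannot be credibly mapped onto the structure."""


@dataclass
class ProteinStructure:
    """Per-residue heavy-atom coordinates plus the native sequence."""

    native_seq: str
    residue_coords: list[np.ndarray]
    chain_id: str = "A"
    residue_numbers: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.native_seq) < 2:
            raise StructureError("structure needs at least 2 residues")
        if len(self.native_seq) != len(self.residue_coords):
            raise StructureError("sequence/coordinate length mismatch")
        for xyz in self.residue_coords:
            if not np.isfinite(xyz).all():
                raise StructureError("non-finite coordinates")
        if self.residue_numbers is None:
            self.residue_numbers = list(range(1, len(self.native_seq) + 1))

    @property
    def L(self) -> int:
        return len(self.native_seq)


def read_pdb(path, chain: str | None = None) -> ProteinStructure:
    """Read the first model of a PDB file; HETATM records are ignored."""
    parser = PDBParser(QUIET=True)
    model = next(iter(parser.get_structure("s", str(path))))
    chains = list(model)
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise StructureError(f"chain {chain!r} not found")
    picked = chains[0]
    seq, coords, numbers = [], [], []
    for res in picked:
        if res.id[0] != " ":
            continue  # HETATM / water
        letter = protein_letters_3to1.get(res.get_resname(), None)
        if letter is None:
            continue
        atoms = np.array([a.get_coord() for a in res.get_atoms()], dtype=float)
        if atoms.size == 0:
            continue
        seq.append(letter)
        coords.append(atoms)
        numbers.append(res.id[1])
    return ProteinStructure(
        native_seq="".join(seq),
        residue_coords=coords,
        chain_id=picked.id,
        residue_numbers=numbers,
    )


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write one ATOM record per stored atom (CA naming for single-atom residues)."""
    aa3 = {v: k for k, v in protein_letters_3to1.items()}
    lines = []
    serial = 1
    for i, (aa, atoms) in enumerate(
        zip(structure.native_seq, structure.residue_coords)
    ):
        resname = aa3[aa]
        resnum = structure.residue_numbers[i]
        for j, (x, y, z) in enumerate(np.atleast_2d(atoms)):
            name = "CA" if j == 0 else f"C{j}"
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} "
                f"{structure.chain_id:1s}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Contact maps and potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactMap:
    L: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for i, j in self.pairs:
            if not (0 <= i < j < self.L):
                raise StructureError(f"bad contact pair ({i}, {j})")

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)


def build_contact_map(
    structure: ProteinStructure,
    cutoff: float = DEFAULT_CUTOFF,
    s_min: int = DEFAULT_S_MIN,
) -> ContactMap:
    """Residues i, j are in contact when |i-j| >= s_min and the minimum
    heavy-atom distance is <= cutoff angstroms."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if s_min < 1:
        raise ValueError("s_min must be >= 1")
    if structure.L < 2:
        raise StructureError("structure needs at least 2 residues")
    coords = [np.atleast_2d(c) for c in structure.residue_coords]
    pairs = set()
    for i in range(structure.L):
        for j in range(i + s_min, structure.L):
            d2 = (
                (coords[i][:, None, :] - coords[j][None, :, :]) ** 2
            ).sum(axis=2)
            if d2.min() <= cutoff * cutoff:
                pairs.add((i, j))
    return ContactMap(L=structure.L, pairs=frozenset(pairs))


@dataclass
class ContactPotential:
    """Symmetric 20x20 contact-energy matrix (alphabetical index order).

    ``U_ext`` extends the matrix with a 21st row/column holding the mean
    potential over the 20 residues, used for gap/X positions.
    """

    U: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.U.shape != (N_AA, N_AA):
            raise StructureError("potential must be 20x20")
        if not np.allclose(self.U, self.U.T):
            raise StructureError("potential must be symmetric")
        ext = np.zeros((N_AA + 1, N_AA + 1))
        ext[:N_AA, :N_AA] = self.U
        ext[N_AA, :N_AA] = self.U.mean(axis=0)
        ext[:N_AA, N_AA] = self.U.mean(axis=1)
        ext[N_AA, N_AA] = self.U.mean()
        self.U_ext = ext


def load_contact_potential(path=None) -> ContactPotential:
    if path is None:
        path = DATA_DIR / "contact_potential.dat"
    rows = [
        [float(x) for x in line.split()]
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return ContactPotential(U=np.array(rows))


def native_energy(seq: str, cmap: ContactMap, potential: ContactPotential) -> float:
    """Sum of pair potentials over the native contacts."""
    if len(seq) != cmap.L:
        raise ValueError(f"sequence length {len(seq)} != map length {cmap.L}")
    enc = encode_seq(seq)
    total = 0.0
    U = potential.U_ext
    for i, j in cmap.pairs:
        total += U[enc[i], enc[j]]
    return total


def make_decoys(
    cmap: ContactMap,
    M: int = DEFAULT_N_DECOYS,
    seed: int = 0,
    s_min: int = DEFAULT_S_MIN,
) -> list[ContactMap]:
    """Circular-shift threading decoys preserving the contact count.

    Decoy k shifts every native pair by k (mod L); shifted pairs that fall
    below the |i-j| >= s_min separation are replaced by uniform draws from
    the remaining valid pairs.
    """
    if M < 2:
        raise ValueError("need at least 2 decoys")
    rng = np.random.default_rng(seed)
    L = cmap.L
    native = cmap.sorted_pairs()
    shifts = 1 + np.arange(M) % max(L - 1, 1)
    decoys = []
    all_valid = [
        (i, j) for i in range(L) for j in range(i + s_min, L)
    ]
    for k in shifts:
        pairs = set()
        for i, j in native:
            a, b = (i + k) % L, (j + k) % L
            a, b = min(a, b), max(a, b)
            if b - a >= s_min:
                pairs.add((a, b))
        deficit = len(native) - len(pairs)
        if deficit > 0:
            candidates = [p for p in all_valid if p not in pairs]
            take = rng.choice(len(candidates), size=deficit, replace=False)
            for t in take:
                pairs.add(candidates[t])
        decoys.append(ContactMap(L=L, pairs=frozenset(pairs)))
    return decoys


def misfold_free_energy(
    seq: str,
    decoys: list[ContactMap],
    potential: ContactPotential,
    T: float,
) -> float:
    """Random-energy-model free energy of the misfolded ensemble.

    G = mean - var/(2T) - T ln M above the freezing temperature
    T_f = sd / sqrt(2 ln M); below T_f the ensemble is frozen into its
    ground state and G is clamped at mean - sd * sqrt(2 ln M).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if not decoys:
        raise ValueError("decoy ensemble is empty")
    energies = np.array([native_energy(seq, d, potential) for d in decoys])
    return rem_free_energy(energies.mean(), energies.var(), len(decoys), T)


def rem_free_energy(mean: float, var: float, M: int, T: float) -> float:
    log_m = math.log(M)
    t_freeze = math.sqrt(var / (2.0 * log_m)) if log_m > 0 else 0.0
    if T >= t_freeze:
        return mean - var / (2.0 * T) - T * log_m
    return mean - math.sqrt(2.0 * var * log_m)


@dataclass
class StabilityModel:
    """Everything needed to predict dG for a sequence on one structure."""

    contact_map: ContactMap
    potential: ContactPotential
    decoys: list[ContactMap]
    T: float = DEFAULT_TEMPERATURE
    s_U: float = DEFAULT_S_UNFOLD
    column_map: dict[int, int] | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.s_U <= 0:
            raise ValueError("unfolding entropy must be positive")
        if len(self.decoys) < 2:
            raise ValueError("need at least 2 decoys")
        if any(d.L != self.contact_map.L for d in self.decoys):
            raise ValueError("decoy length mismatch")

    @property
    def L(self) -> int:
        return self.contact_map.L

    @property
    def M(self) -> int:
        return len(self.decoys)


def build_stability_model(
    structure: ProteinStructure,
    potential: ContactPotential | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    s_min: int = DEFAULT_S_MIN,
    T: float = DEFAULT_TEMPERATURE,
    s_U: float = DEFAULT_S_UNFOLD,
    n_decoys: int = DEFAULT_N_DECOYS,
    decoy_seed: int = 0,
) -> StabilityModel:
    if potential is None:
        potential = load_contact_potential()
    cmap = build_contact_map(structure, cutoff=cutoff, s_min=s_min)
    decoys = make_decoys(cmap, M=n_decoys, seed=decoy_seed, s_min=s_min)
    return StabilityModel(
        contact_map=cmap, potential=potential, decoys=decoys, T=T, s_U=s_U
    )


@dataclass
class StabilityResult:
    E_nat: float
    G_unf: float
    G_misf: float
    dG: float


def combine_free_energies(E_nat: float, G_unf: float, G_misf: float, T: float) -> float:
    # dG = E_nat - (-T ln(e^{-G_unf/T} + e^{-G_misf/T})), computed stably
    m = min(G_unf, G_misf)
    g_non_native = m - T * math.log1p(math.exp(-(max(G_unf, G_misf) - m) / T))
    return E_nat - g_non_native


def delta_g(seq: str, model: StabilityModel) -> StabilityResult:
    """Folding free energy of a sequence threaded on the model structure."""
    if len(seq) != model.L:
        raise ValueError(f"sequence length {len(seq)} != structure length {model.L}")
    enc = encode_seq(seq)
    if (enc == MISSING_INDEX).all():
        raise ValueError("all positions are gaps or X")
    e_nat = native_energy(seq, model.contact_map, model.potential)
    g_unf = -model.T * model.s_U * model.L
    g_misf = misfold_free_energy(seq, model.decoys, model.potential, model.T)
    return StabilityResult(
        E_nat=e_nat,
        G_unf=g_unf,
        G_misf=g_misf,
        dG=combine_free_energies(e_nat, g_unf, g_misf, model.T),
    )


# ---------------------------------------------------------------------------
# Incremental stability engine
# ---------------------------------------------------------------------------

class StabilityEngine:
    """Vectorized dG evaluation with O(contacts-at-site) mutation updates.

    Maintains the native energy and per-decoy energies for a current
    sequence; ``propose`` scores a single-site mutation without committing,
    ``apply`` commits it.
    """

    def __init__(self, model: StabilityModel, seq: str):
        if len(seq) != model.L:
            raise ValueError("sequence/structure length mismatch")
        self.model = model
        self.U = model.potential.U_ext
        L = model.L
        nat_pairs = model.contact_map.sorted_pairs()
        self._nat_i = np.array([p[0] for p in nat_pairs], dtype=np.int64)
        self._nat_j = np.array([p[1] for p in nat_pairs], dtype=np.int64)
        # native neighbor lists
        nat_nbrs: list[list[int]] = [[] for _ in range(L)]
        for i, j in nat_pairs:
            nat_nbrs[i].append(j)
            nat_nbrs[j].append(i)
        self._nat_nbrs = [np.array(v, dtype=np.int64) for v in nat_nbrs]
        # decoy contacts flattened: (decoy index, endpoint i, endpoint j)
        flat_id, flat_i, flat_j = [], [], []
        for k, d in enumerate(model.decoys):
            for i, j in d.pairs:
                flat_id.append(k)
                flat_i.append(i)
                flat_j.append(j)
        self._dec_flat_id = np.array(flat_id, dtype=np.int64)
        self._dec_flat_i = np.array(flat_i, dtype=np.int64)
        self._dec_flat_j = np.array(flat_j, dtype=np.int64)
        # decoy neighbor lists, flattened per site: (decoy index, partner site)
        dec_ids: list[list[int]] = [[] for _ in range(L)]
        dec_nbr: list[list[int]] = [[] for _ in range(L)]
        for k, i, j in zip(flat_id, flat_i, flat_j):
            dec_ids[i].append(k)
            dec_nbr[i].append(j)
            dec_ids[j].append(k)
            dec_nbr[j].append(i)
        self._dec_ids = [np.array(v, dtype=np.int64) for v in dec_ids]
        self._dec_nbr = [np.array(v, dtype=np.int64) for v in dec_nbr]
        self.set_sequence(seq)

    def set_sequence(self, seq: str) -> None:
        self.enc = encode_seq(seq)
        U = self.U
        self.e_nat = float(U[self.enc[self._nat_i], self.enc[self._nat_j]].sum())
        self.decoy_e = np.bincount(
            self._dec_flat_id,
            weights=U[self.enc[self._dec_flat_i], self.enc[self._dec_flat_j]],
            minlength=self.model.M,
        )
        self._g_unf = -self.model.T * self.model.s_U * self.model.L
        self._cur_dg: float | None = None

    @property
    def sequence(self) -> str:
        from .alphabet import decode_seq

        return decode_seq(self.enc)

    def current_result(self) -> StabilityResult:
        m = self.model
        g_misf = rem_free_energy(
            float(self.decoy_e.mean()), float(self.decoy_e.var()), m.M, m.T
        )
        return StabilityResult(
            E_nat=self.e_nat,
            G_unf=self._g_unf,
            G_misf=g_misf,
            dG=combine_free_energies(self.e_nat, self._g_unf, g_misf, m.T),
        )

    @property
    def dG(self) -> float:
        if self._cur_dg is None:
            self._cur_dg = self.current_result().dG
        return self._cur_dg

    def propose(self, site: int, new_aa_index: int):
        """Return (dG_after, d_e_nat, d_decoy_e) for mutating one site."""
        old = self.enc[site]
        U = self.U
        nbrs = self._nat_nbrs[site]
        if nbrs.size:
            states = self.enc[nbrs]
            d_nat = float((U[new_aa_index, states] - U[old, states]).sum())
        else:
            d_nat = 0.0
        ids = self._dec_ids[site]
        if ids.size:
            states = self.enc[self._dec_nbr[site]]
            contrib = U[new_aa_index, states] - U[old, states]
            d_dec = np.bincount(ids, weights=contrib, minlength=self.model.M)
        else:
            d_dec = np.zeros(self.model.M)
        new_dec = self.decoy_e + d_dec
        g_misf = rem_free_energy(
            float(new_dec.mean()), float(new_dec.var()), self.model.M, self.model.T
        )
        dg = combine_free_energies(
            self.e_nat + d_nat, self._g_unf, g_misf, self.model.T
        )
        return dg, d_nat, d_dec

    def apply(
        self,
        site: int,
        new_aa_index: int,
        d_nat: float,
        d_dec: np.ndarray,
        new_dg: float | None = None,
    ) -> None:
        self.enc[site] = new_aa_index
        self.e_nat += d_nat
        self.decoy_e = self.decoy_e + d_dec
        self._cur_dg = new_dg


def get_engine(model: StabilityModel, seq: str) -> StabilityEngine:
    """Per-model cached engine (static neighbor tables are reused)."""
    engine = getattr(model, "_engine", None)
    if engine is None:
        engine = StabilityEngine(model, seq)
        model._engine = engine
    else:
        engine.set_sequence(seq)
    return engine


# ---------------------------------------------------------------------------
# Alignment-to-structure mapping
# ---------------------------------------------------------------------------

def consensus_sequence(aln: Alignment) -> str:
    """Per-column majority canonical residue ('-' if a column is all missing)."""
    cons = []
    for c in range(aln.l):
        counts: dict[str, int] = {}
        for row in aln.rows:
            ch = row[c]
            if ch in AA_INDEX:
                counts[ch] = counts.get(ch, 0) + 1
        if counts:
            cons.append(max(sorted(counts), key=lambda k: counts[k]))
        else:
            cons.append("-")
    return "".join(cons)


def map_alignment_to_structure(
    aln: Alignment,
    structure: ProteinStructure,
    min_identity: float = 0.3,
    report_path=None,
) -> tuple[Alignment, dict[int, int]]:
    """Restrict an alignment to columns with structural homology.

    Globally aligns the alignment consensus to the structure's native
    sequence (BLOSUM62, affine gaps) and keeps only columns matched to a
    residue.  Returns the trimmed alignment and the mapping from kept
    original column index to structure residue index.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    cons = consensus_sequence(aln)
    cons_clean = cons.replace("-", "X")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    alignment = aligner.align(cons_clean, structure.native_seq)[0]
    col_to_res: dict[int, int] = {}
    matched = 0
    identical = 0
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        for off in range(qe - qs):
            col_to_res[qs + off] = ts + off
            matched += 1
            if cons_clean[qs + off] == structure.native_seq[ts + off]:
                identical += 1
    coverage = matched / min(len(cons_clean), len(structure.native_seq))
    if matched == 0 or identical / max(matched, 1) < min_identity or coverage < 0.5:
        raise HomologyError(
            "consensus does not credibly match the structure "
            f"(identity {identical}/{matched}, coverage {coverage:.2f}); "
            "use a closer template"
        )
    kept = sorted(col_to_res)
    if report_path is not None:
        lines = ["column\treason"]
        for c in range(aln.l):
            if c not in col_to_res:
                lines.append(f"{c}\tno_structure_homolog")
        Path(report_path).write_text("\n".join(lines) + "\n")
    dropped = aln.l - len(kept)
    if dropped:
        warnings.warn(f"dropped {dropped} alignment columns without structural homology")
    trimmed = aln.select_columns(kept)
    return trimmed, {c: col_to_res[c] for c in kept}
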