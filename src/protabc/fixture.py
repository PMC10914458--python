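"""Deterministic synthetic scenarios for tests and demos.

Builds a compact chain on a jittered cubic lattice (boustrophedon path, so
nonlocal contacts are guaranteed), derives a stability-optimized native
sequence, and simulates a ground-truth alignment on a coalescent tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AMINO_ACIDS, N_AA
from .evolution import (
    SCSParams,
    evolve_empirical,
    evolve_scs,
    uniform_site_rates,
)
from .genealogy import DemographicParams, scale_tree, simulate_coalescent
from .io_models import Alignment, load_empirical_model
from .structure import (
    ProteinStructure,
    StabilityEngine,
    StabilityModel,
    build_stability_model,
    load_contact_potential,
)

LATTICE_SPACING = 3.8  # angstroms, roughly consecutive-CA distance


@dataclass
class SyntheticScenario:
    structure: ProteinStructure
    stability: StabilityModel
    true_model: str
    true_theta: float
    alignment: Alignment
    seed: int
    N: float
    native_dG: float


def make_chain_structure(L: int, seed: int = 0, jitter: float = 0.15) -> ProteinStructure:
    """Compact self-avoiding CA chain filling a cube, with tiny jitter."""
    if L < 8:
        raise ValueError("need at least 8 residues")
    side = int(np.ceil(L ** (1.0 / 3.0)))
    rng = np.random.default_rng(seed)
    coords = []
    count = 0
    for z in range(side):
        ys = range(side) if z % 2 == 0 else range(side - 1, -1, -1)
        for yi, y in enumerate(ys):
            xs = range(side) if yi % 2 == 0 else range(side - 1, -1, -1)
            for x in xs:
                if count >= L:
                    break
                point = (np.array([x, y, z], dtype=float) * LATTICE_SPACING
                         + rng.normal(0.0, jitter, size=3))
                coords.append(point[None, :])
                count += 1
    placeholder = "A" * L
    return ProteinStructure(native_seq=placeholder, residue_coords=coords)


def optimize_native_sequence(
    stab: StabilityModel, seed: int = 0, sweeps: int = 3
) -> str:
    """Greedy site-sweep minimization of dG starting from a random sequence."""
    rng = np.random.default_rng(seed)
    start = "".join(AMINO_ACIDS[i] for i in rng.integers(N_AA, size=stab.L))
    engine = StabilityEngine(stab, start)
    for _ in range(sweeps):
        order = rng.permutation(stab.L)
        for site in order:
            best_aa, best_move, best_dg = None, None, engine.dG
            for aa in range(N_AA):
                if aa == engine.enc[site]:
                    continue
                dg, d_nat, d_dec = engine.propose(site, aa)
                if dg < best_dg:
                    best_aa, best_move, best_dg = aa, (d_nat, d_dec), dg
            if best_aa is not None:
                engine.apply(site, best_aa, *best_move)
    return engine.sequence


def generate_fixture(
    seed: int,
    L: int = 60,
    n: int = 12,
    true_model: str = "neutral",
    theta: float | None = None,
    N: float = 1000.0,
    n_decoys: int = 200,
    dG_margin: float = 0.25,
    T: float = 1.0,
    Ne: int = 50,
    burnin: int = 0,  # keep the alignment rooted at the native sequence
) -> SyntheticScenario:
    """Build a reproducible structure + alignment scenario.

    ``true_model`` is 'neutral', 'fitness', or a bundled empirical model
    name.  The neutral viability threshold is set ``dG_margin * |dG|``
    above the optimized native stability.
    """
    if L < 20 or n < 4:
        raise ValueError("fixture needs L >= 20 and n >= 4")
    rng = np.random.default_rng(seed)
    structure = make_chain_structure(L, seed=seed)
    stab = build_stability_model(
        structure,
        potential=load_contact_potential(),
        n_decoys=n_decoys,
        decoy_seed=seed,
        T=T,
    )
    native = optimize_native_sequence(stab, seed=seed)
    structure = ProteinStructure(
        native_seq=native,
        residue_coords=structure.residue_coords,
        chain_id=structure.chain_id,
        residue_numbers=structure.residue_numbers,
    )
    native_dG = StabilityEngine(stab, native).dG
    if theta is None:
        theta = float(rng.uniform(20.0, 200.0))

    tree = scale_tree(
        simulate_coalescent(DemographicParams(n=n, N=N), rng), theta, N, L
    )
    threshold = native_dG + dG_margin * abs(native_dG)
    sim_seed = int(rng.integers(2**63 - 1))
    if true_model in ("neutral", "fitness"):
        params = SCSParams(
            kind=true_model, T=T, dG_threshold=threshold, Ne=Ne,
            burnin_proposals=burnin,
        )
        aln = evolve_scs(tree, params, stab, seed=sim_seed, native_seq=native)
    else:
        model = load_empirical_model(true_model)
        aln = evolve_empirical(
            tree, model, rates=uniform_site_rates(L), seed=sim_seed
        )
    return SyntheticScenario(
        structure=structure,
        stability=stab,
        true_model=true_model,
        true_theta=theta,
        alignment=aln,
        seed=seed,
        N=N,
        native_dG=native_dG,
    )
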