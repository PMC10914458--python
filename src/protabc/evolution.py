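"""Forward simulation of protein evolution along a genealogy.

Three simulators share one interface: a site-independent empirical Markov
model, and two structurally constrained models ("neutral": binary
viability threshold on folding stability; "fitness": Moran fixation of
stability-dependent fitness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .alphabet import AMINO_ACIDS, N_AA, decode_seq, encode_seq
from .genealogy import Genealogy, Node
from .io_models import Alignment, EmpiricalModel, build_rate_matrix
from .structure import StabilityEngine, StabilityModel


@dataclass
class SiteRates:
    """Per-site rate multipliers; invariable sites have multiplier 0."""

    multipliers: np.ndarray
    invariant_mask: np.ndarray

    def __post_init__(self) -> None:
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        self.invariant_mask = np.asarray(self.invariant_mask, dtype=bool)
        if self.multipliers.shape != self.invariant_mask.shape:
            raise ValueError("shape mismatch")
        if (self.multipliers[self.invariant_mask] != 0).any():
            raise ValueError("invariable sites must have multiplier 0")
        variable = self.multipliers[~self.invariant_mask]
        if variable.size and abs(variable.mean() - 1.0) > 1e-9:
            raise ValueError("variable-site multipliers must average 1")


def draw_site_rates(
    l: int,
    gamma_shape: float | None = None,
    p_inv: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> SiteRates:
    """Gamma(shape, mean 1) rate multipliers with invariable sites."""
    if gamma_shape is not None and gamma_shape <= 0:
        raise ValueError("gamma shape must be positive")
    if not (0 <= p_inv < 1):
        raise ValueError("p_inv must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.random(l) < p_inv
    mult = np.ones(l)
    if gamma_shape is not None:
        mult = rng.gamma(shape=gamma_shape, scale=1.0 / gamma_shape, size=l)
    mult[mask] = 0.0
    variable = ~mask
    if variable.any():
        mult[variable] /= mult[variable].mean()
    return SiteRates(multipliers=mult, invariant_mask=mask)


def uniform_site_rates(l: int) -> SiteRates:
    return SiteRates(multipliers=np.ones(l), invariant_mask=np.zeros(l, dtype=bool))


# ---------------------------------------------------------------------------
# Empirical simulator
# ---------------------------------------------------------------------------

class _ReversibleKernel:
    """Spectral transition probabilities for a reversible generator."""

    def __init__(self, model: EmpiricalModel):
        self.Q = build_rate_matrix(model)
        self.pi = model.pi
        sq = np.sqrt(self.pi)
        B = self.Q * sq[:, None] / sq[None, :]
        B = 0.5 * (B + B.T)
        w, V = np.linalg.eigh(B)
        self._w = w
        # Q = D^{-1/2} B D^{1/2}; P(t) = D^{-1/2} V e^{wt} V' D^{1/2}
        self._left = V / sq[:, None]
        self._right = V * sq[:, None]

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._w * t)) @ self._right.T
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


def evolve_empirical(
    tree: Genealogy,
    model: EmpiricalModel,
    rates: SiteRates | None = None,
    seed: int | np.random.Generator = 0,
) -> Alignment:
    """Simulate i.i.d.-rooted site-independent evolution along the tree."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tips = tree.tips()
    l = rates.multipliers.size if rates is not None else None
    if rates is None:
        raise ValueError("site rates (or uniform_site_rates(l)) are required")
    kernel = getattr(model, "_kernel", None)
    if kernel is None:
        kernel = _ReversibleKernel(model)
        model._kernel = kernel
    root_states = rng.choice(N_AA, size=l, p=model.pi)
    out: dict[str, np.ndarray] = {}

    unique_rates = np.unique(rates.multipliers)

    def evolve_branch(states: np.ndarray, b: float) -> np.ndarray:
        new = states.copy()
        for r in unique_rates:
            if r == 0.0 or b == 0.0:
                continue
            sites = np.flatnonzero(rates.multipliers == r)
            P = kernel.transition_matrix(b * r)
            sub = states[sites]
            for a in np.unique(sub):
                sel = sites[sub == a]
                new[sel] = rng.choice(N_AA, size=sel.size, p=P[a])
        return new

    def walk(node: Node, states: np.ndarray) -> None:
        if node.is_leaf:
            out[node.name] = states
        for ch in node.children:
            walk(ch, evolve_branch(states, ch.length))

    walk(tree.root, root_states)
    return Alignment(
        ids=[t.name for t in tips], rows=[decode_seq(out[t.name]) for t in tips]
    )


# ---------------------------------------------------------------------------
# Structurally constrained simulators
# ---------------------------------------------------------------------------

@dataclass
class SCSParams:
    kind: str  # "neutral" | "fitness"
    T: float = 1.0
    dG_threshold: float = 0.0
    Ne: int = 100
    root_mode: str = "structure_native"
    root_sequence: str | None = None
    burnin_proposals: int | None = None  # accepted moves; None -> 10 * L

    def __post_init__(self) -> None:
        if self.kind not in ("neutral", "fitness"):
            raise ValueError("kind must be 'neutral' or 'fitness'")
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")
        if self.root_mode not in ("structure_native", "user_sequence"):
            raise ValueError("bad root_mode")
        if self.root_mode == "user_sequence" and not self.root_sequence:
            raise ValueError("root_mode 'user_sequence' needs root_sequence")


def fitness_of(dG: float, T: float) -> float:
    """Native-state occupancy fraction: 1 / (1 + exp(dG / T))."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(expit(-dG / T))


def moran_fixation(f_old: float, f_new: float, Ne: int) -> float:
    """Moran birth-death fixation probability of one mutant among Ne."""
    if f_old <= 0 or f_new <= 0:
        raise ValueError("fitnesses must be positive")
    if Ne < 1:
        raise ValueError("Ne must be >= 1")
    if Ne == 1:
        return 1.0
    rho = f_old / f_new
    if abs(1.0 - rho) < 1e-12:
        return 1.0 / Ne
    if rho > 1.0:
        # (rho - 1) / (rho^Ne - 1), in logs to survive huge rho^Ne
        y = Ne * math.log(rho)
        log_den = y + math.log1p(-math.exp(-y)) if y < 700 else y
        log_p = math.log(rho - 1.0) - log_den
        return math.exp(log_p) if log_p > -745 else 0.0
    return (1.0 - rho) / (1.0 - rho**Ne)


def _log_fitness(dG: float, T: float) -> float:
    # log(1 / (1 + exp(dG/T))) computed stably
    x = dG / T
    if x > 0:
        return -x - math.log1p(math.exp(-x))
    return -math.log1p(math.exp(x))


def scs_acceptance(dG_old: float, dG_new: float, T: float, Ne: int) -> float:
    """Acceptance probability of a proposed mutation under the fitness model.

    The Moran fixation probability is expressed relative to the neutral
    fixation probability 1/Ne (origination-fixation scaling), capped at 1,
    so a selectively neutral proposal is accepted with probability 1.
    Computed in log space to survive extreme dG/T ratios.
    """
    if Ne == 1:
        return 1.0
    x = _log_fitness(dG_old, T) - _log_fitness(dG_new, T)  # log rho
    if abs(x) < 1e-14:
        return 1.0
    # pfix = (1 - e^x) / (1 - e^{Ne x}); acceptance = min(1, Ne * pfix)
    if x > 0:  # new variant less fit
        log_num = x + math.log1p(-math.exp(-x)) if x < 700 else x
        y = Ne * x
        log_den = y + (math.log1p(-math.exp(-y)) if y < 700 else 0.0)
        log_pfix = log_num - log_den
        return min(1.0, Ne * math.exp(log_pfix))
    # new variant fitter: both numerator and denominator in (0, 1]
    pfix = (-math.expm1(x)) / (-math.expm1(Ne * x))
    return min(1.0, Ne * pfix)


@dataclass
class SCSRunLog:
    proposals: int = 0
    accepted: int = 0
    node_dGs: list = None

    def __post_init__(self) -> None:
        if self.node_dGs is None:
            self.node_dGs = []


def evolve_scs(
    tree: Genealogy,
    params: SCSParams,
    stab: StabilityModel,
    seed: int | np.random.Generator = 0,
    rates: SiteRates | None = None,
    native_seq: str | None = None,
    log: SCSRunLog | None = None,
) -> Alignment:
    """Simulate structure-constrained evolution along the tree.

    Branch lengths are *attempted* substitutions per site: proposal events
    arrive as a Poisson process; each picks a site (weighted by site rates)
    and a uniformly random alternative residue; the stability model decides
    acceptance.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = stab.L
    if params.root_mode == "user_sequence":
        root_seq = params.root_sequence
    else:
        if native_seq is None:
            raise ValueError("structure_native root mode needs native_seq")
        root_seq = native_seq
    if len(root_seq) != L:
        raise ValueError("root sequence length must match the structure")
    from .structure import get_engine

    engine = get_engine(stab, root_seq)

    neutral = params.kind == "neutral"
    if neutral and engine.dG > params.dG_threshold:
        raise ValueError(
            "root sequence violates the viability threshold "
            f"(root dG = {engine.dG:.4f}; raise dG_threshold to at least this)"
        )

    if rates is None:
        site_w = None  # uniform: sample sites directly
        total_rate_per_unit = float(L)
    else:
        if rates.multipliers.size != L:
            raise ValueError("site-rate length mismatch")
        total = rates.multipliers.sum()
        if total <= 0:
            raise ValueError("all sites invariable")
        site_w = rates.multipliers / total
        total_rate_per_unit = float(total)

    def accept(dg_old: float, dg_new: float) -> tuple[bool, float]:
        """Return (accepted, u) where u is the uniform draw consumed."""
        u = rng.random()
        if neutral:
            return dg_new <= params.dG_threshold, u
        return u < scs_acceptance(dg_old, dg_new, params.T, params.Ne), u

    def one_proposal() -> bool:
        if site_w is None:
            site = int(rng.integers(L))
        else:
            site = int(rng.choice(L, p=site_w))
        old = engine.enc[site]
        alt = int(rng.integers(N_AA - 1))
        new = alt + 1 if alt >= old else alt
        dg_old = engine.dG if not neutral else 0.0
        dg_new, d_nat, d_dec = engine.propose(site, new)
        ok, _ = accept(dg_old, dg_new)
        if log is not None:
            log.proposals += 1
        if ok:
            engine.apply(site, new, d_nat, d_dec, new_dg=dg_new)
            if log is not None:
                log.accepted += 1
        return ok

    # root equilibration: a fixed number of accepted moves on a virtual stem
    burn_target = params.burnin_proposals
    if burn_target is None:
        burn_target = 10 * L
    accepted = 0
    attempts = 0
    max_attempts = max(200 * burn_target, 1000)
    while accepted < burn_target and attempts < max_attempts:
        attempts += 1
        if one_proposal():
            accepted += 1

    tips = tree.tips()
    out: dict[str, str] = {}

    def walk(node: Node, enc_state: np.ndarray, e_nat: float, dec_e: np.ndarray) -> None:
        engine.enc = enc_state.copy()
        engine.e_nat = e_nat
        engine.decoy_e = dec_e.copy()
        engine._cur_dg = None
        n_events = rng.poisson(node.length * total_rate_per_unit)
        for _ in range(n_events):
            one_proposal()
        if log is not None:
            log.node_dGs.append(engine.dG)
        if node.is_leaf:
            out[node.name] = engine.sequence
        state = (engine.enc.copy(), engine.e_nat, engine.decoy_e.copy())
        for ch in node.children:
            walk(ch, *state)

    root_state = (engine.enc.copy(), engine.e_nat, engine.decoy_e.copy())
    # the root itself undergoes no events; children branch from it
    if log is not None:
        log.node_dGs.append(engine.dG)
    if tree.root.is_leaf:
        out[tree.root.name] = engine.sequence
    for ch in tree.root.children:
        walk(ch, *root_state)

    return Alignment(ids=[t.name for t in tips], rows=[out[t.name] for t in tips])
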