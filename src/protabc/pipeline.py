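"""End-to-end orchestration: configuration, simulation scheduling with
deterministic per-simulation seed substreams, and result bundles."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from . import __version__
from .abc import (
    ABCConfig,
    ConfusionMatrix,
    GoodnessOfFit,
    PosteriorResult,
    SimulationTable,
    cross_validate,
    estimate_posterior,
    goodness_of_fit,
)
from .evolution import (
    SCSParams,
    draw_site_rates,
    evolve_empirical,
    evolve_scs,
    uniform_site_rates,
)
from .genealogy import (
    DemographicParams,
    Genealogy,
    RatePrior,
    read_newick,
    scale_tree,
    simulate_coalescent,
)
from .io_models import Alignment, load_empirical_model, read_alignment
from .structure import (
    StabilityModel,
    build_stability_model,
    map_alignment_to_structure,
    read_pdb,
)
from .summary import SummaryVector, compute_summary_vector, mean_pairwise_identity


@dataclass
class ModelSpec:
    """One candidate substitution model in the comparison."""

    label: str
    kind: str  # "empirical" | "neutral" | "fitness"
    empirical_name: str | None = None
    gamma_shape: float | None = None
    p_inv: float = 0.0
    T: float = 1.0
    dG_threshold: float = 0.0
    Ne: int = 100
    burnin_proposals: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("empirical", "neutral", "fitness"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "empirical" and not self.empirical_name:
            self.empirical_name = self.label


@dataclass
class RunConfig:
    models: list[ModelSpec]
    prior: RatePrior = field(default_factory=RatePrior)
    demography: DemographicParams | None = None
    user_tree: str | None = None  # newick path
    n_sims_per_model: int = 10_000
    method: str = "rejection"
    tolerance: float = 0.005
    seed: int = 0
    workers: int = 1
    query_path: str | None = None
    structure_path: str | None = None
    chain: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if len(self.models) < 2:
            raise ValueError("need at least 2 models to compare")
        if len({m.label for m in self.models}) != len(self.models):
            raise ValueError("model labels must be unique")
        if self.n_sims_per_model < 100:
            raise ValueError("need at least 100 simulations per model")
        if self.demography is None and self.user_tree is None:
            raise ValueError("provide demographic parameters or a user tree")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d

    @classmethod
    def from_manifest(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("version", None)
        d["models"] = [ModelSpec(**m) for m in d["models"]]
        d["prior"] = RatePrior(**d["prior"])
        if d.get("demography") is not None:
            d["demography"] = DemographicParams(**d["demography"])
        return cls(**d)


def sim_seed_stream(master_seed: int, sim_index: int) -> np.random.Generator:
    """Counter-based substream: independent of worker count and schedule."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, sim_index)))


_MODEL_CACHE: dict[tuple, object] = {}


def _cached_empirical(name: str, gamma_shape, p_inv):
    key = (name, gamma_shape, p_inv)
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = load_empirical_model(
            name, gamma_shape=gamma_shape, p_inv=p_inv
        )
    return _MODEL_CACHE[key]


def _structure_mask(column_map: dict[int, int] | None, L: int) -> np.ndarray | None:
    """Boolean mask over structure residues covered by the query alignment."""
    if column_map is None:
        return None
    covered = np.zeros(L, dtype=bool)
    for res in column_map.values():
        covered[res] = True
    return covered if not covered.all() else None


def _apply_mask(aln: Alignment, mask: np.ndarray | None) -> Alignment:
    if mask is None:
        return aln
    rows = [
        "".join(ch if mask[i] else "-" for i, ch in enumerate(row))
        for row in aln.rows
    ]
    return Alignment(ids=list(aln.ids), rows=rows)


def thread_onto_structure(
    trimmed: Alignment, column_map: dict[int, int], L: int
) -> Alignment:
    """Place trimmed alignment columns at their structure residues; residues
    without a column become '-' (scored with the mean potential)."""
    kept_cols = sorted(column_map)
    rows = []
    for row in trimmed.rows:
        assert len(row) == len(kept_cols)
        full = ["-"] * L
        for local, col in enumerate(kept_cols):
            full[column_map[col]] = row[local]
        rows.append("".join(full))
    return Alignment(ids=list(trimmed.ids), rows=rows)


def simulate_one(
    spec: ModelSpec,
    config: RunConfig,
    stab: StabilityModel,
    native_seq: str | None,
    l_sites: int,
    sim_index: int,
    user_tree: Genealogy | None,
    mask: np.ndarray | None,
) -> tuple[str, float, np.ndarray]:
    """One labelled simulation row (model label, theta, summary stats)."""
    rng = sim_seed_stream(config.seed, sim_index)
    theta = config.prior.draw(rng)
    if user_tree is not None:
        tree = user_tree
    else:
        demo = dataclasses.replace(config.demography, n=config.demography.n)
        tree = scale_tree(
            simulate_coalescent(demo, rng), theta, demo.N, l_sites
        )
    if spec.kind == "empirical":
        model = _cached_empirical(spec.empirical_name, spec.gamma_shape, spec.p_inv)
        if spec.gamma_shape is not None or spec.p_inv > 0:
            rates = draw_site_rates(l_sites, spec.gamma_shape, spec.p_inv, rng)
        else:
            rates = uniform_site_rates(l_sites)
        aln = evolve_empirical(tree, model, rates=rates, seed=rng)
    else:
        params = SCSParams(
            kind=spec.kind, T=spec.T, dG_threshold=spec.dG_threshold,
            Ne=spec.Ne, burnin_proposals=spec.burnin_proposals,
        )
        aln = evolve_scs(tree, params, stab, seed=rng, native_seq=native_seq)
    aln = _apply_mask(aln, mask)
    vec = compute_summary_vector(aln, stab)
    return spec.label, theta, vec.as_array()


def build_simulation_table(
    config: RunConfig,
    stab: StabilityModel,
    native_seq: str | None,
    l_sites: int,
    user_tree: Genealogy | None = None,
    mask: np.ndarray | None = None,
) -> SimulationTable:
    jobs = []
    for mi, spec in enumerate(config.models):
        for k in range(config.n_sims_per_model):
            jobs.append((spec, mi * config.n_sims_per_model + k))
    results = Parallel(n_jobs=config.workers, batch_size=16)(
        delayed(simulate_one)(
            spec, config, stab, native_seq, l_sites, sim_index, user_tree, mask
        )
        for spec, sim_index in jobs
    )
    return SimulationTable.from_rows(results)


@dataclass
class ResultBundle:
    observed: SummaryVector
    table: SimulationTable
    posterior: PosteriorResult
    gof: GoodnessOfFit
    confusion: ConfusionMatrix | None = None


def run_pipeline(config: RunConfig, with_crossval: bool = False,
                 n_eval: int = 100) -> ResultBundle:
    """Full query -> simulate -> summarize -> estimate pipeline."""
    if config.query_path is None:
        raise ValueError("run_pipeline needs a query alignment path")
    query = read_alignment(config.query_path).require_query()

    if config.structure_path is None:
        raise ValueError("a structure is required for the dG statistics")
    structure = read_pdb(config.structure_path, chain=config.chain)

    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    trimmed, column_map = map_alignment_to_structure(
        query, structure,
        report_path=(out / "dropped_columns.tsv") if out else None,
    )
    stab = build_stability_model(structure, decoy_seed=config.seed)
    threaded = thread_onto_structure(trimmed, column_map, structure.L)
    mask = _structure_mask(column_map, structure.L)
    observed = compute_summary_vector(threaded, stab)

    user_tree = read_newick(config.user_tree) if config.user_tree else None
    l_sites = structure.L

    table = None
    if out and (out / "simulations.tsv").exists() and (out / "manifest.json").exists():
        manifest = json.loads((out / "manifest.json").read_text())
        if manifest == config.to_manifest():
            table = SimulationTable.from_tsv(out / "simulations.tsv")
    if table is None:
        table = build_simulation_table(
            config, stab, structure.native_seq, l_sites, user_tree, mask
        )

    abc_config = ABCConfig(
        method=config.method, tolerance=config.tolerance,
        n_sims_per_model=config.n_sims_per_model, seed=config.seed,
    )
    posterior = estimate_posterior(observed, table, abc_config)
    gof = goodness_of_fit(observed, table, abc_config)
    confusion = None
    if with_crossval:
        confusion = cross_validate(table, abc_config, n_eval=n_eval)

    if out:
        (out / "manifest.json").write_text(
            json.dumps(config.to_manifest(), indent=2, sort_keys=True) + "\n"
        )
        table.to_tsv(out / "simulations.tsv")
        with (out / "posterior.tsv").open("w") as fh:
            fh.write("model\tposterior\n")
            for m, p in sorted(posterior.probabilities.items()):
                fh.write(f"{m}\t{p:.6f}\n")
        gof.to_frame().to_csv(out / "goodness_of_fit.tsv", sep="\t", index=False)
        if confusion is not None:
            confusion.to_frame().to_csv(out / "confusion_matrix.tsv", sep="\t")
    return ResultBundle(
        observed=observed, table=table, posterior=posterior,
        gof=gof, confusion=confusion,
    )


def run_from_manifest(manifest_path, **kwargs) -> ResultBundle:
    config = RunConfig.from_manifest(json.loads(Path(manifest_path).read_text()))
    return run_pipeline(config, **kwargs)


def calibrate_prior(
    config: RunConfig,
    stab: StabilityModel,
    native_seq: str | None,
    l_sites: int,
    pilot_sims: int = 100,
    query_identity: float | None = None,
    user_tree: Genealogy | None = None,
) -> tuple[float, float]:
    """Pilot-simulation check that the theta prior spans the query identity.

    Returns the achieved (min, max) mean pairwise identity over pilot
    simulations under the first listed model.
    """
    if pilot_sims < 50:
        raise ValueError("need at least 50 pilot simulations")
    spec = config.models[0]
    identities = []
    for k in range(pilot_sims):
        rng = sim_seed_stream(config.seed, 10_000_000 + k)
        theta = config.prior.low + (config.prior.high - config.prior.low) * (
            k / max(pilot_sims - 1, 1)
        )
        if user_tree is not None:
            tree = user_tree
        else:
            tree = scale_tree(
                simulate_coalescent(config.demography, rng),
                theta, config.demography.N, l_sites,
            )
        if spec.kind == "empirical":
            model = load_empirical_model(spec.empirical_name)
            aln = evolve_empirical(
                tree, model, rates=uniform_site_rates(l_sites), seed=rng
            )
        else:
            params = SCSParams(
                kind=spec.kind, T=spec.T, dG_threshold=spec.dG_threshold,
                Ne=spec.Ne, burnin_proposals=spec.burnin_proposals,
            )
            aln = evolve_scs(tree, params, stab, seed=rng, native_seq=native_seq)
        identities.append(mean_pairwise_identity(aln))
    lo, hi = float(min(identities)), float(max(identities))
    if query_identity is not None and not (lo <= query_identity <= hi):
        warnings.warn(
            f"query identity {query_identity:.3f} outside pilot range "
            f"[{lo:.3f}, {hi:.3f}]; adjust the theta prior"
        )
    return lo, hi
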