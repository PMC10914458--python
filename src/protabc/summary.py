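"""The seven summary statistics used for model choice.

Order is fixed: dG mean, dG sd, segregating sites, Grantham mean, sd,
skewness, excess kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import MISSING_INDEX, N_AA, encode_seq
from .io_models import Alignment, GranthamTable, default_grantham_table
from .structure import StabilityModel

STAT_NAMES = (
    "dg_mean", "dg_sd", "seg_sites", "gr_mean", "gr_sd", "gr_skew", "gr_kurt"
)


@dataclass(frozen=True)
class SummaryVector:
    dg_mean: float
    dg_sd: float
    seg_sites: int
    gr_mean: float
    gr_sd: float
    gr_skew: float
    gr_kurt: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.isfinite(arr).all():
            raise ValueError("summary statistics must be finite")
        if self.seg_sites < 0 or self.dg_sd < 0 or self.gr_sd < 0:
            raise ValueError("negative count or spread statistic")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.dg_mean, self.dg_sd, float(self.seg_sites),
                self.gr_mean, self.gr_sd, self.gr_skew, self.gr_kurt,
            ]
        )


def _encoded(aln: Alignment) -> np.ndarray:
    return np.stack([encode_seq(r) for r in aln.rows])


def segregating_sites(aln: Alignment) -> int:
    """Columns with >= 2 distinct canonical residues (gaps/X are missing)."""
    aln.require_query()
    enc = _encoded(aln)
    count = 0
    for c in range(aln.l):
        col = enc[:, c]
        states = np.unique(col[col != MISSING_INDEX])
        if states.size >= 2:
            count += 1
    return count


def _pooled_grantham(aln: Alignment, table: GranthamTable) -> np.ndarray:
    enc = _encoded(aln)
    n = aln.n
    values = []
    for a in range(n):
        for b in range(a + 1, n):
            ra, rb = enc[a], enc[b]
            ok = (ra != MISSING_INDEX) & (rb != MISSING_INDEX) & (ra != rb)
            if ok.any():
                values.append(table.D[ra[ok], rb[ok]])
    if not values:
        return np.empty(0)
    return np.concatenate(values)


def grantham_moments(
    aln: Alignment, table: GranthamTable | None = None
) -> tuple[float, float, float, float]:
    """Sample moments of pooled pairwise per-column Grantham distances.

    Only pairs of *different* canonical residues enter the pool.  Pools
    with fewer than 2 values return zeros by convention so every
    simulation yields a finite vector.
    """
    aln.require_query()
    if table is None:
        table = default_grantham_table()
    pool = _pooled_grantham(aln, table)
    if pool.size == 0:
        return (0.0, 0.0, 0.0, 0.0)
    mean = float(pool.mean())
    if pool.size < 2:
        return (mean, 0.0, 0.0, 0.0)
    sd = float(pool.std(ddof=1))
    m2 = float(((pool - mean) ** 2).mean())
    if m2 == 0.0:
        return (mean, sd, 0.0, 0.0)
    m3 = float(((pool - mean) ** 3).mean())
    m4 = float(((pool - mean) ** 4).mean())
    return (mean, sd, m3 / m2**1.5, m4 / m2**2 - 3.0)


def stability_stats(aln: Alignment, stab: StabilityModel) -> tuple[float, float]:
    """Mean and sd (ddof=1) of per-sequence folding free energies."""
    from .structure import get_engine

    dgs = []
    for row in aln.rows:
        enc = encode_seq(row)
        if (enc == MISSING_INDEX).all():
            raise ValueError("sequence is all gaps or X")
        dgs.append(get_engine(stab, row).dG)
    dgs = np.array(dgs)
    sd = float(dgs.std(ddof=1)) if dgs.size > 1 else 0.0
    return float(dgs.mean()), sd


def compute_summary_vector(
    aln: Alignment,
    stab: StabilityModel,
    table: GranthamTable | None = None,
) -> SummaryVector:
    dg_mean, dg_sd = stability_stats(aln, stab)
    gr_mean, gr_sd, gr_skew, gr_kurt = grantham_moments(aln, table)
    return SummaryVector(
        dg_mean=dg_mean,
        dg_sd=dg_sd,
        seg_sites=segregating_sites(aln),
        gr_mean=gr_mean,
        gr_sd=gr_sd,
        gr_skew=gr_skew,
        gr_kurt=gr_kurt,
    )


def mean_pairwise_identity(aln: Alignment) -> float:
    """Mean over unordered pairs of the fraction of matching canonical
    positions among positions where both residues are canonical."""
    aln.require_query()
    enc = _encoded(aln)
    fractions = []
    for a in range(aln.n):
        for b in range(a + 1, aln.n):
            ra, rb = enc[a], enc[b]
            both = (ra != MISSING_INDEX) & (rb != MISSING_INDEX)
            if both.any():
                fractions.append(float((ra[both] == rb[both]).mean()))
    if not fractions:
        raise ValueError("no pair has comparable canonical positions")
    return float(np.mean(fractions))
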