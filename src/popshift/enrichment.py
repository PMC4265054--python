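"""Gene-set enrichment and growth-rate statistics.

Enrichment follows the classic over-representation scheme: select the
responsive genes of a profile (fold change beyond a threshold and p below
a cut-off, both strict), then score each annotation set with the
upper-tail hypergeometric probability of the observed overlap, optionally
Bonferroni-corrected across sets.

Doubling times are estimated as the reciprocal slope of log2(OD600)
against time over the exponential window of a growth curve, and compared
between strains as log2 ratios versus a wild-type reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "DoublingTimeResult",
    "select_changed_genes",
    "hypergeometric_enrichment",
    "bonferroni",
    "doubling_time",
    "relative_doubling_time",
]


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation test outcome for one gene set."""

    set_name: str
    universe_size: int   # N
    set_size: int        # K (after restriction to the universe)
    selected_size: int   # n
    overlap: int         # k
    p_value: float
    p_bonferroni: float | None = None

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.selected_size):
            raise ValueError("overlap exceeds min(set size, selection size)")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p outside [0, 1]")
        if self.p_bonferroni is not None and self.p_bonferroni < self.p_value:
            raise ValueError("Bonferroni-corrected p below raw p")


def select_changed_genes(
    profile: np.ndarray,
    pvalues: np.ndarray,
    gene_ids: list[str],
    direction: str = "both",
    fold_threshold: float = 1.7,
    p_threshold: float = 0.05,
) -> list[str]:
    """Genes with fold change strictly beyond the threshold and p strictly below.

    ``direction`` selects up-regulated (M > log2 threshold), down-regulated
    (M < -log2 threshold) or both.
    """
    profile = np.asarray(profile, dtype=float)
    pvalues = np.asarray(pvalues, dtype=float)
    if profile.shape != pvalues.shape or profile.size != len(gene_ids):
        raise ValueError("profile, pvalues and gene_ids lengths differ")
    m_cut = math.log2(fold_threshold)
    if direction == "up":
        hit = profile > m_cut
    elif direction == "down":
        hit = profile < -m_cut
    elif direction == "both":
        hit = np.abs(profile) > m_cut
    else:
        raise ValueError("direction must be 'up', 'down' or 'both'")
    hit &= pvalues < p_threshold
    return [g for g, h in zip(gene_ids, hit) if h]


def hypergeometric_enrichment(
    universe: set[str], gene_set: GeneSet, selected: set[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric test P(X >= k) of overlap between a
    selection and an annotation set, both restricted to the universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    members = gene_set.members & universe
    dropped = len(gene_set.members) - len(members)
    sel = set(selected) & universe
    dropped_sel = len(set(selected)) - len(sel)
    if dropped or dropped_sel:
        logger.info(
            "hypergeometric_enrichment(%s): dropped %d set / %d selected genes "
            "outside the universe", gene_set.name, dropped, dropped_sel,
        )
    N, K, n = len(universe), len(members), len(sel)
    k = len(members & sel)
    # P(X >= k) for X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(1.0, max(0.0, p))
    return EnrichmentResult(
        set_name=gene_set.name,
        universe_size=N,
        set_size=K,
        selected_size=n,
        overlap=k,
        p_value=p,
    )


def bonferroni(p_values: list[float] | np.ndarray, m_tests: int | None = None) -> list[float]:
    """Bonferroni correction: p -> min(1, p * m)."""
    p_values = list(p_values)
    m = len(p_values) if m_tests is None else m_tests
    return [min(1.0, p * m) for p in p_values]


@dataclass
class DoublingTimeResult:
    """Doubling time fitted from the exponential window of a growth curve."""

    doubling_time_min: float
    slope: float                    # log2(OD600) per minute
    fit_window: tuple[float, float]
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope > 0 and not math.isclose(
            self.doubling_time_min, 1.0 / self.slope, rel_tol=1e-9
        ):
            raise ValueError("doubling_time inconsistent with slope")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


def doubling_time(
    times_min: np.ndarray,
    od600: np.ndarray,
    window: tuple[float, float] | None = None,
) -> DoublingTimeResult:
    """Least-squares doubling time from log2(OD600) vs time.

    The fit uses the points inside ``window`` (inclusive); by default the
    trailing half of the curve, emulating the practice of reading the slope
    from the exponential stretch just before harvest.
    """
    times_min = np.asarray(times_min, dtype=float)
    od600 = np.asarray(od600, dtype=float)
    if times_min.shape != od600.shape or times_min.ndim != 1:
        raise ValueError("times and OD must be matching 1-D arrays")
    if (od600 <= 0).any():
        raise ValueError("OD600 values must be positive")
    if window is None:
        start = times_min[times_min.size // 2] if times_min.size > 3 else times_min[0]
        window = (float(start), float(times_min[-1]))
    lo, hi = window
    use = (times_min >= lo) & (times_min <= hi)
    if use.sum() < 3:
        raise ValueError("need at least 3 points in the fit window")
    t, y = times_min[use], np.log2(od600[use])
    fit = stats.linregress(t, y)
    if fit.slope <= 0:
        raise ValueError("no growth: non-positive log2(OD600) slope")
    return DoublingTimeResult(
        doubling_time_min=1.0 / fit.slope,
        slope=float(fit.slope),
        fit_window=(float(lo), float(hi)),
        r_squared=float(fit.rvalue**2),
    )


def relative_doubling_time(
    mutant: DoublingTimeResult, wildtype: DoublingTimeResult
) -> float:
    """log2(doubling time in mutant / doubling time in wild-type)."""
    if mutant.doubling_time_min <= 0 or wildtype.doubling_time_min <= 0:
        raise ValueError("doubling times must be positive")
    return math.log2(mutant.doubling_time_min / wildtype.doubling_time_min)
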