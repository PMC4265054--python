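"""Seeded synthetic data with the statistical structure the analysis assumes.

Each generator is a pure function of its parameters and a seed, and
returns both the dataset and a :class:`SyntheticTruth` carrying the
planted ground truth, so that recovery can be verified exactly:

* ``make_compendium`` — a deletion-strain compendium with a planted rank-1
  slow-growth signature whose per-strain loading scales with a planted
  log2 relative doubling time, plus strain-specific effects and noise;
* ``make_cycle_series`` — a sinusoidal cell-cycle time course expressed as
  M-values relative to t = 0 (14 points over 390 min by default);
* ``make_mixture_target`` — a profile constructed as a known
  spline-weighted mixture of the cycle profiles plus noise;
* ``make_enrichment_scenario`` — a perturbation profile with a planted
  responsive gene set contaminated by the slow-growth signature, alongside
  a compendium from which the signature can be estimated;
* ``make_growth_curves`` — exponential OD600 curves.

P-values accompanying generated M-values come from a two-sided z-test of
each value against the known noise scale: cheap, and exactly consistent
with how the noise was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .deconvolution import DEFAULT_CONTROL_X_FRACTIONS, spline_weights, virtual_profile
from .io import CellCycleSeries, ExpressionMatrix, GeneSet

__all__ = [
    "SyntheticTruth",
    "make_compendium",
    "make_cycle_series",
    "make_mixture_target",
    "make_enrichment_scenario",
    "make_growth_curves",
    "zscore_pvalues",
]


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator, for recovery tests."""

    seed: int
    generator_params: dict[str, Any] = field(default_factory=dict)
    planted_signature: np.ndarray | None = None
    planted_growth_rates: np.ndarray | None = None
    true_control_y: np.ndarray | None = None
    true_weights: np.ndarray | None = None
    planted_target_set: list[str] | None = None


def zscore_pvalues(values: np.ndarray, noise_sd: float) -> np.ndarray:
    """Two-sided p-value of each M-value against N(0, noise_sd^2)."""
    values = np.asarray(values, dtype=float)
    if noise_sd <= 0:
        return np.where(values != 0, 0.0, 1.0)
    return 2.0 * stats.norm.sf(np.abs(values) / noise_sd)


def make_compendium(
    n_genes: int = 2000,
    n_strains: int = 200,
    n_signature_genes: int = 600,
    signature_amplitude: float = 1.0,
    beta: float = 1.0,
    specific_effect_strains: int = 40,
    specific_genes_per_strain: int = 20,
    specific_amplitude: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Compendium with a planted rank-1 slow-growth signature.

    The signature vector sigma has half of ``n_signature_genes`` entries at
    +``signature_amplitude`` and half at -, the rest zero.  Each strain s
    draws a log2 relative doubling time g_s ~ Uniform(-0.1, 1.0) and its
    profile is ``beta * g_s * sigma`` plus, for designated strains, a block
    of strain-specific spikes, plus i.i.d. Gaussian noise.  P-values come
    from :func:`zscore_pvalues` against the noise scale.
    """
    if n_signature_genes > n_genes:
        raise ValueError("n_signature_genes exceeds n_genes")
    if specific_effect_strains > n_strains:
        raise ValueError("specific_effect_strains exceeds n_strains")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    sample_ids = [f"strain{s:03d}" for s in range(n_strains)]

    sigma = np.zeros(n_genes)
    sig_genes = rng.permutation(n_genes)[:n_signature_genes]
    half = n_signature_genes // 2
    sigma[sig_genes[:half]] = signature_amplitude
    sigma[sig_genes[half:]] = -signature_amplitude

    growth = rng.uniform(-0.1, 1.0, size=n_strains)
    M = beta * np.outer(sigma, growth)

    specific_strains = rng.permutation(n_strains)[:specific_effect_strains]
    for s in specific_strains:
        genes = rng.permutation(n_genes)[:specific_genes_per_strain]
        signs = rng.choice([-1.0, 1.0], size=specific_genes_per_strain)
        M[genes, s] += specific_amplitude * signs

    if noise_sd > 0:
        M = M + rng.normal(0.0, noise_sd, size=M.shape)
    pvalues = zscore_pvalues(M, noise_sd)

    matrix = ExpressionMatrix(gene_ids, sample_ids, M, pvalues=pvalues)
    truth = SyntheticTruth(
        seed=seed,
        generator_params=dict(
            n_genes=n_genes, n_strains=n_strains,
            n_signature_genes=n_signature_genes,
            signature_amplitude=signature_amplitude, beta=beta,
            specific_effect_strains=specific_effect_strains,
            specific_genes_per_strain=specific_genes_per_strain,
            specific_amplitude=specific_amplitude, noise_sd=noise_sd,
        ),
        planted_signature=sigma,
        planted_growth_rates=growth,
    )
    return matrix, truth


def make_cycle_series(
    n_genes: int = 400,
    n_timepoints: int = 14,
    interval_min: float = 30.0,
    cycle_duration_min: float = 390.0,
    amplitude_range: tuple[float, float] = (0.5, 2.0),
    n_harmonics: int = 3,
    harmonic_relative_amplitude: tuple[float, float] = (0.2, 0.6),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CellCycleSeries, SyntheticTruth]:
    """Periodic cycle time course as M-values relative to t = 0.

    Gene g oscillates with a random fundamental phase and amplitude
    ``A_g ~ Uniform(amplitude_range)`` plus ``n_harmonics - 1`` higher
    harmonics at random relative amplitudes; the t = 0 value is subtracted
    so the first column is exactly zero in the noiseless case and each row
    is periodic with the cycle duration.  Higher harmonics matter: with a
    single harmonic every mixture profile collapses into a two-dimensional
    gene-vector space and the mixture weights are not identifiable.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"C{i:04d}" for i in range(n_genes)]
    t = np.arange(n_timepoints) * interval_min
    base = rng.uniform(*amplitude_range, size=n_genes)
    values = np.zeros((n_genes, n_timepoints))
    for h in range(1, n_harmonics + 1):
        amp = base if h == 1 else base * rng.uniform(
            *harmonic_relative_amplitude, size=n_genes
        )
        phase = rng.uniform(0.0, 2.0 * np.pi, size=n_genes)
        values += amp[:, None] * np.cos(
            2.0 * np.pi * h * t[None, :] / cycle_duration_min - phase[:, None]
        )
    values = values - values[:, [0]]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    series = CellCycleSeries(
        gene_ids=gene_ids,
        timepoints_min=t,
        values=values,
        cycle_duration_min=cycle_duration_min,
    )
    truth = SyntheticTruth(
        seed=seed,
        generator_params=dict(
            n_genes=n_genes, n_timepoints=n_timepoints, interval_min=interval_min,
            cycle_duration_min=cycle_duration_min,
            amplitude_range=tuple(amplitude_range), n_harmonics=n_harmonics,
            harmonic_relative_amplitude=tuple(harmonic_relative_amplitude),
            noise_sd=noise_sd,
        ),
    )
    return series, truth


def make_mixture_target(
    series: CellCycleSeries,
    control_y: tuple[float, float, float, float] = (0.1, 0.9, 0.3, 0.2),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Target profile built as a known spline-weighted mixture of the series."""
    rng = np.random.default_rng(seed)
    control_x = np.asarray(DEFAULT_CONTROL_X_FRACTIONS) * series.cycle_duration_min
    weights = spline_weights(control_x, np.asarray(control_y, dtype=float),
                             series.timepoints_min)
    target = virtual_profile(series, weights)
    if noise_sd > 0:
        target = target + rng.normal(0.0, noise_sd, size=target.shape)
    truth = SyntheticTruth(
        seed=seed,
        generator_params=dict(control_y=tuple(control_y), noise_sd=noise_sd),
        true_control_y=np.asarray(control_y, dtype=float),
        true_weights=weights,
    )
    return target, truth


def make_enrichment_scenario(
    n_genes: int = 1000,
    target_set_size: int = 50,
    direct_effect: float = 1.5,
    contamination: float = 0.8,
    n_strains: int = 100,
    n_signature_genes: int = 300,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str], GeneSet, ExpressionMatrix, SyntheticTruth]:
    """Perturbation profile with a planted responsive set plus signature
    contamination, and a compendium sharing the same signature.

    The profile is ``direct_effect`` on the planted target set (drawn from
    genes outside the signature support, so the direct response and the
    growth-rate confounder are separable), plus ``contamination * sigma``,
    plus noise.  Returns (profile, pvalues, gene_ids, target GeneSet,
    compendium, truth).
    """
    if target_set_size > n_genes:
        raise ValueError("target_set_size exceeds n_genes")
    compendium, comp_truth = make_compendium(
        n_genes=n_genes,
        n_strains=n_strains,
        n_signature_genes=n_signature_genes,
        specific_effect_strains=max(1, n_strains // 5),
        noise_sd=noise_sd,
        seed=seed,
    )
    sigma = comp_truth.planted_signature
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    background = np.where(sigma == 0)[0]
    if background.size < target_set_size:
        raise ValueError("not enough signature-free genes for the target set")
    target_idx = rng.permutation(background)[:target_set_size]
    gene_ids = list(compendium.gene_ids)
    profile = contamination * sigma
    profile = profile.copy()
    profile[target_idx] += direct_effect
    if noise_sd > 0:
        profile = profile + rng.normal(0.0, noise_sd, size=n_genes)
    pvalues = zscore_pvalues(profile, noise_sd)
    gene_set = GeneSet(
        name="planted_target_set",
        members={gene_ids[i] for i in target_idx},
    )
    truth = SyntheticTruth(
        seed=seed,
        generator_params=dict(
            n_genes=n_genes, target_set_size=target_set_size,
            direct_effect=direct_effect, contamination=contamination,
            n_strains=n_strains, n_signature_genes=n_signature_genes,
            noise_sd=noise_sd,
        ),
        planted_signature=sigma,
        planted_growth_rates=comp_truth.planted_growth_rates,
        planted_target_set=sorted(gene_set.members),
    )
    return profile, pvalues, gene_ids, gene_set, compendium, truth


def make_growth_curves(
    doubling_time_min: float = 90.0,
    n_points: int = 20,
    interval_min: float = 15.0,
    noise_sd: float = 0.0,
    od_start: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential OD600 curve with optional multiplicative log-normal noise."""
    if doubling_time_min <= 0 or n_points < 2 or interval_min <= 0:
        raise ValueError("parameters must be positive (and n_points >= 2)")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * interval_min
    od = od_start * 2.0 ** (t / doubling_time_min)
    if noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, noise_sd, size=n_points))
    return t, od
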