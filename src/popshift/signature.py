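"""Extraction and removal of the recurrent slow-growth expression signature.

A compendium of deletion-strain profiles (genes x strains, log2 ratios
versus wild-type) typically shows a dominant shared expression pattern whose
per-strain strength tracks the strain's growth-rate defect.  This module
isolates that pattern as the first mode of the singular value decomposition

    M = U S V^T,      M^(1) = s1 * U1 V1^T,      M* = M - M^(1)

and supports scoring arbitrary profiles against the signature (inner
product with the unit gene-loading vector U1), correlating profiles with
the signature profile, and removing the signature from compendium columns
or from external profiles by Gram-Schmidt projection.

The model object follows the estimator convention: build ``SignatureSVD``
from an :class:`~popshift.io.ExpressionMatrix` and call :meth:`fit` to get a
:class:`SignatureResults` carrying the fitted quantities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "SignatureSVD",
    "SignatureResults",
    "extract_signature",
    "variance_explained",
    "similarity_scores",
    "correlate_with_signature",
    "remove_first_mode",
    "remove_signature_from_profile",
    "robust_strain_filter",
]


class SignatureSVD:
    """First-SVD-mode signature model for an expression compendium.

    Parameters
    ----------
    data
        Complete (imputed) genes x samples matrix of M-values.
    center
        If True, subtract column means before decomposing.  Off by default:
        M-values are already ratios against a common reference, and the
        projection score is then the plain inner product rather than a
        covariance.
    """

    def __init__(self, data: ExpressionMatrix, center: bool = False):
        if not data.is_complete():
            raise ValueError(
                "matrix contains missing values; run impute_missing / .impute() first"
            )
        if data.n_genes < 2 or data.n_samples < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        self.data = data
        self.center = center

    def fit(self) -> "SignatureResults":
        M = self.data.values.astype(float)
        if self.center:
            M = M - M.mean(axis=0, keepdims=True)
        if not np.any(M):
            raise ValueError("all-zero matrix has no signature")
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        u1, s1, v1 = U[:, 0], float(s[0]), Vt[0, :]
        # deterministic sign: the largest-|.| gene loading is positive
        pivot = int(np.argmax(np.abs(u1)))
        if u1[pivot] < 0:
            u1, v1 = -u1, -v1
        total = float(np.sum(s**2))
        variance_fraction = s1**2 / total if total > 0 else 0.0
        # signature profile: the largest-norm column of M^(1) = s1 u1 v1^T,
        # i.e. the column j* maximising |v1[j]| (ties -> smallest index)
        j_star = int(np.argmax(np.abs(v1)))
        signature_profile = s1 * v1[j_star] * u1
        return SignatureResults(
            u1=u1,
            v1=v1,
            s1=s1,
            singular_values=np.asarray(s, dtype=float),
            variance_fraction=variance_fraction,
            signature_profile=signature_profile,
            gene_ids=list(self.data.gene_ids),
            sample_ids=list(self.data.sample_ids),
            center=self.center,
        )


@dataclass
class SignatureResults:
    """Fitted first singular triplet and derived signature quantities."""

    u1: np.ndarray
    v1: np.ndarray
    s1: float
    singular_values: np.ndarray
    variance_fraction: float
    signature_profile: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    center: bool = False
    sign_rule: str = "max-abs-gene-loading-positive"
    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.u1 = np.asarray(self.u1, dtype=float)
        self.v1 = np.asarray(self.v1, dtype=float)
        self.signature_profile = np.asarray(self.signature_profile, dtype=float)
        for name, vec in (("u1", self.u1), ("v1", self.v1)):
            if abs(np.linalg.norm(vec) - 1.0) > 1e-8:
                raise ValueError(f"{name} is not unit-norm")
        if not 0.0 <= self.variance_fraction <= 1.0:
            raise ValueError("variance_fraction outside [0, 1]")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- scoring -----------------------------------------------------------

    def _align(self, gene_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Indices of shared genes in (model order, query order)."""
        model_idx, query_idx = [], []
        for qi, g in enumerate(gene_ids):
            mi = self._gene_index.get(g)
            if mi is not None:
                model_idx.append(mi)
                query_idx.append(qi)
        return np.asarray(model_idx, dtype=int), np.asarray(query_idx, dtype=int)

    def similarity_scores(self, m: ExpressionMatrix) -> np.ndarray:
        """Per-sample projection score <column, u1> over shared genes."""
        mi, qi = self._align(m.gene_ids)
        if mi.size == 0:
            raise ValueError("no genes shared between matrix and signature model")
        if mi.size < len(self.gene_ids):
            import logging

            logging.getLogger(__name__).warning(
                "similarity_scores: %d of %d model genes matched",
                mi.size, len(self.gene_ids),
            )
        return m.values[qi, :].T @ self.u1[mi]

    def correlate(self, m: ExpressionMatrix) -> np.ndarray:
        """Pearson r of each sample column with the signature profile."""
        mi, qi = self._align(m.gene_ids)
        if mi.size < 3:
            raise ValueError("need at least 3 shared genes for correlation")
        sig = self.signature_profile[mi]
        cols = m.values[qi, :]
        sig_c = sig - sig.mean()
        cols_c = cols - cols.mean(axis=0, keepdims=True)
        denom = np.linalg.norm(sig_c) * np.linalg.norm(cols_c, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (cols_c.T @ sig_c) / denom
        return r

    # -- removal -----------------------------------------------------------

    def remove_first_mode(self, m: ExpressionMatrix) -> ExpressionMatrix:
        """Return the transformed compendium M* = M - s1 * U1 V1^T."""
        if m.gene_ids != self.gene_ids or m.sample_ids != self.sample_ids:
            raise ValueError("matrix ids do not match the ids the model was fitted on")
        M = m.values.astype(float)
        if self.center:
            M = M - m.values.mean(axis=0, keepdims=True)
        rank1 = self.s1 * np.outer(self.u1, self.v1)
        return ExpressionMatrix(
            gene_ids=list(m.gene_ids),
            sample_ids=list(m.sample_ids),
            values=M - rank1,
            pvalues=None if m.pvalues is None else m.pvalues.copy(),
        )

    def remove_from_profile(
        self, profile: np.ndarray, gene_ids: list[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Gram-Schmidt removal of the signature from an external profile.

        Over the genes shared with the model, u1 is re-normalised on the
        shared subset and the profile's projection onto it is subtracted;
        unmatched genes pass through unchanged.  Returns the transformed
        profile (same order/length as the input) and a boolean mask of the
        genes that were shared (False = passed through untouched).
        """
        profile = np.asarray(profile, dtype=float)
        if profile.ndim != 1 or profile.size != len(gene_ids):
            raise ValueError("profile length does not match gene_ids")
        mi, qi = self._align(list(gene_ids))
        if mi.size == 0:
            raise ValueError("no genes shared between profile and signature model")
        if mi.size < 3:
            raise ValueError("need at least 3 shared genes")
        u_sub = self.u1[mi]
        u_hat = u_sub / np.linalg.norm(u_sub)
        out = profile.copy()
        out[qi] = profile[qi] - (profile[qi] @ u_hat) * u_hat
        shared = np.zeros(profile.size, dtype=bool)
        shared[qi] = True
        return out, shared

    # -- persistence & reporting -------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "u1": self.u1.tolist(),
            "sample_ids": self.sample_ids,
            "v1": self.v1.tolist(),
            "s1": self.s1,
            "singular_values": self.singular_values.tolist(),
            "variance_fraction": self.variance_fraction,
            "signature_profile": self.signature_profile.tolist(),
            "center": self.center,
            "sign_rule": self.sign_rule,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureResults":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            u1=np.asarray(d["u1"], dtype=float),
            v1=np.asarray(d["v1"], dtype=float),
            s1=float(d["s1"]),
            singular_values=np.asarray(d.get("singular_values", [d["s1"]]), dtype=float),
            variance_fraction=float(d["variance_fraction"]),
            signature_profile=np.asarray(d["signature_profile"], dtype=float),
            gene_ids=list(d["gene_ids"]),
            sample_ids=list(d["sample_ids"]),
            center=bool(d.get("center", False)),
            sign_rule=d.get("sign_rule", "max-abs-gene-loading-positive"),
        )

    def summary(self) -> str:
        lines = [
            "Recurrent-signature SVD fit",
            "===========================",
            f"genes: {len(self.gene_ids)}   samples: {len(self.sample_ids)}",
            f"centered: {self.center}",
            f"first singular value s1: {self.s1:.6g}",
            f"variance explained by first mode: {100 * self.variance_fraction:.1f}%",
            f"sign rule: {self.sign_rule}",
            "top gene loadings (|u1|):",
        ]
        top = np.argsort(-np.abs(self.u1))[:5]
        for i in top:
            lines.append(f"  {self.gene_ids[i]:>12s}  {self.u1[i]:+.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface


def extract_signature(m: ExpressionMatrix, center: bool = False) -> SignatureResults:
    """Fit the first-SVD-mode signature of a compendium."""
    return SignatureSVD(m, center=center).fit()


def variance_explained(model: SignatureResults) -> float:
    """Fraction of total variance carried by the first mode (s1^2 / sum sk^2)."""
    return model.variance_fraction


def similarity_scores(m: ExpressionMatrix, model: SignatureResults) -> np.ndarray:
    return model.similarity_scores(m)


def correlate_with_signature(m: ExpressionMatrix, model: SignatureResults) -> np.ndarray:
    return model.correlate(m)


def remove_first_mode(m: ExpressionMatrix, model: SignatureResults) -> ExpressionMatrix:
    return model.remove_first_mode(m)


def remove_signature_from_profile(
    profile: np.ndarray, gene_ids: list[str], model: SignatureResults
) -> tuple[np.ndarray, np.ndarray]:
    return model.remove_from_profile(profile, gene_ids)


def robust_strain_filter(
    m: ExpressionMatrix,
    fold_threshold: float = 1.7,
    p_threshold: float = 0.05,
    min_transcripts: int = 3,
) -> list[str]:
    """Samples with strictly more than ``min_transcripts`` responsive genes.

    A gene is responsive in a sample when |M| > log2(fold_threshold) and
    p < p_threshold (both strict, matching the robust-change criterion).
    """
    if m.pvalues is None:
        raise ValueError("robust_strain_filter requires a p-value matrix")
    m_cut = math.log2(fold_threshold)
    qualifies = (np.abs(m.values) > m_cut) & (m.pvalues < p_threshold)
    counts = qualifies.sum(axis=0)
    return [sid for sid, c in zip(m.sample_ids, counts) if c > min_transcripts]
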