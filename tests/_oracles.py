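"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (loops, enumeration, power iteration)
kept separate from the package so they share no code path with it.
"""

from __future__ import annotations

from math import comb

import numpy as np


def knn_impute_bruteforce(values: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive-distance KNN row imputation, mirroring the documented
    definition: RMS distance over co-observed columns, k nearest rows,
    per-column mean of their observed values."""
    values = np.array(values, dtype=float)
    n_rows, n_cols = values.shape
    obs = ~np.isnan(values)
    col_means = np.nanmean(values, axis=0)
    out = values.copy()
    for i in range(n_rows):
        if obs[i].all():
            continue
        cand = []
        for j in range(n_rows):
            if j == i:
                continue
            both = [c for c in range(n_cols) if obs[i, c] and obs[j, c]]
            if not both:
                continue
            d = np.sqrt(
                sum((values[i, c] - values[j, c]) ** 2 for c in both) / len(both)
            )
            cand.append((d, j))
        cand.sort(key=lambda t: (t[0], t[1]))
        nn = [j for _, j in cand[:k]]
        for c in range(n_cols):
            if obs[i, c]:
                continue
            vals = [values[j, c] for j in nn if obs[j, c]]
            out[i, c] = float(np.mean(vals)) if vals else col_means[c]
    return out


def first_triplet_power_iteration(
    M: np.ndarray, tol: float = 1e-14, max_iter: int = 200_000
) -> tuple[np.ndarray, float, np.ndarray]:
    """First singular triplet by power iteration on M^T M."""
    M = np.asarray(M, dtype=float)
    rng = np.random.default_rng(12345)
    v = rng.normal(size=M.shape[1])
    v /= np.linalg.norm(v)
    A = M.T @ M
    for _ in range(max_iter):
        v_new = A @ v
        norm = np.linalg.norm(v_new)
        if norm == 0:
            break
        v_new /= norm
        if np.linalg.norm(v_new - v) < tol and _ > 10:
            v = v_new
            break
        v = v_new
    s1 = float(np.linalg.norm(M @ v))
    u = M @ v / s1 if s1 > 0 else np.zeros(M.shape[0])
    return u, s1, v


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    denom = comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += comb(K, j) * comb(N - K, n - j)
    return total / denom


class SlotOracle:
    """Naive list-of-masses reimplementation of the circular slot model."""

    def __init__(self, n_slots=77, barrier_after=14, recovery=25,
                 one_n_last=28, release_mode="cohort"):
        self.n = n_slots
        self.barrier_after = barrier_after  # 1-based: barrier between this and next
        self.recovery = recovery
        self.one_n_last = one_n_last
        self.release_mode = release_mode
        self.slots = [1.0 / n_slots] * n_slots  # index 0 == slot 1

    def step(self, barrier: bool, draining: bool) -> None:
        old = self.slots
        n = self.n
        new = [0.0] * n
        for i in range(n):
            new[(i + 1) % n] = old[i]
        b = self.barrier_after - 1
        nxt = (b + 1) % n
        if barrier:
            new[nxt] = 0.0
            new[b] = old[b] + old[b - 1]
        elif draining:
            quota = 1.0 / n
            crossing = min(old[b], quota)
            new[nxt] = crossing
            new[b] = (old[b] - crossing) + old[b - 1]
        self.slots = new

    def run(self, t_end: int, shock_at: int = 0):
        """Return per-minute (densities, one_n_fractions) including t = 0."""
        densities = [list(self.slots)]
        fractions = [sum(self.slots[: self.one_n_last])]
        for t in range(t_end):
            if shock_at >= 0:
                barrier = shock_at <= t < shock_at + self.recovery
                draining = (self.release_mode == "drain"
                            and t >= shock_at + self.recovery)
            else:
                barrier = draining = False
            self.step(barrier, draining)
            densities.append(list(self.slots))
            fractions.append(sum(self.slots[: self.one_n_last]))
        return np.asarray(densities), np.asarray(fractions)


def lagrange_cubic(x: np.ndarray, y: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Evaluate the unique cubic through 4 points by the Lagrange formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    q = np.asarray(q, dtype=float)
    assert x.size == 4
    out = np.zeros_like(q)
    for i in range(4):
        li = np.ones_like(q)
        for j in range(4):
            if j != i:
                li *= (q - x[j]) / (x[i] - x[j])
        out += y[i] * li
    return out


def spline_weights_oracle(x, y, timepoints):
    """Lagrange-cubic evaluation followed by clamp-to-zero and normalisation."""
    w = lagrange_cubic(x, y, timepoints)
    w = np.where(w < 0, 0.0, w)
    return w / w.sum()
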