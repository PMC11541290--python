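"""Positive matrix factorization (PMF) for pollution source apportionment.

A sample x species concentration matrix A (n x m) is decomposed into
nonnegative factor contributions C (n x k) and factor profiles B (m x k),

    A ~ C B^T + D,

by minimising the uncertainty-weighted objective

    Q_true = sum_ij (d_ij / s_ij)^2,    d_ij = a_ij - (C B^T)_ij,

where s_ij are per-cell measurement uncertainties.  The robust variant
down-weights extreme scaled residuals (|d/s| > 4) EPA-style, replacing
their squared contribution with 4|d/s|.

Measurement uncertainties follow the detection-limit convention: when a
concentration exceeds its minimum detection limit (MDL) — or the species
standard deviation where no MDL is reported —

    s = Cs/10 + limit/3,

otherwise s = 5*limit/6.

The solver is an uncertainty-weighted multiplicative-update scheme
(weighted nonnegative least squares on d/s) with multi-start restarts; the
run with the least Q_robust is retained, matching the receptor-modelling
practice of repeated random-seed runs.  Factor order and scale are not
identified; recovery comparisons must align factors first
(:func:`align_factors`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EPS = 1e-12
#: Scaled-residual magnitude beyond which Q_robust down-weights a cell.
ROBUST_CUTOFF = 4.0


class Uncertainty(NamedTuple):
    value: float
    branch: str  # "above_limit" | "below_limit"


def compute_uncertainty(cs: float, limit: float, limit_kind: str = "MDL") -> Uncertainty:
    """Per-cell measurement uncertainty from a concentration and its MDL/SD.

    Strictly above the limit: ``Cs/10 + limit/3``; at or below it:
    ``5*limit/6``.  ``limit_kind`` is bookkeeping only ("MDL" or "SD") —
    the arithmetic is identical, the flag records provenance.
    """
    if limit_kind not in ("MDL", "SD"):
        raise ValueError(f"limit_kind must be 'MDL' or 'SD', got {limit_kind!r}")
    if not limit > 0:
        raise ValueError(f"detection limit / SD must be > 0, got {limit}")
    if cs < 0:
        raise ValueError(f"concentration must be >= 0, got {cs}")
    if cs > limit:
        return Uncertainty(cs / 10.0 + limit / 3.0, "above_limit")
    return Uncertainty(5.0 * limit / 6.0, "below_limit")


def build_uncertainty_matrix(
    A: np.ndarray, limits: np.ndarray, limit_kinds=None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised uncertainty matrix for A (n x m) given per-species limits.

    Returns (S, branches) where branches is an object array of provenance
    flags per cell.
    """
    A = np.asarray(A, float)
    limits = np.broadcast_to(np.asarray(limits, float), A.shape)
    if np.any(limits <= 0):
        raise ValueError("all detection limits / SDs must be > 0")
    above = A > limits
    S = np.where(above, A / 10.0 + limits / 3.0, 5.0 * limits / 6.0)
    branches = np.where(above, "above_limit", "below_limit")
    return S, branches


def impute_missing(A: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill missing (NaN) concentration cells before fitting.

    Missing concentrations are replaced by the species median of the
    observed cells; their uncertainty is inflated to 4x the species median
    uncertainty so imputed cells barely constrain the fit.  Returns
    (A_filled, S_filled, imputed_mask); raises if a species has no
    observed values at all.
    """
    A = np.array(A, float)
    S = np.array(S, float)
    mask = ~np.isfinite(A)
    for j in range(A.shape[1]):
        col = mask[:, j]
        if not col.any():
            continue
        if col.all():
            raise ValueError(f"species column {j} has no observed values")
        A[col, j] = np.median(A[~col, j])
        S[col, j] = 4.0 * np.median(S[~col, j])
    return A, S, mask


def q_value(A, S, B, C, mode: str = "true") -> float:
    """PMF objective: sum of squared uncertainty-scaled residuals.

    ``mode="robust"`` replaces the squared contribution of cells with
    |d/s| > 4 by 4|d/s| (square of the EPA-convention scaled residual
    sqrt(4|d/s|)).
    """
    A, S, B, C = (np.asarray(x, float) for x in (A, S, B, C))
    if A.shape != S.shape or C.shape[0] != A.shape[0] or B.shape[0] != A.shape[1] \
            or B.shape[1] != C.shape[1]:
        raise ValueError(f"shape mismatch: A{A.shape} S{S.shape} B{B.shape} C{C.shape}")
    r = (A - C @ B.T) / S
    r2 = r ** 2
    if mode == "true":
        return float(np.sum(r2))
    if mode == "robust":
        extreme = np.abs(r) > ROBUST_CUTOFF
        r2 = np.where(extreme, ROBUST_CUTOFF * np.abs(r), r2)
        return float(np.sum(r2))
    raise ValueError(f"mode must be 'true' or 'robust', got {mode!r}")


@dataclass
class PmfSolution:
    """One fitted factorization (best of the multi-start runs)."""

    B: np.ndarray          # m species x k factors, >= 0
    C: np.ndarray          # n samples x k factors, >= 0
    D: np.ndarray          # residuals A - C B^T
    q_true: float
    q_robust: float
    converged: bool
    seed: int
    n_iterations: int
    q_path: np.ndarray     # Q_true per iteration of the winning run

    @property
    def k(self) -> int:
        return self.B.shape[1]

    def reconstruction(self) -> np.ndarray:
        return self.C @ self.B.T


def _wnnls_sweep(A, W, B, C):
    """One exact block-coordinate pass: solve the weighted nonnegative
    least-squares problem row-wise for C given B, then for B given C."""
    from scipy.optimize import nnls

    n, m = A.shape
    for i in range(n):
        w = np.sqrt(W[i])
        C[i], _ = nnls(B * w[:, None], A[i] * w)
    for j in range(m):
        w = np.sqrt(W[:, j])
        B[j], _ = nnls(C * w[:, None], A[:, j] * w)
    return B, C


def _single_run(A, S, k, rng, max_iter, tol, polish_sweeps):
    n, m = A.shape
    W = 1.0 / S ** 2
    scale = np.sqrt(A.mean() / k)
    C = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    B = rng.uniform(0.1, 1.0, size=(m, k)) * scale
    WA = W * A
    q_prev = q_value(A, S, B, C, "true")
    q_path = [q_prev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        R = C @ B.T
        C *= (WA @ B) / ((W * R) @ B + _EPS)
        R = C @ B.T
        B *= (WA.T @ C) / ((W * R).T @ C + _EPS)
        q = q_value(A, S, B, C, "true")
        q_path.append(q)
        if q_prev > 0 and abs(q_prev - q) / max(q_prev, _EPS) < tol:
            converged = True
            break
        q_prev = q
    # exact alternating weighted-NNLS polish: multiplicative updates slow to
    # a crawl near degenerate optima; each NNLS block solve is an exact
    # minimiser, so Q stays monotone and interior exact factorizations are
    # driven to machine precision
    for _ in range(polish_sweeps):
        B, C = _wnnls_sweep(A, W, B, C)
        q = q_value(A, S, B, C, "true")
        q_path.append(q)
        if q_prev > 0 and abs(q_prev - q) / max(q_prev, _EPS) < tol:
            converged = True
            break
        q_prev = q
    return B, C, np.array(q_path), converged, it


def pmf_fit(
    A,
    S,
    k: int,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-8,
    polish_sweeps: int = 30,
) -> tuple[PmfSolution, pd.DataFrame]:
    """Multi-start uncertainty-weighted factorization.

    Each start draws random nonnegative B, C (from a child seed spawned
    deterministically from ``seed``) and refines them by multiplicative
    updates until the relative Q_true change drops below ``tol`` or
    ``max_iter`` iterations, followed by up to ``polish_sweeps`` exact
    alternating weighted-NNLS passes.  The run with the least Q_robust wins; the
    per-run Q table is returned alongside for factor-count diagnostics.
    """
    A = np.asarray(A, float)
    S = np.asarray(S, float)
    if np.any(A < 0):
        raise ValueError("concentration matrix must be nonnegative")
    if np.any(S <= 0):
        raise ValueError("uncertainty matrix must be strictly positive")
    n, m = A.shape
    if not 1 <= k <= m:
        raise ValueError(f"factor count k={k} outside [1, n_species={m}]")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    master = np.random.SeedSequence(seed)
    runs = []
    best = None
    for run_idx, child in enumerate(master.spawn(n_starts)):
        rng = np.random.default_rng(child)
        B, C, q_path, converged, n_iter = _single_run(A, S, k, rng, max_iter, tol, polish_sweeps)
        q_true = q_path[-1]
        q_robust = q_value(A, S, B, C, "robust")
        runs.append({"run": run_idx, "q_true": q_true, "q_robust": q_robust,
                     "converged": converged, "n_iterations": n_iter})
        if best is None or q_robust < best[0]:
            best = (q_robust, q_true, B, C, converged, run_idx, n_iter, q_path)
    q_robust, q_true, B, C, converged, run_idx, n_iter, q_path = best
    if not any(r["converged"] for r in runs):
        logger.warning("pmf_fit: no start converged within %d iterations "
                       "(best-effort solution returned)", max_iter)
    solution = PmfSolution(B=B, C=C, D=A - C @ B.T, q_true=q_true,
                           q_robust=q_robust, converged=converged,
                           seed=seed, n_iterations=n_iter, q_path=q_path)
    return solution, pd.DataFrame(runs)


def select_n_factors(
    A, S, k_range=range(3, 7), n_starts: int = 20, seed: int = 0, **fit_kwargs
) -> pd.DataFrame:
    """Per-k diagnostics over a factor-count range.

    Reports Q_robust, Q_true, their ratio and the mean per-species R² for
    each candidate k.  No automatic choice is made — the analyst picks from
    the diagnostics (lowest Q_robust/Q_true, highest R²), as is standard
    for receptor models.
    """
    rows = []
    for k in k_range:
        try:
            sol, _ = pmf_fit(A, S, k, n_starts=n_starts, seed=seed + k, **fit_kwargs)
        except Exception as exc:
            logger.warning("select_n_factors: k=%d failed: %s", k, exc)
            continue
        r2 = species_r2(A, sol)
        rows.append({"k": k, "q_robust": sol.q_robust, "q_true": sol.q_true,
                     "q_ratio": sol.q_robust / sol.q_true if sol.q_true > 0 else 1.0,
                     "mean_r2": float(np.nanmean(r2)),
                     "min_r2": float(np.nanmin(r2))})
    return pd.DataFrame(rows)


def profile_percentages(B) -> np.ndarray:
    """Percent of each species mass attributed to each factor.

    percent[j, k] = 100 * b_jk / sum_k b_jk; every species row sums to 100.
    """
    B = np.asarray(B, float)
    if np.any(B < 0):
        raise ValueError("profile matrix must be nonnegative")
    totals = B.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"species rows {zero.tolist()} are all zero; "
                         "percentages undefined")
    return 100.0 * B / totals[:, None]


def contribution_rates(C, B, mode: str = "mass") -> np.ndarray:
    """Percent share of each factor in the total source contribution.

    Default ``mode="mass"``: rate_k proportional to the reconstructed mass
    sum_i c_ik * sum_j b_jk.  ``mode="mean"`` instead uses the mean
    normalised contribution per factor (profiles scaled to unit mass).
    Degenerate all-zero factors get rate 0 with a warning.
    """
    B = np.asarray(B, float)
    C = np.asarray(C, float)
    if mode == "mass":
        mass = C.sum(axis=0) * B.sum(axis=0)
    elif mode == "mean":
        mass = C.mean(axis=0) * B.sum(axis=0)
    else:
        raise ValueError(f"mode must be 'mass' or 'mean', got {mode!r}")
    total = mass.sum()
    if total == 0:
        raise ValueError("all factors are zero; contribution rates undefined")
    if np.any(mass == 0):
        logger.warning("contribution_rates: factor(s) %s carry zero mass",
                       np.flatnonzero(mass == 0).tolist())
    return 100.0 * mass / total


def species_r2(A, solution: PmfSolution) -> np.ndarray:
    """Squared Pearson correlation between observed and reconstructed
    concentrations, per species.

    NaN where the observed column has zero variance (undefined); 0 where
    only the reconstruction is constant (no per-sample information).
    """
    A = np.asarray(A, float)
    recon = solution.reconstruction()
    out = np.empty(A.shape[1])
    for j in range(A.shape[1]):
        obs, pred = A[:, j], recon[:, j]
        if np.std(obs) == 0:
            out[j] = np.nan
        elif np.std(pred) == 0:
            out[j] = 0.0
        else:
            out[j] = np.corrcoef(obs, pred)[0, 1] ** 2
    return out


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def align_factors(B_ref: np.ndarray, B_other: np.ndarray) -> np.ndarray:
    """Greedy permutation matching columns of ``B_other`` to ``B_ref`` by
    maximum cosine similarity.

    Returns ``perm`` such that ``B_other[:, perm[j]]`` corresponds to
    ``B_ref[:, j]``; each factor is used once.
    """
    B_ref = np.asarray(B_ref, float)
    B_other = np.asarray(B_other, float)
    k = B_ref.shape[1]
    if B_other.shape[1] != k:
        raise ValueError("factor counts differ")
    sim = np.array([[_cosine(B_ref[:, i], B_other[:, j]) for j in range(k)]
                    for i in range(k)])
    perm = np.full(k, -1)
    used: set[int] = set()
    for _ in range(k):
        masked = sim.copy()
        masked[perm >= 0, :] = -np.inf
        masked[:, list(used)] = -np.inf
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        perm[i] = j
        used.add(int(j))
    return perm


def bootstrap_pmf(
    A,
    S,
    base_solution: PmfSolution,
    n_boot: int = 100,
    block_len: int = 6,
    seed: int = 0,
    n_starts: int = 4,
    map_threshold: float = 0.6,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Block-bootstrap reproducibility of the factor profiles.

    Rows of (A, S) are resampled in contiguous blocks of ``block_len``
    (preserving short-range temporal correlation), the model is refit, and
    each bootstrap factor is mapped to the base factor with the highest
    profile Pearson correlation provided it exceeds ``map_threshold``;
    otherwise it stays unmapped.  Returns, per base factor, the percent of
    bootstrap runs in which some factor mapped to it, plus refit-failure
    and unmapped counts.  Low mapped fractions flag an unstable solution.
    """
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20 for a meaningful mapping table")
    A = np.asarray(A, float)
    S = np.asarray(S, float)
    n, _ = A.shape
    k = base_solution.k
    rng = np.random.default_rng(seed)
    mapped = np.zeros(k, int)
    unmapped_total = 0
    failures = 0
    n_blocks = int(np.ceil(n / block_len))
    for b in range(n_boot):
        starts = rng.integers(0, max(n - block_len, 1), size=n_blocks)
        idx = np.concatenate([np.arange(s, s + block_len) for s in starts])[:n]
        try:
            sol, _ = pmf_fit(A[idx], S[idx], k, n_starts=n_starts,
                             seed=seed * 100003 + b, max_iter=max_iter)
        except Exception as exc:
            logger.warning("bootstrap_pmf: refit %d failed: %s", b, exc)
            failures += 1
            continue
        hit = np.zeros(k, bool)
        for j in range(k):
            cors = [abs(np.corrcoef(base_solution.B[:, i], sol.B[:, j])[0, 1])
                    if np.std(sol.B[:, j]) > 0 and np.std(base_solution.B[:, i]) > 0
                    else 0.0
                    for i in range(k)]
            best = int(np.argmax(cors))
            if cors[best] >= map_threshold:
                hit[best] = True
            else:
                unmapped_total += 1
        mapped += hit
    n_ok = n_boot - failures
    return pd.DataFrame({
        "factor": np.arange(k),
        "mapped_fraction_pct": 100.0 * mapped / max(n_ok, 1),
        "n_boot": n_boot,
        "n_failed": failures,
        "n_unmapped_total": unmapped_total,
    })
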