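"""Muscle-synergy extraction and activation-timing metrics.

Non-negative matrix factorization E ~= W A uses Lee-Seung multiplicative
updates for the squared Frobenius objective, with 50 random restarts, a
maximum of 1000 iterations per restart, and a 1e-6 relative-decrease
tolerance on the objective; the restart with the lowest reconstruction error
is kept. The W/A scale ambiguity is resolved by max-normalizing W columns
(A rescaled inversely, product invariant), which makes the timing metrics
scale-free.

FWHM of a 100-sample activation profile is the count of samples above half
of the min-subtracted maximum; CoA is the angle of the circular first
moment of the profile over the gait cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

_EPS = 1e-12


@dataclass
class SynergyModel:
    """Muscle weightings W (muscles x k) and activation profiles A (k x N)."""

    W: np.ndarray
    A: np.ndarray
    vaf: float
    k: int
    rep_errors: np.ndarray = field(default_factory=lambda: np.empty(0))
    muscles: tuple[str, ...] = ()

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.A

    def activation_strides(self, samples_per_stride: int = 100) -> np.ndarray:
        """(k, n_strides, samples) view of the activation profiles."""
        n = self.A.shape[1] // samples_per_stride
        return self.A[:, : n * samples_per_stride].reshape(self.k, n, samples_per_stride)

    def summary(self) -> str:
        lines = [f"SynergyModel: k={self.k}, VAF={self.vaf:.4f}"]
        for j in range(self.k):
            top = np.argsort(self.W[:, j])[::-1][:3]
            names = [self.muscles[i] if self.muscles else str(i) for i in top]
            lines.append(f"  synergy {j + 1}: top muscles {', '.join(names)}")
        return "\n".join(lines)


def _vaf(E: np.ndarray, W: np.ndarray, A: np.ndarray, normE2: float) -> float:
    resid = E - W @ A
    return 1.0 - float(np.sum(resid**2)) / normE2


def _mu_factorize(
    E: np.ndarray, W: np.ndarray, A: np.ndarray,
    max_iter: int, tol: float, normE2: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Multiplicative updates from a given init; returns (W, A, sq. error)."""
    obj_prev = np.inf
    for _ in range(max_iter):
        # W <- W * (E A^T) / (W A A^T)
        AAt = A @ A.T
        W *= (E @ A.T) / np.maximum(W @ AAt, _EPS)
        # A <- A * (W^T E) / (W^T W A)
        WtW = W.T @ W
        WtE = W.T @ E
        A *= WtE / np.maximum(WtW @ A, _EPS)
        # objective via the trace identity (no full reconstruction needed)
        obj = normE2 - 2.0 * float(np.sum(A * WtE)) + float(np.sum((W.T @ W) * (A @ A.T)))
        if obj_prev < np.inf and obj_prev > 0:
            if (obj_prev - obj) / obj_prev < tol:
                obj_prev = obj
                break
        obj_prev = obj
    return W, A, max(obj_prev, 0.0)


def _normalize_scale(W: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scale = np.maximum(W.max(axis=0), _EPS)
    return W / scale, A * scale[:, None]


def nnmf(
    E: np.ndarray,
    k: int,
    restarts: int = 50,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    muscles: Sequence[str] = (),
    inits: Optional[list[tuple[np.ndarray, np.ndarray]]] = None,
) -> SynergyModel:
    """Best-of-``restarts`` Lee-Seung factorization of a nonnegative E.

    ``inits`` may supply extra (W0, A0) warm starts appended to the random
    restarts (used by the k-selection sweep to keep VAF monotone in k).
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("E must be nonnegative")
    if k > E.shape[0]:
        raise ValueError(f"k={k} exceeds number of muscles {E.shape[0]}")
    if np.any(E.max(axis=1) <= 0):
        raise ValueError("E contains an all-zero muscle row")
    rng = np.random.default_rng(seed)
    normE2 = float(np.sum(E**2))
    scale = np.sqrt(E.mean() / k)

    best: Optional[tuple[np.ndarray, np.ndarray, float]] = None
    errors = []
    starts: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(restarts):
        W0 = scale * rng.uniform(_EPS, 1.0, size=(E.shape[0], k))
        A0 = scale * rng.uniform(_EPS, 1.0, size=(k, E.shape[1]))
        starts.append((W0, A0))
    if inits:
        starts.extend((np.array(w, float), np.array(a, float)) for w, a in inits)
    for W0, A0 in starts:
        W, A, err = _mu_factorize(E, W0, A0, max_iter, tol, normE2)
        errors.append(err)
        if best is None or err < best[2]:
            best = (W, A, err)
    W, A, err = best  # type: ignore[misc]
    W, A = _normalize_scale(W, A)
    return SynergyModel(
        W=W, A=A, vaf=_vaf(E, W, A, normE2), k=k,
        rep_errors=np.asarray(errors), muscles=tuple(muscles),
    )


def select_k(
    E: np.ndarray,
    vaf_min: float = 0.85,
    k_max: int = 11,
    restarts: int = 50,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[int, dict[int, SynergyModel]]:
    """Smallest k whose VAF reaches ``vaf_min``.

    The best factorization at k-1 (padded with one small random component)
    is reused as a warm start at k, which keeps the VAF curve monotone
    non-decreasing. Returns (k, models fitted along the sweep).
    """
    if not 0.0 < vaf_min < 1.0:
        raise ValueError("vaf_min must be in (0, 1)")
    rng = np.random.default_rng(seed + 1)
    models: dict[int, SynergyModel] = {}
    prev: Optional[SynergyModel] = None
    k_max = min(k_max, np.asarray(E).shape[0])
    for k in range(1, k_max + 1):
        inits = None
        if prev is not None:
            W0 = np.hstack([prev.W, 0.01 * rng.uniform(size=(prev.W.shape[0], 1))])
            A0 = np.vstack([prev.A, 0.01 * rng.uniform(size=(1, prev.A.shape[1]))])
            inits = [(W0, A0)]
        m = nnmf(E, k, restarts=restarts, max_iter=max_iter, tol=tol,
                 seed=seed + k, inits=inits)
        models[k] = m
        prev = m
        if m.vaf >= vaf_min:
            return k, models
    raise ValueError(
        f"no k <= {k_max} reaches VAF {vaf_min:.2f} "
        f"(best {max(m.vaf for m in models.values()):.3f})"
    )


def fit_fixed_W(
    blocks: dict[tuple[str, str], np.ndarray],
    k: int,
    **nnmf_kwargs,
) -> tuple[SynergyModel, dict[tuple[str, str], np.ndarray]]:
    """One factorization of the column-concatenated blocks -> fixed W.

    Muscle weightings are shared across all condition x time-point blocks
    (block order preserved); the activation matrix is sliced back per block.
    """
    keys = list(blocks.keys())
    mats = [np.asarray(blocks[key], dtype=float) for key in keys]
    n_rows = {m.shape[0] for m in mats}
    if len(n_rows) != 1:
        raise ValueError("blocks disagree on muscle count")
    E = np.concatenate(mats, axis=1)
    model = nnmf(E, k, **nnmf_kwargs)
    out: dict[tuple[str, str], np.ndarray] = {}
    start = 0
    for key, m in zip(keys, mats):
        out[key] = model.A[:, start:start + m.shape[1]]
        start += m.shape[1]
    return model, out


# ---------------------------------------------------------------------------
# Activation-timing metrics
# ---------------------------------------------------------------------------

def fwhm(profile: np.ndarray) -> int:
    """Samples above half of the min-subtracted maximum (0 for flat input)."""
    p = np.asarray(profile, dtype=float)
    lo, hi = p.min(), p.max()
    if hi - lo <= 0:
        return 0
    return int(np.sum(p - lo > 0.5 * (hi - lo)))


def coa(profile: np.ndarray) -> float:
    """Center-of-activity angle (rad in [0, 2pi)) of a cyclic profile.

    The profile is treated as a mass distribution on the circle with sample
    t at angle 2*pi*t/n; the CoA is the angle of the resultant vector.
    """
    p = np.asarray(profile, dtype=float)
    theta = 2.0 * np.pi * np.arange(p.size) / p.size
    s, c = float(np.sum(p * np.sin(theta))), float(np.sum(p * np.cos(theta)))
    if np.hypot(s, c) < 1e-12 * max(float(np.sum(np.abs(p))), 1e-300):
        raise ValueError("center of activity undefined: zero resultant")
    return float(np.arctan2(s, c) % (2.0 * np.pi))


def fwhm_per_stride(activations: np.ndarray, samples_per_stride: int = 100) -> np.ndarray:
    """FWHM per stride for one activation row; thresholding is per stride."""
    a = np.asarray(activations, dtype=float).ravel()
    n = a.size // samples_per_stride
    return np.array([
        fwhm(a[i * samples_per_stride:(i + 1) * samples_per_stride])
        for i in range(n)
    ], dtype=float)


def coa_per_stride(activations: np.ndarray, samples_per_stride: int = 100) -> np.ndarray:
    a = np.asarray(activations, dtype=float).ravel()
    n = a.size // samples_per_stride
    return np.array([
        coa(a[i * samples_per_stride:(i + 1) * samples_per_stride])
        for i in range(n)
    ])


@dataclass
class ActivationTiming:
    """Across-stride FWHM (arithmetic mean, % cycle) and CoA (circular mean,
    rad) per synergy."""

    fwhm: np.ndarray
    coa: np.ndarray


def activation_timing(A: np.ndarray, samples_per_stride: int = 100) -> ActivationTiming:
    from .stats import circ_mean

    A = np.atleast_2d(np.asarray(A, dtype=float))
    fw = np.array([fwhm_per_stride(row, samples_per_stride).mean() for row in A])
    ca = np.array([circ_mean(coa_per_stride(row, samples_per_stride)) for row in A])
    return ActivationTiming(fwhm=fw, coa=ca)


def cosine_similarity_matrix(Wa: np.ndarray, Wb: np.ndarray) -> np.ndarray:
    a = Wa / np.maximum(np.linalg.norm(Wa, axis=0), _EPS)
    b = Wb / np.maximum(np.linalg.norm(Wb, axis=0), _EPS)
    return a.T @ b


def match_synergies(Wa: np.ndarray, Wb: np.ndarray) -> np.ndarray:
    """Permutation p maximizing summed cosine similarity of W columns,
    such that Wb[:, p[j]] matches Wa[:, j] (Hungarian assignment,
    deterministic tie-break by column index)."""
    sim = cosine_similarity_matrix(Wa, Wb)
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(Wa.shape[1], dtype=int)
    perm[rows] = cols
    return perm


def matched_cosines(Wa: np.ndarray, Wb: np.ndarray) -> np.ndarray:
    """Cosine similarity of each Wa column with its matched Wb column."""
    sim = cosine_similarity_matrix(Wa, Wb)
    perm = match_synergies(Wa, Wb)
    return sim[np.arange(Wa.shape[1]), perm]
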