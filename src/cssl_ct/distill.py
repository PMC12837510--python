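"""Feature-distillation objectives: Wasserstein-style moment matching (WKD)
and batch knowledge ensembling (BKE).

WKD summarizes a batch of token features P ∈ R^{B×T×E} by channel-wise
Gaussian statistics — the mean vector μ and the standard-deviation vector δ
(the square root of the diagonal of the population covariance, divisor
d = B·T) — and penalizes the distance between teacher and student summaries:

    L_WKD = γ·‖μ_T − μ_S‖₂ + ‖δ_T − δ_S‖₂ ,

with unsquared Euclidean norms and a mean–covariance ratio γ.  Diagonal
covariance keeps the estimate stable in high dimensions; the full 2-Wasserstein
distance between the Gaussians is never evaluated directly.

BKE ensembles the replayed teacher features before they enter WKD.  Token
vectors of teacher and student are L2-normalized and their per-slice dot
products form an affinity A ∈ R^{B×T×T}; a self-excluded softmax over the
student-token axis makes each row a distribution over the other tokens
(Â, zero diagonal, rows summing to 1).  Propagating

    Q⁽ᵗ⁾ = ω·Â·Q⁽ᵗ⁻¹⁾ + (1−ω)·P_T ,   Q⁽⁰⁾ = P_T

and letting t → ∞ gives the closed form Q_T = (1−ω)(I − ωÂ)⁻¹ P_T, whose
propagation matrix is entrywise non-negative with unit row sums, so every
ensembled token is a convex combination of teacher tokens.

Teacher quantities (P_T, Â, Q_T) are constants during optimization; gradients
flow only into the student features, which may arrive as autodiff Tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .exceptions import ConfigurationError, InvalidInputError, ShapeError

__all__ = [
    "GaussianStats",
    "FDConfig",
    "compute_stats",
    "wkd_loss",
    "bke_affinity",
    "bke_iterate",
    "bke_closed_form",
    "propagation_matrix",
    "fd_loss",
]

_NORM_EPS = 1e-12

FD_MODES = ("mse", "wkd", "bke_mse", "wkd_bke")


@dataclass
class GaussianStats:
    """Channel-wise Gaussian summary of a feature batch.

    ``mu`` and ``delta`` are length-l vectors (numpy arrays, or autodiff
    Tensors when computed from a student Tensor so gradients can flow).
    ``d`` is the number of token samples pooled (B·T).
    """

    mu: np.ndarray | Tensor
    delta: np.ndarray | Tensor
    l: int
    d: int


@dataclass(frozen=True)
class FDConfig:
    """Feature-distillation configuration.

    gamma ≥ 0 weighs the mean term against the standard-deviation term;
    omega ∈ [0, 1) is the BKE propagation weight; lambda_fd scales L_FD in
    the total stage-3 loss; t_max caps the iterative propagation solver.
    """

    mode: str = "wkd_bke"
    gamma: float = 2.0
    omega: float = 0.5
    lambda_fd: float = 1.0
    t_max: int = 60

    def __post_init__(self):
        if self.mode not in FD_MODES:
            raise ConfigurationError(f"unknown distillation mode {self.mode!r}")
        if not 0 <= self.omega < 1:
            raise ConfigurationError(f"omega must be in [0,1), got {self.omega}")
        if self.gamma < 0 or self.lambda_fd < 0:
            raise ConfigurationError("gamma and lambda_fd must be non-negative")


def _as_batched(p) -> tuple:
    data = p.data if isinstance(p, Tensor) else np.asarray(p)
    if data.ndim == 2:
        shape = (1,) + data.shape
    elif data.ndim == 3:
        shape = data.shape
    else:
        raise ShapeError(f"expected (B,T,E) or (T,E) features, got {data.shape}")
    return shape


def compute_stats(p) -> GaussianStats:
    """Channel-wise μ and population δ over all B·T token samples.

    Accepts a numpy array (returns numpy stats) or an autodiff Tensor
    (returns Tensor stats on the graph, for the student side).
    """
    b, t, e = _as_batched(p)
    d = b * t
    if d < 2:
        raise InvalidInputError(f"need at least 2 token samples, got {d}")
    if isinstance(p, Tensor):
        flat = p.reshape(d, e)
        mu = flat.mean(axis=0)
        centered = flat - mu.reshape(1, e)
        var = (centered * centered).mean(axis=0)
        delta = var.sqrt()
        return GaussianStats(mu=mu, delta=delta, l=e, d=d)
    flat = np.asarray(p, dtype=np.float64).reshape(d, e)
    mu = flat.mean(axis=0)
    var = ((flat - mu) ** 2).mean(axis=0)  # population divisor d
    return GaussianStats(mu=mu, delta=np.sqrt(var), l=e, d=d)


def wkd_loss(teacher: GaussianStats, student: GaussianStats, gamma: float):
    """γ·‖μ_T − μ_S‖₂ + ‖δ_T − δ_S‖₂ (unsquared norms).

    Symmetric in its arguments; zero iff both summaries coincide.  Returns a
    float for numpy stats, a graph Tensor if either side carries Tensors.
    """
    if teacher.l != student.l:
        raise ShapeError(f"channel mismatch: {teacher.l} vs {student.l}")
    tensorial = any(isinstance(x, Tensor) for x in (teacher.mu, student.mu))
    if not tensorial:
        d_mean = float(np.linalg.norm(np.asarray(teacher.mu) - np.asarray(student.mu)))
        d_cov = float(np.linalg.norm(np.asarray(teacher.delta) - np.asarray(student.delta)))
        return gamma * d_mean + d_cov

    def _t(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    dmu = _t(teacher.mu) - _t(student.mu)
    ddelta = _t(teacher.delta) - _t(student.delta)
    d_mean = (dmu * dmu).sum().sqrt()
    d_cov = (ddelta * ddelta).sum().sqrt()
    return d_mean * gamma + d_cov


def bke_affinity(p_t: np.ndarray, p_s: np.ndarray) -> np.ndarray:
    """Softmax-normalized token affinity Â ∈ R^{B×T×T}.

    ``Â[b, i, j]`` relates teacher token i to student token j within batch
    slice b; the diagonal is zero and each row sums to 1 over the T−1
    off-diagonal entries.
    """
    p_t = np.asarray(p_t, dtype=np.float64)
    p_s = np.asarray(p_s, dtype=np.float64)
    if p_t.shape != p_s.shape:
        raise ShapeError(f"teacher/student shape mismatch {p_t.shape} vs {p_s.shape}")
    if p_t.ndim == 2:
        p_t, p_s = p_t[None], p_s[None]
    b, t, e = p_t.shape
    nt = np.linalg.norm(p_t, axis=-1, keepdims=True)
    ns = np.linalg.norm(p_s, axis=-1, keepdims=True)
    if np.any(nt == 0) or np.any(ns == 0):
        raise InvalidInputError(
            "zero-norm token vector cannot be normalized; add an epsilon upstream"
        )
    a = (p_t / (nt + _NORM_EPS)) @ np.swapaxes(p_s / (ns + _NORM_EPS), -1, -2)
    ex = np.exp(a)
    idx = np.arange(t)
    ex[:, idx, idx] = 0.0
    return ex / ex.sum(axis=-1, keepdims=True)


def bke_iterate(a_hat: np.ndarray, p_t: np.ndarray, omega: float, t: int) -> np.ndarray:
    """t propagation steps: Q⁽ᵏ⁾ = ω·Â·Q⁽ᵏ⁻¹⁾ + (1−ω)·P_T, Q⁽⁰⁾ = P_T."""
    if not 0 <= omega < 1:
        raise ConfigurationError(f"omega must be in [0,1), got {omega}")
    q = np.asarray(p_t, dtype=np.float64)
    p_t = q
    for _ in range(t):
        q = omega * (a_hat @ q) + (1.0 - omega) * p_t
    return q


def propagation_matrix(a_hat: np.ndarray, omega: float) -> np.ndarray:
    """M = (1−ω)(I − ωÂ)⁻¹ per batch slice; non-negative with unit row sums."""
    if not 0 <= omega < 1:
        raise ConfigurationError(f"omega must be in [0,1), got {omega}")
    a_hat = np.asarray(a_hat, dtype=np.float64)
    t = a_hat.shape[-1]
    eye = np.eye(t)
    return (1.0 - omega) * np.linalg.inv(eye - omega * a_hat)


def bke_closed_form(a_hat: np.ndarray, p_t: np.ndarray, omega: float) -> np.ndarray:
    """Fixed point of the propagation: Q_T = (1−ω)(I − ωÂ)⁻¹ P_T.

    Solved as a batched linear system rather than by explicit inversion.
    ω < 1 guarantees invertibility because Â is row-stochastic.
    """
    if not 0 <= omega < 1:
        raise ConfigurationError(f"omega must be in [0,1), got {omega}")
    a_hat = np.asarray(a_hat, dtype=np.float64)
    p_t = np.asarray(p_t, dtype=np.float64)
    t = a_hat.shape[-1]
    lhs = np.eye(t) - omega * a_hat
    return (1.0 - omega) * np.linalg.solve(lhs, p_t)


def _mse(teacher_const: np.ndarray, student):
    if isinstance(student, Tensor):
        diff = student - Tensor(teacher_const.astype(student.data.dtype))
        return (diff * diff).mean()
    return float(np.mean((np.asarray(student, dtype=np.float64) - teacher_const) ** 2))


def fd_loss(p_t: np.ndarray, p_s, cfg: FDConfig):
    """The combined feature-distillation loss L_FD.

    Parameters
    ----------
    p_t : (B, T, E) array
        Teacher features replayed from the memory buffer (constant).
    p_s : (B, T, E) array or Tensor
        Student features from the current encoder; pass a Tensor to obtain a
        differentiable loss.
    cfg : FDConfig
        ``mode`` selects: plain feature MSE (``mse``), moment matching
        (``wkd``), BKE-ensembled MSE (``bke_mse``), or the full
        BKE-then-WKD objective (``wkd_bke``).
    """
    p_t = np.asarray(p_t, dtype=np.float64)
    s_data = p_s.data if isinstance(p_s, Tensor) else np.asarray(p_s)
    if p_t.shape != s_data.shape:
        raise ShapeError(f"teacher/student shape mismatch {p_t.shape} vs {s_data.shape}")
    if cfg.mode == "mse":
        return _mse(p_t, p_s)
    if cfg.mode == "wkd":
        return wkd_loss(compute_stats(p_t), compute_stats(p_s), cfg.gamma)
    a_hat = bke_affinity(p_t, np.asarray(s_data, dtype=np.float64))
    q_t = bke_closed_form(a_hat, p_t, cfg.omega)
    if cfg.mode == "bke_mse":
        return _mse(q_t, p_s)
    return wkd_loss(compute_stats(q_t), compute_stats(p_s), cfg.gamma)
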