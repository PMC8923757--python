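"""Capon-family adaptive beamformers.

* ``scb_weights`` — standard Capon / MVDR: minimise output power subject to
  unit gain along the steering vector.
* ``iscb_weights`` — improved pipeline: forward-backward covariance
  correction, eigen split of the corrected covariance at a threshold of
  ``threshold_factor`` times the largest eigenvalue, quadratically
  constrained steering-vector correction solved by a Lagrange multiplier,
  then Capon weighting.
* ``rls_weights`` / ``ser_weights`` — recursive-least-squares and
  sequential-regression (constrained LMS) baselines in their standard
  textbook forms.

Steering-vector correction solves

    minimise  lam^H A lam   s.t.  ||lam - lam_bar||^2 <= tau,

with ``A = Ws Pi_s Ws^H`` the signal-subspace energy.  The stationarity
condition gives ``lam(beta) = (I + A/beta)^(-1) lam_bar``; the residual
``d(beta) = ||lam(beta) - lam_bar||^2`` is monotone decreasing in ``beta``,
so the multiplier activating the constraint is found by bisection whenever
the unconstrained minimiser (the projection onto A's null space) violates it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariance import CovarianceEstimate, forward_backward_correct

__all__ = [
    "SubspaceDecomposition",
    "SteeringVector",
    "BeamformerWeights",
    "scb_weights",
    "eigendecompose_subspace",
    "correct_steering_vector",
    "iscb_weights",
    "rls_weights",
    "ser_weights",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class SubspaceDecomposition:
    """Eigen split of a Hermitian covariance into signal and noise parts.

    Signal eigenvalues are those ``>= threshold_factor * max eigenvalue``
    (ties go to the signal side); both blocks are sorted descending.
    """

    signal_vectors: np.ndarray  # (L, k)
    signal_values: np.ndarray  # (k,)
    noise_vectors: np.ndarray  # (L, L - k)
    noise_values: np.ndarray  # (L - k,)
    threshold_factor: float

    @property
    def signal_dim(self) -> int:
        return int(self.signal_values.size)

    @property
    def size(self) -> int:
        return int(self.signal_vectors.shape[0])

    def signal_energy_matrix(self) -> np.ndarray:
        """``A = Ws Pi_s Ws^H`` — PSD energy operator of the signal subspace."""
        ws, pis = self.signal_vectors, self.signal_values
        return (ws * pis) @ ws.conj().T

    def reconstruct(self) -> np.ndarray:
        """``Ws Pi_s Ws^H + Wm Pi_m Wm^H`` — equals the decomposed input."""
        out = self.signal_energy_matrix()
        if self.noise_values.size:
            wm, pim = self.noise_vectors, self.noise_values
            out = out + (wm * pim) @ wm.conj().T
        return out


@dataclass(frozen=True)
class SteeringVector:
    """Nominal and corrected steering vectors with the error budget."""

    nominal: np.ndarray
    corrected: np.ndarray
    tau: float
    beta: float  # Lagrange multiplier; inf when the constraint pinned lam=lam_bar

    def __post_init__(self) -> None:
        nom = np.asarray(self.nominal, dtype=complex).ravel()
        cor = np.asarray(self.corrected, dtype=complex).ravel()
        if nom.shape != cor.shape:
            raise ValueError("nominal and corrected must have the same length")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        err = float(np.linalg.norm(cor - nom) ** 2)
        if err > self.tau + 1e-9:
            raise ValueError(
                f"corrected steering violates the error budget: {err:g} > tau={self.tau:g}"
            )
        object.__setattr__(self, "nominal", nom)
        object.__setattr__(self, "corrected", cor)


@dataclass(frozen=True)
class BeamformerWeights:
    """Complex weight vector plus the steering it was built for."""

    weights: np.ndarray
    method: str
    steering: SteeringVector | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=complex).ravel()
        if not np.isfinite(w).all():
            raise ValueError("weights must be finite")
        object.__setattr__(self, "weights", w)

    def output(self, snapshot: np.ndarray) -> complex:
        return complex(np.vdot(self.weights, np.asarray(snapshot).ravel()))


def _as_matrix(f) -> np.ndarray:
    return f.matrix if isinstance(f, CovarianceEstimate) else np.asarray(f)


def scb_weights(f, steering: np.ndarray, method: str = "SCB") -> BeamformerWeights:
    """Capon / MVDR weights ``Z = F^-1 lam / (lam^H F^-1 lam)``.

    ``f`` must be positive definite (apply diagonal loading first); a
    condition number above 1e12 raises with a loading suggestion.  The output
    power against ``f`` is ``1 / (lam^H F^-1 lam)`` and ``Z^H lam = 1``.
    """
    mat = _as_matrix(f)
    lam = np.asarray(steering, dtype=complex).ravel()
    if lam.size != mat.shape[0]:
        raise ValueError(
            f"steering length {lam.size} does not match covariance size {mat.shape[0]}"
        )
    if not np.any(np.abs(lam) > 0):
        raise ValueError("steering vector must be nonzero")
    evals = np.linalg.eigvalsh(mat)
    if evals[0] <= 0 or evals[-1] / evals[0] > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            "covariance is singular or ill-conditioned "
            f"(condition number ~ {np.inf if evals[0] <= 0 else evals[-1] / evals[0]:.2e}); "
            "apply diagonal loading"
        )
    finv_lam = np.linalg.solve(mat, lam)
    denom = np.vdot(lam, finv_lam)
    w = finv_lam / denom
    nominal = SteeringVector(nominal=lam, corrected=lam, tau=0.0, beta=np.inf)
    return BeamformerWeights(weights=w, method=method, steering=nominal)


def eigendecompose_subspace(
    f, threshold_factor: float = 0.5
) -> SubspaceDecomposition:
    """Eigendecompose a Hermitian covariance and split at the threshold.

    The signal subspace collects eigenvalues ``>= threshold_factor * max``;
    the largest eigenvalue always qualifies, so ``k >= 1``.
    """
    mat = _as_matrix(f)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("covariance must be square")
    scale = max(float(np.abs(mat).max()), np.finfo(float).tiny)
    if np.abs(mat - mat.conj().T).max() > 1e-10 * scale:
        raise ValueError("covariance must be Hermitian")
    if not 0.0 < threshold_factor <= 1.0:
        raise ValueError("threshold_factor must lie in (0, 1]")
    evals, evecs = np.linalg.eigh(mat)
    evals, evecs = evals[::-1], evecs[:, ::-1]  # descending
    threshold = threshold_factor * evals[0]
    is_signal = evals >= threshold
    is_signal[0] = True
    return SubspaceDecomposition(
        signal_vectors=evecs[:, is_signal],
        signal_values=evals[is_signal],
        noise_vectors=evecs[:, ~is_signal],
        noise_values=evals[~is_signal],
        threshold_factor=float(threshold_factor),
    )


def correct_steering_vector(
    subspace: SubspaceDecomposition | np.ndarray,
    nominal: np.ndarray,
    tau: float,
    beta_tol: float = 1e-10,
) -> SteeringVector:
    """Quadratically constrained steering correction.

    Minimises the steering vector's energy in the signal subspace,
    ``lam^H A lam`` with ``A = Ws Pi_s Ws^H``, subject to
    ``||lam - lam_bar||^2 <= tau``.  Solved in A's eigenbasis:
    ``lam(beta) = (I + A/beta)^(-1) lam_bar`` with ``beta`` bisected so the
    constraint is active whenever the null-space projection of ``lam_bar``
    violates it.  ``tau = 0`` or ``A lam_bar = 0`` return ``lam_bar``.
    """
    lam_bar = np.asarray(nominal, dtype=complex).ravel()
    if tau < 0:
        raise ValueError("tau must be >= 0")
    a = (
        subspace.signal_energy_matrix()
        if isinstance(subspace, SubspaceDecomposition)
        else np.asarray(subspace)
    )
    if a.shape != (lam_bar.size, lam_bar.size):
        raise ValueError("signal-energy matrix size must match the steering length")

    if tau == 0.0 or np.allclose(a @ lam_bar, 0.0, atol=1e-300):
        return SteeringVector(nominal=lam_bar, corrected=lam_bar.copy(), tau=float(tau), beta=np.inf)

    pi, w = np.linalg.eigh(a)  # pi >= 0 (A is PSD)
    pi = np.clip(pi, 0.0, None)
    c = w.conj().T @ lam_bar  # lam_bar in the eigenbasis
    pos = pi > pi.max() * 1e-15

    # unconstrained minimiser: zero the components with positive eigenvalue
    d_floor = float(np.sum(np.abs(c[pos]) ** 2))
    if d_floor <= tau:
        coef = np.where(pos, 0.0, c)
        lam = w @ coef
        return SteeringVector(nominal=lam_bar, corrected=lam, tau=float(tau), beta=0.0)

    def residual(beta: float) -> float:
        # ||lam(beta) - lam_bar||^2 in the eigenbasis
        shrink = pi / (pi + beta)
        return float(np.sum(np.abs(shrink * c) ** 2))

    pi_max = float(pi.max())
    lo, hi = 1e-8 * pi_max, 1e8 * pi_max
    # widen until the root is bracketed: residual(lo) > tau > residual(hi)
    for _ in range(200):
        if residual(lo) > tau:
            break
        lo /= 10.0
    for _ in range(200):
        if residual(hi) < tau:
            break
        hi *= 10.0
    if not (residual(lo) >= tau >= residual(hi)):
        raise RuntimeError(
            "failed to bracket the Lagrange multiplier: "
            f"residual({lo:g})={residual(lo):g}, residual({hi:g})={residual(hi):g}, tau={tau:g}"
        )
    beta = np.sqrt(lo * hi)
    for _ in range(400):
        beta = np.sqrt(lo * hi)
        res = residual(beta)
        if res > tau:
            lo = beta
        else:
            hi = beta
        if hi - lo < beta_tol * hi or abs(res - tau) < beta_tol * tau:
            break
    lam = w @ (beta / (pi + beta) * c)
    # guard: never return a vector violating the constraint
    err = float(np.linalg.norm(lam - lam_bar) ** 2)
    if err > tau:
        lam = lam_bar + (lam - lam_bar) * np.sqrt(tau / err)
    return SteeringVector(nominal=lam_bar, corrected=lam, tau=float(tau), beta=float(beta))


def iscb_weights(
    f_raw,
    nominal: np.ndarray,
    tau: float | None = None,
    threshold_factor: float = 0.5,
) -> BeamformerWeights:
    """Improved Capon pipeline.

    Forward-backward-correct the raw covariance, eigen-split it, correct the
    steering vector inside the error ball ``tau`` (default ``0.1 * L``),
    rescale the corrected steering to norm ``sqrt(L)``, then apply Capon
    weighting on the corrected covariance.
    """
    mat = _as_matrix(f_raw)
    L = mat.shape[0]
    if tau is None:
        tau = 0.1 * L
    f_fb = forward_backward_correct(f_raw)
    subspace = eigendecompose_subspace(f_fb, threshold_factor=threshold_factor)
    steering = correct_steering_vector(subspace, nominal, tau)
    lam = steering.corrected
    norm = np.linalg.norm(lam)
    if norm == 0:
        raise ValueError("steering correction collapsed to zero; reduce tau")
    lam_scaled = lam * (np.sqrt(L) / norm)
    out = scb_weights(f_fb, lam_scaled, method="ISCB")
    return BeamformerWeights(weights=out.weights, method="ISCB", steering=steering)


def rls_weights(
    snapshot_stream,
    steering: np.ndarray,
    forgetting_factor: float = 1.0,
    init_delta: float = 1.0,
) -> BeamformerWeights:
    """Recursive-least-squares Capon baseline.

    Propagates the inverse of the exponentially weighted sample covariance
    ``sum_k ff^(n-k) x_k x_k^H + ff^n * delta * I`` with the matrix inversion
    lemma and applies Capon normalisation at the end.  With
    ``forgetting_factor = 1`` this equals ``scb_weights`` on the plain sample
    covariance plus ``delta`` loading.
    """
    if not 0.0 < forgetting_factor <= 1.0:
        raise ValueError("forgetting_factor must lie in (0, 1]")
    if init_delta <= 0:
        raise ValueError("init_delta must be > 0")
    lam = np.asarray(steering, dtype=complex).ravel()
    snaps = [np.asarray(getattr(s, "values", s), dtype=complex).ravel() for s in snapshot_stream]
    if not snaps:
        raise ValueError("snapshot stream is empty")
    n = lam.size
    p = np.eye(n, dtype=complex) / init_delta
    ff = forgetting_factor
    for x in snaps:
        px = p @ x
        k = px / (ff + np.vdot(x, px))
        p = (p - np.outer(k, px.conj())) / ff
        p = 0.5 * (p + p.conj().T)
    p_lam = p @ lam
    w = p_lam / np.vdot(lam, p_lam)
    nominal = SteeringVector(nominal=lam, corrected=lam, tau=0.0, beta=np.inf)
    return BeamformerWeights(weights=w, method="RLS", steering=nominal)


def ser_weights(
    snapshot_stream,
    steering: np.ndarray,
    step_schedule=0.5,
) -> BeamformerWeights:
    """Sequential-regression (constrained stochastic gradient) baseline.

    Starts from the quiescent solution ``lam / ||lam||^2``, takes a
    normalised gradient step against each snapshot's instantaneous power and
    re-imposes the unit-gain constraint by projection after every step.
    ``step_schedule`` may be a scalar or a callable ``k -> mu_k``; steps are
    normalised by the snapshot power, so stability requires ``mu < 1``.
    """
    lam = np.asarray(steering, dtype=complex).ravel()
    snaps = [np.asarray(getattr(s, "values", s), dtype=complex).ravel() for s in snapshot_stream]
    if not snaps:
        raise ValueError("snapshot stream is empty")
    mu_of = step_schedule if callable(step_schedule) else (lambda k: step_schedule)
    lam_sq = float(np.vdot(lam, lam).real)
    f_quiescent = lam / lam_sq
    proj = lambda v: v - lam * (np.vdot(lam, v) / lam_sq)  # noqa: E731
    w = f_quiescent.copy()
    for k, x in enumerate(snaps):
        mu = mu_of(k)
        power = float(np.vdot(x, x).real)
        if power > 0 and mu != 0:
            y = np.vdot(w, x)  # beamformer output for this snapshot
            grad = x * np.conj(y)  # d|y|^2 / d conj(w)
            w = w - (mu / power) * grad
        # re-impose unit gain toward the steering vector
        w = f_quiescent + proj(w)
    nominal = SteeringVector(nominal=lam, corrected=lam, tau=0.0, beta=np.inf)
    return BeamformerWeights(weights=w, method="SER", steering=nominal)
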