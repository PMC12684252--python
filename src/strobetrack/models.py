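"""Shared model containers: multi-state diffusion models and the camera."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiffusionModel", "CameraModel"]


@dataclass(frozen=True)
class DiffusionModel:
    """A K-state diffusive mixture (K = 1..3).

    Parameters
    ----------
    D : array-like
        Per-state diffusion coefficient, um^2/s, each > 0.
    w : array-like
        Per-state weight on the simplex (sums to 1).
    A : array-like, optional
        K x K per-frame transition probability matrix (row-stochastic).
        When supplied its stationary distribution should equal ``w``;
        when absent, simulated molecules keep their initial state.
    """

    D: np.ndarray
    w: np.ndarray
    A: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "D", np.atleast_1d(np.asarray(self.D, dtype=float)))
        object.__setattr__(self, "w", np.atleast_1d(np.asarray(self.w, dtype=float)))
        if self.A is not None:
            object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        if np.any(self.D <= 0):
            raise ValueError("all diffusion coefficients must be positive")
        if len(self.w) != len(self.D):
            raise ValueError("D and w must have the same length")
        if np.any(self.w < 0) or abs(self.w.sum() - 1.0) > 1e-8:
            raise ValueError("w must lie on the probability simplex")
        if self.A is not None:
            A = self.A
            if A.shape != (self.K, self.K):
                raise ValueError("A must be K x K")
            if np.any(A < 0) or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-8):
                raise ValueError("A must be row-stochastic")

    @property
    def K(self) -> int:
        return len(self.D)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of ``A`` (or ``w`` when A is absent)."""
        if self.A is None:
            return self.w.copy()
        vals, vecs = np.linalg.eig(self.A.T)
        i = np.argmin(np.abs(vals - 1.0))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()


@dataclass(frozen=True)
class CameraModel:
    """Photon-calibrated camera: ADU = offset + gain * Poisson + read noise.

    ``gain`` is in ADU per detected photon; ``read_noise`` is the standard
    deviation (ADU) of the additive Gaussian read-out noise.  Quantum
    efficiency is folded into the photon emission rate upstream.
    """

    gain: float = 2.0
    offset: float = 100.0
    read_noise: float = 1.5

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.read_noise < 0:
            raise ValueError("read_noise must be non-negative")

    def to_photons(self, adu: np.ndarray) -> np.ndarray:
        """Invert the camera map, clipping negative values at zero."""
        return np.clip((np.asarray(adu, dtype=float) - self.offset) / self.gain, 0.0, None)
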