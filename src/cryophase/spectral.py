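"""Periodic 2-D pseudo-spectral machinery.

All fields live on a uniform ``n x n`` collocation grid covering the
scaled periodic square ``[0, 2*pi)^2`` (the physical domain is
``2*pi*L x 2*pi*L``).  Wavenumbers are therefore integers, transforms use
the real FFT (forward unnormalised, inverse 1/n^2 — numpy's default), and
nonlinear products are dealiased with the 2/3 rule.

Layout: row-major ``[iy, ix]``; x increases rightward (axis 1), y upward
(axis 0); gravity points along -y.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = ["SpectralGrid"]

log = logging.getLogger(__name__)


class SpectralGrid:
    """Collocation points, wavenumbers and operators for the periodic square.

    Parameters
    ----------
    n : int
        Number of points per side; must be even and >= 32.
    """

    def __init__(self, n: int):
        if n % 2 != 0 or n < 32:
            raise ValueError(f"grid size must be even and >= 32, got {n}")
        self.n = int(n)
        self.length = 2.0 * np.pi
        self.dx = self.length / n
        x1 = np.arange(n) * self.dx
        self.x, self.y = np.meshgrid(x1, x1)          # [iy, ix]
        # rfft along axis 1 (x), full fft along axis 0 (y)
        kx1 = np.fft.rfftfreq(n, d=1.0 / n)           # 0..n/2
        ky1 = np.fft.fftfreq(n, d=1.0 / n)            # 0..n/2-1, -n/2..-1
        self.kx, self.ky = np.meshgrid(kx1, ky1)
        self.k2 = self.kx**2 + self.ky**2
        # derivative wavenumbers: zero the unpaired Nyquist modes so that
        # derivatives of real fields stay real
        dkx = kx1.copy()
        dkx[-1] = 0.0
        dky = ky1.copy()
        dky[n // 2] = 0.0
        self.dkx, self.dky = np.meshgrid(dkx, dky)
        kcut = n / 3.0
        self.dealias_mask = (np.abs(self.kx) <= kcut) & (np.abs(self.ky) <= kcut)

    # -- transforms ---------------------------------------------------------

    def fft(self, f: np.ndarray) -> np.ndarray:
        self._check(f)
        return np.fft.rfft2(f)

    def ifft(self, f_hat: np.ndarray) -> np.ndarray:
        return np.fft.irfft2(f_hat, s=(self.n, self.n))

    def _check(self, f: np.ndarray) -> None:
        if f.shape != (self.n, self.n):
            raise ValueError(f"field shape {f.shape} does not match grid ({self.n}, {self.n})")

    # -- differential operators ---------------------------------------------

    def grad(self, f: np.ndarray):
        """Spectral gradient; returns ``(df/dx, df/dy)``."""
        f_hat = self.fft(f)
        return (
            self.ifft(1j * self.dkx * f_hat),
            self.ifft(1j * self.dky * f_hat),
        )

    def div(self, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
        """Spectral divergence of a vector field."""
        return self.ifft(self.div_hat(fx, fy))

    def div_hat(self, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
        """Fourier coefficients of the divergence (mean mode exactly zero)."""
        return 1j * self.dkx * self.fft(fx) + 1j * self.dky * self.fft(fy)

    def curl(self, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
        """Scalar (out-of-plane) vorticity d(fy)/dx - d(fx)/dy."""
        return self.ifft(1j * self.dkx * self.fft(fy) - 1j * self.dky * self.fft(fx))

    def laplacian(self, f: np.ndarray) -> np.ndarray:
        return self.ifft(-self.k2 * self.fft(f))

    def biharmonic(self, f: np.ndarray) -> np.ndarray:
        return self.ifft(self.k2**2 * self.fft(f))

    # -- dealiasing ----------------------------------------------------------

    def dealias(self, f_hat: np.ndarray) -> np.ndarray:
        """Zero modes with |kx| or |ky| > n/3 (2/3 rule); idempotent."""
        return f_hat * self.dealias_mask

    # -- elliptic solves ------------------------------------------------------

    def solve_poisson(self, rhs: np.ndarray) -> np.ndarray:
        """Solve ``lap(out) = rhs - mean(rhs)`` with zero-mean gauge.

        A nonzero-mean right-hand side is not solvable on the periodic
        domain; the mean is subtracted and logged.
        """
        rhs_hat = self.fft(rhs)
        mean = rhs_hat[0, 0].real / self.n**2
        if abs(mean) > 1e-12 * (1.0 + np.max(np.abs(rhs))):
            log.debug("solve_poisson: subtracting nonzero mean %.3e from rhs", mean)
        with np.errstate(divide="ignore", invalid="ignore"):
            out_hat = np.where(self.k2 > 0, -rhs_hat / self.k2, 0.0)
        out_hat[0, 0] = 0.0
        return self.ifft(out_hat)

    def implicit_diffusion_step(
        self, f: np.ndarray, coeff: float, dt: float, order: int = 2
    ) -> np.ndarray:
        """Backward-Euler constant-coefficient diffusion filter.

        Returns the inverse transform of ``f_hat / (1 + dt coeff k^order)``
        with ``order`` 2 (Laplacian) or 4 (biharmonic).  Unconditionally
        stable and constant-preserving (the k = 0 mode is untouched).
        """
        if coeff < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if order == 2:
            denom = 1.0 + dt * coeff * self.k2
        elif order == 4:
            denom = 1.0 + dt * coeff * self.k2**2
        else:
            raise ValueError("order must be 2 or 4")
        return self.ifft(self.fft(f) / denom)
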