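"""Analytic potential terms of the bead-spring chromatin model.

All quantities are in Lennard-Jones reduced units (sigma for length, epsilon
for energy, tau for time).  Forces returned here are radial magnitudes along
the pair separation, F(r) = -dU/dr, positive = repulsive.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import ValidationError

__all__ = [
    "WCA_CUTOFF",
    "fene_energy", "fene_force",
    "lj_energy", "lj_force",
    "loop_energy", "loop_force",
    "soft_energy", "soft_force",
]

#: Minimum of the 12-6 potential, 2^(1/6) sigma: cutting here leaves the
#: purely repulsive Weeks-Chandler-Andersen form.
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


def fene_energy(r, k_s: float = 30.0, r0: float = 1.6):
    """Finitely extensible nonlinear elastic bond,
    U(r) = -0.5 K_S R_0^2 ln[1 - (r/R_0)^2]; diverges as r -> R_0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= r0):
        raise ValidationError(f"FENE requires 0 <= r < R_0 = {r0}")
    return -0.5 * k_s * r0 ** 2 * np.log1p(-((r / r0) ** 2))


def fene_force(r, k_s: float = 30.0, r0: float = 1.6):
    """-dU/dr of the FENE bond: always attractive (negative)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= r0):
        raise ValidationError(f"FENE requires 0 <= r < R_0 = {r0}")
    return -k_s * r / (1.0 - (r / r0) ** 2)


def lj_energy(r, eps: float = 1.0, sigma: float = 1.0,
              cutoff: float | None = None, shifted: bool = True):
    """12-6 Lennard-Jones, U(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6].

    With a cutoff the potential is truncated (zero beyond) and, when
    ``shifted``, shifted so it is exactly zero at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("LJ potential is singular at r = 0")
    sr6 = (sigma / r) ** 6
    u = 4.0 * eps * (sr6 ** 2 - sr6)
    if cutoff is not None:
        if shifted:
            src6 = (sigma / cutoff) ** 6
            u = u - 4.0 * eps * (src6 ** 2 - src6)
        u = np.where(r <= cutoff, u, 0.0)
    return u


def lj_force(r, eps: float = 1.0, sigma: float = 1.0,
             cutoff: float | None = None):
    """-dU/dr of the 12-6 form: 24 eps (2 (s/r)^12 - (s/r)^6) / r."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("LJ potential is singular at r = 0")
    sr6 = (sigma / r) ** 6
    f = 24.0 * eps * (2.0 * sr6 ** 2 - sr6) / r
    if cutoff is not None:
        f = np.where(r <= cutoff, f, 0.0)
    return f


def loop_energy(r, k_l: float = 300.0, r0l: float = 1.2):
    """Harmonic loop-anchor restraint U(r) = K_L (r - R0L)^2."""
    r = np.asarray(r, dtype=float)
    return k_l * (r - r0l) ** 2


def loop_force(r, k_l: float = 300.0, r0l: float = 1.2):
    """-dU/dr of the loop restraint: -2 K_L (r - R0L)."""
    r = np.asarray(r, dtype=float)
    return -2.0 * k_l * (r - r0l)


def soft_energy(r, a: float, r0s: float = WCA_CUTOFF):
    """Bounded push-off potential U(r) = A [1 + cos(pi r / R0S)] for r <= R0S."""
    r = np.asarray(r, dtype=float)
    u = a * (1.0 + np.cos(np.pi * r / r0s))
    return np.where(r <= r0s, u, 0.0)


def soft_force(r, a: float, r0s: float = WCA_CUTOFF):
    """-dU/dr of the push-off potential: (A pi / R0S) sin(pi r / R0S)."""
    r = np.asarray(r, dtype=float)
    f = a * np.pi / r0s * np.sin(np.pi * r / r0s)
    return np.where(r <= r0s, f, 0.0)
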