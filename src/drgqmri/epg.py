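"""Extended-phase-graph (EPG) forward model for CPMG multi-echo spin-echo trains.

The EPG formalism tracks the configuration states ``(F+(k), F-(k), Z(k))`` of
the magnetisation, indexed by dephasing order ``k``, through the pulse
sequence.  For a 90° excitation followed by a train of refocusing pulses with
effective flip angle ``b1 * 180°``, imperfect refocusing (``b1 != 1``) mixes
transverse and longitudinal states and generates stimulated-echo pathways, so
the measured echo decay is no longer a mono-exponential in T2.  Modelling this
explicitly is what makes T2 estimation robust to transmit-field (B1)
inhomogeneity.

Conventions
-----------
* Excitation: 90° about x, so the initial transverse state is ``F+(0) = -i M0``.
* Refocusing pulses: about y (Meiboom-Gill phase), flip angle ``b1 * pi``.
* One echo period is: relax ``dTE/2`` -> gradient shift -> RF -> shift ->
  relax ``dTE/2`` -> echo read-out at ``|F+(0)|``.
* States with order ``k > n_echoes + 1`` cannot refocus within the train and
  are truncated without loss of accuracy.

At ``b1 = 1`` no stimulated pathways exist and the k-th echo is exactly
``M0 * exp(-k * dTE / T2)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["epg_cpmg_signal", "epg_cpmg_batch"]


def epg_cpmg_batch(
    t2: np.ndarray,
    t1: np.ndarray,
    b1: np.ndarray,
    n_echoes: int,
    delta_te: float,
) -> np.ndarray:
    """Unit-M0 CPMG echo amplitudes for a batch of voxels.

    Parameters
    ----------
    t2, t1 : array_like, shape (n,)
        Relaxation times in ms; must be positive.
    b1 : array_like, shape (n,)
        Relative transmit field; the refocusing flip angle is ``b1 * 180°``.
    n_echoes : int
        Number of echoes in the train (>= 1).
    delta_te : float
        Echo spacing in ms (> 0).

    Returns
    -------
    ndarray, shape (n_echoes, n)
        Echo magnitudes for unit equilibrium magnetisation.  The signal is
        linear in M0, so callers scale the result.
    """
    t2 = np.atleast_1d(np.asarray(t2, dtype=float))
    t1 = np.atleast_1d(np.asarray(t1, dtype=float))
    b1 = np.atleast_1d(np.asarray(b1, dtype=float))
    t2, t1, b1 = np.broadcast_arrays(t2, t1, b1)
    if t2.ndim != 1:
        t2, t1, b1 = t2.ravel(), t1.ravel(), b1.ravel()
    n = t2.size
    if n_echoes < 1:
        raise ValueError("n_echoes must be >= 1")
    if delta_te <= 0:
        raise ValueError("delta_te must be positive")
    if np.any(t2 <= 0) or np.any(t1 <= 0):
        raise ValueError("t2 and t1 must be positive")
    if np.any(b1 < 0):
        raise ValueError("b1 must be non-negative")

    n_states = n_echoes + 2  # orders 0 .. n_states-1
    fp = np.zeros((n_states, n), dtype=complex)
    fm = np.zeros((n_states, n), dtype=complex)
    z = np.zeros((n_states, n), dtype=complex)
    fp[0] = -1j  # 90° about x applied to unit Mz
    fm[0] = np.conj(fp[0])

    tau = delta_te / 2.0
    e2 = np.exp(-tau / t2)
    e1 = np.exp(-tau / t1)
    rec = 1.0 - e1  # T1 recovery of Z(0) toward unit M0 per half period

    # Refocusing rotation about y (phase pi/2), flip alpha = b1*pi.
    alpha = b1 * np.pi
    ca2 = np.cos(alpha / 2.0) ** 2
    sa2 = np.sin(alpha / 2.0) ** 2
    sa = np.sin(alpha)
    ca = np.cos(alpha)
    # exp(±2i*phi) = -1, exp(i*phi) = i, exp(-i*phi) = -i  for phi = pi/2
    t00 = ca2
    t01 = -sa2
    t02 = sa  # -i * e^{i phi} * sin(a) = -i*i*sa = +sa
    t10 = -sa2
    t11 = ca2
    t12 = sa  # +i * e^{-i phi} * sin(a) = i*(-i)*sa = +sa
    t20 = -0.5 * sa  # -(i/2) e^{-i phi} sin(a) = -(i/2)(-i) sa = -sa/2
    t21 = -0.5 * sa  # (i/2) e^{i phi} sin(a) = (i/2)(i) sa = -sa/2
    t22 = ca

    echoes = np.empty((n_echoes, n), dtype=float)

    def relax() -> None:
        fp[...] *= e2
        fm[...] *= e2
        z[...] *= e1
        z[0] += rec

    def shift() -> None:
        fp[1:] = fp[:-1]
        fp[0] = np.conj(fm[1])
        fm[:-1] = fm[1:]
        fm[-1] = 0.0

    for k in range(n_echoes):
        relax()
        shift()
        fp_new = t00 * fp + t01 * fm + t02 * z
        fm_new = t10 * fp + t11 * fm + t12 * z
        z_new = t20 * fp + t21 * fm + t22 * z
        fp, fm, z = fp_new, fm_new, z_new
        shift()
        relax()
        echoes[k] = np.abs(fp[0])

    return echoes


def epg_cpmg_signal(
    t2: float,
    t1: float,
    b1: float,
    m0: float,
    n_echoes: int,
    delta_te: float,
) -> np.ndarray:
    """CPMG echo amplitudes for a single voxel, scaled by ``m0``.

    See :func:`epg_cpmg_batch` for the model.  Raises ``ValueError`` for
    non-physical inputs (non-positive ``t2``/``t1``/``delta_te``, negative
    ``b1`` or ``m0``).
    """
    if m0 < 0:
        raise ValueError("m0 must be non-negative")
    return float(m0) * epg_cpmg_batch(
        np.array([t2]), np.array([t1]), np.array([b1]), n_echoes, delta_te
    )[:, 0]
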