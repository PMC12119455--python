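"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own code paths: the
isochromat simulator integrates Bloch rotations over discrete dephasing
partitions instead of configuration states, and the ANOVA oracle assembles
sums of squares with explicit double loops.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from drgqmri.phantom import AcquisitionProtocol, default_cohort_config


# ---------------------------------------------------------------------------
# independent isochromat (Bloch rotation) CPMG simulator
# ---------------------------------------------------------------------------

def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def iso_cpmg(t2, t1, b1, m0, n_echoes, delta_te, n_iso=257):
    """Brute-force CPMG echo magnitudes from n_iso dephasing partitions.

    Each isochromat accumulates a fixed phase 2*pi*i/n_iso per half interval;
    with n_iso exceeding the number of distinct dephasing orders the partition
    average is exact, so this matches an exact state-space evolution to
    rounding error.
    """
    th = 2 * np.pi * np.arange(n_iso) / n_iso
    M = np.zeros((n_iso, 3))
    M[:, 2] = m0
    tau = delta_te / 2.0
    e2, e1 = np.exp(-tau / t2), np.exp(-tau / t1)
    cos_t, sin_t = np.cos(th), np.sin(th)

    def half_interval():
        M[:, 0] *= e2
        M[:, 1] *= e2
        M[:, 2] = M[:, 2] * e1 + m0 * (1 - e1)
        x = M[:, 0] * cos_t - M[:, 1] * sin_t
        y = M[:, 0] * sin_t + M[:, 1] * cos_t
        M[:, 0], M[:, 1] = x, y

    M[:] = M @ _rx(np.pi / 2).T
    refocus = _ry(b1 * np.pi)
    echoes = []
    for _ in range(n_echoes):
        half_interval()
        M[:] = M @ refocus.T
        half_interval()
        echoes.append(abs(np.mean(M[:, 0] + 1j * M[:, 1])))
    return np.array(echoes)


# ---------------------------------------------------------------------------
# explicit double-loop two-way ANOVA ICC oracle
# ---------------------------------------------------------------------------

def icc_anova_oracle(x):
    """ICC(A,1) from sums of squares assembled with explicit loops."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += x[i, j]
    grand /= n * k
    ss_rows = 0.0
    for i in range(n):
        row_mean = sum(x[i, j] for j in range(k)) / k
        ss_rows += k * (row_mean - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        col_mean = sum(x[i, j] for i in range(n)) / n
        ss_cols += n * (col_mean - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (x[i, j] - grand) ** 2
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def degenerate_hc_config():
    """Two HC subjects, zero spread, zero noise: every feature is exactly the
    configured group median."""
    cfg = default_cohort_config(seed=11).scaled(0.0)
    return replace(cfg, noise_sigma=0.0,
                   groups={"HC": replace(cfg.groups["HC"], n=2)})
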