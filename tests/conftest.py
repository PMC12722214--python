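"""Shared fixtures and independent numerical oracles.

The oracles here are deliberately written from scratch (their own matrix
construction, their own mean-squares algebra) so that agreement with the
package is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from cestmrf import (Pool, SemisolidPool, TissueModel, base_tissue,
                     default_schedule)
from cestmrf.physics import GAMMA_HZ_PER_T


# ---------------------------------------------------------------------------
# Tissue fixtures


@pytest.fixture
def amide_pool() -> Pool:
    return Pool("amide", 3.5, 1.0, 0.04, 200.0, 0.003)


@pytest.fixture
def two_pool_tissue(amide_pool) -> TissueModel:
    """Water + amide, no semisolid: the textbook two-pool exchange model."""
    return TissueModel(water_t1=1.8, water_t2=0.075, solute_pools=[amide_pool])


@pytest.fixture
def full_tissue() -> TissueModel:
    """Brain-like tissue with rNOE, amide, glutamate and semisolid pools."""
    return base_tissue(solutes=("rnoe", "amide", "glu"))


@pytest.fixture
def mt_schedule():
    return default_schedule("mt")


# ---------------------------------------------------------------------------
# Two-pool Bloch-McConnell oracles (independent construction)


def two_pool_matrix(w1, dw_w, dw_s, r1w, r2w, r1s, r2s, f, k):
    """6x6 generator for water+solute, assembled independently of the
    package's layout conventions."""
    kws = f * k
    A = np.array([
        [-(r2w + kws), dw_w, 0.0, k, 0.0, 0.0],
        [-dw_w, -(r2w + kws), w1, 0.0, k, 0.0],
        [0.0, -w1, -(r1w + kws), 0.0, 0.0, k],
        [kws, 0.0, 0.0, -(r2s + k), dw_s, 0.0],
        [0.0, kws, 0.0, -dw_s, -(r2s + k), w1],
        [0.0, 0.0, kws, 0.0, -w1, -(r1s + k)],
    ])
    b = np.array([0.0, 0.0, r1w, 0.0, 0.0, r1s * f])
    return A, b


def two_pool_steady_state_z(b1_uT, offset_ppm, tissue: TissueModel,
                            b0_field=7.0) -> float:
    """Driven steady-state water z from a direct linear solve."""
    pool = tissue.solute_pools[0]
    gamma = 2 * np.pi * GAMMA_HZ_PER_T
    w1 = gamma * 1e-6 * b1_uT
    dw_w = gamma * b0_field * (0.0 - offset_ppm) * 1e-6
    dw_s = gamma * b0_field * (pool.chemical_shift - offset_ppm) * 1e-6
    A, b = two_pool_matrix(
        w1, dw_w, dw_s, 1 / tissue.water_t1, 1 / tissue.water_t2,
        1 / pool.t1, 1 / pool.t2, pool.volume_fraction, pool.exchange_rate)
    return float(np.linalg.solve(A, -b)[2])


def two_pool_rk4_evolve(state6, b1_uT, offset_ppm, tissue: TissueModel,
                        duration, step=1e-5, b0_field=7.0) -> np.ndarray:
    """Fine-step classical Runge-Kutta integration of the same system."""
    pool = tissue.solute_pools[0]
    gamma = 2 * np.pi * GAMMA_HZ_PER_T
    w1 = gamma * 1e-6 * b1_uT
    dw_w = gamma * b0_field * (0.0 - offset_ppm) * 1e-6
    dw_s = gamma * b0_field * (pool.chemical_shift - offset_ppm) * 1e-6
    A, b = two_pool_matrix(
        w1, dw_w, dw_s, 1 / tissue.water_t1, 1 / tissue.water_t2,
        1 / pool.t1, 1 / pool.t2, pool.volume_fraction, pool.exchange_rate)
    m = np.asarray(state6, dtype=float).copy()
    n_full, remainder = divmod(duration, step)
    f = lambda y: A @ y + b

    def rk4_step(y, h):
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        return y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    for _ in range(int(n_full)):
        m = rk4_step(m, step)
    if remainder > 0:
        m = rk4_step(m, remainder)
    return m


# ---------------------------------------------------------------------------
# Statistics oracles (mean-squares algebra, no library calls)


def icc_a1_oracle(x, y) -> float:
    """ICC(2,1) (two-way random, absolute agreement, single measure) from
    the classical ANOVA mean-squares decomposition."""
    data = np.stack([np.asarray(x, float), np.asarray(y, float)], axis=1)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def anova_f_oracle(groups) -> float:
    """One-way ANOVA F from explicit between/within variance decomposition."""
    groups = [np.asarray(g, float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)
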