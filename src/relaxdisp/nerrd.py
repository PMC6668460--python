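"""Spinning-frequency dependence of R1rho under the simple model-free model.

Forward-models 15N R1rho as the sum of the NH-dipolar and 15N-CSA
contributions under MAS, fits the order parameter S^2 at a fixed
correlation time (tau is an input, never fitted: two-parameter fits on two
or three MAS points are underdetermined, so tau is pinned externally, e.g.
to the inverse of the average exchange rate), and translates fitted order
parameters into two-site jump geometries over a grid of minor-state
populations.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .model import (
    FieldContext,
    MotionModel,
    SpinSystemGeometry,
    csa_r1rho,
    dipolar_r1rho,
    jump_angle_from_s2,
)

__all__ = [
    "total_mas_r1rho",
    "fit_s2_fixed_tau",
    "mc_s2_error",
    "jump_interpretation",
]


def total_mas_r1rho(
    geometry: SpinSystemGeometry,
    field: FieldContext,
    spin_lock_nutation: float,
    motion: MotionModel,
) -> float:
    """Total model-free R1rho under MAS: dipolar + CSA contributions (s^-1)."""
    return dipolar_r1rho(geometry, field, spin_lock_nutation, motion) + csa_r1rho(
        geometry, field, spin_lock_nutation, motion
    )


def _basis_rates(series: pd.DataFrame, geometry: SpinSystemGeometry, tau: float):
    """Predicted rate per point at (1 - S^2) = 1; the model is linear in it."""
    base = MotionModel(order_parameter=0.0, correlation_time=tau)
    out = np.empty(len(series))
    for i, (_, row) in enumerate(series.iterrows()):
        fld = FieldContext(float(row["field_mhz"]), float(row["mas_khz"]))
        w1 = 2.0 * math.pi * float(row["spinlock_khz"]) * 1e3
        out[i] = total_mas_r1rho(geometry, fld, w1, base)
    return out


def fit_s2_fixed_tau(
    series: pd.DataFrame,
    tau: float,
    geometry: Optional[SpinSystemGeometry] = None,
    include_offset: bool = False,
) -> Tuple[float, bool]:
    """Fit S^2 in [0, 1] to an R1rho-vs-MAS series at fixed tau.

    ``series`` needs columns (field_mhz, mas_khz, spinlock_khz, r1rho,
    error) with at least two distinct MAS frequencies. The rate is linear
    in (1 - S^2), so the fit is a bounded weighted linear solve; with
    ``include_offset`` an additive nonnegative baseline (non-modelled,
    MAS-independent contribution) is co-fitted. Returns (S^2,
    constrained): ``constrained`` is False when the MAS grid does not
    discriminate S^2 from the offset (degenerate series).
    """
    if tau <= 0:
        raise ValueError("correlation time must be positive")
    if series["mas_khz"].nunique() < 2:
        raise ValueError("need at least two distinct MAS frequencies")
    if not (series["error"] > 0).all():
        raise ValueError("rate errors must be positive")
    geometry = geometry or SpinSystemGeometry()
    c = _basis_rates(series, geometry, tau)
    y = series["r1rho"].to_numpy(dtype=float)
    s = series["error"].to_numpy(dtype=float)
    constrained = True
    if include_offset:
        spread = np.ptp(c) / max(np.max(np.abs(c)), 1e-300)
        if spread < 1e-9:
            constrained = False
        a = np.column_stack([c / s, 1.0 / s])
        res = lsq_linear(a, y / s, bounds=([0.0, 0.0], [1.0, np.inf]))
        one_minus_s2 = float(res.x[0])
    else:
        a = (c / s)[:, None]
        res = lsq_linear(a, y / s, bounds=([0.0], [1.0]))
        one_minus_s2 = float(res.x[0])
    return 1.0 - one_minus_s2, constrained


def mc_s2_error(
    series: pd.DataFrame,
    tau: float,
    s2: float,
    geometry: Optional[SpinSystemGeometry] = None,
    include_offset: bool = False,
    replicates: int = 250,
    seed: int = 0,
) -> float:
    """Monte-Carlo error on S^2: perturb rates by their errors, refit, 2 x SD."""
    geometry = geometry or SpinSystemGeometry()
    c = _basis_rates(series, geometry, tau)
    ideal = (1.0 - s2) * c
    s = series["error"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    reps = np.empty(replicates)
    work = series.copy()
    for r in range(replicates):
        work["r1rho"] = ideal + rng.normal(0.0, 1.0, size=s.size) * s
        reps[r], _ = fit_s2_fixed_tau(work, tau, geometry, include_offset)
    return float(2.0 * np.std(reps, ddof=1))


def jump_interpretation(
    s2: float, populations: Sequence[float]
) -> pd.DataFrame:
    """Two-site jump angles (degrees) consistent with an order parameter.

    For each minor-state population the jump angle solving
    S^2 = 1 - 3 pA pB sin^2(theta) is reported; populations for which S^2
    is below the attainable floor are marked unattainable (NaN angle).
    """
    rows = []
    for p in populations:
        try:
            ang = math.degrees(jump_angle_from_s2(s2, p))
            rows.append((p, ang, True))
        except ValueError:
            rows.append((p, float("nan"), False))
    return pd.DataFrame(rows, columns=["p_minor", "jump_angle_deg", "attainable"])
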