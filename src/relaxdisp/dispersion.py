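"""Assembly and fitting of on-resonance R1rho dispersion datasets.

Workflow: measured off-resonance rates are corrected to on-resonance via the
tilt angle, points where the spin lock does not adequately cover the peak
are excluded, and the fast-exchange two-site model

    R1rho(w1) = R1rho_0[residue, field] + s_f * phi_ex[residue] * kex / (w1^2 + kex^2)

is fitted per residue, per group (shared kex) or globally, at one or several
static fields jointly (s_f the squared field ratio to the reference field).
Fits minimise the chi-square target sum((calc - exp)^2 / sigma^2), optionally
with per-field weights chosen so each field contributes equally.

Numerically the model is linear in phi_ex and the plateaus once kex is held
fixed, so every fit is a variable-projection scheme: a nonnegative linear
least-squares solve per residue (phi_ex >= 0, R1rho_0 >= 0) inside a
deterministic one-dimensional search over kex (50-point log grid on
[1e2, 1e6] s^-1 followed by bounded local refinement). The same inner solve
powers the fixed-kex chi-square profiles.

Model comparison uses BIC = chi^2 + k*ln(n); Monte-Carlo parameter errors
perturb the on-resonance rates by their errors, refit, and report twice the
replicate standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar, nnls

from .model import FieldContext, onres_r1rho, tilt_angle

__all__ = [
    "DispersionDataset",
    "GroupFitResult",
    "KexProfile",
    "assemble_onres_dataset",
    "chi2",
    "field_weighting",
    "per_field_min_chi2",
    "fit_group",
    "kex_profile",
    "bic",
    "model_selection",
    "combine_group_fits",
    "mc_fit_error",
    "classify_dispersion",
]

KEX_BOUNDS = (1e2, 1e6)  # s^-1 search window; fast-exchange validity documented
COARSE_GRID_POINTS = 50


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionDataset:
    """On-resonance dispersion points plus the exclusion record.

    ``points`` columns: residue_label, field_mhz, spinlock_khz, r1rho, error.
    ``exclusions`` columns: residue_label, field_mhz, spinlock_khz, reason.
    phi_ex from any fit of this dataset is expressed at ``reference_mhz``,
    the lowest static field present.
    """

    points: pd.DataFrame
    reference_mhz: float
    exclusions: pd.DataFrame = dc_field(
        default_factory=lambda: pd.DataFrame(
            columns=["residue_label", "field_mhz", "spinlock_khz", "reason"]
        )
    )

    def __post_init__(self) -> None:
        if len(self.points) and not (self.points["error"] > 0).all():
            raise ValueError("every dispersion point needs a positive error")
        if len(self.points):
            lo = float(self.points["field_mhz"].min())
            if not math.isclose(lo, self.reference_mhz):
                raise ValueError("reference field must be the lowest field present")

    def residues(self) -> List[str]:
        return sorted(self.points["residue_label"].unique())

    def restrict(self, members: Iterable[str]) -> "DispersionDataset":
        members = set(members)
        pts = self.points[self.points["residue_label"].isin(members)].reset_index(
            drop=True
        )
        return DispersionDataset(pts, float(pts["field_mhz"].min()), self.exclusions)


def _as_mapping(table, key_col: str, val_col: str) -> Dict[str, float]:
    if isinstance(table, Mapping):
        return {str(k): float(v) for k, v in table.items()}
    return {
        str(r[key_col]): float(r[val_col]) for _, r in table.iterrows()
    }


def assemble_onres_dataset(
    rates: pd.DataFrame,
    offsets,
    r1_rates,
    exclusion_threshold_deg: float = 45.0,
    mas_khz: float = 60.0,
) -> DispersionDataset:
    """Build an on-resonance dispersion dataset from measured rates.

    ``rates`` needs columns (residue_label, field_mhz, spinlock_khz,
    r1rho_obs, r1rho_obs_error); ``offsets`` maps residue -> offset in ppm
    (dict or table with offset_ppm column), ``r1_rates`` maps residue -> R1
    in s^-1 (dict or table with r1_s column). Offsets are converted to
    angular frequency at each field's 15N Larmor frequency; points whose
    tilt angle falls below the threshold (default 45 deg, i.e. |Omega| >=
    omega_1) are moved to the exclusion record, as are residues lacking an
    offset or R1 and series whose decay fit failed.
    """
    off = _as_mapping(offsets, "residue_label", "offset_ppm")
    r1 = _as_mapping(r1_rates, "residue_label", "r1_s")
    theta_min = math.radians(exclusion_threshold_deg)
    pts, excl = [], []
    for _, row in rates.iterrows():
        label = str(row["residue_label"])
        mhz = float(row["field_mhz"])
        sl = float(row["spinlock_khz"])
        if label not in off or label not in r1:
            excl.append((label, mhz, sl, "missing-ancillary"))
            continue
        if ("fit_ok" in row and not row["fit_ok"]) or not np.isfinite(row["r1rho_obs"]):
            excl.append((label, mhz, sl, "decay-fit-failed"))
            continue
        fld = FieldContext(mhz, mas_khz)
        omega1 = 2.0 * math.pi * sl * 1e3
        omega_off = off[label] * 1e-6 * fld.omega_n
        theta = tilt_angle(omega1, omega_off)
        if theta < theta_min:
            excl.append((label, mhz, sl, "tilt-below-threshold"))
            continue
        r_on = onres_r1rho(float(row["r1rho_obs"]), r1[label], theta)
        err_on = float(row["r1rho_obs_error"]) / math.sin(theta) ** 2
        pts.append((label, mhz, sl, r_on, err_on))
    points = pd.DataFrame(
        pts, columns=["residue_label", "field_mhz", "spinlock_khz", "r1rho", "error"]
    )
    exclusions = pd.DataFrame(
        excl, columns=["residue_label", "field_mhz", "spinlock_khz", "reason"]
    )
    ref = float(points["field_mhz"].min()) if len(points) else float("nan")
    return DispersionDataset(points, ref, exclusions)


# ---------------------------------------------------------------------------
# chi-square and weighting
# ---------------------------------------------------------------------------

def chi2(
    experimental: np.ndarray,
    calculated: np.ndarray,
    errors: np.ndarray,
    field_labels: Optional[np.ndarray] = None,
    field_weights: Optional[Mapping[float, float]] = None,
) -> float:
    """Weighted chi-square target: sum_f w_f sum_i (calc-exp)^2 / sigma^2."""
    exp = np.asarray(experimental, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    sig = np.asarray(errors, dtype=float)
    if exp.shape != calc.shape or exp.shape != sig.shape:
        raise ValueError("mismatched chi-square inputs")
    if np.any(sig <= 0):
        raise ValueError("chi-square requires positive errors")
    w = np.ones_like(exp)
    if field_weights is not None:
        if field_labels is None:
            raise ValueError("field labels required with field weights")
        w = np.array([field_weights[f] for f in field_labels], dtype=float)
    return float(np.sum(w * (calc - exp) ** 2 / sig**2))


def field_weighting(
    per_field_min: Mapping[float, float], reference_mhz: float
) -> Dict[float, float]:
    """Per-field chi-square weights so each field contributes equally.

    w_f = min-chi2(reference field) / min-chi2(field f); the reference
    weight is 1 by construction. Determined from separate per-field fits.
    """
    ref = per_field_min[reference_mhz]
    if any(v <= 0 for v in per_field_min.values()):
        raise ValueError("per-field minimum chi-square must be positive to weight")
    return {f: ref / v for f, v in per_field_min.items()}


# ---------------------------------------------------------------------------
# variable-projection machinery
# ---------------------------------------------------------------------------

class _ResidueBlock:
    """Precomputed arrays for one residue's joint-field inner solve."""

    __slots__ = ("label", "omega1", "scale", "rates", "inv_sigma", "field_idx", "fields")

    def __init__(self, label: str, grp: pd.DataFrame, reference_mhz: float, weights):
        self.label = label
        self.omega1 = 2.0 * math.pi * grp["spinlock_khz"].to_numpy() * 1e3
        mhz = grp["field_mhz"].to_numpy()
        self.scale = (mhz / reference_mhz) ** 2
        self.rates = grp["r1rho"].to_numpy(dtype=float)
        w = np.array([weights.get(f, 1.0) for f in mhz]) if weights else np.ones_like(mhz)
        self.inv_sigma = np.sqrt(w) / grp["error"].to_numpy(dtype=float)
        self.fields = sorted(set(mhz.tolist()))
        self.field_idx = np.searchsorted(self.fields, mhz)

    def solve(self, kex: float, rates: Optional[np.ndarray] = None):
        """NNLS solve for (plateaus per field, phi_ex) at fixed kex.

        Returns (phi_ex, {field: plateau}, chi2_contribution).
        """
        y = self.rates if rates is None else rates
        g = kex / (self.omega1**2 + kex**2)
        nf = len(self.fields)
        a = np.zeros((y.size, nf + 1))
        a[np.arange(y.size), self.field_idx] = self.inv_sigma
        a[:, nf] = self.scale * g * self.inv_sigma
        x, rnorm = nnls(a, y * self.inv_sigma)
        plateaus = {f: float(x[i]) for i, f in enumerate(self.fields)}
        return float(x[nf]), plateaus, float(rnorm**2)


def _blocks(
    dataset: DispersionDataset,
    members: Sequence[str],
    field_weights: Optional[Mapping[float, float]],
) -> List[_ResidueBlock]:
    out = []
    for label in members:
        grp = dataset.points[dataset.points["residue_label"] == label]
        if grp["spinlock_khz"].nunique() < 3:
            raise ValueError(
                f"residue {label}: need >= 3 distinct spin-lock frequencies"
            )
        out.append(_ResidueBlock(label, grp, dataset.reference_mhz, field_weights))
    return out


def _chi2_at_kex(blocks: List[_ResidueBlock], kex: float) -> float:
    return sum(b.solve(kex)[2] for b in blocks)


def _minimise_kex(
    blocks: List[_ResidueBlock],
    bounds: Tuple[float, float] = KEX_BOUNDS,
    coarse_points: int = COARSE_GRID_POINTS,
) -> float:
    """Deterministic kex search: coarse log grid then bounded refinement."""
    grid = np.logspace(math.log10(bounds[0]), math.log10(bounds[1]), coarse_points)
    vals = np.array([_chi2_at_kex(blocks, k) for k in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda x: _chi2_at_kex(blocks, 10.0**x),
        bounds=(math.log10(lo), math.log10(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(10.0**res.x)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class GroupFitResult:
    """Joint fit of one residue group sharing a common exchange rate."""

    member_residues: Tuple[str, ...]
    kex: float
    phi_ex: Dict[str, float]
    r1rho_plateau: Dict[Tuple[str, float], float]
    chi2: float
    n_points: int
    n_params: int
    field_weights: Dict[float, float]
    kex_error: Optional[float] = None
    phi_ex_error: Optional[Dict[str, float]] = None
    per_residue_kex: Optional[Dict[str, float]] = None
    points_signature: Tuple = ()
    label: str = ""

    @property
    def bic(self) -> float:
        return bic(self.chi2, self.n_params, self.n_points)

    def predict(self, residue: str, field_mhz: float, omega1, reference_mhz: float):
        scale = (field_mhz / reference_mhz) ** 2
        kex = (
            self.per_residue_kex[residue]
            if self.per_residue_kex is not None
            else self.kex
        )
        w1 = np.asarray(omega1, dtype=float)
        return self.r1rho_plateau[(residue, field_mhz)] + scale * self.phi_ex[
            residue
        ] * kex / (w1**2 + kex**2)


@dataclass(frozen=True)
class KexProfile:
    """Chi-square of a group refit at each fixed kex on a grid."""

    grid: np.ndarray
    chi2_values: np.ndarray

    @property
    def normalized_chi2(self) -> np.ndarray:
        return self.chi2_values / self.chi2_values.min()

    @property
    def kex_at_minimum(self) -> float:
        return float(self.grid[int(np.argmin(self.chi2_values))])


def _signature(dataset: DispersionDataset, members: Sequence[str]) -> Tuple:
    pts = dataset.points[dataset.points["residue_label"].isin(set(members))]
    return tuple(
        sorted(
            zip(pts["residue_label"], pts["field_mhz"], pts["spinlock_khz"])
        )
    )


def fit_group(
    dataset: DispersionDataset,
    members: Optional[Sequence[str]] = None,
    shared_kex: bool = True,
    kex_fixed: Optional[float] = None,
    field_weights: Optional[Mapping[float, float]] = None,
    kex_bounds: Tuple[float, float] = KEX_BOUNDS,
    label: str = "",
) -> GroupFitResult:
    """Fit the two-site exchange model to a residue group.

    With ``shared_kex`` (default) a single exchange rate is common to all
    members while phi_ex is residue-specific and the plateau R1rho_0 is per
    residue and per field. ``kex_fixed`` pins the exchange rate (used by the
    chi-square profiles). With ``shared_kex=False`` every member is fitted
    independently and the results are combined (kex reported per residue).
    """
    members = tuple(members if members is not None else dataset.residues())
    if not members:
        raise ValueError("a group needs at least one member")
    if not shared_kex:
        fits = [
            fit_group(dataset, [m], True, kex_fixed, field_weights, kex_bounds)
            for m in members
        ]
        combined = combine_group_fits(fits, label=label or "independent")
        return combined
    blocks = _blocks(dataset, members, field_weights)
    n_points = sum(b.rates.size for b in blocks)
    n_plateaus = sum(len(b.fields) for b in blocks)
    n_params = (0 if kex_fixed is not None else 1) + len(members) + n_plateaus
    if n_points < n_params:
        raise ValueError(
            f"group has {n_points} points but {n_params} parameters; refusing to fit"
        )
    kex = float(kex_fixed) if kex_fixed is not None else _minimise_kex(blocks, kex_bounds)
    phi, plateaus, total = {}, {}, 0.0
    for b in blocks:
        p, plat, c2 = b.solve(kex)
        phi[b.label] = p
        for f, v in plat.items():
            plateaus[(b.label, f)] = v
        total += c2
    return GroupFitResult(
        member_residues=members,
        kex=kex,
        phi_ex=phi,
        r1rho_plateau=plateaus,
        chi2=total,
        n_points=n_points,
        n_params=n_params,
        field_weights=dict(field_weights or {}),
        points_signature=_signature(dataset, members),
        label=label,
    )


def per_field_min_chi2(
    dataset: DispersionDataset, members: Optional[Sequence[str]] = None
) -> Dict[float, float]:
    """Minimum chi-square from fitting each static field separately.

    Input to :func:`field_weighting`. Each single-field fit uses its own
    free kex and unweighted chi-square.
    """
    members = tuple(members if members is not None else dataset.residues())
    out = {}
    for mhz in sorted(dataset.points["field_mhz"].unique()):
        pts = dataset.points[dataset.points["field_mhz"] == mhz].reset_index(drop=True)
        sub = DispersionDataset(pts, float(mhz), dataset.exclusions)
        fit = fit_group(sub, [m for m in members if m in sub.residues()])
        out[float(mhz)] = fit.chi2
    return out


def kex_profile(
    dataset: DispersionDataset,
    members: Optional[Sequence[str]] = None,
    grid: Optional[np.ndarray] = None,
    field_weights: Optional[Mapping[float, float]] = None,
) -> KexProfile:
    """Chi-square vs fixed kex, refitting all other parameters at each point.

    The grid must span at least two decades with at least 25 points; the
    default is 60 log-spaced points over the kex search window.
    """
    if grid is None:
        grid = np.logspace(math.log10(KEX_BOUNDS[0]), math.log10(KEX_BOUNDS[1]), 60)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 25 or grid.max() / grid.min() < 100.0:
        raise ValueError("profile grid must have >= 25 points spanning >= 2 decades")
    members = tuple(members if members is not None else dataset.residues())
    blocks = _blocks(dataset, members, field_weights)
    vals = np.array([_chi2_at_kex(blocks, k) for k in grid])
    return KexProfile(grid=grid, chi2_values=vals)


def bic(chi2_value: float, n_params: int, n_points: int) -> float:
    """Bayesian information criterion BIC = chi^2 + k * ln(n)."""
    if n_points < 1:
        raise ValueError("BIC needs at least one data point")
    return float(chi2_value + n_params * math.log(n_points))


def combine_group_fits(
    fits: Sequence[GroupFitResult], label: str = "combined"
) -> GroupFitResult:
    """Combine fits of disjoint residue partitions into one composite model.

    Chi-square, parameter counts and point counts add; kex becomes
    per-residue. Used to compare, e.g., a two-group partition against a
    single global fit on the same point set.
    """
    members: List[str] = []
    phi: Dict[str, float] = {}
    plateaus: Dict[Tuple[str, float], float] = {}
    per_kex: Dict[str, float] = {}
    sig: List = []
    total_chi2 = total_pts = total_par = 0
    for f in fits:
        for m in f.member_residues:
            if m in phi:
                raise ValueError("partitions overlap; cannot combine")
            per_kex[m] = f.per_residue_kex[m] if f.per_residue_kex else f.kex
        members.extend(f.member_residues)
        phi.update(f.phi_ex)
        plateaus.update(f.r1rho_plateau)
        total_chi2 += f.chi2
        total_pts += f.n_points
        total_par += f.n_params
        sig.extend(f.points_signature)
    return GroupFitResult(
        member_residues=tuple(members),
        kex=float("nan"),
        phi_ex=phi,
        r1rho_plateau=plateaus,
        chi2=total_chi2,
        n_points=total_pts,
        n_params=total_par,
        field_weights=dict(fits[0].field_weights) if fits else {},
        per_residue_kex=per_kex,
        points_signature=tuple(sorted(sig)),
        label=label,
    )


def model_selection(candidates: Sequence[GroupFitResult]) -> List[GroupFitResult]:
    """Rank candidate models by BIC (ascending), ties broken by fewer parameters.

    All candidates must have been fitted on the identical point set,
    otherwise their BICs are not comparable and a ValueError is raised.
    """
    if not candidates:
        raise ValueError("no candidate models")
    sig0 = candidates[0].points_signature
    for c in candidates[1:]:
        if c.points_signature != sig0:
            raise ValueError("candidates fitted on different point sets")
    return sorted(candidates, key=lambda c: (c.bic, c.n_params))


def mc_fit_error(
    dataset: DispersionDataset,
    fit: GroupFitResult,
    replicates: int = 250,
    seed: int = 0,
    mode: str = "gaussian",
) -> GroupFitResult:
    """Monte-Carlo errors on kex and phi_ex: perturb rates, refit, 2 x SD.

    Replicate datasets are the fitted model's back-calculated rates plus
    noise scaled by each point's error (gaussian N(0, sigma) by default, or
    the one-sided literal U(0,1)*sigma mode). Each replicate re-searches
    kex locally within one decade of the base-fit value. Returns a copy of
    ``fit`` carrying kex_error and phi_ex_error; the errors are flagged
    unreliable (NaN) if more than 10% of replicates pin kex at the local
    search bounds.
    """
    if mode not in ("gaussian", "literal"):
        raise ValueError("mode must be 'gaussian' or 'literal'")
    members = fit.member_residues
    weights = fit.field_weights or None
    blocks = _blocks(dataset.restrict(members), members, weights)
    ref = dataset.reference_mhz
    # back-calculated rates per block (per-point field scaling)
    ideal = {}
    sigmas = {}
    for b in blocks:
        grp = dataset.points[dataset.points["residue_label"] == b.label]
        mhz = grp["field_mhz"].to_numpy()
        w1 = 2.0 * math.pi * grp["spinlock_khz"].to_numpy() * 1e3
        pred = np.array(
            [
                fit.predict(b.label, m, w, ref)
                for m, w in zip(mhz, w1)
            ]
        )
        ideal[b.label] = pred
        sigmas[b.label] = grp["error"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    lo, hi = math.log10(fit.kex) - 1.0, math.log10(fit.kex) + 1.0
    kex_reps = np.empty(replicates)
    phi_reps = {m: np.empty(replicates) for m in members}
    pinned = 0
    for r in range(replicates):
        rep_rates = {}
        for b in blocks:
            sig = sigmas[b.label]
            if mode == "gaussian":
                noise = rng.normal(0.0, 1.0, size=sig.size) * sig
            else:
                noise = rng.uniform(0.0, 1.0, size=sig.size) * sig
            rep_rates[b.label] = ideal[b.label] + noise

        def rep_chi2(logk):
            k = 10.0**logk
            return sum(b.solve(k, rep_rates[b.label])[2] for b in blocks)

        res = minimize_scalar(
            rep_chi2, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
        )
        k = float(10.0**res.x)
        if res.x - lo < 1e-4 or hi - res.x < 1e-4:
            pinned += 1
        kex_reps[r] = k
        for b in blocks:
            phi_reps[b.label][r] = b.solve(k, rep_rates[b.label])[0]
    reliable = pinned <= 0.1 * replicates
    kex_err = float(2.0 * np.std(kex_reps, ddof=1)) if reliable else float("nan")
    phi_err = {m: float(2.0 * np.std(v, ddof=1)) for m, v in phi_reps.items()}
    fit.kex_error = kex_err
    fit.phi_ex_error = phi_err
    return fit


def classify_dispersion(
    dataset: DispersionDataset, residue: str,
    field_weights: Optional[Mapping[float, float]] = None,
) -> str:
    """Classify a residue as 'dispersive' or 'flat' by BIC comparison.

    The exchange model (free kex, phi_ex, per-field plateau) is compared
    against a flat model (per-field plateau only, the error-weighted mean);
    the residue is dispersive iff the exchange model's BIC is lower.
    """
    pts = dataset.points[dataset.points["residue_label"] == residue]
    if pts["spinlock_khz"].nunique() < 3:
        raise ValueError("need >= 3 spin-lock points to classify")
    exch = fit_group(dataset, [residue], field_weights=field_weights)
    flat_chi2 = 0.0
    nf = 0
    for mhz, grp in pts.groupby("field_mhz"):
        y = grp["r1rho"].to_numpy(dtype=float)
        s = grp["error"].to_numpy(dtype=float)
        w = (field_weights or {}).get(float(mhz), 1.0)
        mean = np.sum(y / s**2) / np.sum(1.0 / s**2)
        flat_chi2 += w * float(np.sum((y - mean) ** 2 / s**2))
        nf += 1
    flat_bic = bic(flat_chi2, nf, len(pts))
    return "dispersive" if exch.bic < flat_bic else "flat"
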