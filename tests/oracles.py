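"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the closed-form expressions directly, with
its own constants and no imports from the package, so it stays an
independent check of the implementation path.
"""

import math

# CODATA constants, typed here independently of the package
_GAMMA_H = 2.6752218708e8      # rad s^-1 T^-1
_GAMMA_N_ABS = 2.7116e7        # rad s^-1 T^-1 (magnitude; 15N gamma is negative)
_MU0_OVER_4PI = 1.0e-7
_HBAR = 1.054571817e-34

# fixture values recorded from these oracles before the main build:
# NH dipolar and 15N CSA R1rho at r_NH = 1.02 A, 600 MHz, 60 kHz MAS,
# 10 kHz spin lock, S^2 = 0.99, tau = 67 us
DIPOLAR_FIXTURE = 0.8825593499845
CSA_FIXTURE = 0.3185157776463
TOTAL_FIXTURE = DIPOLAR_FIXTURE + CSA_FIXTURE


def smf_j(s2, tau, omega):
    return (1.0 - s2) * tau / (1.0 + (abs(omega) * tau) ** 2)


def oracle_dipolar(r_nh_ang, proton_mhz, mas_khz, spinlock_khz, s2, tau):
    """Term-by-term NH dipolar R1rho under MAS, simple model-free J."""
    w_h = 2.0 * math.pi * proton_mhz * 1e6
    w_n = w_h * _GAMMA_N_ABS / _GAMMA_H
    w_r = 2.0 * math.pi * mas_khz * 1e3
    w_1 = 2.0 * math.pi * spinlock_khz * 1e3
    d = _MU0_OVER_4PI * _HBAR * _GAMMA_H * _GAMMA_N_ABS / (r_nh_ang * 1e-10) ** 3
    total = 0.0
    total += (2.0 / 3.0) * smf_j(s2, tau, w_1 + 2.0 * w_r)
    total += (2.0 / 3.0) * smf_j(s2, tau, w_1 - 2.0 * w_r)
    total += (4.0 / 3.0) * smf_j(s2, tau, w_1 + w_r)
    total += (4.0 / 3.0) * smf_j(s2, tau, w_1 - w_r)
    total += 3.0 * smf_j(s2, tau, w_n)
    total += 1.0 * smf_j(s2, tau, w_h - w_n)
    total += 6.0 * smf_j(s2, tau, w_h)
    total += 6.0 * smf_j(s2, tau, w_h + w_n)
    return (1.0 / 20.0) * d * d * total


def oracle_csa(delta_sigma_ppm, proton_mhz, mas_khz, spinlock_khz, s2, tau):
    """Term-by-term 15N CSA R1rho under MAS (axially symmetric tensor)."""
    w_h = 2.0 * math.pi * proton_mhz * 1e6
    w_n = w_h * _GAMMA_N_ABS / _GAMMA_H
    w_r = 2.0 * math.pi * mas_khz * 1e3
    w_1 = 2.0 * math.pi * spinlock_khz * 1e3
    dw = delta_sigma_ppm * 1e-6 * w_n
    total = 0.0
    total += (2.0 / 3.0) * smf_j(s2, tau, w_1 + 2.0 * w_r)
    total += (2.0 / 3.0) * smf_j(s2, tau, w_1 - 2.0 * w_r)
    total += (4.0 / 3.0) * smf_j(s2, tau, w_1 + w_r)
    total += (4.0 / 3.0) * smf_j(s2, tau, w_1 - w_r)
    total += 3.0 * smf_j(s2, tau, w_n)
    return (1.0 / 45.0) * dw * dw * total


def oracle_bm(plateau, phi, kex, omega1, scale=1.0):
    return plateau + scale * phi * kex / (omega1 * omega1 + kex * kex)


def grid_search_chi2(points, kex_grid, phi_grid, plateau_grid, reference_mhz):
    """Exhaustive lattice minimum of the dispersion chi-square.

    ``points``: list of (residue, field_mhz, omega1, rate, sigma). For each
    lattice kex the best (phi, plateau-per-field) lattice pair is found per
    residue by full enumeration.
    """
    residues = sorted({p[0] for p in points})
    best = math.inf
    for kex in kex_grid:
        total = 0.0
        for res in residues:
            pts = [p for p in points if p[0] == res]
            fields = sorted({p[1] for p in pts})
            best_res = math.inf
            for phi in phi_grid:
                chi_fields = 0.0
                for f in fields:
                    scale = (f / reference_mhz) ** 2
                    best_f = math.inf
                    for r0 in plateau_grid:
                        c2 = sum(
                            (oracle_bm(r0, phi, kex, p[2], scale) - p[3]) ** 2
                            / p[4] ** 2
                            for p in pts
                            if p[1] == f
                        )
                        best_f = min(best_f, c2)
                    chi_fields += best_f
                best_res = min(best_res, chi_fields)
            total += best_res
        best = min(best, total)
    return best
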