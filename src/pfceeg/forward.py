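"""Analytic four-sphere EEG forward model.

The circuit's current dipole moment is mapped to a scalp potential through
the concentric brain/CSF/skull/scalp volume-conductor model (radii 79, 80,
85, 90 mm; conductivities 0.47, 1.71, 0.02, 0.41 S/m; purely resistive).
The solution is a Legendre series with per-shell matched boundary
conditions: in shell s the n-th harmonic is A_s (r/r_s)^n + B_s (r_s/r)^{n+1},
the free-space dipole expansion acts as the source term in the brain shell,
potential and radial current density are continuous at the three interfaces,
and no current leaves the scalp.  The per-harmonic 7x7 system is solved
numerically in a normalized basis (all powers < 1, so the series is stable
to high order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre, lpmv

__all__ = [
    "FourSphereModel",
    "neuron_dipole",
    "four_sphere_potential",
    "simulate_eeg",
]


def neuron_dipole(axial_current_nA, separation_um: float, orientation):
    """Current-dipole contribution of one neuron: p(t) = I_axial(t) * d * u.

    ``axial_current_nA`` is the somatic-to-apical axial current time series
    (nA), ``separation_um`` the sink-source separation (um), ``orientation``
    a unit 3-vector.  Returns an (n_t, 3) array in nA*um.  Contributions of
    multiple neurons sum linearly.
    """

    if separation_um <= 0:
        raise ValueError("separation must be positive")
    I = np.asarray(axial_current_nA, dtype=float)
    u = np.asarray(orientation, dtype=float)
    u = u / np.linalg.norm(u)
    return I[:, None] * (separation_um * u)[None, :]


@dataclass
class FourSphereModel:
    """Four concentric spheres with a point current dipole in the brain.

    Radii in mm (strictly increasing), conductivities in S/m.  The default
    dipole sits 0.7 mm below the brain surface (mid-L2/3 of a radially
    oriented cortical patch) on the z-axis, with a single vertex electrode
    directly above on the scalp.
    """

    radii_mm: tuple[float, float, float, float] = (79.0, 80.0, 85.0, 90.0)
    conductivities: tuple[float, float, float, float] = (0.47, 1.71, 0.02, 0.41)
    dipole_position_mm: tuple[float, float, float] = (0.0, 0.0, 78.3)
    electrode_position_mm: tuple[float, float, float] = (0.0, 0.0, 90.0)
    n_terms: int = 60
    max_terms: int = 1000
    tail_rtol: float = 1e-3
    _coeff_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        r = self.radii_mm
        if not all(r[i] < r[i + 1] for i in range(3)):
            raise ValueError("radii must be strictly increasing")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")
        rz = float(np.linalg.norm(self.dipole_position_mm))
        if not (0 < rz < r[0]):
            raise ValueError("dipole must lie strictly inside the brain sphere")
        re = float(np.linalg.norm(self.electrode_position_mm))
        if abs(re - r[3]) > 1e-6 * r[3]:
            raise ValueError("electrode must lie on the scalp surface")

    # -- per-harmonic scalp coefficients --------------------------------
    def _scalp_coefficients(self, n_max: int) -> np.ndarray:
        """G[n-1] = (A4 + B4) for a unit source amplitude, n = 1..n_max."""

        key = n_max
        if key in self._coeff_cache:
            return self._coeff_cache[key]
        r1, r2, r3, r4 = self.radii_mm
        s1, s2, s3, s4 = self.conductivities
        rz = float(np.linalg.norm(self.dipole_position_mm))
        G = np.zeros(n_max)
        for n in range(1, n_max + 1):
            q1 = (rz / r1) ** (n + 1)
            t12, t23, t34 = (r1 / r2) ** n, (r2 / r3) ** n, (r3 / r4) ** n
            u21, u32, u43 = (r2 / r1) ** (n + 1), (r3 / r2) ** (n + 1), (r4 / r3) ** (n + 1)
            # unknowns [A1, A2, B2, A3, B3, A4, B4]
            M = np.zeros((7, 7))
            rhs = np.zeros(7)
            np1 = n + 1.0
            # interface r1: potential continuity
            M[0] = [1.0, -t12, -u21, 0, 0, 0, 0]
            rhs[0] = -q1
            # interface r1: radial current continuity (times r1)
            M[1] = [s1 * n, -s2 * n * t12, s2 * np1 * u21, 0, 0, 0, 0]
            rhs[1] = s1 * np1 * q1
            # interface r2
            M[2] = [0, 1.0, 1.0, -t23, -u32, 0, 0]
            M[3] = [0, s2 * n, -s2 * np1, -s3 * n * t23, s3 * np1 * u32, 0, 0]
            # interface r3
            M[4] = [0, 0, 0, 1.0, 1.0, -t34, -u43]
            M[5] = [0, 0, 0, s3 * n, -s3 * np1, -s4 * n * t34, s4 * np1 * u43]
            # insulating scalp surface
            M[6] = [0, 0, 0, 0, 0, n, -np1]
            x = np.linalg.solve(M, rhs)
            G[n - 1] = x[5] + x[6]
        self._coeff_cache[key] = G
        return G

    # -- geometry --------------------------------------------------------
    def _angles(self):
        r0 = np.asarray(self.dipole_position_mm, dtype=float)
        re = np.asarray(self.electrode_position_mm, dtype=float)
        rz = np.linalg.norm(r0)
        rhat = r0 / rz
        ehat = re / np.linalg.norm(re)
        cos_theta = float(np.clip(rhat @ ehat, -1.0, 1.0))
        return rhat, ehat, cos_theta

    def transfer_vector(self) -> np.ndarray:
        """nV of scalp potential per unit dipole moment (nA*um) along x, y, z."""

        return np.array(
            [self.potential_nV(np.eye(3)[k]) for k in range(3)]
        )

    def potential_nV(self, moment_nAum) -> float:
        """Scalp potential (nV) at the electrode for a dipole moment (nA*um)."""

        p = np.asarray(moment_nAum, dtype=float)
        rhat, ehat, cos_theta = self._angles()
        p_rad = float(p @ rhat)
        p_tan_vec = p - p_rad * rhat
        p_tan = float(np.linalg.norm(p_tan_vec))
        if p_tan > 0:
            that = p_tan_vec / p_tan
            sin_theta = np.sqrt(max(0.0, 1.0 - cos_theta**2))
            cos_phi = float(that @ ehat) / sin_theta if sin_theta > 1e-12 else 0.0
        else:
            cos_phi = 0.0

        rz_m = np.linalg.norm(self.dipole_position_mm) * 1e-3
        # moment nA*um = 1e-15 A*m; output V -> nV is 1e9
        prefactor = 1e-6 / (4.0 * np.pi * self.conductivities[0] * rz_m**2)

        n_terms = self.n_terms
        while True:
            G = self._scalp_coefficients(n_terms)
            ns = np.arange(1, n_terms + 1)
            Pn = eval_legendre(ns, cos_theta)
            terms = p_rad * ns * G * Pn
            if p_tan > 0:
                Pn1 = lpmv(1, ns, cos_theta)
                terms = terms - p_tan * G * Pn1 * cos_phi
            total = float(np.sum(terms))
            tail = float(np.sum(np.abs(terms[-5:])))
            scale = max(abs(total), 1e-300)
            if tail / scale <= self.tail_rtol or n_terms >= self.max_terms:
                if tail / scale > self.tail_rtol:
                    warnings.warn(
                        "four-sphere series not converged at order "
                        f"{n_terms}; residual tail {tail / scale:.2e}",
                        RuntimeWarning,
                    )
                return prefactor * total
            n_terms = min(self.max_terms, n_terms * 2)


def four_sphere_potential(model: FourSphereModel, moment_nAum) -> float:
    """Scalp potential (nV) of a dipole moment (3-vector, nA*um)."""

    return model.potential_nV(moment_nAum)


def simulate_eeg(sim_result, model: FourSphereModel | None = None) -> np.ndarray:
    """EEG time series (nV) from a simulation's dipole moment series.

    The circuit dipole is radial (along the local apical axis, taken as the
    z/radial direction of the head model); the forward map is linear, so the
    whole series is one transfer coefficient times the moment series.
    """

    if model is None:
        model = FourSphereModel()
    k_z = model.potential_nV(np.array([0.0, 0.0, 1.0]))
    return k_z * np.asarray(sim_result.dipole_nAum, dtype=float)
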