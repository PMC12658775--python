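"""Three-shell spherical volume-conduction model and equivalent-dipole fitting.

The head is modelled as three concentric spherical shells (brain, skull,
scalp).  Surface potentials from a current dipole are computed with the
classical Legendre-series solution of Laplace's equation: in each shell the
potential is ``A r^n + B r^-(n+1)`` per spherical-harmonic degree ``n``, the
coefficients being fixed by continuity of potential and radial current at
each interface and a no-flux condition at the scalp surface.  The series is
truncated at ``n_terms`` (the terms decay like ``(b/R)^n`` for a dipole at
eccentricity ``b/R``).

All geometry is in millimetres; the default scalp radius is 85 mm with
brain/skull interfaces at the conventional 0.87/0.92 relative radii and
conductivities 0.33 / 0.0042 / 0.33 S/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.optimize import minimize

__all__ = ["HeadModel", "scalp_montage", "dipole_potential", "fit_dipole"]


@dataclass(frozen=True)
class HeadModel:
    """Concentric-shell conductor geometry (innermost shell first)."""

    radii_mm: tuple = (73.95, 78.2, 85.0)
    conductivities: tuple = (0.33, 0.0042, 0.33)
    n_terms: int = 40

    @property
    def scalp_radius(self) -> float:
        return self.radii_mm[-1]

    @property
    def brain_radius(self) -> float:
        return self.radii_mm[0]


def scalp_montage(n_channels: int, head: HeadModel | None = None) -> np.ndarray:
    """Idealized electrode montage: Fibonacci-spaced points on the upper cap.

    Returns (n_channels, 3) positions on the scalp sphere, in mm.  Electrodes
    cover the cap above z = 0 (plus a small rim margin), roughly emulating a
    10-05 style coverage without named positions.
    """
    head = head or HeadModel()
    golden = (1 + 5**0.5) / 2
    i = np.arange(n_channels)
    # z from near-vertex down to just above the equator
    z = 1.0 - 0.95 * (i + 0.5) / n_channels
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z**2)
    pts = np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    return pts * head.scalp_radius


_FACTOR_CACHE: dict = {}
_DERIV_CACHE: dict = {}


def _radial_surface_factors(head: HeadModel) -> np.ndarray:
    """Per-degree surface factors Phi_n(R) for a unit source coefficient.

    For each degree n, solves the shell linear system for the homogeneous
    coefficients given the particular (infinite-medium) source term
    r^-(n+1) in the innermost shell, and returns the total surface value
    A_M R^n + B_M R^-(n+1) + [source if M == 1].  Radii are normalized so
    that the scalp radius is 1.  Independent of the dipole, hence cached.
    """
    cached = _FACTOR_CACHE.get(head)
    if cached is not None:
        return cached
    radii = np.asarray(head.radii_mm, dtype=float) / head.scalp_radius
    sig = np.asarray(head.conductivities, dtype=float)
    m = len(radii)
    out = np.empty(head.n_terms + 1)
    out[0] = 0.0
    for n in range(1, head.n_terms + 1):
        size = 2 * m - 1
        a_mat = np.zeros((size, size))
        rhs = np.zeros(size)
        # unknowns: [A_1, A_2, B_2, ..., A_m, B_m]
        def col_a(j):  # A_j column index (j from 1)
            return 0 if j == 1 else 2 * j - 3

        def col_b(j):
            return 2 * j - 2

        row = 0
        for j in range(1, m):  # interface between shell j and j+1 at radii[j-1]
            r = radii[j - 1]
            # potential continuity
            a_mat[row, col_a(j)] += r**n
            if j > 1:
                a_mat[row, col_b(j)] += r ** -(n + 1)
            a_mat[row, col_a(j + 1)] -= r**n
            a_mat[row, col_b(j + 1)] -= r ** -(n + 1)
            if j == 1:
                rhs[row] = -(r ** -(n + 1))  # source term lives in shell 1
            row += 1
            # radial current continuity
            a_mat[row, col_a(j)] += sig[j - 1] * n * r ** (n - 1)
            if j > 1:
                a_mat[row, col_b(j)] -= sig[j - 1] * (n + 1) * r ** -(n + 2)
            a_mat[row, col_a(j + 1)] -= sig[j] * n * r ** (n - 1)
            a_mat[row, col_b(j + 1)] += sig[j] * (n + 1) * r ** -(n + 2)
            if j == 1:
                rhs[row] = sig[0] * (n + 1) * r ** -(n + 2)
            row += 1
        # insulating outer boundary at r = 1
        a_mat[row, col_a(m)] = n
        if m > 1:
            a_mat[row, col_b(m)] = -(n + 1)
        else:
            rhs[row] = (n + 1)  # single-shell: balance the source gradient
        coef = np.linalg.solve(a_mat, rhs)
        val = coef[col_a(m)]
        if m > 1:
            val += coef[col_b(m)]
        else:
            val += 1.0  # source term at the surface
        out[n] = val
    _FACTOR_CACHE[head] = out
    return out


def _legendre_deriv_matrix(n_terms: int) -> np.ndarray:
    """Coefficient matrix mapping the Legendre basis to P'_n rows; cached."""
    cached = _DERIV_CACHE.get(n_terms)
    if cached is not None:
        return cached
    dcoefs = np.zeros((n_terms + 1, n_terms + 1))
    for n in range(1, n_terms + 1):
        c = np.zeros(n_terms + 1)
        c[n] = 1.0
        dcoefs[n, :n_terms] = npleg.legder(c)[:n_terms]
    _DERIV_CACHE[n_terms] = dcoefs
    return dcoefs


def dipole_potential(
    location_mm: np.ndarray,
    moment: np.ndarray,
    electrodes_mm: np.ndarray,
    head: HeadModel | None = None,
) -> np.ndarray:
    """Scalp potential of a current dipole inside the innermost shell.

    Parameters
    ----------
    location_mm : (3,) dipole position, must lie inside the brain shell.
    moment : (3,) dipole moment (arbitrary units; output is linear in it).
    electrodes_mm : (n, 3) scalp electrode positions.

    Returns the potential at each electrode (not average-referenced).
    """
    head = head or HeadModel()
    r0 = np.asarray(location_mm, dtype=float) / head.scalp_radius
    q = np.asarray(moment, dtype=float)
    elec = np.asarray(electrodes_mm, dtype=float) / head.scalp_radius
    b = np.linalg.norm(r0)
    if b * head.scalp_radius >= head.radii_mm[0]:
        raise ValueError("dipole lies outside the innermost (brain) shell")
    factors = _radial_surface_factors(head)
    ns = np.arange(1, head.n_terms + 1)

    if b < 1e-9:
        rhat0 = np.array([0.0, 0.0, 1.0])
    else:
        rhat0 = r0 / b
    q_r = float(q @ rhat0)
    q_tan = q - q_r * rhat0
    qt = np.linalg.norm(q_tan)
    that = q_tan / qt if qt > 1e-15 else np.zeros(3)

    ehat = elec / np.linalg.norm(elec, axis=1, keepdims=True)
    x = np.clip(ehat @ rhat0, -1.0, 1.0)  # cos(gamma)
    # Legendre P_n(x) and derivative P'_n(x) for n = 0..n_terms
    vander = npleg.legvander(x, head.n_terms)  # (n_elec, n_terms+1)
    dcoefs = _legendre_deriv_matrix(head.n_terms)
    dp = vander[:, : head.n_terms] @ dcoefs[:, : head.n_terms].T  # P'_n(x)

    bpow = b ** (ns - 1.0)
    fac = factors[1:] * bpow / (4 * np.pi * head.conductivities[0])
    # radial part: n * q_r * P_n(x)
    v = (vander[:, 1:] * ns) @ fac * q_r
    if qt > 1e-15:
        # tangential part: q_t * P^1_n(x) cos(phi); P^1_n(x)cos(phi) =
        # sin(gamma) P'_n(x) * (t_hat . e_perp_hat) with the regular form
        # (e_hat - x r_hat0) . t_hat = sin(gamma) cos(phi)
        cosphi_sing = (ehat - x[:, None] * rhat0[None, :]) @ that
        v = v + (dp[:, ns] @ fac) * cosphi_sing * qt
    # scale: potentials were computed with radii normalized to 1
    return v / head.scalp_radius**2


def _leadfield(location_mm, electrodes_mm, head):
    cols = [
        dipole_potential(location_mm, m, electrodes_mm, head)
        for m in np.eye(3)
    ]
    lf = np.stack(cols, axis=1)
    return lf - lf.mean(axis=0, keepdims=True)


def fit_dipole(
    scalp_map: np.ndarray,
    electrodes_mm: np.ndarray,
    head: HeadModel | None = None,
    n_grid: int = 120,
    seed_starts: int = 3,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit a single equivalent current dipole to a scalp map.

    Coarse grid search inside the brain shell followed by Nelder-Mead
    refinement; the moment is solved linearly at each candidate location.

    Returns ``(location_mm, moment, residual_variance)`` where residual
    variance is the fraction of (average-referenced) map variance left
    unexplained.  On optimizer failure an RV of 1.0 is returned.
    """
    head = head or HeadModel()
    y = np.asarray(scalp_map, dtype=float)
    y = y - y.mean()
    denom = float(y @ y)
    if denom <= 0:
        return np.zeros(3), np.zeros(3), 1.0

    def rv_at(loc):
        r = np.linalg.norm(loc)
        if r >= 0.95 * head.brain_radius:
            return 1.0 + r / head.brain_radius, None
        lf = _leadfield(loc, electrodes_mm, head)
        m, *_ = np.linalg.lstsq(lf, y, rcond=None)
        resid = y - lf @ m
        return float(resid @ resid) / denom, m

    # quasi-random interior grid
    rng = np.random.default_rng(0)
    pts = rng.uniform(-1, 1, size=(n_grid * 3, 3))
    pts = pts[np.linalg.norm(pts, axis=1) < 0.9][:n_grid] * head.brain_radius
    scores = [rv_at(p)[0] for p in pts]
    order = np.argsort(scores)
    best_rv, best_loc, best_m = np.inf, np.zeros(3), np.zeros(3)
    try:
        for idx in order[:seed_starts]:
            res = minimize(
                lambda p: rv_at(p)[0], pts[idx], method="Nelder-Mead",
                options={"xatol": 0.05, "fatol": 1e-7, "maxiter": 400},
            )
            rv, m = rv_at(res.x)
            if rv < best_rv and m is not None:
                best_rv, best_loc, best_m = rv, res.x, m
    except (np.linalg.LinAlgError, ValueError):
        return np.zeros(3), np.zeros(3), 1.0
    if not np.isfinite(best_rv) or best_m is None or best_rv > 1.0:
        return best_loc, np.zeros(3), 1.0
    return best_loc, best_m, best_rv
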