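"""Geometry-derived steric descriptors computed per conformer.

Implements the steric quantities tabulated for each conformer of an ensemble:
Sterimol L/B1/B5 along a moiety bond axis, percent buried volume around an
atom, trivalent-nitrogen pyramidalization, Shrake-Rupley solvent-accessible
surface area, grid-integrated solvent-accessible volume, and a point-charge
dipole moment.

Van der Waals radii default to the Bondi set; buried volume conventionally
scales them by 1.17.  All lengths angstrom, areas angstrom^2, volumes
angstrom^3, angles degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Bondi (1964) van der Waals radii, angstrom, with the common extensions for
# B (Mantina et al. 2009).  Unknown elements raise; no silent default.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "As": 1.85, "Se": 1.90, "Br": 1.85, "Kr": 2.02,
    "Sn": 2.17, "Te": 2.06, "I": 1.98, "Xe": 2.16,
}


@dataclass(frozen=True)
class RadiiTable:
    """Element -> vdW radius lookup with a multiplicative scale factor."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    scale: float = 1.0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("all radii must be positive")

    def __getitem__(self, element: str) -> float:
        try:
            return self.radii[element] * self.scale
        except KeyError:
            raise KeyError(
                f"no van der Waals radius for element {element!r}; extend the "
                "RadiiTable explicitly"
            ) from None

    def for_symbols(self, symbols: list[str]) -> np.ndarray:
        return np.array([self[s] for s in symbols])


STERIMOL_RADII = RadiiTable(scale=1.0)
VBUR_RADII = RadiiTable(scale=1.17)  # the usual %Vbur convention


@dataclass(frozen=True)
class SterimolResult:
    L: float
    B1: float
    B5: float
    axis_from_role: str = ""
    axis_to_role: str = ""


def _substituent_atoms(
    n_atoms: int, bonds: list[tuple[int, int]], attach_idx: int, first_idx: int
) -> list[int]:
    """Atoms on the ``first_idx`` side of the cut attach-first bond."""
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    seen = {attach_idx, first_idx}
    stack = [first_idx]
    out = [first_idx]
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if nb not in seen:
                seen.add(nb)
                out.append(nb)
                stack.append(nb)
    return sorted(out)


def _b1_exact(q2d: np.ndarray, radii: np.ndarray) -> float:
    """Minimum over in-plane unit directions v of max_i(q_i . v + r_i).

    f(theta) = max_i(A_i cos(theta - phi_i) + r_i) is a pointwise max of
    shifted sinusoids, so its minimum lies either at the minimum of one branch
    (theta = phi_i + pi) or at a crossing of two branches; all candidates are
    enumerated and the smallest f value returned.
    """
    amp = np.hypot(q2d[:, 0], q2d[:, 1])
    phi = np.arctan2(q2d[:, 1], q2d[:, 0])

    def f(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_1d(theta)
        vals = amp[None, :] * np.cos(theta[:, None] - phi[None, :]) + radii[None, :]
        return vals.max(axis=1)

    candidates = list(phi + np.pi)
    n = len(radii)
    for i in range(n):
        for j in range(i + 1, n):
            # A_i cos(t - phi_i) - A_j cos(t - phi_j) = r_j - r_i
            c = amp[i] * np.cos(phi[i]) - amp[j] * np.cos(phi[j])
            s = amp[i] * np.sin(phi[i]) - amp[j] * np.sin(phi[j])
            k = radii[j] - radii[i]
            norm = np.hypot(c, s)
            if norm < 1e-15:
                continue
            if abs(k) <= norm:
                base = np.arctan2(s, c)
                delta = np.arccos(np.clip(k / norm, -1.0, 1.0))
                candidates.extend([base + delta, base - delta])
    return float(f(np.array(candidates)).min())


def sterimol(
    coords: np.ndarray,
    symbols: list[str],
    attach_idx: int,
    first_idx: int,
    radii: RadiiTable = STERIMOL_RADII,
    bonds: list[tuple[int, int]] | None = None,
    substituent: list[int] | None = None,
    axis_from_role: str = "",
    axis_to_role: str = "",
    l_correction: float = 0.0,
) -> SterimolResult:
    """Sterimol L/B1/B5 of the substituent rooted at ``first_idx``.

    The axis u points from the attachment atom to the first substituent atom.
    With p_i the substituent-atom positions measured from the attachment atom
    and r_i their vdW radii: L = max_i(p_i.u + r_i); the perpendicular
    components q_i give B5 = max_i(|q_i| + r_i) and B1 as the minimum over
    perpendicular directions v of max_i(q_i.v + r_i).  The historical
    Verloop +0.40 A bond-length correction is off by default
    (``l_correction``).

    The substituent is either given explicitly or derived from ``bonds`` as
    the connected component of ``first_idx`` once the attach-first bond is cut.
    """
    coords = np.asarray(coords, float)
    if attach_idx == first_idx:
        raise ValueError("attach_idx and first_idx must differ")
    if substituent is None:
        if bonds is None:
            raise ValueError("provide either bonds or an explicit substituent list")
        substituent = _substituent_atoms(len(coords), bonds, attach_idx, first_idx)
    if not substituent:
        raise ValueError("substituent is empty")

    origin = coords[attach_idx]
    u = coords[first_idx] - origin
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise ValueError("attach and first atoms are coincident")
    u = u / nu

    p = coords[substituent] - origin
    r = radii.for_symbols([symbols[i] for i in substituent])

    along = p @ u
    L = float(np.max(along + r)) + l_correction

    q = p - np.outer(along, u)
    B5 = float(np.max(np.linalg.norm(q, axis=1) + r))

    # orthonormal in-plane basis
    e1 = np.array([1.0, 0.0, 0.0])
    if abs(u @ e1) > 0.9:
        e1 = np.array([0.0, 1.0, 0.0])
    e1 = e1 - (e1 @ u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    q2d = np.column_stack([q @ e1, q @ e2])
    B1 = _b1_exact(q2d, r)

    return SterimolResult(L=L, B1=B1, B5=B5,
                          axis_from_role=axis_from_role, axis_to_role=axis_to_role)


def buried_volume(
    coords: np.ndarray,
    symbols: list[str],
    center_idx: int,
    sphere_r: float = 3.5,
    radii: RadiiTable = VBUR_RADII,
    grid: float = 0.05,
) -> float:
    """Percent of the probe sphere buried by the vdW spheres of other atoms.

    A uniform Cartesian grid of spacing ``grid`` fills the sphere of radius
    ``sphere_r`` centred on atom ``center_idx``; the returned value is the
    percentage of those grid points falling inside the union of the scaled vdW
    spheres of all *other* atoms (the central atom is excluded, hydrogens are
    included).
    """
    if sphere_r <= 0:
        raise ValueError("sphere_r must be positive")
    coords = np.asarray(coords, float)
    center = coords[center_idx]

    ax = np.arange(-sphere_r, sphere_r + grid / 2, grid)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.einsum("ij,ij->i", pts, pts) <= sphere_r**2]
    n_sphere = len(pts)

    buried = np.zeros(n_sphere, dtype=bool)
    for i, (pos, sym) in enumerate(zip(coords, symbols)):
        if i == center_idx:
            continue
        r = radii[sym]
        d_center = np.linalg.norm(pos - center)
        if d_center > sphere_r + r:
            continue
        d2 = np.einsum("ij,ij->i", pts - (pos - center), pts - (pos - center))
        buried |= d2 <= r**2
    return 100.0 * float(buried.sum()) / n_sphere


def pyramidalization(coords: np.ndarray, n_idx: int, neighbor_idx: list[int]) -> float:
    """360 degrees minus the sum of the three bond angles at ``n_idx``.

    Zero for a perfectly planar center; ~31.6 degrees for ideal sp3.
    """
    if len(neighbor_idx) != 3:
        raise ValueError("pyramidalization requires exactly 3 bonded neighbors")
    coords = np.asarray(coords, float)
    c = coords[n_idx]
    vecs = [coords[j] - c for j in neighbor_idx]
    vecs = [v / np.linalg.norm(v) for v in vecs]
    pairs = [(0, 1), (0, 2), (1, 2)]
    total = sum(
        np.degrees(np.arccos(np.clip(vecs[a] @ vecs[b], -1.0, 1.0))) for a, b in pairs
    )
    return 360.0 - float(total)


def _golden_spiral(n: int) -> np.ndarray:
    """n near-uniform unit vectors (Fibonacci sphere)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa_and_volume(
    coords: np.ndarray,
    symbols: list[str],
    radii: RadiiTable = STERIMOL_RADII,
    probe: float = 1.4,
    n_points: int = 960,
    grid: float = 0.2,
) -> tuple[float, float]:
    """Shrake-Rupley SASA and grid-integrated solvent-accessible volume.

    SASA scatters ``n_points`` test points on each probe-inflated sphere and
    counts those outside every other inflated sphere.  The volume integrates
    the union of the inflated spheres on a Cartesian grid of the given
    spacing.
    """
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    coords = np.asarray(coords, float)
    if len(coords) == 0:
        raise ValueError("empty conformer")
    r_inf = radii.for_symbols(symbols) + probe

    sphere = _golden_spiral(n_points)
    sasa = 0.0
    for i in range(len(coords)):
        pts = coords[i] + r_inf[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) >= r_inf[i] + r_inf[j]:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= r_inf[j] ** 2
        sasa += 4.0 * np.pi * r_inf[i] ** 2 * accessible.sum() / n_points

    # volume: midpoint grid integration with linear antialiasing of boundary
    # cells via the signed distance to the sphere-union surface
    lo = (coords - r_inf[:, None]).min(axis=0) - grid
    hi = (coords + r_inf[:, None]).max(axis=0) + grid
    axes = [np.arange(lo[d], hi[d] + grid / 2, grid) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    sdist = np.full(len(pts), np.inf)
    for i in range(len(coords)):
        d = np.sqrt(np.einsum("ij,ij->i", pts - coords[i], pts - coords[i]))
        sdist = np.minimum(sdist, d - r_inf[i])
    weight = np.clip(0.5 - sdist / grid, 0.0, 1.0)
    volume = float(weight.sum()) * grid**3
    return float(sasa), volume


E_ANGSTROM_TO_DEBYE = 4.80320


def point_charge_dipole(coords: np.ndarray, charges: np.ndarray) -> float:
    """|sum q_i p_i| in Debye (1 e.angstrom = 4.80320 D).

    Origin-independent only for a net-neutral charge set; a warning is issued
    otherwise.
    """
    import warnings

    coords = np.asarray(coords, float)
    charges = np.asarray(charges, float)
    if len(charges) != len(coords):
        raise ValueError("one charge per atom required")
    if abs(charges.sum()) > 1e-6:
        warnings.warn(
            "net charge is nonzero; the point-charge dipole is origin-dependent",
            stacklevel=2,
        )
    mu = charges @ coords
    return float(np.linalg.norm(mu)) * E_ANGSTROM_TO_DEBYE
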