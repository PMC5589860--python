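"""Spherical head model: source grid, electrode montage, analytic lead field.

The grid is a regular cubic lattice clipped to a spherical shell; the inner
shell radius is auto-tuned so the node count approaches a target (~3005 at
6 mm spacing).  The forward model is the classical dipole-in-concentric-
spheres solution (three shells, brain/skull/scalp) evaluated by a Legendre
series; per-degree radial transfer factors are obtained by solving the
boundary-condition system for each harmonic degree, so the same code covers
the homogeneous single-sphere limit (equal conductivities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .containers import Montage

__all__ = [
    "SourceSpace",
    "LeadField",
    "build_source_grid",
    "load_montage",
    "fit_to_sphere",
    "standard_64_montage",
    "compute_lead_field",
]

DEFAULT_HEAD_RADIUS = 85.0  # mm
DEFAULT_RADII_FRACTIONS = (0.87, 0.92, 1.0)  # brain / skull / scalp
DEFAULT_CONDUCTIVITIES = (1.0, 1.0 / 80.0, 1.0)  # relative, brain : skull : scalp
BRAIN_CONDUCTIVITY = 0.33  # S/m, absolute scale


# ---------------------------------------------------------------------------
# source space


@dataclass
class SourceSpace:
    """Cubic-lattice nodes inside a spherical shell (positions in mm)."""

    nodes: np.ndarray
    spacing: float
    head_radius: float
    inner_radius: float
    outer_radius: float

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def adjacency(self, radius: float) -> sparse.csr_matrix:
        """Symmetric node adjacency: pairs closer than ``radius`` (mm)."""
        tree = cKDTree(self.nodes)
        mat = tree.sparse_distance_matrix(tree, max_distance=radius)
        mat = mat.tocsr()
        mat.setdiag(0.0)
        mat.eliminate_zeros()
        adj = mat.copy()
        adj.data[:] = 1.0
        return adj


def _shell_grid(spacing: float, r_inner: float, r_outer: float) -> np.ndarray:
    k = int(np.floor(r_outer / spacing))
    ax = np.arange(-k, k + 1) * spacing
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    r = np.linalg.norm(pts, axis=1)
    return pts[(r >= r_inner) & (r <= r_outer)]


def build_source_grid(
    head_radius: float = DEFAULT_HEAD_RADIUS,
    spacing: float = 6.0,
    shell: tuple[float, float] = (0.35, 0.80),
    target_n: int = 3005,
    tolerance: float = 0.10,
) -> SourceSpace:
    """Regular grid clipped to a spherical shell, tuned to ``target_n`` nodes.

    The outer shell fraction is fixed; the inner fraction is adjusted by
    bisection until the node count is within ``tolerance`` of ``target_n``
    (a warning reports the achieved count when the target is unattainable).
    """
    inner_frac, outer_frac = shell
    if not 0.0 < inner_frac < outer_frac <= 1.0:
        raise ValueError("shell fractions must satisfy 0 < inner < outer <= 1")
    r_outer = outer_frac * head_radius

    def count(ri: float) -> int:
        return _shell_grid(spacing, ri, r_outer).shape[0]

    lo, hi = 0.0, r_outer  # node count decreases monotonically in ri
    ri = inner_frac * head_radius
    n = count(ri)
    if abs(n - target_n) > tolerance * target_n:
        for _ in range(60):
            ri = 0.5 * (lo + hi)
            n = count(ri)
            if n > target_n:
                lo = ri
            else:
                hi = ri
            if abs(n - target_n) <= tolerance * target_n:
                break
        else:
            pass
    if abs(n - target_n) > tolerance * target_n:
        warnings.warn(
            f"could not reach target node count {target_n}; achieved {n}"
        )
    nodes = _shell_grid(spacing, ri, r_outer)
    return SourceSpace(
        nodes=nodes,
        spacing=spacing,
        head_radius=head_radius,
        inner_radius=ri,
        outer_radius=r_outer,
    )


# ---------------------------------------------------------------------------
# montage


# Idealized 10-10 layout: each electrode is placed by an anterior-posterior
# tilt angle (deg, + forward) and a lateral angle (deg, + right), both from
# the vertex.  Rows step by 18 deg, matching the classical equal-arc scheme.
_ROWS: list[tuple[float, list[tuple[str, float]]]] = [
    (72.0, [("Fp1", -18), ("Fpz", 0), ("Fp2", 18)]),
    (54.0, [("AF7", -36), ("AF3", -18), ("AFz", 0), ("AF4", 18), ("AF8", 36)]),
    (36.0, [("F7", -54), ("F5", -40.5), ("F3", -27), ("F1", -13.5), ("Fz", 0),
            ("F2", 13.5), ("F4", 27), ("F6", 40.5), ("F8", 54)]),
    (18.0, [("FT7", -72), ("FC5", -54), ("FC3", -36), ("FC1", -18), ("FCz", 0),
            ("FC2", 18), ("FC4", 36), ("FC6", 54), ("FT8", 72)]),
    (0.0, [("T7", -72), ("C5", -54), ("C3", -36), ("C1", -18), ("Cz", 0),
           ("C2", 18), ("C4", 36), ("C6", 54), ("T8", 72)]),
    (-18.0, [("TP7", -72), ("CP5", -54), ("CP3", -36), ("CP1", -18), ("CPz", 0),
             ("CP2", 18), ("CP4", 36), ("CP6", 54), ("TP8", 72)]),
    (-36.0, [("P9", -72), ("P7", -54), ("P5", -40.5), ("P3", -27), ("P1", -13.5),
             ("Pz", 0), ("P2", 13.5), ("P4", 27), ("P6", 40.5), ("P8", 54),
             ("P10", 72)]),
    (-54.0, [("PO7", -36), ("PO3", -18), ("POz", 0), ("PO4", 18), ("PO8", 36)]),
    (-72.0, [("O1", -18), ("Oz", 0), ("O2", 18)]),
    (-90.0, [("Iz", 0)]),
]


def standard_64_montage(head_radius: float = DEFAULT_HEAD_RADIUS) -> Montage:
    """Idealized 64-channel 10-10 montage on a sphere of ``head_radius`` mm.

    Coordinates: x right, y anterior, z superior, head-centered.
    """
    labels: list[str] = []
    pos: list[np.ndarray] = []
    for ap, row in _ROWS:
        a = np.deg2rad(ap)
        for lab, lat in row:
            b = np.deg2rad(lat)
            u = np.array([np.sin(b), np.cos(b) * np.sin(a), np.cos(b) * np.cos(a)])
            labels.append(lab)
            pos.append(head_radius * u)
    return Montage(labels=labels, positions=np.asarray(pos))


def load_montage(path: str | None = None) -> Montage:
    """Read a .sfp montage; with no path, the packaged 64-channel fixture."""
    if path is None:
        ref = resources.files("enigo").joinpath("data/biosemi64.sfp")
        with resources.as_file(ref) as p:
            return Montage.load_sfp(p)
    return Montage.load_sfp(path)


def fit_to_sphere(montage: Montage, head_radius: float = DEFAULT_HEAD_RADIUS) -> Montage:
    """Project electrode positions radially onto the head sphere."""
    r = montage.radii()
    if (r == 0).any():
        raise ValueError("electrode at the head center cannot be projected")
    pos = montage.positions * (head_radius / r)[:, None]
    return Montage(labels=list(montage.labels), positions=pos)


# ---------------------------------------------------------------------------
# lead field


@dataclass
class LeadField:
    """Gain mapping dipole moments to scalp potentials.

    ``gain`` has shape (electrodes, nodes, 3) in microvolts per nA*m; every
    (node, component) column is average-referenced.
    """

    gain: np.ndarray
    montage: Montage
    space: SourceSpace
    head_radius: float
    radii_fractions: tuple[float, float, float] = DEFAULT_RADII_FRACTIONS
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.gain.shape[1]

    def gain2d(self) -> np.ndarray:
        """Gain reshaped (electrodes, 3 * nodes), node-major."""
        return self.gain.reshape(self.n_channels, 3 * self.n_nodes)


def _radial_transfer(
    n_max: int,
    radii: tuple[float, float, float],
    sigmas: tuple[float, float, float],
) -> np.ndarray:
    """Per-degree scalp response to a unit r^-(n+1) primary term.

    Radii are normalized to the outer (scalp) surface.  For each degree n
    the Laplace solutions in the three shells are matched (potential and
    radial current continuity at the two interfaces, zero current at the
    scalp) and the scalp-surface value of the total potential is returned.
    In the homogeneous limit the result is (2n+1)/n analytically.
    """
    r1, r2, r3 = radii
    s1, s2, s3 = sigmas
    g = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3 ; source term r^-(n+1) lives in shell 1
        a = np.zeros((5, 5))
        b = np.zeros(5)
        rn1, rm1 = r1**n, r1 ** -(n + 1)
        rn2, rm2 = r2**n, r2 ** -(n + 1)
        rn3, rm3 = r3**n, r3 ** -(n + 1)
        # potential continuity at r1
        a[0] = [rn1, -rn1, -rm1, 0, 0]
        b[0] = -rm1
        # current continuity at r1
        a[1] = [s1 * n * rn1, -s2 * n * rn1, s2 * (n + 1) * rm1, 0, 0]
        b[1] = s1 * (n + 1) * rm1
        # potential continuity at r2
        a[2] = [0, rn2, rm2, -rn2, -rm2]
        # current continuity at r2
        a[3] = [0, s2 * n * rn2, -s2 * (n + 1) * rm2, -s3 * n * rn2, s3 * (n + 1) * rm2]
        # insulating outer boundary at r3
        a[4] = [0, 0, 0, n * rn3, -(n + 1) * rm3]
        sol = np.linalg.solve(a, b)
        g[n] = sol[3] * rn3 + sol[4] * rm3
    return g


def compute_lead_field(
    space: SourceSpace,
    montage: Montage,
    model: str = "three_shell",
    radii_fractions: tuple[float, float, float] = DEFAULT_RADII_FRACTIONS,
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES,
    brain_conductivity: float = BRAIN_CONDUCTIVITY,
    tol: float = 1e-6,
    n_max: int = 300,
) -> LeadField:
    """Analytic dipole-in-concentric-spheres lead field.

    ``model='three_shell'`` uses the given conductivity ratios;
    ``'single_shell'`` forces a homogeneous sphere.  Gain columns are
    average-referenced.  Nodes must lie strictly inside the innermost
    conducting shell.
    """
    if montage.n_channels < 32:
        raise ValueError("need >= 32 electrodes for a stable inversion")
    if model == "single_shell":
        conductivities = (1.0, 1.0, 1.0)
    elif model != "three_shell":
        raise ValueError(f"unknown model {model!r}")

    R = space.head_radius
    elec = montage.positions / R
    elec_r = np.linalg.norm(elec, axis=1)
    if not np.allclose(elec_r, 1.0, atol=1e-6):
        raise ValueError("montage must lie on the head sphere; use fit_to_sphere")

    nodes = space.nodes / R
    b = np.linalg.norm(nodes, axis=1)
    if np.any(b >= 0.95 * radii_fractions[0]):
        raise ValueError("source node too close to the inner shell boundary")

    rho_max = float(b.max())
    if rho_max > 0:
        n_need = int(np.ceil(np.log(tol) / np.log(max(rho_max, 0.1))))
        n_terms = int(np.clip(n_need, 40, n_max))
    else:
        n_terms = 40
    g = _radial_transfer(n_terms, radii_fractions, conductivities)

    node_dir = np.where(b[:, None] > 0, nodes / np.where(b[:, None] > 0, b[:, None], 1.0), 0.0)
    x = node_dir @ elec.T  # (nodes, electrodes) cos of angle
    x = np.clip(x, -1.0, 1.0)

    # Legendre recurrences accumulated over degrees:
    #   S1 = sum_n g_n n rho^(n-1) P_n(x),  S2 = sum_n g_n rho^(n-1) P_n'(x)
    p_nm1 = np.ones_like(x)       # P_0
    p_n = x.copy()                # P_1
    dp_nm1 = np.zeros_like(x)     # P_0'
    dp_n = np.ones_like(x)        # P_1'
    rho_pow = np.ones_like(b)     # rho^(n-1) at n=1
    s1 = np.zeros_like(x)
    s2 = np.zeros_like(x)
    for n in range(1, n_terms + 1):
        w = g[n] * rho_pow[:, None]
        s1 += n * w * p_n
        s2 += w * dp_n
        if n == n_terms:
            break
        p_np1 = ((2 * n + 1) * x * p_n - n * p_nm1) / (n + 1)
        dp_np1 = ((2 * n + 1) * (p_n + x * dp_n) - n * dp_nm1) / (n + 1)
        p_nm1, p_n = p_n, p_np1
        dp_nm1, dp_n = dp_n, dp_np1
        rho_pow = rho_pow * b

    # V = K [ S1 (q . r_hat_q) + S2 (q . (r_hat_e - x r_hat_q)) ]
    R_m = R * 1e-3  # mm -> m
    K = 1.0 / (4.0 * np.pi * brain_conductivity * R_m**2)
    n_el, n_nd = montage.n_channels, space.n_nodes
    gain = np.empty((n_el, n_nd, 3))
    for c in range(3):
        radial = node_dir[:, c][:, None]          # (nodes, 1)
        tang = elec[None, :, c] - x * radial      # (nodes, electrodes)
        v = K * (s1 * radial + s2 * tang)         # volts per A*m
        gain[:, :, c] = v.T * 1e-3               # microvolts per nA*m

    gain -= gain.mean(axis=0, keepdims=True)  # average reference
    return LeadField(
        gain=gain,
        montage=montage,
        space=space,
        head_radius=R,
        radii_fractions=radii_fractions,
        conductivities=conductivities,
        meta={"model": model, "n_terms": n_terms},
    )
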