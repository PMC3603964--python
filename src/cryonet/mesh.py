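"""Axisymmetric structured meshes for the cell interior.

The oocyte is an ellipsoid of revolution; the nucleus is a smaller offset
ellipsoid whose centre displacement (8 um) is less than its on-axis
semi-axis (15.15 um), so the nucleus contains the cell centre and every ray
from the origin crosses nucleus first, cytoplasm second.  The mesh exploits
this: rays at fixed polar angles theta_j carry a block of radial layers
fitted to the nucleus surface b(theta) and a block fitted between b(theta)
and the membrane R(theta).  Cell shrinkage rescales only the outer block
(Lagrangian layer rescaling); the nucleus never moves.

Cells are quadrilaterals in the (rho, z) half-plane revolved about the z
axis; volumes and face areas are exact for the polygonal boundary
(Pappus-type formulas), so refinement converges to the analytic ellipsoid
volume.

A 1-D slab constructor is provided for analytic diffusion benchmarks; it
shares the generic cell/face arrays with the axisymmetric mesh so the same
finite-volume solver runs on both.
"""

from __future__ import annotations

import numpy as np

from .params import CellGeometry, ConfigurationError

__all__ = ["Mesh", "ellipse_radius", "nucleus_radius"]

REGION_CYTO = 0
REGION_NUC = 1


def ellipse_radius(theta, a, b):
    """Radius of an axisymmetric ellipse boundary along polar angle theta.

    ``a`` is the semi-axis along the symmetry (z) axis, ``b`` transverse.
    """
    ct, st = np.cos(theta), np.sin(theta)
    return 1.0 / np.sqrt((ct / a) ** 2 + (st / b) ** 2)


def nucleus_radius(theta, geom: CellGeometry):
    """Distance from the cell centre to the nucleus surface along theta (um).

    Solves ((r cos t - d)/s_maj)^2 + (r sin t / s_min)^2 = 1 for the
    positive root; requires the origin inside the nucleus (d < s_maj).
    """
    ct, st = np.cos(theta), np.sin(theta)
    A = (ct / geom.s_maj) ** 2 + (st / geom.s_min) ** 2
    B = -2.0 * geom.d_nlr * ct / geom.s_maj ** 2
    C = (geom.d_nlr / geom.s_maj) ** 2 - 1.0
    disc = B * B - 4.0 * A * C
    if np.any(disc <= 0):
        raise ConfigurationError("nucleus does not contain the cell centre")
    return (-B + np.sqrt(disc)) / (2.0 * A)


def _revolved_volume(rho, z):
    """Volume of revolution of closed polygons given vertex arrays.

    rho, z have shape (..., nv); vertices traversed in order.  Uses
    V = pi/3 * |sum (z_{k+1}-z_k)(rho_k^2 + rho_k rho_{k+1} + rho_{k+1}^2)|.
    """
    rho2 = np.roll(rho, -1, axis=-1)
    z2 = np.roll(z, -1, axis=-1)
    s = np.sum((z2 - z) * (rho * rho + rho * rho2 + rho2 * rho2), axis=-1)
    return np.abs(s) * np.pi / 3.0


def _frustum_area(rho1, z1, rho2, z2):
    """Lateral area of the surface swept by segment (1)-(2) about the z axis."""
    slant = np.hypot(rho2 - rho1, z2 - z1)
    return np.pi * (rho1 + rho2) * slant


class Mesh:
    """Generic finite-volume mesh (cells, faces, membrane patches).

    Attributes
    ----------
    vol : (n_cells,) cell volumes, m^3
    centroid : (n_cells, 2) cell centres in (rho, z) or (x, 0), m
    region : (n_cells,) int codes (0 cytoplasm, 1 nucleus)
    face_a, face_b : (n_faces,) cell indices of each interior face
    face_area, face_dist : (n_faces,) face area m^2, centre distance m
    face_envelope : (n_faces,) bool, faces crossing the nuclear envelope
    mem_cell, mem_area : membrane patches (outermost cells) and areas
    """

    def __init__(self):
        self.kind = "generic"
        self.geom = None
        self.n_r = self.n_t = 0
        self.n_nuc = 0
        self.theta = None     # (n_t+1,) polar-angle edges
        self.R = None         # (n_t+1,) membrane radius at angle edges, m
        self.b = None         # (n_t+1,) nucleus radius at angle edges, m
        self.rad = None       # (n_r+1, n_t+1) node radii, m

    # ------------------------------------------------------------------
    @classmethod
    def axisymmetric(cls, geom: CellGeometry, n_r: int, n_theta: int) -> "Mesh":
        """Body-fitted layered mesh of the (possibly nucleated) ellipsoid."""
        if n_r < 8 or n_theta < 8:
            raise ConfigurationError("resolution must be >= 8 cells per axis")
        geom.validate()
        m = cls()
        m.kind = "axisym"
        m.geom = geom
        m.n_r, m.n_t = n_r, n_theta
        m.theta = np.linspace(0.0, np.pi, n_theta + 1)
        m.R = ellipse_radius(m.theta, geom.l_maj, geom.l_min) * 1e-6
        if geom.has_nucleus:
            m.n_nuc = max(2, n_r // 2)
            m.b = nucleus_radius(m.theta, geom) * 1e-6
        else:
            m.n_nuc = 0
            m.b = np.zeros_like(m.R)
        m._layer_nodes()
        m._rebuild_geometry()
        return m

    #: cytoplasm layers shrink geometrically toward the membrane so the
    #: dried boundary film (a steep nonlinear-diffusion front well under a
    #: micrometre wide) stays resolved at every test resolution
    GRADING = 1.4

    def _graded(self, n):
        w = self.GRADING ** np.arange(n)[::-1]
        s = np.concatenate([[0.0], np.cumsum(w)])
        return s / s[-1]

    def _layer_nodes(self):
        """Node radii: uniform layers in the nucleus, graded in the gap."""
        n_cyt = self.n_r - self.n_nuc
        rad = np.empty((self.n_r + 1, self.n_t + 1))
        if self.n_nuc:
            s_in = np.linspace(0.0, 1.0, self.n_nuc + 1)[:, None]
            rad[: self.n_nuc + 1] = s_in * self.b[None, :]
            s_out = self._graded(n_cyt)[1:, None]
            rad[self.n_nuc + 1:] = self.b[None, :] + s_out * (self.R - self.b)[None, :]
        else:
            s = self._graded(self.n_r)[:, None]
            rad[:] = s * self.R[None, :]
        self.rad = rad

    @classmethod
    def slab(cls, length: float, n_cells: int, section_area: float = 1.0) -> "Mesh":
        """1-D slab of given length (m) with closed ends, for benchmarks."""
        m = cls()
        m.kind = "slab"
        dx = length / n_cells
        m.vol = np.full(n_cells, dx * section_area)
        x = (np.arange(n_cells) + 0.5) * dx
        m.centroid = np.column_stack([x, np.zeros(n_cells)])
        m.region = np.zeros(n_cells, dtype=int)
        m.face_a = np.arange(n_cells - 1)
        m.face_b = np.arange(1, n_cells)
        m.face_area = np.full(n_cells - 1, section_area)
        m.face_dist = np.full(n_cells - 1, dx)
        m.face_envelope = np.zeros(n_cells - 1, dtype=bool)
        m.mem_cell = np.array([], dtype=int)
        m.mem_area = np.array([])
        return m

    # ------------------------------------------------------------------
    def _rebuild_geometry(self):
        """Recompute volumes, centroids, faces from current node radii."""
        th = self.theta[None, :]
        rho = self.rad * np.sin(th)
        z = self.rad * np.cos(th)
        nr, nt = self.n_r, self.n_t

        # cell corner stacks, shape (nr, nt, 4)
        p_rho = np.stack([rho[:-1, :-1], rho[1:, :-1], rho[1:, 1:], rho[:-1, 1:]], axis=-1)
        p_z = np.stack([z[:-1, :-1], z[1:, :-1], z[1:, 1:], z[:-1, 1:]], axis=-1)
        self.vol = _revolved_volume(p_rho, p_z).reshape(-1)
        cen = np.stack([p_rho.mean(axis=-1), p_z.mean(axis=-1)], axis=-1)
        self.centroid = cen.reshape(-1, 2)

        self.region = np.zeros(nr * nt, dtype=int)
        if self.n_nuc:
            idx = (np.arange(nr * nt) // nt) < self.n_nuc
            self.region[idx] = REGION_NUC

        cell = np.arange(nr * nt).reshape(nr, nt)
        # radial faces between layers i and i+1 (edge at node row i+1)
        fa_r = cell[:-1, :].reshape(-1)
        fb_r = cell[1:, :].reshape(-1)
        ar_r = _frustum_area(rho[1:-1, :-1], z[1:-1, :-1], rho[1:-1, 1:], z[1:-1, 1:]).reshape(-1)
        # angular faces between columns j and j+1 (edge at angle j+1)
        fa_t = cell[:, :-1].reshape(-1)
        fb_t = cell[:, 1:].reshape(-1)
        ar_t = _frustum_area(rho[:-1, 1:-1], z[:-1, 1:-1], rho[1:, 1:-1], z[1:, 1:-1]).reshape(-1)

        self.face_a = np.concatenate([fa_r, fa_t])
        self.face_b = np.concatenate([fb_r, fb_t])
        self.face_area = np.concatenate([ar_r, ar_t])
        d = self.centroid[self.face_a] - self.centroid[self.face_b]
        self.face_dist = np.maximum(np.hypot(d[:, 0], d[:, 1]), 1e-12)
        env = np.zeros_like(self.face_a, dtype=bool)
        if self.n_nuc:
            env_rows = (fa_r // nt) == (self.n_nuc - 1)
            env[: fa_r.size][env_rows] = True
        self.face_envelope = env

        self.mem_cell = cell[-1, :].copy()
        self.mem_area = _frustum_area(rho[-1, :-1], z[-1, :-1], rho[-1, 1:], z[-1, 1:])

        # drop zero-area faces (on-axis degeneracies)
        keep = self.face_area > 0
        if not keep.all():
            self.face_a = self.face_a[keep]
            self.face_b = self.face_b[keep]
            self.face_area = self.face_area[keep]
            self.face_dist = self.face_dist[keep]
            self.face_envelope = self.face_envelope[keep]

    @property
    def n_cells(self) -> int:
        return self.vol.size

    def total_volume(self) -> float:
        return float(self.vol.sum())

    # ------------------------------------------------------------------
    def move_membrane(self, v_n, dt):
        """Advance the membrane inward by normal speed v_n (per column, m/s).

        Returns (old_vols, new_vols) of the cytoplasm block so callers can
        conservatively remap cell contents.  Raises RuntimeError when the
        cytoplasm gap collapses onto the nucleus.
        """
        if self.kind != "axisym":
            raise ConfigurationError("moving boundary requires an axisymmetric mesh")
        v_n = np.asarray(v_n, dtype=float)
        # column values -> angle-edge values
        v_e = np.empty(self.n_t + 1)
        v_e[1:-1] = 0.5 * (v_n[1:] + v_n[:-1])
        v_e[0], v_e[-1] = v_n[0], v_n[-1]
        dR_dth = np.gradient(self.R, self.theta)
        metric = np.sqrt(1.0 + (dR_dth / np.maximum(self.R, 1e-12)) ** 2)
        old_vol = self.vol.reshape(self.n_r, self.n_t).copy()
        self.R = self.R - v_e * metric * dt
        if np.any(self.R - self.b <= 0.05 * self.b + 1e-9):
            raise RuntimeError("membrane collapsed onto the nucleus")
        self._layer_nodes()
        self._rebuild_geometry()
        new_vol = self.vol.reshape(self.n_r, self.n_t)
        return old_vol, new_vol
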