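"""Unstructured tetrahedral meshes and mesoscopic diffusion jump rates.

A voxel is the lumped-mass dual volume around a mesh vertex: a quarter of the
volume of every incident tetrahedron.  Diffusive jumps between neighbouring
voxels are derived from the piecewise-linear finite-element stiffness matrix
of the Laplacian: the jump rate from voxel i to voxel j is
``D * max(-K_ij, 0) / v_i``.  On a uniform Cartesian-derived mesh these rates
satisfy detailed balance, ``v_i q_ij = v_j q_ji``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["Mesh", "voxel_volumes", "assemble_stiffness", "assemble_jump_rates",
           "interval_jump_rates", "MeshError"]

#: litres per cubic metre
L_PER_M3 = 1000.0


class MeshError(ValueError):
    pass


@dataclass
class Mesh:
    """Vertices (metres), tetrahedra (0-based 4-tuples), per-vertex subdomain
    labels, and derived per-vertex voxel volumes (litres)."""

    vertices: np.ndarray  # (n, 3)
    tetrahedra: np.ndarray  # (m, 4)
    subdomain_labels: list = None
    gene_site_vertex: int | None = None  # optional marked vertex
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.tetrahedra = np.asarray(self.tetrahedra, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.tetrahedra.ndim != 2 or self.tetrahedra.shape[1] != 4:
            raise MeshError("tetrahedra must be an (m, 4) array")
        if self.tetrahedra.size and (
            self.tetrahedra.min() < 0 or self.tetrahedra.max() >= len(self.vertices)
        ):
            raise MeshError("tetrahedron vertex index out of range")
        if self.subdomain_labels is None:
            self.subdomain_labels = ["domain"] * len(self.vertices)
        if len(self.subdomain_labels) != len(self.vertices):
            raise MeshError("one subdomain label per vertex required")
        self._canonicalize_orientation()
        used = np.zeros(len(self.vertices), dtype=bool)
        used[self.tetrahedra.ravel()] = True
        if not used.all():
            raise MeshError(f"vertices not part of any tetrahedron: {np.nonzero(~used)[0][:5]}")
        self._voxel_volumes = None

    def _signed_volumes(self) -> np.ndarray:
        p = self.vertices
        t = self.tetrahedra
        a = p[t[:, 1]] - p[t[:, 0]]
        b = p[t[:, 2]] - p[t[:, 0]]
        c = p[t[:, 3]] - p[t[:, 0]]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def _canonicalize_orientation(self):
        vols = self._signed_volumes()
        if np.any(vols == 0):
            raise MeshError("degenerate (zero-volume) tetrahedron")
        flip = vols < 0
        if flip.any():
            self.tetrahedra[flip] = self.tetrahedra[flip][:, [0, 1, 3, 2]]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def tet_volumes_m3(self) -> np.ndarray:
        return self._signed_volumes()

    @property
    def voxel_volumes(self) -> np.ndarray:
        """Per-vertex lumped dual volumes in litres; they sum exactly to the
        total mesh volume."""
        if self._voxel_volumes is None:
            v = np.zeros(self.n_vertices)
            quarter = self.tet_volumes_m3() / 4.0
            for k in range(4):
                np.add.at(v, self.tetrahedra[:, k], quarter)
            self._voxel_volumes = v * L_PER_M3
        return self._voxel_volumes

    @property
    def total_volume(self) -> float:
        """Total mesh volume in litres."""
        return float(self.tet_volumes_m3().sum() * L_PER_M3)

    def subdomain_vertices(self, label: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.subdomain_labels) if l == label],
                        dtype=np.int64)

    def subdomain_volume(self, label: str) -> float:
        idx = self.subdomain_vertices(label)
        return float(self.voxel_volumes[idx].sum())


def voxel_volumes(mesh: Mesh) -> np.ndarray:
    return mesh.voxel_volumes


def assemble_stiffness(mesh: Mesh) -> sp.csr_matrix:
    """P1 finite-element stiffness matrix of the Laplacian (n x n, symmetric).

    Element contribution: K_e = V_e * G G^T with G the (4, 3) matrix of basis
    gradients, obtained from the inverse edge matrix of the tetrahedron.
    """
    n = mesh.n_vertices
    tets = mesh.tetrahedra
    p = mesh.vertices
    vols = mesh.tet_volumes_m3()
    if np.any(vols <= 0):
        raise MeshError("degenerate tetrahedron in stiffness assembly")

    # edge matrices (m, 3, 3): rows p1-p0, p2-p0, p3-p0
    E = np.stack([p[tets[:, k]] - p[tets[:, 0]] for k in (1, 2, 3)], axis=1)
    Einv = np.linalg.inv(E)
    # gradients of basis 1..3 are columns of Einv^T; basis 0 is minus their sum
    G123 = np.transpose(Einv, (0, 2, 1))  # (m, 3, 3): row k-1 = grad phi_k
    G0 = -G123.sum(axis=1, keepdims=True)
    G = np.concatenate([G0, G123], axis=1)  # (m, 4, 3)
    Ke = np.einsum("mik,mjk,m->mij", G, G, vols)  # (m, 4, 4)

    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    K.sum_duplicates()
    return K


def assemble_jump_rates(
    mesh: Mesh,
    diffusion_coefficient: float,
    allowed_subdomains: frozenset | set | None = None,
) -> sp.csr_matrix:
    """Sparse voxel-to-voxel diffusion jump-rate matrix (per second).

    Off-diagonal entry (i, j) is the rate at which one molecule in voxel i
    jumps to voxel j; the diagonal is the negated row sum.  Rates into or out
    of voxels whose subdomain is not allowed are zeroed.  Positive
    off-diagonal stiffness entries (possible on poor-quality meshes) would
    yield negative rates and are truncated to zero with a warning.
    """
    if diffusion_coefficient < 0:
        raise ValueError("diffusion coefficient must be nonnegative")
    n = mesh.n_vertices
    if diffusion_coefficient == 0:
        return sp.csr_matrix((n, n))
    K = assemble_stiffness(mesh).tocoo()
    off = K.row != K.col
    rows, cols, vals = K.row[off], K.col[off], K.data[off]
    rates = -vals  # jump conductance; should be >= 0 on good meshes
    bad = rates < -1e-12 * np.abs(vals).max()
    if bad.any():
        warnings.warn(
            f"truncated {int(bad.sum())} negative jump rates from positive "
            "off-diagonal stiffness entries (poor mesh quality)",
            stacklevel=2,
        )
    rates = np.maximum(rates, 0.0)
    # voxel volumes in m^3 so rates come out in 1/s
    v_m3 = mesh.voxel_volumes / L_PER_M3
    rates = diffusion_coefficient * rates / v_m3[rows]

    if allowed_subdomains:
        allowed = np.array([l in allowed_subdomains for l in mesh.subdomain_labels])
        keep = allowed[rows] & allowed[cols]
        rows, cols, rates = rows[keep], cols[keep], rates[keep]

    Q = sp.coo_matrix((rates, (rows, cols)), shape=(n, n)).tocsr()
    Q.sum_duplicates()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=1)).ravel())
    return Q.tocsr()


def interval_jump_rates(x: np.ndarray, diffusion_coefficient: float) -> sp.csr_matrix:
    """1D verification path: P1 assembly on an interval mesh.

    For uniform spacing h this reproduces the classical nearest-neighbour jump
    rate D/h^2.  Used only for verification; the spatial solver is 3D.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    h = np.diff(x)
    if np.any(h <= 0):
        raise MeshError("duplicate coordinates in interval mesh")
    K = sp.lil_matrix((n, n))
    v = np.zeros(n)
    for e in range(n - 1):
        k = 1.0 / h[e]
        K[e, e] += k
        K[e + 1, e + 1] += k
        K[e, e + 1] -= k
        K[e + 1, e] -= k
        v[e] += h[e] / 2
        v[e + 1] += h[e] / 2
    K = K.tocoo()
    off = K.row != K.col
    rates = diffusion_coefficient * np.maximum(-K.data[off], 0.0) / v[K.row[off]]
    Q = sp.coo_matrix((rates, (K.row[off], K.col[off])), shape=(n, n)).tocsr()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=1)).ravel())
    return Q.tocsr()
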