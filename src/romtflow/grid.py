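"""Cell-centered grids, fields, and the two halves of the transport step.

The transport model evolves a nonnegative density on a uniform cell-centered
lattice by operator splitting: a particle-in-cell (PIC) advection step that
carries each cell's mass along the velocity and deposits it back to cell
centers with trilinear weights, followed by a backward-Euler diffusion step
with an isotropic diffusivity ``sigma2`` and zero-flux (Neumann) boundaries.
Both halves conserve total mass and preserve nonnegativity, which is what the
physical interpretation of the intensities as tracer mass requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "ImageGrid",
    "ScalarField",
    "VectorField",
    "DiffusionSpec",
    "gradient",
    "laplacian_matrix",
    "diffusion_operator",
    "pic_advect",
    "implicit_diffuse",
    "DiffusionSolver",
    "deposition_matrices",
]

logger = logging.getLogger(__name__)

# above this many cells (I - dt*D) is solved iteratively instead of factorized
DIRECT_SOLVE_MAX_CELLS = 80_000


@dataclass(frozen=True)
class ImageGrid:
    """Uniform cell-centered 3D lattice shared by all fields.

    Parameters
    ----------
    dims : tuple of int
        Lattice shape ``(m1, m2, m3)``; each entry >= 1.
    voxel_size : float
        Uniform edge length ``dx`` in world units (e.g. mm).
    affine : (4, 4) ndarray, optional
        Voxel-index to world-coordinate map. Defaults to ``dx * I`` with zero
        origin, i.e. world coordinates are scaled voxel indices.
    """

    dims: tuple[int, int, int]
    voxel_size: float = 1.0
    affine: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        object.__setattr__(self, "dims", dims)
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if self.affine is None:
            aff = np.diag([self.voxel_size] * 3 + [1.0])
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            if abs(np.linalg.det(aff)) < 1e-300:
                raise ValueError("affine must be invertible")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @property
    def n_cells(self) -> int:
        m1, m2, m3 = self.dims
        return m1 * m2 * m3

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (continuous, shape (..., 3)) to world coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def cell_index_coords(self) -> np.ndarray:
        """(M, 3) array of the integer index coordinates of every cell center."""
        grids = np.meshgrid(*[np.arange(m) for m in self.dims], indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1).astype(float)


@dataclass
class ScalarField:
    """One real value per cell; densities additionally satisfy values >= 0."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            if self.values.size == self.grid.n_cells:
                self.values = self.values.reshape(self.grid.dims)
            else:
                raise ValueError(
                    f"values shape {self.values.shape} does not match grid {self.grid.dims}"
                )

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()

    def total_mass(self) -> float:
        """Total mass: voxel volume times the sum of cell values."""
        return float(self.values.sum()) * self.grid.voxel_size**3


@dataclass
class VectorField:
    """Cell-centered 3-component velocity, world units per unit normalized time."""

    grid: ImageGrid
    components: np.ndarray  # (3, m1, m2, m3)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != (3, *self.grid.dims):
            if self.components.size == 3 * self.grid.n_cells:
                self.components = self.components.reshape((3, *self.grid.dims))
            else:
                raise ValueError("components must have shape (3, m1, m2, m3)")
        if not np.all(np.isfinite(self.components)):
            raise ValueError("velocity field contains non-finite values")

    @classmethod
    def zeros(cls, grid: ImageGrid) -> "VectorField":
        return cls(grid, np.zeros((3, *grid.dims)))

    def magnitude(self) -> ScalarField:
        return ScalarField(self.grid, np.sqrt((self.components**2).sum(axis=0)))


@dataclass(frozen=True)
class DiffusionSpec:
    """Isotropic constant diffusivity D = sigma2 * I."""

    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")


def gradient(f: ScalarField) -> VectorField:
    """Cell-centered discrete gradient: central differences in the interior,
    one-sided at the boundary, scaled by 1/dx.

    Axes of size 1 get a zero component (logged), so the operator degrades
    gracefully to 2D/1D data.
    """
    dx = f.grid.voxel_size
    comps = np.zeros((3, *f.grid.dims))
    for ax in range(3):
        if f.grid.dims[ax] < 2:
            logger.debug("gradient: axis %d has size 1; component set to zero", ax)
            continue
        comps[ax] = np.gradient(f.values, dx, axis=ax)
    return VectorField(f.grid, comps)


def _neumann_laplacian_1d(m: int) -> sp.csr_matrix:
    """1D second-difference matrix with zero-flux closure (no 1/dx^2 factor)."""
    if m == 1:
        return sp.csr_matrix((1, 1))
    main = np.full(m, -2.0)
    main[0] = main[-1] = -1.0
    off = np.ones(m - 1)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr")


def laplacian_matrix(grid: ImageGrid) -> sp.csr_matrix:
    """7-point Laplacian with Neumann closure, scaled by 1/dx^2.

    Symmetric negative semidefinite; constant fields span its null space, so
    backward-Euler diffusion built on it conserves total mass exactly.
    """
    m1, m2, m3 = grid.dims
    inv_dx2 = 1.0 / grid.voxel_size**2
    I1, I2, I3 = (sp.identity(m, format="csr") for m in (m1, m2, m3))
    L = (
        sp.kron(_neumann_laplacian_1d(m1), sp.kron(I2, I3))
        + sp.kron(I1, sp.kron(_neumann_laplacian_1d(m2), I3))
        + sp.kron(I1, sp.kron(I2, _neumann_laplacian_1d(m3)))
    )
    return (inv_dx2 * L).tocsr()


def diffusion_operator(grid: ImageGrid, spec: DiffusionSpec) -> sp.csr_matrix:
    """Sparse diffusion operator sigma2 * Laplacian (div D grad with D = sigma2 I)."""
    if spec.sigma2 == 0.0:
        M = grid.n_cells
        return sp.csr_matrix((M, M))
    return (spec.sigma2 * laplacian_matrix(grid)).tocsr()


# ---------------------------------------------------------------------------
# particle-in-cell machinery
# ---------------------------------------------------------------------------


def _trilinear_stencil(grid: ImageGrid, positions: np.ndarray):
    """Trilinear deposition stencil for particles at continuous index coords.

    Returns corner flat indices (8, P), weights (8, P) and the weight
    derivatives (3, 8, P) with respect to each position component. Positions
    are clamped to the domain; the derivative is zero where clamping is
    active, which is the subgradient consistent with mass staying in-domain.
    """
    dims = np.array(grid.dims)
    P = positions.shape[0]
    p = np.clip(positions, 0.0, (dims - 1).astype(float))
    active = (positions > 0.0) & (positions < (dims - 1))  # derivative mask
    # size-1 axes: everything collapses to index 0 with weight 1
    i0 = np.floor(p).astype(np.int64)
    i0 = np.minimum(i0, np.maximum(dims - 2, 0))
    f = p - i0
    one_m_f = 1.0 - f

    corner_offsets = np.array(
        [[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)]
    )  # (8, 3)
    idx = np.empty((8, P), dtype=np.int64)
    w = np.empty((8, P))
    dw = np.empty((3, 8, P))
    strides = np.array([dims[1] * dims[2], dims[2], 1])
    df = active.astype(float)  # d f / d position (0 where clamped)
    for k, off in enumerate(corner_offsets):
        corner = np.minimum(i0 + off, dims - 1)
        idx[k] = corner @ strides
        # per-axis weight factor and its derivative
        wax = np.where(off == 1, f, one_m_f)  # (P, 3)
        dwax = np.where(off == 1, df, -df)
        w[k] = wax.prod(axis=1)
        for c in range(3):
            others = [a for a in range(3) if a != c]
            dw[c, k] = dwax[:, c] * wax[:, others[0]] * wax[:, others[1]]
    return idx, w, dw


def deposition_matrices(
    grid: ImageGrid, v: VectorField, dt: float, with_derivatives: bool = True
):
    """Sparse PIC deposition matrix A(v) and its velocity derivatives.

    ``A`` is (M, M): column i holds the trilinear weights with which the
    particle starting at cell i (displaced by ``dt * v_i / dx`` in index
    coordinates) deposits its mass onto cell centers. Columns sum to 1, hence
    mass conservation is exact by construction.

    When ``with_derivatives``, also returns ``G = [G_x, G_y, G_z]`` with
    ``G_c = dA/dv_c`` (the ``dt/dx`` chain factor included).
    """
    if not np.all(np.isfinite(v.components)):
        raise ValueError("velocity field contains non-finite values")
    M = grid.n_cells
    base = grid.cell_index_coords()  # (M, 3)
    disp = v.components.reshape(3, M).T * (dt / grid.voxel_size)
    idx, w, dw = _trilinear_stencil(grid, base + disp)
    cols = np.tile(np.arange(M), 8)
    A = sp.csr_matrix((w.ravel(), (idx.ravel(), cols)), shape=(M, M))
    if not with_derivatives:
        return A, None
    scale = dt / grid.voxel_size
    G = [
        sp.csr_matrix((scale * dw[c].ravel(), (idx.ravel(), cols)), shape=(M, M))
        for c in range(3)
    ]
    return A, G


def pic_advect(mu: ScalarField, v: VectorField, dt: float) -> ScalarField:
    """Particle-in-cell advection: returns A(v) mu.

    Each cell's mass rides a particle displaced by ``v*dt`` and is deposited
    to the neighboring cell centers by trilinear weights; particles pushed
    past the boundary are clamped so no mass leaves the domain.
    """
    A, _ = deposition_matrices(mu.grid, v, dt, with_derivatives=False)
    return ScalarField(mu.grid, A @ mu.flat)


class DiffusionSolver:
    """Cached solver for the backward-Euler diffusion system (I - dt*sigma2*L).

    Direct sparse LU up to ``DIRECT_SOLVE_MAX_CELLS`` cells, conjugate
    gradients (tol 1e-10) above. The system matrix is a symmetric M-matrix,
    so solutions of nonnegative right-hand sides stay nonnegative up to
    solver tolerance.
    """

    def __init__(self, grid: ImageGrid, spec: DiffusionSpec, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.grid = grid
        self.spec = spec
        self.dt = dt
        self.identity = spec.sigma2 == 0.0
        if self.identity:
            return
        M = grid.n_cells
        self.matrix = (sp.identity(M, format="csr") - dt * diffusion_operator(grid, spec)).tocsc()
        self._direct = M <= DIRECT_SOLVE_MAX_CELLS
        if self._direct:
            self._lu = spla.splu(self.matrix)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        if self.identity:
            return np.asarray(rhs, dtype=float).copy()
        rhs = np.asarray(rhs, dtype=float).ravel()
        if self._direct:
            out = self._lu.solve(rhs)
        else:
            out, info = spla.cg(self.matrix, rhs, rtol=1e-10, atol=0.0)
            if info != 0:
                res = np.linalg.norm(self.matrix @ out - rhs)
                raise RuntimeError(
                    f"diffusion solve failed (cg info={info}, residual={res:.3e})"
                )
        if not np.all(np.isfinite(out)):
            raise RuntimeError("diffusion solve produced non-finite values")
        return out


def implicit_diffuse(mu: ScalarField, spec: DiffusionSpec, dt: float) -> ScalarField:
    """One backward-Euler diffusion step: solve (I - dt*sigma2*L) mu' = mu."""
    solver = DiffusionSolver(mu.grid, spec, dt)
    return ScalarField(mu.grid, solver.solve(mu.flat))
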