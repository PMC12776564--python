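"""2D finite-element forward solver for EIT on the unit disk.

Linear (P1) triangular elements, 16 point electrodes equally spaced on the
boundary, adjacent-pair current drive.  The potential u solves
div(sigma grad u) = 0 with Neumann current injection at the electrodes;
the gauge is fixed by a zero-mean constraint (Lagrange multiplier).  One
sparse LU factorization per conductivity state serves all 16 drives.

Measurement convention (standard adjacent protocol): for each drive pair
(d, d+1) the differential voltages u[m] - u[m+1] are read on the 13
adjacent pairs (m, m+1) that touch neither drive electrode, in increasing
m order; drives are traversed in order, giving 16 x 13 = 208 measurements.
Currents are specified in mA, voltages returned in volts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay

from .phantoms import ThoraxPhantom

def _cross2(a: "np.ndarray", b: "np.ndarray") -> "np.ndarray":
    """z-component of the cross product of stacked 2D vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


N_ELECTRODES = 16
N_MEASUREMENTS = 208  # 16 drives x 13 measurement pairs


class MeshError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FEMesh:
    """Triangulated unit disk with electrode node indices.

    nodes : (n_nodes, 2) coordinates; triangles : (n_elems, 3) CCW index
    triples; electrode_nodes : (16,) node indices counter-clockwise from
    angle 0.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    electrode_nodes: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)


def build_mesh(
    target_element_count: int = 1024, electrode_count: int = N_ELECTRODES
) -> FEMesh:
    """Structured ring mesh of the unit disk.

    Nodes sit on concentric rings, ring j of radius j/R carrying
    ``electrode_count * j`` equally spaced nodes, so the node set is
    invariant under rotation by one electrode pitch and the element count
    is ``electrode_count * R**2`` (within Delaunay tie-breaking).
    """
    if electrode_count != N_ELECTRODES:
        raise MeshError(
            f"protocol requires {N_ELECTRODES} electrodes, got {electrode_count}"
        )
    if target_element_count < 256:
        raise MeshError("target element count must be >= 256")
    n_rings = max(4, round(np.sqrt(target_element_count / electrode_count)))
    pts = [np.zeros((1, 2))]
    for j in range(1, n_rings + 1):
        m = electrode_count * j
        theta = 2 * np.pi * np.arange(m) / m
        r = j / n_rings
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    nodes = np.vstack(pts)
    tri = Delaunay(nodes).simplices
    # enforce CCW orientation
    p = nodes[tri]
    areas = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = areas < 0
    tri[flip] = tri[flip][:, ::-1]
    # drop degenerate slivers (collinear boundary points cannot occur on a
    # circle, but guard anyway)
    p = nodes[tri]
    areas = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    tri = tri[areas > 1e-14]

    first_boundary = nodes.shape[0] - electrode_count * n_rings
    electrode_nodes = first_boundary + n_rings * np.arange(electrode_count)
    mesh = FEMesh(nodes, np.ascontiguousarray(tri), electrode_nodes)
    if not (0.5 * target_element_count <= mesh.n_elements
            <= 2 * target_element_count):
        raise MeshError(
            f"meshing produced {mesh.n_elements} elements for target "
            f"{target_element_count}"
        )
    return mesh


@dataclass(frozen=True)
class StimulationProtocol:
    """Adjacent-pair drive and measurement pattern for 16 electrodes."""

    n_electrodes: int = N_ELECTRODES
    drive_current_ma: float = 1.0

    def drive_pairs(self) -> list[tuple[int, int]]:
        n = self.n_electrodes
        return [(d, (d + 1) % n) for d in range(n)]

    def measurement_pairs(self, drive: int) -> list[tuple[int, int]]:
        """The 13 adjacent pairs not touching either drive electrode."""
        n = self.n_electrodes
        skip = {(drive - 1) % n, drive, (drive + 1) % n}
        return [(m, (m + 1) % n) for m in range(n) if m not in skip]

    @property
    def n_measurements(self) -> int:
        return self.n_electrodes * (self.n_electrodes - 3)

    def index(self, drive: int, meas_pair: tuple[int, int]) -> int:
        """Flat measurement index (drive-major ordering)."""
        pairs = self.measurement_pairs(drive)
        return drive * len(pairs) + pairs.index(meas_pair)


@dataclass(frozen=True)
class VoltageFrame:
    """One frame of 208 differential boundary voltages (volts)."""

    voltages: np.ndarray
    state: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        if v.shape != (N_MEASUREMENTS,):
            raise ValueError(
                f"expected {N_MEASUREMENTS} voltages, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite voltages in frame")
        object.__setattr__(self, "voltages", v)


def element_conductivities(
    mesh: FEMesh, phantom: ThoraxPhantom
) -> np.ndarray:
    """Per-element conductivity: inclusion value at the centroid, else background."""
    c = mesh.element_centroids()
    sigma = np.full(mesh.n_elements, phantom.background_conductivity)
    for inc in phantom.inclusions:
        sigma[inc.contains(c[:, 0], c[:, 1])] = inc.conductivity
    return sigma


def _gradient_operators(mesh: FEMesh) -> tuple[sp.csr_matrix, sp.csr_matrix, np.ndarray]:
    """Sparse (n_elems x n_nodes) operators mapping nodal values to constant
    per-element gradient components, plus element areas."""
    tri = mesh.triangles
    p = mesh.nodes[tri]
    x, y = p[..., 0], p[..., 1]
    area = 0.5 * ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
                  - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
    # P1 shape-function gradients: grad phi_i = (b_i, c_i) / (2A)
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    rows = np.repeat(np.arange(mesh.n_elements), 3)
    cols = tri.ravel()
    shape = (mesh.n_elements, mesh.n_nodes)
    gx = sp.csr_matrix(((b / (2 * area[:, None])).ravel(), (rows, cols)), shape)
    gy = sp.csr_matrix(((c / (2 * area[:, None])).ravel(), (rows, cols)), shape)
    return gx, gy, area


def _stiffness(mesh: FEMesh, sigma: np.ndarray) -> sp.csc_matrix:
    gx, gy, area = _gradient_operators(mesh)
    w = sp.diags(sigma * area)
    K = gx.T @ w @ gx + gy.T @ w @ gy
    return K.tocsc()


class ForwardOperator:
    """Factorized forward model for one mesh; reusable across conductivity states.

    The zero-mean gauge is imposed with a Lagrange multiplier, so the
    augmented system stays symmetric and non-singular for any strictly
    positive conductivity field.
    """

    def __init__(self, mesh: FEMesh,
                 protocol: StimulationProtocol | None = None) -> None:
        self.mesh = mesh
        self.protocol = protocol or StimulationProtocol()
        self.gx, self.gy, self.areas = _gradient_operators(mesh)
        n = mesh.n_nodes
        # injection patterns, one column per adjacent pair (unit current)
        cols = []
        for a, b in self.protocol.drive_pairs():
            v = np.zeros(n)
            v[mesh.electrode_nodes[a]] = 1.0
            v[mesh.electrode_nodes[b]] = -1.0
            cols.append(v)
        self._pair_injections = np.column_stack(cols)

    def _factorize(self, sigma: np.ndarray):
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (self.mesh.n_elements,):
            raise SolverError(
                f"conductivity vector has shape {sigma.shape}, expected "
                f"({self.mesh.n_elements},)"
            )
        if np.any(sigma <= 0) or not np.all(np.isfinite(sigma)):
            raise SolverError("conductivities must be finite and positive")
        K = _stiffness(self.mesh, sigma)
        n = self.mesh.n_nodes
        one = np.ones((n, 1)) / n
        A = sp.bmat([[K, one], [one.T, None]], format="csc")
        try:
            return splu(A)
        except RuntimeError as exc:  # pragma: no cover - pathological input
            raise SolverError(f"singular FEM system: {exc}") from exc

    def solve_fields(self, sigma: np.ndarray,
                     current_ma: float | None = None) -> np.ndarray:
        """Nodal potential fields, one column per adjacent-pair injection."""
        lu = self._factorize(sigma)
        amps = 1e-3 * (current_ma if current_ma is not None
                       else self.protocol.drive_current_ma)
        rhs = np.zeros((self.mesh.n_nodes + 1, N_ELECTRODES))
        rhs[:-1] = self._pair_injections * amps
        sol = lu.solve(rhs)
        return sol[:-1]

    def voltages(self, sigma: np.ndarray, state: str = "") -> VoltageFrame:
        fields = self.solve_fields(sigma)
        ue = fields[self.mesh.electrode_nodes]  # (16 electrodes, 16 drives)
        out = np.empty(self.protocol.n_measurements)
        for d in range(N_ELECTRODES):
            for k, (m, m1) in enumerate(self.protocol.measurement_pairs(d)):
                out[d * 13 + k] = ue[m, d] - ue[m1, d]
        return VoltageFrame(out, state=state)

    def jacobian(self, sigma: np.ndarray) -> np.ndarray:
        """Sensitivity dV/dsigma_e via the adjoint-field formula, (208, n_elems).

        With drive fields u_d (at the protocol current) and auxiliary
        fields w_m for unit current at each measurement pair,
        dV_{d,m}/dsigma_e = -area_e * grad(u_d) . grad(w_m) on element e.
        """
        fields = self.solve_fields(sigma)                       # protocol current
        lu = self._factorize(sigma)
        rhs = np.zeros((self.mesh.n_nodes + 1, N_ELECTRODES))
        rhs[:-1] = self._pair_injections                         # unit current
        meas_fields = lu.solve(rhs)[:-1]
        gux, guy = self.gx @ fields, self.gy @ fields
        gwx, gwy = self.gx @ meas_fields, self.gy @ meas_fields
        J = np.empty((self.protocol.n_measurements, self.mesh.n_elements))
        for d in range(N_ELECTRODES):
            for k, (m, _) in enumerate(self.protocol.measurement_pairs(d)):
                J[d * 13 + k] = -self.areas * (
                    gux[:, d] * gwx[:, m] + guy[:, d] * gwy[:, m]
                )
        return J


def solve_forward(
    mesh: FEMesh,
    conductivities: np.ndarray,
    protocol: StimulationProtocol | None = None,
    state: str = "",
) -> VoltageFrame:
    """One-shot forward solve returning the 208-measurement frame."""
    return ForwardOperator(mesh, protocol).voltages(conductivities, state=state)


def compute_jacobian(
    mesh: FEMesh,
    baseline_conductivities: np.ndarray,
    protocol: StimulationProtocol | None = None,
) -> np.ndarray:
    """Sensitivity matrix of the 208 measurements w.r.t. element conductivities."""
    return ForwardOperator(mesh, protocol).jacobian(baseline_conductivities)


def analytic_disk_potential(
    points: np.ndarray,
    source: np.ndarray,
    sink: np.ndarray,
    sigma: float,
    current_a: float,
) -> np.ndarray:
    """Closed-form potential in a homogeneous unit disk for a boundary
    point-source/sink pair.

    u(x) = I/(pi*sigma) * (ln|x - sink| - ln|x - source|), up to an additive
    constant; the boundary flux of each log term is constant (1/2 per unit
    angle) on the unit circle, so the pair satisfies the insulating boundary
    condition away from the contacts.
    """
    d_src = np.linalg.norm(points - source, axis=-1)
    d_snk = np.linalg.norm(points - sink, axis=-1)
    with np.errstate(divide="ignore"):   # infinite at the contact points
        return current_a / (np.pi * sigma) * (np.log(d_snk) - np.log(d_src))
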