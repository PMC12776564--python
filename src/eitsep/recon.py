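"""GREIT-style linear difference reconstruction onto a 32x32 pixel grid.

The reconstruction matrix R maps normalized voltage differences
z = (v - v_ref) / |v_ref| to a pixel image.  Following the standard GREIT
recipe, R is trained on simulated point targets: random small conductivity
perturbations are pushed through the linearized forward model, the desired
image of each is a small disk at the target location, and R solves the
regularized least-squares fit

    R = X Z^T (Z Z^T + lambda^2 I)^(-1)

with lambda set from a noise-figure-like amplitude relative to the mean
signal power.  Conductivity increases map to positive pixel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import ForwardOperator, FEMesh, StimulationProtocol, VoltageFrame
from .grid import PixelGridSpec


@dataclass(frozen=True)
class EITImage:
    """Reconstructed conductivity-change image with circular support."""

    values: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape != self.support.shape:
            raise ValueError("image and support shapes disagree")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite image values")
        if np.any(v[~self.support] != 0):
            raise ValueError("out-of-support pixels must be exactly zero")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ReconstructionModel:
    """Trained linear reconstruction: pixel image = matrix @ normalized diff."""

    matrix: np.ndarray            # (n_pixels, 208)
    grid: PixelGridSpec
    support: np.ndarray           # (n, n) bool
    reference: VoltageFrame       # homogeneous-background frame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite reconstruction matrix")
        out = ~self.support.ravel()
        if np.any(self.matrix[out] != 0):
            raise ValueError("rows for out-of-support pixels must be zero")


def desired_point_image(
    grid: PixelGridSpec, center: np.ndarray, radius: float
) -> np.ndarray:
    x, y = grid.centers()
    return (((x - center[0]) ** 2 + (y - center[1]) ** 2)
            <= radius**2).astype(float)


def train_reconstruction_matrix(
    mesh: FEMesh,
    protocol: StimulationProtocol | None = None,
    n_targets: int = 500,
    target_radius: float = 0.05,
    desired_psf_radius: float = 0.1,
    noise_amplitude: float = 0.5,
    rng: np.random.Generator | None = None,
    grid: PixelGridSpec | None = None,
    background_conductivity: float = 1.0,
) -> ReconstructionModel:
    """Fit the linear reconstruction matrix on simulated point targets."""
    if n_targets < 200:
        raise ValueError("need at least 200 training targets")
    protocol = protocol or StimulationProtocol()
    grid = grid or PixelGridSpec()
    rng = rng if rng is not None else np.random.default_rng(0)

    op = ForwardOperator(mesh, protocol)
    sigma0 = np.full(mesh.n_elements, background_conductivity)
    v_ref = op.voltages(sigma0, state="reference")
    J = op.jacobian(sigma0)
    centroids = mesh.element_centroids()

    # random target centers uniform over the disk, kept inside the support
    max_r = 1.0 - desired_psf_radius
    u = rng.random(n_targets)
    theta = rng.random(n_targets) * 2 * np.pi
    centers = (np.sqrt(u) * max_r)[:, None] * np.column_stack(
        [np.cos(theta), np.sin(theta)]
    )

    delta = 0.1 * background_conductivity
    Z = np.empty((protocol.n_measurements, n_targets))
    X = np.empty((grid.n * grid.n, n_targets))
    scale = np.abs(v_ref.voltages)
    for k, c in enumerate(centers):
        hit = (np.linalg.norm(centroids - c, axis=1) <= target_radius)
        if not hit.any():  # tiny target between centroids: take nearest element
            hit = np.zeros(mesh.n_elements, bool)
            hit[np.argmin(np.linalg.norm(centroids - c, axis=1))] = True
        dv = J[:, hit].sum(axis=1) * delta
        Z[:, k] = dv / scale
        X[:, k] = desired_point_image(grid, c, desired_psf_radius).ravel()

    G = Z @ Z.T
    # effective-noise penalty: lambda scales with the mean signal power of
    # the training targets so that noise_amplitude acts as a unitless
    # noise-to-signal knob (0.5 approximates the community default noise
    # figure for this protocol; see docs/methods.md)
    lam = noise_amplitude**2 * np.trace(G) / G.shape[0]
    if np.linalg.matrix_rank(G + lam * np.eye(G.shape[0])) < G.shape[0]:
        raise np.linalg.LinAlgError(
            "rank-deficient target covariance: too few training targets"
        )
    R = X @ Z.T @ np.linalg.inv(G + lam * np.eye(G.shape[0]))

    support = grid.support_mask()
    R[~support.ravel()] = 0.0
    return ReconstructionModel(
        matrix=R, grid=grid, support=support, reference=v_ref,
        meta=dict(
            n_targets=n_targets, target_radius=target_radius,
            desired_psf_radius=desired_psf_radius,
            noise_amplitude=noise_amplitude,
            target_centers=centers,
            training_signals=Z,
        ),
    )


def reconstruct(
    model: ReconstructionModel,
    frame: VoltageFrame,
    reference: VoltageFrame | None = None,
) -> EITImage:
    """Apply the linear reconstruction to a normalized voltage difference."""
    ref = reference if reference is not None else model.reference
    denom = np.abs(ref.voltages)
    if np.any(denom == 0):
        raise ValueError(
            "reference frame contains zero voltages: protocol mismatch?"
        )
    z = (frame.voltages - ref.voltages) / denom
    img = (model.matrix @ z).reshape(model.grid.n, model.grid.n)
    img[~model.support] = 0.0
    return EITImage(img, model.support)


def normalize_image(image: EITImage) -> EITImage:
    """Affine min-max rescale of the support pixels to [0, 1].

    Constant images (no contrast) map to all zeros.
    """
    vals = image.values[image.support]
    lo, hi = vals.min(), vals.max()
    out = np.zeros_like(image.values)
    if hi > lo:
        out[image.support] = (image.values[image.support] - lo) / (hi - lo)
    return EITImage(out, image.support)
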