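"""Paired simulation dataset: EIT image in, lung + heart target maps out.

One sample is produced by sampling a random thorax phantom, solving the
FEM forward problem for the inclusion state and for the homogeneous
background, reconstructing the normalized difference image with the
trained GREIT-style matrix, and rasterizing the ground-truth organ masks
(default) or reconstructing each organ system alone (continuous target
mode).  The whole stream is reproducible from a single seed; the test set
is drawn from a disjoint seed stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .forward import ForwardOperator, StimulationProtocol, build_mesh
from .grid import PixelGridSpec
from .phantoms import (PhantomSamplingConfig, ThoraxPhantom,
                       isolated_phantoms, rasterize_masks, sample_phantom)
from .recon import normalize_image, reconstruct, train_reconstruction_matrix
from . import forward as _forward


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one dataset deterministically."""

    phantom: PhantomSamplingConfig = field(default_factory=PhantomSamplingConfig)
    mesh_elements: int = 1024
    grid_n: int = 32
    greit_targets: int = 500
    greit_target_radius: float = 0.05
    greit_psf_radius: float = 0.1
    greit_noise_amplitude: float = 0.5
    target_mode: str = "binary"     # or "continuous"

    def __post_init__(self) -> None:
        if self.target_mode not in ("binary", "continuous"):
            raise ValueError(f"unknown target mode {self.target_mode!r}")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class TrainingSample:
    """(input image, lung target, heart target) plus phantom provenance."""

    image: np.ndarray
    lung_target: np.ndarray
    heart_target: np.ndarray
    provenance: dict

    def provenance_key(self) -> str:
        return hashlib.sha256(
            json.dumps(self.provenance, sort_keys=True).encode()
        ).hexdigest()


class SimulationPipeline:
    """Reusable phantom -> voltages -> image -> targets pipeline.

    Builds the mesh, the forward factorization machinery, the homogeneous
    reference frame and the reconstruction matrix once; each ``sample``
    call then costs one (or three, in continuous mode) forward solves.
    """

    def __init__(self, config: SimulationConfig | None = None,
                 seed: int = 0) -> None:
        self.config = config or SimulationConfig()
        self.mesh = build_mesh(self.config.mesh_elements)
        self.protocol = StimulationProtocol()
        self.operator = ForwardOperator(self.mesh, self.protocol)
        self.grid = PixelGridSpec(self.config.grid_n)
        self.recon_model = train_reconstruction_matrix(
            self.mesh, self.protocol,
            n_targets=self.config.greit_targets,
            target_radius=self.config.greit_target_radius,
            desired_psf_radius=self.config.greit_psf_radius,
            noise_amplitude=self.config.greit_noise_amplitude,
            rng=np.random.default_rng(seed),
            grid=self.grid,
            background_conductivity=self.config.phantom.background_conductivity,
        )

    def image_of(self, phantom: ThoraxPhantom) -> np.ndarray:
        sigma = _forward.element_conductivities(self.mesh, phantom)
        frame = self.operator.voltages(sigma)
        return normalize_image(
            reconstruct(self.recon_model, frame)
        ).values.astype(np.float32)

    def sample(self, rng: np.random.Generator) -> TrainingSample:
        phantom = sample_phantom(self.config.phantom, rng)
        image = self.image_of(phantom)
        if self.config.target_mode == "binary":
            lung_t, heart_t = rasterize_masks(phantom, self.grid)
        else:
            lungs_only, heart_only = isolated_phantoms(phantom)
            lung_t = self.image_of(lungs_only)
            heart_t = self.image_of(heart_only)
        prov = {
            "background": phantom.background_conductivity,
            "inclusions": [
                {"label": i.label,
                 "center": [round(c, 12) for c in i.center],
                 "radius": round(i.radius, 12),
                 "conductivity": i.conductivity}
                for i in phantom.inclusions
            ],
        }
        return TrainingSample(image, lung_t, heart_t, prov)


def generate_dataset(n: int, config: SimulationConfig | None = None,
                     seed: int = 0,
                     pipeline: SimulationPipeline | None = None,
                     stream: int = 0) -> list[TrainingSample]:
    """Generate ``n`` reproducible samples.

    ``stream`` selects a disjoint child of the seed (stream 0 for
    train/validation, stream 1 for the independent test set).
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    pipeline = pipeline or SimulationPipeline(config, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])
    out = []
    for i in range(n):
        try:
            out.append(pipeline.sample(rng))
        except Exception as exc:
            raise RuntimeError(f"sample {i} failed: {exc}") from exc
    return out


def samples_to_arrays(samples: list[TrainingSample]):
    """Stack samples into ``X (n, H, W)`` and ``y (n, 2, H, W)`` arrays."""
    X = np.stack([s.image for s in samples]).astype(np.float32)
    y = np.stack(
        [np.stack([s.lung_target, s.heart_target]) for s in samples]
    ).astype(np.float32)
    return X, y


@dataclass(frozen=True)
class DatasetSplit:
    """Deterministic train/validation index split of one sample list."""

    train_indices: np.ndarray
    val_indices: np.ndarray

    def __post_init__(self) -> None:
        tr, va = set(self.train_indices.tolist()), set(self.val_indices.tolist())
        if tr & va:
            raise ValueError("train and validation indices overlap")


def split_dataset(n_or_samples, ratio: float = 0.9,
                  seed: int = 0) -> DatasetSplit:
    """Shuffled split with ``floor(n * ratio)`` training samples."""
    n = n_or_samples if isinstance(n_or_samples, int) else len(n_or_samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0 < ratio < 1:
        raise ValueError("split ratio must be in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(n * ratio))
    return DatasetSplit(np.sort(perm[:n_train]), np.sort(perm[n_train:]))


def kfold_indices(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """k shuffled folds partitioning 0..n-1 with sizes differing by <= 1."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


# ---------------------------------------------------------------------------
# HDF5 container


def save_dataset(path, samples: list[TrainingSample],
                 config: SimulationConfig | None = None,
                 seed: int | None = None) -> None:
    X, y = samples_to_arrays(samples)
    prov = np.array([json.dumps(s.provenance, sort_keys=True)
                     for s in samples], dtype=h5py.string_dtype())
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=X)
        f.create_dataset("lung_targets", data=y[:, 0])
        f.create_dataset("heart_targets", data=y[:, 1])
        f.create_dataset("provenance", data=prov)
        if config is not None:
            f.attrs["config_hash"] = config.digest()
        if seed is not None:
            f.attrs["seed"] = int(seed)


def load_dataset(path) -> list[TrainingSample]:
    with h5py.File(path, "r") as f:
        X = f["inputs"][:]
        lung = f["lung_targets"][:]
        heart = f["heart_targets"][:]
        prov = [json.loads(p) for p in f["provenance"][:]]
    return [TrainingSample(X[i], lung[i], heart[i], prov[i])
            for i in range(X.shape[0])]


def export_triptych(sample: TrainingSample, path) -> None:
    """PNG of (input image, lung target, heart target) for eyeballing."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, arr, title in zip(
            axes,
            (sample.image, sample.lung_target, sample.heart_target),
            ("input EIT image", "lung target", "heart target")):
        ax.imshow(arr, origin="lower", cmap="viridis")
        ax.set_title(title); ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
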