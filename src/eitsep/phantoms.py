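"""Random thorax phantoms: two lung disks and one heart disk in a unit disk.

Each phantom is a 2D slice of the simulated thorax: a circular background
with two lateral low-conductivity inclusions (the lungs, 0.5 S/m) and one
central high-conductivity inclusion (the heart, 2 S/m).  Inclusion radii
are drawn uniformly from the configured ranges (lungs 0.3-0.6, heart
0.1-0.3, domain radius = 1, arbitrary units); centers are jittered around a
fixed anatomical layout (lungs at (+-0.5, 0), heart slightly anterior of
center).  Sampling rejects overlapping or out-of-domain placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .grid import PixelGridSpec

LUNG_LEFT = "lung_left"
LUNG_RIGHT = "lung_right"
HEART = "heart"

_LABELS = (LUNG_LEFT, LUNG_RIGHT, HEART)


@dataclass(frozen=True)
class OrganInclusion:
    """One disk-shaped organ inclusion."""

    label: str
    center: tuple[float, float]
    radius: float
    conductivity: float  # S/m

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"unknown organ label {self.label!r}")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.conductivity <= 0:
            raise ValueError("conductivity must be positive")
        if np.hypot(*self.center) + self.radius > 1.0 + 1e-12:
            raise ValueError(
                f"inclusion {self.label} extends outside the unit domain: "
                f"|center|+radius = {np.hypot(*self.center) + self.radius:.4f}"
            )

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 <= self.radius**2


@dataclass(frozen=True)
class ThoraxPhantom:
    """Background conductivity plus exactly two lungs and one heart."""

    background_conductivity: float
    inclusions: tuple[OrganInclusion, ...]

    def __post_init__(self) -> None:
        if self.background_conductivity <= 0:
            raise ValueError("background conductivity must be positive")
        labels = sorted(inc.label for inc in self.inclusions)
        if labels != sorted([LUNG_LEFT, LUNG_RIGHT, HEART]):
            raise ValueError(
                "phantom needs exactly one lung_left, one lung_right and one "
                f"heart inclusion, got labels {labels}"
            )
        for a, b in ((0, 1), (0, 2), (1, 2)):
            ia, ib = self.inclusions[a], self.inclusions[b]
            gap = np.hypot(
                ia.center[0] - ib.center[0], ia.center[1] - ib.center[1]
            )
            if gap < ia.radius + ib.radius - 1e-12:
                raise ValueError(
                    f"inclusions {ia.label} and {ib.label} overlap"
                )

    @property
    def lungs(self) -> tuple[OrganInclusion, ...]:
        return tuple(i for i in self.inclusions if i.label != HEART)

    @property
    def heart(self) -> OrganInclusion:
        return next(i for i in self.inclusions if i.label == HEART)


@dataclass(frozen=True)
class PhantomSamplingConfig:
    """Sampling distribution for random phantoms.

    Defaults encode the simulation conditions: lung radii uniform on
    [0.3, 0.6], heart radius uniform on [0.1, 0.3], lung conductivity
    0.5 S/m, heart 2 S/m, background 1 S/m.  Lungs are centered at
    (+-0.5, 0) and the heart at (0, 0.15), each with independent uniform
    jitter of +-0.1 per axis; draws violating disjointness or the domain
    boundary are rejected and redrawn.
    """

    lung_radius_range: tuple[float, float] = (0.3, 0.6)
    heart_radius_range: tuple[float, float] = (0.1, 0.3)
    lung_centers: tuple[tuple[float, float], ...] = ((-0.5, 0.0), (0.5, 0.0))
    heart_center: tuple[float, float] = (0.0, 0.15)
    center_jitter: float = 0.1
    lung_conductivity: float = 0.5
    heart_conductivity: float = 2.0
    background_conductivity: float = 1.0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        for lo, hi in (self.lung_radius_range, self.heart_radius_range):
            if not (0 < lo <= hi < 1):
                raise ValueError(f"radius range ({lo}, {hi}) not within (0, 1)")
        if self.center_jitter < 0:
            raise ValueError("center jitter must be non-negative")
        for c in (*self.lung_centers, self.heart_center):
            reach = np.hypot(*c) + self.center_jitter * np.sqrt(2)
            if reach >= 1:
                raise ValueError("placement region leaves the unit domain")


class PlacementError(RuntimeError):
    """Raised when no non-overlapping placement is found within the retry budget."""


def _draw_inclusion(
    rng: np.random.Generator,
    label: str,
    nominal_center: tuple[float, float],
    radius_range: tuple[float, float],
    conductivity: float,
    jitter: float,
) -> OrganInclusion:
    r = rng.uniform(*radius_range)
    cx = nominal_center[0] + rng.uniform(-jitter, jitter)
    cy = nominal_center[1] + rng.uniform(-jitter, jitter)
    # pull back inside the domain if the jittered disk pokes out
    norm = np.hypot(cx, cy)
    if norm + r > 1.0 and norm > 0:
        scale = max(0.0, (1.0 - r) / norm)
        cx, cy = cx * scale, cy * scale
    return OrganInclusion(label, (cx, cy), r, conductivity)


def sample_phantom(
    config: PhantomSamplingConfig, rng: np.random.Generator
) -> ThoraxPhantom:
    """Draw one phantom; bounded resampling resolves inclusion overlap."""
    for _ in range(config.max_retries):
        incs = [
            _draw_inclusion(
                rng, label, c, config.lung_radius_range,
                config.lung_conductivity, config.center_jitter,
            )
            for label, c in zip((LUNG_LEFT, LUNG_RIGHT), config.lung_centers)
        ]
        incs.append(
            _draw_inclusion(
                rng, HEART, config.heart_center, config.heart_radius_range,
                config.heart_conductivity, config.center_jitter,
            )
        )
        try:
            return ThoraxPhantom(
                config.background_conductivity, tuple(incs)
            )
        except ValueError:
            continue
    raise PlacementError(
        f"no disjoint placement found in {config.max_retries} draws; "
        "the sampling config is over-constrained"
    )


def rasterize_masks(
    phantom: ThoraxPhantom, grid: PixelGridSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binary lung and heart target maps on the reconstruction grid.

    A pixel is 1 iff its center lies inside the corresponding disk; the
    lung map is the union of the two lung disks.  Disjoint phantoms give
    elementwise-disjoint maps.  Pixels outside the circular domain are 0
    by construction (inclusions live inside the unit disk).
    """
    grid = grid or PixelGridSpec()
    x, y = grid.centers()
    lung = np.zeros((grid.n, grid.n), dtype=np.float32)
    for inc in phantom.lungs:
        lung[inc.contains(x, y)] = 1.0
    heart = phantom.heart.contains(x, y).astype(np.float32)
    return lung, heart


def isolated_phantoms(
    phantom: ThoraxPhantom,
) -> tuple[ThoraxPhantom, ThoraxPhantom]:
    """Split into a lungs-only and a heart-only phantom (same background).

    Used for the continuous-target variant where the targets are
    reconstructions of each organ system imaged alone.
    """
    lungs_only = _subset(phantom, phantom.lungs)
    heart_only = _subset(phantom, (phantom.heart,))
    return lungs_only, heart_only


def _subset(
    phantom: ThoraxPhantom, incs: tuple[OrganInclusion, ...]
) -> ThoraxPhantom:
    # bypass the 2-lungs-1-heart invariant for partial phantoms
    obj = object.__new__(ThoraxPhantom)
    object.__setattr__(obj, "background_conductivity",
                       phantom.background_conductivity)
    object.__setattr__(obj, "inclusions", tuple(incs))
    return obj


# ---------------------------------------------------------------------------
# HDF5 (de)serialization of phantom batches


def save_phantom_batch(
    group: h5py.Group, phantoms: list[ThoraxPhantom], seed: int | None = None
) -> None:
    n = len(phantoms)
    centers = np.zeros((n, 3, 2))
    radii = np.zeros((n, 3))
    conds = np.zeros((n, 3))
    order = (LUNG_LEFT, LUNG_RIGHT, HEART)
    for i, ph in enumerate(phantoms):
        by_label = {inc.label: inc for inc in ph.inclusions}
        for j, lab in enumerate(order):
            inc = by_label[lab]
            centers[i, j] = inc.center
            radii[i, j] = inc.radius
            conds[i, j] = inc.conductivity
    group.create_dataset("centers", data=centers)
    group.create_dataset("radii", data=radii)
    group.create_dataset("conductivities", data=conds)
    group.create_dataset(
        "background", data=[ph.background_conductivity for ph in phantoms]
    )
    group.attrs["label_order"] = ",".join(order)
    if seed is not None:
        group.attrs["seed"] = int(seed)


def load_phantom_batch(group: h5py.Group) -> list[ThoraxPhantom]:
    order = group.attrs["label_order"].split(",")
    centers = group["centers"][:]
    radii = group["radii"][:]
    conds = group["conductivities"][:]
    bg = group["background"][:]
    out = []
    for i in range(len(bg)):
        incs = tuple(
            OrganInclusion(
                lab, tuple(centers[i, j]), float(radii[i, j]),
                float(conds[i, j]),
            )
            for j, lab in enumerate(order)
        )
        out.append(ThoraxPhantom(float(bg[i]), incs))
    return out
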