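"""Optional adapter for real human EIT frames (EIDORS sample data).

Loads a MATLAB v5 ``.mat`` file of raw 16-electrode adjacent-protocol
measurement frames (e.g. the public ``montreal_data_1995.mat`` healthy
adult recording, 7 Hz), reconstructs each frame against an
end-expiration-proxy reference, and runs zero-shot inference with a
simulation-trained network.  Everything here is qualitative: no ground
truth exists for these frames, so nothing in this module participates in
the quantitative evaluation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.io import loadmat

from .forward import N_MEASUREMENTS, VoltageFrame
from .recon import EITImage, ReconstructionModel, normalize_image, reconstruct


class RealDataError(RuntimeError):
    pass


@dataclass(frozen=True)
class RealFrameSequence:
    """Raw differential-voltage frames, one column per time point."""

    frames: np.ndarray           # (n_measurements, n_frames)
    sampling_rate_hz: float = 7.0
    source: str = ""

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]


def read_eidors_mat(path, max_frames: int = 24,
                    sampling_rate_hz: float = 7.0) -> RealFrameSequence:
    """Extract measurement frames from an EIDORS-style ``.mat`` file.

    Field mapping: the file is scanned for the largest 2D numeric array
    with one axis equal to 208 (full adjacent protocol) or a multiple of
    16 consistent with per-drive frames; the time axis is oriented to
    columns and the first ``max_frames`` frames are kept.
    """
    if not os.path.exists(path):
        raise RealDataError(
            f"external data not present: {path!r} (user-supplied download)"
        )
    raw = loadmat(path)
    candidates = []
    for key, val in raw.items():
        if key.startswith("__") or not isinstance(val, np.ndarray):
            continue
        if val.ndim == 2 and np.issubdtype(val.dtype, np.number):
            candidates.append((val.size, key, val))
    for _, key, arr in sorted(candidates, reverse=True):
        arr = np.real(arr).astype(float)
        if arr.shape[0] == N_MEASUREMENTS:
            frames = arr
        elif arr.shape[1] == N_MEASUREMENTS:
            frames = arr.T
        else:
            continue
        frames = frames[:, :max_frames]
        if not np.all(np.isfinite(frames)):
            continue
        return RealFrameSequence(frames, sampling_rate_hz, source=key)
    raise RealDataError(
        f"no {N_MEASUREMENTS}-measurement frame array found in {path!r}; "
        f"candidate variables: {[k for _, k, _ in candidates]}"
    )


def reference_frame(sequence: RealFrameSequence) -> VoltageFrame:
    """End-expiration proxy: the frame with minimum total signal magnitude.

    Heuristic — the true reference state of the recording is unknown.
    """
    norms = np.abs(sequence.frames).sum(axis=0)
    return VoltageFrame(sequence.frames[:, int(np.argmin(norms))],
                        state="reference(min-signal)")


def infer_sequence(model, sequence: RealFrameSequence,
                   recon_model: ReconstructionModel,
                   threshold: float = 0.5):
    """Zero-shot per-frame inference: (EIT image, lung map, heart map).

    The simulation-trained estimator is applied as-is; no retraining or
    adaptation is performed.
    """
    ref = reference_frame(sequence)
    out = []
    for k in range(sequence.n_frames):
        frame = VoltageFrame(sequence.frames[:, k], state=f"frame{k}")
        img = normalize_image(reconstruct(recon_model, frame, reference=ref))
        proba = model.predict_proba(img.values[None])
        lung = (proba[0, 0] >= threshold).astype(np.uint8)
        heart = (proba[0, 1] >= threshold).astype(np.uint8)
        out.append((img, lung, heart))
    return out
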