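"""Facial-patch extraction and the spatio-temporal tensor expression profile.

Eight 31×31 facial patches (two cheek, six background) are cut out of every
frame; the Red-channel intensities of the patch with the highest and the
patch with the lowest time-averaged mean are differenced pixelwise to form
the pixel×time tensor expression profile, whose rows are then standardized
to zero mean and unit variance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .framestack import FrameStack
from .synthgen import N_PATCHES

_RED = 0


@dataclass
class PatchSeries:
    """Red-channel pixel series of the eight facial patches.

    ``data`` has shape (8, pixels, T) with pixels = w*h of each box
    (961 for the standard 31×31 patch); ``means`` holds the per-frame
    patch-mean intensity, shape (8, T).
    """

    data: np.ndarray
    roles: list[str]
    means: np.ndarray
    boxes: list[dict]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


@dataclass
class TensorProfile:
    """Normalized pixel×time difference between extreme-intensity patches.

    ``values`` holds the z-scored rows (zero-variance rows are imputed to
    zeros and flagged in ``degenerate``); ``raw`` keeps the unnormalized
    difference matrix; ``scalar_series`` is the patch-mean difference time
    series, exposed for comparison with the pixelwise profile.
    """

    values: np.ndarray
    raw: np.ndarray
    row_mean: np.ndarray
    row_sd: np.ndarray
    degenerate: np.ndarray
    max_patch: int
    min_patch: int
    scalar_series: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def save_csv(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.values, delimiter=",")
        sidecar = {
            "max_patch": int(self.max_patch),
            "min_patch": int(self.min_patch),
            "n_degenerate_rows": int(self.degenerate.sum()),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _validate_manifest(manifest: list[dict], frame_hw: tuple[int, int]) -> None:
    if len(manifest) != N_PATCHES:
        raise ValueError(f"manifest must list exactly {N_PATCHES} boxes, got {len(manifest)}")
    h, w = frame_hw
    for box in manifest:
        if box["x"] < 0 or box["y"] < 0 or box["x"] + box["w"] > w or box["y"] + box["h"] > h:
            raise ValueError(f"patch box {box} outside the {h}×{w} frame")


def extract_patches(stack: FrameStack, manifest: list[dict]) -> PatchSeries:
    """Cut the manifest's boxes out of every frame (Red channel only)."""
    _validate_manifest(manifest, stack.frame_shape)
    T = stack.n_frames
    data = []
    means = []
    for box in manifest:
        patch = stack.frames[:, box["y"] : box["y"] + box["h"], box["x"] : box["x"] + box["w"], _RED]
        flat = patch.reshape(T, -1).T  # (pixels, T)
        data.append(flat)
        means.append(flat.mean(axis=0))
    return PatchSeries(
        data=np.stack(data),
        roles=[box["role"] for box in manifest],
        means=np.stack(means),
        boxes=list(manifest),
    )


def tensor_profile(ps: PatchSeries) -> TensorProfile:
    """Pixelwise difference between the extreme-intensity patches, row-z-scored.

    The highest- and lowest-intensity patches are identified once per
    segment by their time-averaged mean (avoiding frame-to-frame identity
    switching), the pixelwise difference matrix is formed, and each pixel
    row is standardized.  Zero-variance rows are flagged degenerate,
    imputed to zeros, and a warning is emitted.
    """
    overall = ps.means.mean(axis=1)
    max_patch = int(np.argmax(overall))
    min_patch = int(np.argmin(overall))
    if max_patch == min_patch or np.isclose(overall[max_patch], overall[min_patch]):
        raise ValueError("patches have identical mean intensity; profile undefined")
    raw = ps.data[max_patch] - ps.data[min_patch]
    row_mean = raw.mean(axis=1)
    row_sd = raw.std(axis=1)
    degenerate = row_sd == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance rows imputed to zeros"
        )
    safe_sd = np.where(degenerate, 1.0, row_sd)
    values = (raw - row_mean[:, None]) / safe_sd[:, None]
    values[degenerate] = 0.0
    return TensorProfile(
        values=values,
        raw=raw,
        row_mean=row_mean,
        row_sd=row_sd,
        degenerate=degenerate,
        max_patch=max_patch,
        min_patch=min_patch,
        scalar_series=ps.means[max_patch] - ps.means[min_patch],
    )
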