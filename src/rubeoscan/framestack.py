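"""Frame-stack container and TIFF directory I/O.

A :class:`FrameStack` holds an ordered RGB video segment as a float array in
[0, 1] together with its frame rate.  On disk a stack is a directory of
zero-padded 16-bit TIFF frames plus a JSON sidecar (fps, segment index);
16-bit depth preserves sub-quantization pulse modulation that 8-bit video
would round away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

_SIDECAR = "stack.json"
_U16_MAX = 65535


@dataclass
class FrameStack:
    """An ordered stack of RGB frames with frame-rate metadata.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W, 3)
        Float intensities in [0, 1] (values outside are allowed in memory;
        they are clipped only at PNG export).
    fps : float
        Frames per second.
    segment_index : int, optional
        Position of this segment within a subject's recording session.
    """

    frames: np.ndarray
    fps: float
    segment_index: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must have shape (T, H, W, 3), got {self.frames.shape}"
            )
        if self.n_frames == 0:
            raise ValueError("frame stack is empty")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.n_frames / self.fps

    def save(self, directory: str | Path) -> Path:
        """Write the stack as zero-padded 16-bit TIFFs plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        width = max(6, len(str(self.n_frames)))
        quantized = np.clip(self.frames, 0.0, 1.0)
        quantized = np.round(quantized * _U16_MAX).astype(np.uint16)
        for t in range(self.n_frames):
            tifffile.imwrite(directory / f"frame_{t:0{width}d}.tif", quantized[t])
        sidecar = {
            "fps": self.fps,
            "segment_index": self.segment_index,
            "n_frames": self.n_frames,
            "bit_depth": 16,
        }
        (directory / _SIDECAR).write_text(json.dumps(sidecar, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "FrameStack":
        """Read a stack written by :meth:`save`."""
        directory = Path(directory)
        sidecar_path = directory / _SIDECAR
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar_path}")
        sidecar = json.loads(sidecar_path.read_text())
        paths = sorted(directory.glob("frame_*.tif"))
        if not paths:
            raise FileNotFoundError(f"no frame TIFFs found in {directory}")
        frames = np.stack([tifffile.imread(p) for p in paths]).astype(np.float64)
        frames /= _U16_MAX
        return cls(
            frames=frames,
            fps=float(sidecar["fps"]),
            segment_index=sidecar.get("segment_index"),
        )
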