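"""Largest-eigenvalue spectra of windowed covariance matrices.

One video segment yields a single pixel×time tensor profile; its empirical
spectral density of largest eigenvalues is populated by sliding a temporal
window over the segment, forming the sample covariance of the pixel rows
within each window, and recording the top eigenvalue of every window
(length 250 frames = 5 s, stride 50 = 1 s at 50 fps by default).

The top eigenvalue is computed by power iteration on the implicit
covariance operator v -> A (A^T v) / (w - 1), which never forms the
N×N covariance matrix explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_WINDOW = 250
DEFAULT_STRIDE = 50


@dataclass
class EigenSample:
    """Largest eigenvalues, one per sliding window.

    Attributes
    ----------
    values : ndarray
        The lambda_max collection whose ESD is analyzed downstream.
    N : int
        Covariance dimension (number of pixel rows).
    window_length, stride : int
        Sliding-window geometry in frames (0 when the sample was produced
        directly by a generator rather than from a profile).
    """

    values: np.ndarray
    N: int
    window_length: int = 0
    stride: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()

    def __len__(self) -> int:
        return self.values.size

    def save_csv(self, path) -> None:
        np.savetxt(path, self.values, header="lambda_max", comments="")

    @classmethod
    def load_csv(cls, path, N: int = 0) -> "EigenSample":
        values = np.loadtxt(path, skiprows=1)
        return cls(values=np.atleast_1d(values), N=N)


@dataclass
class ESD:
    """Histogram estimate of the eigenvalue density rho(lambda)."""

    bin_edges: np.ndarray
    density: np.ndarray
    values: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def save_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.bin_centers, self.density]),
            header="bin_center,density",
            delimiter=",",
            comments="",
        )


def lambda_max_power(
    window: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    seed: int = 0,
) -> float:
    """Top eigenvalue of the sample covariance of the rows of ``window``.

    ``window`` has shape (N, w): N pixel rows observed over w frames.  Rows
    are centered over the window and the covariance A A^T / (w - 1) is
    applied implicitly inside a power iteration started from a fixed-seed
    random vector, so results are deterministic.
    """
    A = np.asarray(window, dtype=np.float64)
    if A.ndim != 2:
        raise ValueError(f"window must be 2-D, got shape {A.shape}")
    n, w = A.shape
    if w < 2:
        raise ValueError("window needs at least 2 frames")
    A = A - A.mean(axis=1, keepdims=True)
    denom = w - 1
    scale = np.abs(A).max()
    if scale == 0.0:
        return 0.0
    rng = np.random.RandomState(seed)
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        u = A @ (A.T @ v) / denom
        norm = np.linalg.norm(u)
        if norm == 0.0:
            return 0.0
        lam_new = float(v @ u)
        v = u / norm
        if abs(lam_new - lam) <= tol * max(abs(lam_new), 1e-300):
            lam = lam_new
            break
        lam = lam_new
    return float(lam)


def windowed_lambda_max(
    tp,
    window_length: int = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    seed: int = 0,
) -> EigenSample:
    """Largest covariance eigenvalue per sliding window of a tensor profile.

    ``tp`` is a TensorProfile or any (N, T) array.  The number of windows is
    floor((T - window_length) / stride) + 1.
    """
    matrix = np.asarray(getattr(tp, "values", tp), dtype=np.float64)
    if matrix.ndim != 2:
        raise ValueError(f"profile must be 2-D (pixels × frames), got {matrix.shape}")
    n, T = matrix.shape
    if window_length < 2:
        raise ValueError(f"window_length must be >= 2, got {window_length}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if T < window_length:
        raise ValueError(f"profile has {T} frames, shorter than window {window_length}")
    starts = range(0, T - window_length + 1, stride)
    values = np.array(
        [
            lambda_max_power(matrix[:, s : s + window_length], tol=tol, max_iter=max_iter, seed=seed)
            for s in starts
        ]
    )
    return EigenSample(values=values, N=n, window_length=window_length, stride=stride)


def esd(values, bins="fd") -> ESD:
    """Normalized histogram estimate of the empirical spectral density.

    ``bins`` follows ``numpy.histogram`` (Freedman-Diaconis by default).
    A degenerate sample (all values equal) gets a single narrow bin so the
    density still integrates to one.
    """
    values = np.asarray(getattr(values, "values", values), dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("cannot form an ESD from an empty sample")
    if np.ptp(values) == 0.0:
        center = values[0]
        half = max(abs(center), 1.0) * 1e-6
        edges = np.array([center - half, center + half])
        density = np.array([1.0 / (2 * half)])
        return ESD(bin_edges=edges, density=density, values=values)
    density, edges = np.histogram(values, bins=bins, density=True)
    return ESD(bin_edges=edges, density=density, values=values)


def tw_normalize(lambda_max, N: int):
    """Tracy-Widom centering and scaling: xi = sqrt(2) N^(1/6) (lambda - sqrt(2N))."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    lam = np.asarray(lambda_max, dtype=np.float64)
    xi = np.sqrt(2.0) * N ** (1.0 / 6.0) * (lam - np.sqrt(2.0 * N))
    return float(xi) if xi.ndim == 0 else xi
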