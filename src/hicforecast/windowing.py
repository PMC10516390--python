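"""Diagonal sliding-window sampling and prediction reassembly.

Training and prediction operate on square submatrices sliding along the
main diagonal of each chromosome's contact map: window size 50 bins, step
3 bins by default.  Samples across time-steps are stacked into an
n x t x 1 x w x w tensor.  Because overlapping windows predict the same
pixels several times, genome-scale predictions are rebuilt by averaging
every prediction covering a pixel; pixels outside the diagonal band
covered by at least one window are marked missing (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hic_io import ContactMatrix, SpatioTemporalStack

__all__ = ["SampleTensor", "extract_windows", "reassemble", "coverage_count"]


@dataclass
class SampleTensor:
    """n x t x 1 x w x w sample array plus the bookkeeping to reassemble.

    offsets[k] is the diagonal start bin of sample k: sample k covers the
    square [offsets[k] : offsets[k]+window) on both axes at every step.
    """

    data: np.ndarray
    offsets: np.ndarray
    window: int
    step: int
    n_bins: int

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.offsets = np.asarray(self.offsets, dtype=np.intp)
        if self.data.ndim != 5 or self.data.shape[2] != 1:
            raise ValueError(f"sample tensor must be (n, t, 1, w, w), got {self.data.shape}")
        if self.data.shape[3] != self.window or self.data.shape[4] != self.window:
            raise ValueError("sample tensor spatial dims inconsistent with window size")
        if self.data.shape[0] != len(self.offsets):
            raise ValueError("one offset per sample required")
        if len(self.offsets) > 1 and not np.all(np.diff(self.offsets) == self.step):
            raise ValueError("offsets must increase by exactly the step size")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_steps(self) -> int:
        return self.data.shape[1]

    def save(self, path) -> None:
        """Persist to a single .npz container with the offset index."""
        np.savez_compressed(
            path,
            data=self.data,
            offsets=self.offsets,
            meta=np.array([self.window, self.step, self.n_bins]),
        )

    @classmethod
    def load(cls, path) -> "SampleTensor":
        with np.load(path) as z:
            window, step, n_bins = (int(x) for x in z["meta"])
            return cls(z["data"], z["offsets"], window, step, n_bins)


def extract_windows(
    stack: SpatioTemporalStack, window: int = 50, step: int = 3
) -> SampleTensor:
    """Slide a w x w window along the diagonal of every time-step.

    Start positions are 0, step, 2*step, ... while the full window fits;
    trailing bins that do not admit a complete window are dropped.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    n_bins = stack.n_bins
    if n_bins < window:
        raise ValueError(
            f"matrix has {n_bins} bins but the window needs {window}; "
            "use a smaller window or a longer chromosome"
        )
    starts = np.arange(0, n_bins - window + 1, step)
    arr = stack.as_array()  # (T, n, n)
    data = np.empty((len(starts), stack.n_steps, 1, window, window), dtype=arr.dtype)
    for k, s in enumerate(starts):
        data[k, :, 0] = arr[:, s:s + window, s:s + window]
    return SampleTensor(data=data, offsets=starts, window=window, step=step, n_bins=n_bins)


def coverage_count(n_bins: int, window: int, step: int) -> np.ndarray:
    """How many sliding windows cover each pixel (i, j)."""
    starts = np.arange(0, n_bins - window + 1, step)
    count = np.zeros((n_bins, n_bins), dtype=np.intp)
    for s in starts:
        count[s:s + window, s:s + window] += 1
    return count


def reassemble(
    predictions: np.ndarray,
    offsets: np.ndarray,
    n_bins: int,
    chrom: str = "chr?",
    resolution: int = 40000,
    clamp: bool = True,
) -> list:
    """Average overlapping window predictions into per-step matrices.

    predictions: (n, t_pred, 1, w, w) or (n, t_pred, w, w).  Each pixel of
    the output is the arithmetic mean of all window predictions covering
    it; never-covered pixels are NaN.  Outputs are clamped to [0, 1] (the
    rescaled-contact scale) before averaging unless ``clamp=False``, and
    symmetrized as (M + M.T) / 2.
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.ndim == 5:
        if predictions.shape[2] != 1:
            raise ValueError("channel axis must have size 1")
        predictions = predictions[:, :, 0]
    if predictions.ndim != 4:
        raise ValueError(f"predictions must be 4- or 5-axis, got shape {predictions.shape}")
    n, t_pred, w, w2 = predictions.shape
    if w != w2:
        raise ValueError("windows must be square")
    offsets = np.asarray(offsets, dtype=np.intp)
    if len(offsets) != n:
        raise ValueError("one offset per predicted sample required")
    if len(offsets) and (offsets.min() < 0 or offsets.max() + w > n_bins):
        raise ValueError("window offset out of matrix range")
    if clamp:
        predictions = np.clip(predictions, 0.0, 1.0)

    out = []
    for t in range(t_pred):
        total = np.zeros((n_bins, n_bins))
        count = np.zeros((n_bins, n_bins))
        for k, s in enumerate(offsets):
            total[s:s + w, s:s + w] += predictions[k, t]
            count[s:s + w, s:s + w] += 1.0
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        mean = 0.5 * (mean + mean.T)
        out.append(_MaskedContactMatrix(chrom, resolution, mean))
    return out


class _MaskedContactMatrix(ContactMatrix):
    """ContactMatrix that tolerates NaN (missing, never-covered) pixels."""

    def __init__(self, chrom, resolution, values):
        values = np.asarray(values, dtype=float)
        finite = np.nan_to_num(values)
        if not np.allclose(finite, finite.T, rtol=0, atol=1e-9):
            raise ValueError("reassembled matrix must be symmetric")
        self.chrom = chrom
        self.resolution = int(resolution)
        self.values = values

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def filled(self, fill: float = 0.0) -> ContactMatrix:
        """Dense ContactMatrix with missing pixels replaced by ``fill``."""
        return ContactMatrix(self.chrom, self.resolution, np.nan_to_num(self.values, nan=fill))
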