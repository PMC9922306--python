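"""Containers and I/O for TCSPC decay cubes, IRFs and ROI masks.

A decay cube is the raw AOFLIO measurement: a per-pixel histogram of photon
arrival times within one laser period (rows x cols x time bins).  Cubes, their
instrument response function (IRF) and acquisition metadata travel together in
one HDF5 container; ROI masks are 16-bit label images with a small CSV mapping
each label to its kind (individual cone or pooled rod region).

Repeated exposures of the same retinal location are co-aligned by integer-pixel
cross-correlation of their intensity images (sum over time bins) and cropped to
the common overlap; the crop rectangle is recorded so the same crop applies to
masks.  No sub-pixel resampling is ever applied to photon histograms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

__all__ = [
    "AcquisitionMeta",
    "DecayCube",
    "Irf",
    "RoiMask",
    "CropRect",
    "FormatError",
    "DegenerateInputError",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "intensity_image",
    "register_translation",
    "align_and_crop",
]


class FormatError(ValueError):
    """Raised when a container file is malformed or inconsistent."""


class DegenerateInputError(ValueError):
    """Raised for inputs on which an operation is mathematically undefined."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """TCSPC acquisition parameters.

    Parameters
    ----------
    repetition_rate : float
        Laser repetition rate in Hz (80 MHz for the reference instrument).
    n_bins : int
        Number of TCSPC time bins per laser period.
    bin_width : float
        Width of one time bin in seconds.  Defaults to one laser period
        divided by ``n_bins`` so the histogram spans exactly one period.
    pixel_dims : tuple of int
        Image shape as (rows, cols).
    """

    repetition_rate: float = 8.0e7
    n_bins: int = 256
    bin_width: float | None = None
    pixel_dims: tuple[int, int] = (253, 300)

    def __post_init__(self) -> None:
        if self.repetition_rate <= 0:
            raise ValueError("repetition_rate must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.bin_width is None:
            object.__setattr__(
                self, "bin_width", 1.0 / (self.repetition_rate * self.n_bins)
            )
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        period = 1.0 / self.repetition_rate
        if self.n_bins * self.bin_width > period + 1e-15:
            raise ValueError("histogram span exceeds one laser period")

    @property
    def period(self) -> float:
        """One laser period in seconds."""
        return 1.0 / self.repetition_rate

    def bin_centers(self) -> np.ndarray:
        """Bin-center times t_k = (k + 1/2) * bin_width, in seconds."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass
class DecayCube:
    """Photon-count histograms, one per pixel: counts[row, col, bin]."""

    counts: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3-D (row, col, bin) array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = np.round(self.counts).astype(np.int64)
        if self.counts.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.shape[2] != self.meta.n_bins:
            raise FormatError(
                f"cube has {self.counts.shape[2]} bins, metadata says "
                f"{self.meta.n_bins}"
            )
        if self.counts.shape[:2] != tuple(self.meta.pixel_dims):
            self.meta = AcquisitionMeta(
                repetition_rate=self.meta.repetition_rate,
                n_bins=self.meta.n_bins,
                bin_width=self.meta.bin_width,
                pixel_dims=self.counts.shape[:2],
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape


@dataclass
class Irf:
    """Instrument response function sampled on the same time bins as the cubes."""

    curve: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if self.curve.ndim != 1:
            raise ValueError("IRF curve must be 1-D")
        if self.curve.size != self.meta.n_bins:
            raise FormatError("IRF bin count does not match metadata")
        if np.any(self.curve < 0):
            raise ValueError("IRF must be non-negative")
        if self.curve.sum() <= 0:
            raise ValueError("IRF must have positive total")

    def normalized(self) -> np.ndarray:
        return self.curve / self.curve.sum()


@dataclass
class RoiMask:
    """Integer label image marking ROIs; 0 is background.

    ``kind_by_label`` maps every nonzero label to ``"cone"`` or
    ``"rod_region"``.
    """

    labels: np.ndarray
    kind_by_label: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.kind_by_label)
        if missing:
            raise ValueError(f"labels without a kind: {sorted(missing)[:5]} ...")
        bad = set(self.kind_by_label.values()) - {"cone", "rod_region"}
        if bad:
            raise ValueError(f"unknown ROI kinds: {bad}")

    def labels_of_kind(self, kind: str) -> list[int]:
        return sorted(l for l, k in self.kind_by_label.items() if k == kind)


@dataclass(frozen=True)
class CropRect:
    """Crop rectangle in 0-based (row, col) coordinates, end-exclusive."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def apply(self, image: np.ndarray) -> np.ndarray:
        return image[self.row_start : self.row_stop, self.col_start : self.col_stop]

    def apply_mask(self, mask: RoiMask) -> RoiMask:
        cropped = self.apply(mask.labels)
        kinds = {
            l: mask.kind_by_label[l]
            for l in np.unique(cropped).tolist()
            if l != 0
        }
        return RoiMask(labels=cropped, kind_by_label=kinds)


# ---------------------------------------------------------------------------
# HDF5 container I/O


def write_cube(path: str | Path, cube: DecayCube, irf: Irf | None = None) -> None:
    """Write a cube (and optionally its IRF) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=cube.counts, compression="gzip")
        if irf is not None:
            f.create_dataset("irf", data=irf.curve)
        f.attrs["repetition_rate_hz"] = cube.meta.repetition_rate
        f.attrs["n_bins"] = cube.meta.n_bins
        f.attrs["bin_width_s"] = cube.meta.bin_width


def read_cube(path: str | Path) -> DecayCube:
    """Read a decay cube from an HDF5 container written by :func:`write_cube`."""
    with h5py.File(path, "r") as f:
        if "counts" not in f:
            raise FormatError(f"{path}: no /counts dataset")
        for attr in ("repetition_rate_hz", "n_bins", "bin_width_s"):
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing attribute {attr}")
        counts = f["counts"][()]
        meta = AcquisitionMeta(
            repetition_rate=float(f.attrs["repetition_rate_hz"]),
            n_bins=int(f.attrs["n_bins"]),
            bin_width=float(f.attrs["bin_width_s"]),
            pixel_dims=counts.shape[:2],
        )
    if counts.ndim != 3 or counts.shape[2] != meta.n_bins:
        raise FormatError(f"{path}: counts shape {counts.shape} inconsistent with n_bins")
    if counts.min(initial=0) < 0:
        raise ValueError(f"{path}: negative counts")
    return DecayCube(counts=counts, meta=meta)


def read_irf(path: str | Path) -> Irf:
    """Read the IRF stored alongside a cube."""
    with h5py.File(path, "r") as f:
        if "irf" not in f:
            raise FormatError(f"{path}: no /irf dataset")
        curve = f["irf"][()]
        meta = AcquisitionMeta(
            repetition_rate=float(f.attrs["repetition_rate_hz"]),
            n_bins=int(f.attrs["n_bins"]),
            bin_width=float(f.attrs["bin_width_s"]),
            pixel_dims=(1, 1),
        )
    return Irf(curve=curve, meta=meta)


def write_mask(path: str | Path, mask: RoiMask) -> None:
    """Write the label image as 16-bit TIFF plus a (label, kind) CSV next to it."""
    path = Path(path)
    labels = mask.labels
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more labels than a 16-bit image can hold")
    tifffile.imwrite(path, labels.astype(np.uint16))
    with open(path.with_suffix(".csv"), "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["label", "kind"])
        for label in sorted(mask.kind_by_label):
            w.writerow([label, mask.kind_by_label[label]])


def read_mask(path: str | Path) -> RoiMask:
    """Read a mask written by :func:`write_mask`."""
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int64)
    kinds: dict[int, str] = {}
    with open(path.with_suffix(".csv"), newline="") as f:
        for row in csv.DictReader(f):
            kinds[int(row["label"])] = row["kind"]
    return RoiMask(labels=labels, kind_by_label=kinds)


# ---------------------------------------------------------------------------
# Registration and cropping


def intensity_image(cube: DecayCube) -> np.ndarray:
    """Total photon counts per pixel (the natural FLIM intensity image)."""
    return cube.counts.sum(axis=2)


def register_translation(
    ref_image: np.ndarray, mov_image: np.ndarray
) -> tuple[int, int]:
    """Integer shift (dr, dc) maximizing the circular normalized cross-correlation.

    The returned shift satisfies ``np.roll(ref, (dr, dc), axis=(0, 1)) ~ mov``.
    Ties are broken by smallest ``|dr| + |dc|``, then smallest dr, then dc.
    """
    ref = np.asarray(ref_image, dtype=float)
    mov = np.asarray(mov_image, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("images must have the same shape")
    if ref.std() == 0 or mov.std() == 0:
        raise DegenerateInputError("constant image has no registration signal")
    a = (ref - ref.mean()) / ref.std()
    b = (mov - mov.mean()) / mov.std()
    # circular cross-correlation via FFT; corr[d] = sum_x a[x] * b[x + d is rolled]
    corr = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    peak = corr.max()
    # all near-degenerate maxima, then deterministic tie-break
    rows, cols = np.nonzero(corr >= peak - 1e-9 * max(1.0, abs(peak)))
    n_r, n_c = ref.shape
    best: tuple[int, int, int] | None = None
    best_shift = (0, 0)
    for r, c in zip(rows.tolist(), cols.tolist()):
        dr = r - n_r if r > n_r // 2 else r
        dc = c - n_c if c > n_c // 2 else c
        key = (abs(dr) + abs(dc), dr, dc)
        if best is None or key < best:
            best = key
            best_shift = (dr, dc)
    return best_shift


def align_and_crop(
    cube_a: DecayCube, cube_b: DecayCube, shift: tuple[int, int]
) -> tuple[DecayCube, DecayCube, CropRect]:
    """Crop two cubes to their overlap after applying an integer shift.

    ``shift`` is the (dr, dc) returned by :func:`register_translation` with
    ``cube_a`` as reference, i.e. content at A[r, c] appears at B[r+dr, c+dc].
    Returns the cropped cubes plus the crop rectangle in A's coordinates (the
    same rectangle, offset by the shift, applies to B and to B's masks).
    """
    dr, dc = int(shift[0]), int(shift[1])
    n_r, n_c, _ = cube_a.shape
    if abs(dr) >= n_r or abs(dc) >= n_c:
        raise ValueError("shift leaves no overlap")
    r0_a, r1_a = max(0, -dr), n_r - max(0, dr)
    c0_a, c1_a = max(0, -dc), n_c - max(0, dc)
    crop_a = CropRect(r0_a, r1_a, c0_a, c1_a)
    crop_b = CropRect(r0_a + dr, r1_a + dr, c0_a + dc, c1_a + dc)
    out_a = DecayCube(
        counts=cube_a.counts[crop_a.row_start : crop_a.row_stop,
                             crop_a.col_start : crop_a.col_stop],
        meta=cube_a.meta,
    )
    out_b = DecayCube(
        counts=cube_b.counts[crop_b.row_start : crop_b.row_stop,
                             crop_b.col_start : crop_b.col_stop],
        meta=cube_b.meta,
    )
    return out_a, out_b, crop_a
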