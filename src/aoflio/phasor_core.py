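"""Phasor representation of fluorescence decays.

The phasor of a decay d[k] at angular frequency omega is the normalized
cosine/sine Fourier pair

    g = sum_k d[k] cos(omega t_k) / sum_k d[k]
    s = sum_k d[k] sin(omega t_k) / sum_k d[k]

evaluated at the laser repetition rate (first harmonic), with bin-center times
t_k = (k + 1/2) * bin_width.  Mono-exponential decays map onto the universal
semicircle (g - 1/2)^2 + s^2 = 1/4; mixtures map strictly inside it, and the
transform is linear in the decay, so the phasor of a photon-weighted sum of
decays is the photon-weighted convex combination of their phasors.

Instrument-response correction is done in phasor space: periodic convolution
with the IRF multiplies the complex phasor z = g + i s by the IRF's own
transform, so dividing by the IRF reference phasor undoes it exactly.  One
subtlety: with bin-center times the discrete convolution theorem picks up a
half-bin phase; computing the IRF *reference* phasor on bin left edges
(:func:`irf_reference_phasor`) cancels it, making the complex division an
exact inverse of periodic convolution for binned data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .flim_io import AcquisitionMeta, DecayCube, Irf, RoiMask

__all__ = [
    "PhasorPoint",
    "RoiDecay",
    "UndefinedPhasorError",
    "IllConditionedIrfError",
    "aggregate_rois",
    "phasor_transform",
    "irf_reference_phasor",
    "deconvolve_irf",
    "phasor_of_monoexp",
    "phasor_of_biexp",
    "phasor_of_biexp_binned",
    "discretize_biexp",
]


class UndefinedPhasorError(ValueError):
    """Raised when a phasor is requested for a decay with zero total counts."""


class IllConditionedIrfError(ValueError):
    """Raised when the IRF phasor modulus is too small for stable division."""


@dataclass(frozen=True)
class PhasorPoint:
    """A (g, s) phasor coordinate at a given evaluation frequency (Hz)."""

    g: float
    s: float
    frequency: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g) and np.isfinite(self.s)):
            raise ValueError("phasor coordinates must be finite")

    @property
    def z(self) -> complex:
        return complex(self.g, self.s)

    @property
    def modulus(self) -> float:
        return abs(self.z)


@dataclass
class RoiDecay:
    """Aggregate decay of one ROI (summed over its member pixels)."""

    roi_label: int
    kind: str
    decay: np.ndarray
    total_photons: int

    def __post_init__(self) -> None:
        self.decay = np.asarray(self.decay)
        assert self.total_photons == int(self.decay.sum())


def aggregate_rois(cube: DecayCube, mask: RoiMask) -> list[RoiDecay]:
    """Sum per-pixel decay histograms within each labeled ROI.

    ROIs with zero photons (or zero pixels) are excluded with a warning.
    Returned in ascending label order.
    """
    if mask.labels.shape != cube.counts.shape[:2]:
        raise ValueError("mask shape does not match cube pixel dimensions")
    labels_flat = mask.labels.ravel()
    n_lab = int(labels_flat.max(initial=0))
    counts_flat = cube.counts.reshape(-1, cube.meta.n_bins)
    # per-label decay sums via one bincount per time bin
    sums = np.empty((n_lab + 1, cube.meta.n_bins), dtype=np.int64)
    for b in range(cube.meta.n_bins):
        sums[:, b] = np.bincount(
            labels_flat, weights=counts_flat[:, b], minlength=n_lab + 1
        )
    out: list[RoiDecay] = []
    for label in sorted(mask.kind_by_label):
        decay = sums[label] if label <= n_lab else np.zeros(cube.meta.n_bins, int)
        total = int(decay.sum())
        if total == 0:
            warnings.warn(f"ROI {label} has zero photons; excluded", stacklevel=2)
            continue
        out.append(
            RoiDecay(
                roi_label=label,
                kind=mask.kind_by_label[label],
                decay=decay,
                total_photons=total,
            )
        )
    return out


def phasor_transform(
    decay: np.ndarray, meta: AcquisitionMeta, harmonic: int = 1
) -> PhasorPoint:
    """Phasor of a decay histogram at the given harmonic of the repetition rate."""
    d = np.asarray(decay, dtype=float)
    total = d.sum()
    if total <= 0:
        raise UndefinedPhasorError("all-zero decay has no phasor")
    omega = 2.0 * np.pi * harmonic * meta.repetition_rate
    t = meta.bin_centers()[: d.size]
    g = float(np.dot(d, np.cos(omega * t)) / total)
    s = float(np.dot(d, np.sin(omega * t)) / total)
    return PhasorPoint(g=g, s=s, frequency=harmonic * meta.repetition_rate)


def irf_reference_phasor(
    irf: Irf, meta: AcquisitionMeta, harmonic: int = 1
) -> PhasorPoint:
    """IRF phasor on bin *left edges* (t_k = k * bin_width).

    With decays transformed at bin centers, periodic convolution with the IRF
    multiplies the complex phasor by exactly this quantity, so
    :func:`deconvolve_irf` against it is an exact inverse (noise-free).
    """
    curve = irf.normalized()
    omega = 2.0 * np.pi * harmonic * meta.repetition_rate
    t = np.arange(curve.size) * meta.bin_width
    g = float(np.dot(curve, np.cos(omega * t)))
    s = float(np.dot(curve, np.sin(omega * t)))
    return PhasorPoint(g=g, s=s, frequency=harmonic * meta.repetition_rate)


def deconvolve_irf(
    measured: PhasorPoint, irf_phasor: PhasorPoint, epsilon: float = 1e-9
) -> PhasorPoint:
    """Remove the IRF contribution by complex division z_measured / z_irf."""
    if measured.frequency != irf_phasor.frequency:
        raise ValueError("phasor frequencies differ")
    if irf_phasor.modulus <= epsilon:
        raise IllConditionedIrfError(
            f"IRF phasor modulus {irf_phasor.modulus:g} <= {epsilon:g}"
        )
    z = measured.z / irf_phasor.z
    return PhasorPoint(g=z.real, s=z.imag, frequency=measured.frequency)


# ---------------------------------------------------------------------------
# Closed-form oracles


def phasor_of_monoexp(tau: float, omega: float) -> PhasorPoint:
    """Continuous-time phasor of a single exponential: lies on the semicircle."""
    wt = omega * tau
    denom = 1.0 + wt * wt
    return PhasorPoint(g=1.0 / denom, s=wt / denom, frequency=omega / (2 * np.pi))


def phasor_of_biexp(
    a1: float, tau1: float, a2: float, tau2: float, omega: float
) -> PhasorPoint:
    """Continuous-time phasor of a biexponential decay.

    The phasor is the intensity-weighted combination of the component phasors,
    with intensity fractions f_i = a_i tau_i / (a1 tau1 + a2 tau2).
    """
    w1, w2 = a1 * tau1, a2 * tau2
    total = w1 + w2
    if total <= 0:
        raise ValueError("a1*tau1 + a2*tau2 must be positive")
    p1 = phasor_of_monoexp(tau1, omega)
    p2 = phasor_of_monoexp(tau2, omega)
    f1, f2 = w1 / total, w2 / total
    return PhasorPoint(
        g=f1 * p1.g + f2 * p2.g,
        s=f1 * p1.s + f2 * p2.s,
        frequency=omega / (2 * np.pi),
    )


def _binned_monoexp_phasor(tau: float, meta: AcquisitionMeta, harmonic: int) -> complex:
    """Exact phasor of the bin-integrated, period-wrapped exponential.

    The expected bin mass of a periodically wrapped exponential is a geometric
    sequence; summing it against e^{i omega t_k} at bin centers gives the
    closed form  z = (1 - E) e^{i omega dt / 2} / (1 - E e^{i omega dt}),
    with E = exp(-dt / tau).
    """
    dt = meta.bin_width
    omega = 2.0 * np.pi * harmonic * meta.repetition_rate
    e = np.exp(-dt / tau)
    return (1.0 - e) * np.exp(0.5j * omega * dt) / (1.0 - e * np.exp(1j * omega * dt))


def phasor_of_biexp_binned(
    a1: float,
    tau1: float,
    a2: float,
    tau2: float,
    meta: AcquisitionMeta,
    harmonic: int = 1,
) -> PhasorPoint:
    """Exact phasor of the *discretized* periodic biexponential.

    Closed form for what :func:`phasor_transform` returns on the expected
    (noise-free) bin-integrated decay; used as the machine-precision oracle
    for the rendering + transform path.  Differs from :func:`phasor_of_biexp`
    by O((omega * bin_width)^2) discretization terms.
    """
    w1, w2 = a1 * tau1, a2 * tau2
    total = w1 + w2
    if total <= 0:
        raise ValueError("a1*tau1 + a2*tau2 must be positive")
    z = (w1 * _binned_monoexp_phasor(tau1, meta, harmonic)
         + w2 * _binned_monoexp_phasor(tau2, meta, harmonic)) / total
    return PhasorPoint(
        g=z.real, s=z.imag, frequency=harmonic * meta.repetition_rate
    )


def discretize_biexp(
    a1: float, tau1: float, a2: float, tau2: float, meta: AcquisitionMeta
) -> np.ndarray:
    """Normalized expected bin masses of a period-wrapped biexponential.

    Each component contributes bin integrals of sum_n a e^{-(t + nT)/tau}
    over one period T; the result is normalized to unit total, giving the
    probability that a photon falls in each TCSPC bin.
    """
    dt, n = meta.bin_width, meta.n_bins
    period = n * dt
    edges = np.arange(n + 1) * dt
    out = np.zeros(n)
    for a, tau in ((a1, tau1), (a2, tau2)):
        if a == 0:
            continue
        wrap = 1.0 - np.exp(-period / tau)
        cdf = -np.expm1(-edges / tau)  # 1 - e^{-t/tau}, stable near 0
        out += a * tau * np.diff(cdf) / wrap
    total = out.sum()
    if total <= 0:
        raise ValueError("degenerate kinetics: zero total intensity")
    return out / total
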