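"""Synthetic AOFLIO scenes: photoreceptor mosaics with ground truth.

Real AOFLIO acquisitions of the photoreceptor layer show a hexagonally packed
cone mosaic with a sparse (~8-14%) semi-crystalline S-cone submosaic — S cones
are rarely adjacent to one another — and rod photoreceptors filling the space
between cones.  Each cell class has its own fluorescence decay kinetics.  This
module generates such scenes with full ground truth (cell positions, class
labels, damage flags) and renders them into TCSPC decay cubes:

* per-class biexponential decay, bin-integrated over one laser period with
  periodic wrap-around (incomplete decay at 80 MHz),
* circular convolution with the instrument response function,
* optional optical crosstalk mixing a fraction of each cell's signal with its
  neighbors' decays,
* per-cell brightness variability (lognormal, mean 1),
* Poisson photon statistics per (pixel, bin).

A selective photodamage mode emulates high-exposure S-cone damage: damaged
cells lose brightness by a constant factor (2.6-fold by default) and their
lifetimes shorten, moving their phasor toward (1, 0).

Default kinetics are synthetic: the real per-class decay parameters are
unknown (only mean-lifetime summaries are published), so the defaults were
chosen once to reproduce the key geometry — S and M/L cones with nearly equal
amplitude-weighted mean lifetime but well-separated phasors, rods closest to
(1, 0).  See docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .flim_io import AcquisitionMeta, DecayCube, Irf, RoiMask
from .phasor_core import discretize_biexp

__all__ = [
    "CellKinetics",
    "SimScene",
    "DEFAULT_KINETICS",
    "default_irf",
    "build_mosaic",
    "render_cube",
    "apply_damage",
]

S_CONE = "S_cone"
ML_CONE = "ML_cone"
ROD = "rod"


@dataclass(frozen=True)
class CellKinetics:
    """Biexponential decay parameters and expected photon budget for one class.

    ``a1`` and ``a2`` are fractional amplitudes (a1 + a2 = 1 by convention);
    ``tau1 <= tau2`` in seconds; ``brightness`` is the expected total photon
    count collected from one cell (or one rod region tile).
    """

    a1: float
    tau1: float
    a2: float
    tau2: float
    brightness: float

    def __post_init__(self) -> None:
        if self.tau1 > self.tau2:
            raise ValueError("component ordering requires tau1 <= tau2")
        if self.a1 < 0 or self.a2 < 0 or self.a1 + self.a2 <= 0:
            raise ValueError("amplitudes must be non-negative with positive sum")
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")

    @property
    def tau_mean(self) -> float:
        """Amplitude-weighted mean lifetime (a1 tau1 + a2 tau2)/(a1 + a2)."""
        return (self.a1 * self.tau1 + self.a2 * self.tau2) / (self.a1 + self.a2)


#: Synthetic per-class kinetics (times in seconds, brightness in photons).
#: S and M/L mean lifetimes differ by <2% while their phasors separate widely;
#: rods sit nearest (1, 0).
DEFAULT_KINETICS: dict[str, CellKinetics] = {
    ML_CONE: CellKinetics(a1=0.70, tau1=150e-12, a2=0.30, tau2=1100e-12,
                          brightness=1e4),
    S_CONE: CellKinetics(a1=0.85, tau1=150e-12, a2=0.15, tau2=2050e-12,
                         brightness=1e4),
    ROD: CellKinetics(a1=0.85, tau1=90e-12, a2=0.15, tau2=850e-12,
                      brightness=8e3),
}


def default_irf(meta: AcquisitionMeta, fwhm: float = 150e-12,
                center_bin: float = 10.0) -> Irf:
    """Gaussian IRF (FWHM 150 ps, centered at bin 10) on the cube's time bins."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = meta.bin_centers()
    curve = np.exp(-0.5 * ((t - center_bin * meta.bin_width) / sigma) ** 2)
    return Irf(curve=curve, meta=meta)


@dataclass
class SimScene:
    """Ground truth for one synthetic retinal field.

    Cone cells are listed first in ``cell_centers`` / ``cell_class``; rod
    region tiles are materialized at render time by Voronoi assignment of
    interstitial pixels to the nearest cone.
    """

    field_dims: tuple[int, int]
    cell_centers: np.ndarray          # (n_cones, 2) float (row, col)
    cell_class: np.ndarray            # (n_cones,) unicode, S_CONE or ML_CONE
    cell_radius_px: float
    cone_spacing_px: float
    kinetics_by_class: dict[str, CellKinetics]
    damaged: np.ndarray               # (n_cones,) bool
    brightness_factor: np.ndarray     # (n_cones,) lognormal, mean 1
    crosstalk_fraction: float = 0.0
    damage_intensity_factor: float = 1.0
    damage_lifetime_scale: float = 1.0
    seed: int = 0
    s_labeling_warning: str | None = None
    neighbor_pairs: np.ndarray = field(default=None, repr=False)  # lattice edges

    @property
    def n_cones(self) -> int:
        return len(self.cell_centers)

    def s_mask(self) -> np.ndarray:
        return self.cell_class == S_CONE

    def damaged_kinetics(self, cls: str) -> CellKinetics:
        """Kinetics of a damaged cell of class ``cls`` (shortened lifetimes)."""
        k = self.kinetics_by_class[cls]
        return replace(
            k,
            tau1=k.tau1 * self.damage_lifetime_scale,
            tau2=k.tau2 * self.damage_lifetime_scale,
            brightness=k.brightness / self.damage_intensity_factor,
        )


def _hex_lattice(field_dims: tuple[int, int], spacing: float,
                 margin: float) -> np.ndarray:
    rows, cols = field_dims
    dy = spacing * np.sqrt(3.0) / 2.0
    centers = []
    r = margin
    i = 0
    while r <= rows - 1 - margin:
        offset = 0.0 if i % 2 == 0 else spacing / 2.0
        c = margin + offset
        while c <= cols - 1 - margin:
            centers.append((r, c))
            c += spacing
        r += dy
        i += 1
    return np.array(centers, dtype=float)


def _label_s_cones(n: int, n_s: int, edges: np.ndarray, rng: np.random.Generator,
                   max_restarts: int = 200) -> tuple[np.ndarray, str | None]:
    """Pick n_s S cones with no two adjacent on the lattice neighbor graph.

    Random sequential selection with adjacency exclusion, restarted on
    dead-ends; falls back to unconstrained random labeling with a warning if
    all restarts fail.
    """
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    for _ in range(max_restarts):
        order = rng.permutation(n)
        chosen: list[int] = []
        blocked = np.zeros(n, dtype=bool)
        for idx in order:
            if not blocked[idx]:
                chosen.append(int(idx))
                blocked[idx] = True
                for nb in adj[idx]:
                    blocked[nb] = True
                if len(chosen) == n_s:
                    mask = np.zeros(n, dtype=bool)
                    mask[chosen] = True
                    return mask, None
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=n_s, replace=False)] = True
    msg = "S-cone exclusion labeling failed; fell back to random labels"
    warnings.warn(msg, stacklevel=3)
    return mask, msg


def build_mosaic(
    field_dims: tuple[int, int] = (253, 300),
    cone_spacing_px: float = 16.0,
    s_fraction: float = 0.12,
    seed: int = 0,
    cell_radius_px: float = 3.0,
    jitter_px: float = 0.5,
    brightness_sigma: float = 0.12,
    crosstalk_fraction: float = 0.0,
    kinetics_by_class: dict[str, CellKinetics] | None = None,
) -> SimScene:
    """Generate a jittered hexagonal cone mosaic with a sparse S-cone submosaic.

    S-cone labels are drawn by rejection so that no two S cones are lattice
    neighbors (enforceable for s_fraction <= 0.15; falls back to random
    labeling with a warning otherwise).  Deterministic given ``seed``.
    """
    if not 0.0 < s_fraction < 0.5:
        raise ValueError("s_fraction must be in (0, 0.5)")
    if cone_spacing_px < 3.0:
        raise ValueError("cone spacing must be >= 3 px")
    rng = np.random.default_rng(seed)
    margin = cell_radius_px + 1.0
    lattice = _hex_lattice(field_dims, cone_spacing_px, margin)
    if len(lattice) < 20:
        raise ValueError(
            f"field {field_dims} too small: only {len(lattice)} cones fit"
        )
    # lattice neighbor graph before jitter (jitter never changes adjacency)
    tree = cKDTree(lattice)
    pairs = tree.query_pairs(r=1.3 * cone_spacing_px, output_type="ndarray")
    centers = lattice + rng.normal(0.0, jitter_px, size=lattice.shape)
    centers[:, 0] = np.clip(centers[:, 0], margin, field_dims[0] - 1 - margin)
    centers[:, 1] = np.clip(centers[:, 1], margin, field_dims[1] - 1 - margin)

    n = len(centers)
    n_s = int(round(s_fraction * n))
    s_mask, warning = _label_s_cones(n, n_s, pairs, rng)
    classes = np.where(s_mask, S_CONE, ML_CONE)

    sigma = brightness_sigma
    factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)

    return SimScene(
        field_dims=tuple(field_dims),
        cell_centers=centers,
        cell_class=classes,
        cell_radius_px=cell_radius_px,
        cone_spacing_px=cone_spacing_px,
        kinetics_by_class=dict(kinetics_by_class or DEFAULT_KINETICS),
        damaged=np.zeros(n, dtype=bool),
        brightness_factor=factors,
        crosstalk_fraction=float(crosstalk_fraction),
        seed=seed,
        s_labeling_warning=warning,
        neighbor_pairs=pairs,
    )


def apply_damage(
    scene: SimScene,
    intensity_factor: float = 2.6,
    lifetime_scale: float = 0.6,
) -> SimScene:
    """Selective S-cone photodamage: dimmer cells with shortened lifetimes.

    All S cones are flagged damaged; their brightness is divided by
    ``intensity_factor`` and both lifetime components are multiplied by
    ``lifetime_scale``, moving the damaged-cone phasor toward (1, 0).
    Returns a new scene; the input is unchanged.
    """
    if intensity_factor < 1.0:
        raise ValueError("intensity_factor must be >= 1")
    if not 0.0 < lifetime_scale <= 1.0:
        raise ValueError("lifetime_scale must be in (0, 1]")
    return replace(
        scene,
        damaged=scene.s_mask().copy(),
        damage_intensity_factor=float(intensity_factor),
        damage_lifetime_scale=float(lifetime_scale),
    )


def _cone_pixel_sets(scene: SimScene) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pixel (row, col) index arrays of the disk footprint of each cone."""
    rows, cols = scene.field_dims
    rad = scene.cell_radius_px
    out = []
    for cr, cc in scene.cell_centers:
        r0, r1 = int(np.floor(cr - rad)), int(np.ceil(cr + rad)) + 1
        c0, c1 = int(np.floor(cc - rad)), int(np.ceil(cc + rad)) + 1
        rr, cc_ = np.mgrid[max(r0, 0):min(r1, rows), max(c0, 0):min(c1, cols)]
        inside = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= rad**2
        out.append((rr[inside], cc_[inside]))
    return out


def _cell_shapes(scene: SimScene, irf: Irf, meta: AcquisitionMeta) -> np.ndarray:
    """Per-cone normalized expected decay shape (IRF-convolved, crosstalk-mixed)."""
    irf_n = irf.normalized()
    irf_fft = np.fft.rfft(irf_n)

    def conv_shape(kin: CellKinetics) -> np.ndarray:
        pdf = discretize_biexp(kin.a1, kin.tau1, kin.a2, kin.tau2, meta)
        return np.fft.irfft(np.fft.rfft(pdf) * irf_fft, n=meta.n_bins)

    cache: dict[tuple[str, bool], np.ndarray] = {}
    shapes = np.empty((scene.n_cones, meta.n_bins))
    for i in range(scene.n_cones):
        key = (str(scene.cell_class[i]), bool(scene.damaged[i]))
        if key not in cache:
            kin = (scene.damaged_kinetics(key[0]) if key[1]
                   else scene.kinetics_by_class[key[0]])
            cache[key] = conv_shape(kin)
        shapes[i] = cache[key]

    x = scene.crosstalk_fraction
    if x > 0.0:
        # mix each cell's shape with the brightness-weighted mean of its
        # lattice neighbors' shapes
        bright = np.array([
            (scene.damaged_kinetics(c).brightness if d
             else scene.kinetics_by_class[c].brightness) * f
            for c, d, f in zip(scene.cell_class, scene.damaged,
                               scene.brightness_factor)
        ])
        mixed = shapes.copy()
        adj: list[list[int]] = [[] for _ in range(scene.n_cones)]
        for i, j in scene.neighbor_pairs:
            adj[i].append(j)
            adj[j].append(i)
        for i, nbs in enumerate(adj):
            if nbs:
                w = bright[nbs]
                nb_shape = (shapes[nbs] * w[:, None]).sum(0) / w.sum()
                mixed[i] = (1.0 - x) * shapes[i] + x * nb_shape
        shapes = mixed
    return shapes


def render_cube(
    scene: SimScene,
    irf: Irf | None = None,
    meta: AcquisitionMeta | None = None,
    seed: int = 0,
    sample_noise: bool = True,
) -> tuple[DecayCube, RoiMask]:
    """Render a scene to a decay cube plus its ground-truth ROI mask.

    Cone labels are 1..n_cones (in scene order); rod region tiles — Voronoi
    cells of interstitial pixels around each cone — get labels
    n_cones+1..2*n_cones.  With ``sample_noise=False`` the cube holds the
    expected (noise-free) per-bin values rounded to the nearest integer when
    converted to counts; pass the raw expectation to analysis code via
    ``render_expectation`` semantics by keeping noise off.
    """
    meta = meta or AcquisitionMeta(pixel_dims=scene.field_dims)
    if meta.pixel_dims != tuple(scene.field_dims):
        meta = AcquisitionMeta(
            repetition_rate=meta.repetition_rate, n_bins=meta.n_bins,
            bin_width=meta.bin_width, pixel_dims=tuple(scene.field_dims),
        )
    irf = irf or default_irf(meta)
    rng = np.random.default_rng(seed)
    rows, cols = scene.field_dims
    n_bins = meta.n_bins

    labels = np.zeros((rows, cols), dtype=np.int32)
    expected = np.zeros((rows, cols, n_bins), dtype=np.float64)

    shapes = _cell_shapes(scene, irf, meta)
    pixel_sets = _cone_pixel_sets(scene)
    for i, (rr, cc) in enumerate(pixel_sets):
        if rr.size == 0:
            continue
        kin = (scene.damaged_kinetics(str(scene.cell_class[i]))
               if scene.damaged[i]
               else scene.kinetics_by_class[str(scene.cell_class[i])])
        per_px = kin.brightness * scene.brightness_factor[i] / rr.size
        expected[rr, cc, :] = per_px * shapes[i]
        labels[rr, cc] = i + 1

    # rod tiles: interstitial pixels assigned to the nearest cone center
    rod_kin = scene.kinetics_by_class[ROD]
    irf_fft = np.fft.rfft(irf.normalized())
    rod_pdf = discretize_biexp(rod_kin.a1, rod_kin.tau1, rod_kin.a2,
                               rod_kin.tau2, meta)
    rod_shape = np.fft.irfft(np.fft.rfft(rod_pdf) * irf_fft, n=n_bins)
    interstitial = labels == 0
    ir, ic = np.nonzero(interstitial)
    tree = cKDTree(scene.cell_centers)
    _, nearest = tree.query(np.column_stack([ir, ic]))
    tile_labels = scene.n_cones + 1 + nearest.astype(np.int32)
    labels[ir, ic] = tile_labels
    tile_sizes = np.bincount(nearest, minlength=scene.n_cones).astype(float)
    per_px_rod = rod_kin.brightness / np.maximum(tile_sizes[nearest], 1.0)
    expected[ir, ic, :] = per_px_rod[:, None] * rod_shape[None, :]

    if sample_noise:
        # sampling the flat view is markedly faster than the 3-D array
        counts = rng.poisson(expected.ravel()).reshape(expected.shape)
    else:
        counts = np.round(expected).astype(np.int64)

    kinds = {i + 1: "cone" for i in range(scene.n_cones)}
    kinds.update({scene.n_cones + 1 + i: "rod_region"
                  for i in np.unique(nearest).tolist()})
    mask = RoiMask(labels=labels, kind_by_label=kinds)
    return DecayCube(counts=counts, meta=meta), mask


def expected_roi_decay(
    scene: SimScene, cell_index: int, irf: Irf, meta: AcquisitionMeta
) -> np.ndarray:
    """Noise-free expected aggregate decay of one cone (for oracle tests)."""
    shapes = _cell_shapes(scene, irf, meta)
    kin = (scene.damaged_kinetics(str(scene.cell_class[cell_index]))
           if scene.damaged[cell_index]
           else scene.kinetics_by_class[str(scene.cell_class[cell_index])])
    return kin.brightness * scene.brightness_factor[cell_index] * shapes[cell_index]
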