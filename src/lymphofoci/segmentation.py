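"""Nucleus segmentation (DAPI) and sub-micron focus detection in physical units.

Segmentation follows the standard fluorescence-microscopy recipe: Otsu
threshold on DAPI, hole filling, a distance-transform watershed to split
touching nuclei, then size and border filters.  Foci are found per nucleus
with multiscale Laplacian-of-Gaussian blob detection; each focus "size" is
reported as its half-maximum diameter in um (robust radial profile), which
is the measurement the >= 1 um large-focus rule is applied to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import blob_log, peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.segmentation import clear_border, watershed


@dataclass
class ImageField:
    """Named 2-D channels sharing one shape, with the pixel size in um."""

    channels: dict[str, np.ndarray]
    pixel_size: float
    field_id: str = "field"

    def __post_init__(self) -> None:
        if self.pixel_size is None or self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0 (um per pixel)")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} missing; have "
                           f"{sorted(self.channels)}")
        return self.channels[name]


def project_zstack(frames) -> np.ndarray:
    """Maximum-intensity projection of a stack of equally shaped 2-D frames."""
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("empty stack")
    if len({f.shape for f in frames}) > 1:
        raise ValueError("stack frames must share one shape")
    return np.maximum.reduce(frames)


@dataclass
class NucleusMask:
    nucleus_id: int
    centroid_um: tuple[float, float]     # (y, x)
    area_um2: float
    bbox: tuple[int, int, int, int]      # (y0, x0, y1, x1) in pixels
    image: np.ndarray                    # bool mask within bbox

    def contains_px(self, y: float, x: float) -> bool:
        y0, x0, y1, x1 = self.bbox
        iy, ix = int(round(y)), int(round(x))
        if not (y0 <= iy < y1 and x0 <= ix < x1):
            return False
        return bool(self.image[iy - y0, ix - x0])


@dataclass(frozen=True)
class SegmentationConfig:
    dapi_channel: str = "DAPI"
    min_area_um2: float = 15.0
    exclude_border: bool = True
    watershed_min_distance_um: float = 2.0
    threshold: float | None = None       # absolute; None -> Otsu
    fill_holes: bool = True


def segment_nuclei(field: ImageField, cfg: SegmentationConfig = SegmentationConfig()
                   ) -> list[NucleusMask]:
    """Segment nuclei from the DAPI channel.

    Returns masks sorted by (top, left) bounding-box corner so labels are
    deterministic for a given image.  A blank DAPI channel yields an empty
    list with a warning.
    """
    dapi = field.channel(cfg.dapi_channel).astype(float)
    if dapi.max() - dapi.min() < 1e-12:
        warnings.warn("blank DAPI channel: no nuclei segmented", stacklevel=2)
        return []
    thr = cfg.threshold if cfg.threshold is not None else threshold_otsu(dapi)
    binary = dapi > thr
    if cfg.fill_holes:
        binary = ndi.binary_fill_holes(binary)

    min_area_px = cfg.min_area_um2 / field.pixel_size**2
    distance = ndi.distance_transform_edt(binary)
    min_dist_px = max(int(cfg.watershed_min_distance_um / field.pixel_size), 1)
    peaks = peak_local_max(distance, min_distance=min_dist_px,
                           labels=sk_label(binary), exclude_border=False)
    markers = np.zeros_like(dapi, dtype=np.int32)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    labels = watershed(-distance, markers, mask=binary)
    if cfg.exclude_border:
        labels = clear_border(labels)

    props = [p for p in regionprops(labels) if p.area >= min_area_px]
    props.sort(key=lambda p: (p.bbox[0], p.bbox[1]))
    masks = []
    for i, p in enumerate(props, start=1):
        y0, x0, y1, x1 = p.bbox
        masks.append(NucleusMask(
            nucleus_id=i,
            centroid_um=(p.centroid[0] * field.pixel_size,
                         p.centroid[1] * field.pixel_size),
            area_um2=p.area * field.pixel_size**2,
            bbox=(y0, x0, y1, x1),
            image=p.image.copy()))
    return masks


@dataclass
class Focus:
    nucleus_id: int
    centroid_um: tuple[float, float]
    diameter_um: float
    peak_intensity: float


@dataclass(frozen=True)
class FociConfig:
    channel: str = "53BP1"
    min_diameter_um: float = 0.2
    max_diameter_um: float = 3.0
    num_scales: int = 10
    rel_threshold: float = 0.2    # fraction of per-nucleus dynamic range
    log_threshold: float = 0.06   # permissive LoG response floor (normalized image)
    noise_floor_sigma: float = 6.0   # peaks below this many robust SDs are noise
    merge_factor: float = 1.0        # merge radius = factor x larger blob radius


def _halfmax_diameter_px(crop: np.ndarray, cy: float, cx: float, bg: float,
                         peak: float, max_radius_px: float,
                         n_rays: int = 16) -> float:
    """Half-maximum diameter around (cy, cx) from a robust radial profile.

    The radius along each of ``n_rays`` directions is where the intensity
    first crosses bg + (peak - bg)/2 (linear sub-pixel interpolation); the
    diameter is twice the median ray.  The median makes the measure robust
    to a neighbouring focus bridging the half-maximum level along a few
    directions, which would inflate a connected-component area.
    """
    level = bg + 0.5 * (peak - bg)
    h, w = crop.shape
    steps = np.arange(0.0, max_radius_px + 0.5, 0.5)
    radii = []
    for ang in np.linspace(0, 2 * np.pi, n_rays, endpoint=False):
        dy, dx = np.sin(ang), np.cos(ang)
        prev_val, prev_r = peak, 0.0
        r_cross = steps[-1]
        for r in steps[1:]:
            iy, ix = int(round(cy + r * dy)), int(round(cx + r * dx))
            if not (0 <= iy < h and 0 <= ix < w):
                r_cross = prev_r
                break
            val = crop[iy, ix]
            if val < level:
                frac = ((prev_val - level) / (prev_val - val)
                        if prev_val > val else 0.0)
                r_cross = prev_r + frac * (r - prev_r)
                break
            prev_val, prev_r = val, r
        radii.append(r_cross)
    return 2.0 * float(np.median(radii))


def detect_foci(field: ImageField, masks: list[NucleusMask],
                cfg: FociConfig = FociConfig()) -> list[Focus]:
    """Detect discrete foci within each nucleus.

    Per nucleus the channel is normalized by the local dynamic range (median
    to maximum), so detection is invariant to global intensity scaling.
    Multiscale LoG candidates below ``rel_threshold`` of the dynamic range
    (or below a robust noise floor) are discarded; overlapping candidates
    are merged keeping the strongest (merge radius = larger blob radius).
    Diameters are half-maximum diameters in um from a robust radial profile.
    """
    if field.pixel_size is None or field.pixel_size <= 0:
        raise ValueError("pixel_size required for physical focus sizes")
    img = field.channel(cfg.channel).astype(float)
    px = field.pixel_size
    fwhm_to_sigma = 1.0 / 2.3548
    min_sigma = max(cfg.min_diameter_um / px * fwhm_to_sigma, 0.8)
    max_sigma = cfg.max_diameter_um / px * fwhm_to_sigma
    out: list[Focus] = []

    for m in masks:
        y0, x0, y1, x1 = m.bbox
        pad = int(np.ceil(3 * max_sigma))
        wy0, wx0 = max(y0 - pad, 0), max(x0 - pad, 0)
        crop = img[wy0:min(y1 + pad, img.shape[0]),
                   wx0:min(x1 + pad, img.shape[1])].copy()
        inmask = np.zeros(crop.shape, dtype=bool)
        inmask[y0 - wy0:y1 - wy0, x0 - wx0:x1 - wx0] = m.image
        vals = crop[inmask]
        # low percentiles estimate background and noise SD without being
        # inflated by the (bright) foci and their Gaussian skirts, even when
        # foci cover a large share of the nucleus
        bg = float(np.percentile(vals, 25.0))
        rng_dyn = float(vals.max() - bg)
        noise_sd = (bg - float(np.percentile(vals, 5.0))) / 0.97
        min_peak = max(cfg.rel_threshold * rng_dyn,
                       cfg.noise_floor_sigma * noise_sd)
        if rng_dyn <= 0:
            continue
        crop[~inmask] = bg                       # suppress neighbours
        norm = np.clip((crop - bg) / rng_dyn, 0, None)
        # overlap=1 disables skimage's scale-space pruning, which would cede
        # fine-scale candidates to one coarse blob spanning a whole focus
        # cluster; deduplication is done below with fine-scale precedence
        blobs = blob_log(norm, min_sigma=min_sigma, max_sigma=max_sigma,
                         num_sigma=cfg.num_scales, threshold=cfg.log_threshold,
                         overlap=1.0)

        cands = []
        for by, bx, bs in blobs:
            iy, ix = int(round(by)), int(round(bx))
            if not inmask[iy, ix]:
                continue
            peak = float(crop[iy, ix])
            if peak - bg < min_peak:
                continue
            cands.append((peak, by, bx, bs))

        # fine-scale detections (implied FWHM below the large-focus regime)
        # take precedence: a coarse blob spanning a cluster of resolved foci
        # must not swallow its members, so coarse candidates are admitted
        # only where no kept detection already explains the signal
        sigma_split = 1.0 / px / 2.3548
        fine = sorted((c for c in cands if c[3] < sigma_split), reverse=True)
        coarse = sorted((c for c in cands if c[3] >= sigma_split),
                        reverse=True)
        kept: list[tuple[float, float, float, float]] = []
        for peak, by, bx, bs in fine + coarse:
            r = bs * 2.3548 / 2.0                # half the implied FWHM, px
            clash = False
            for kp, ky, kx, ks in kept:
                kr = ks * 2.3548 / 2.0
                if np.hypot(by - ky, bx - kx) <= cfg.merge_factor * max(r, kr):
                    clash = True
                    break
            if not clash:
                kept.append((peak, by, bx, bs))

        max_ray_px = cfg.max_diameter_um / px
        for peak, by, bx, bs in kept:
            diam = _halfmax_diameter_px(crop, by, bx, bg, peak,
                                        max_radius_px=max_ray_px) * px
            if diam < cfg.min_diameter_um:
                continue                         # noise spike, not a focus
            out.append(Focus(nucleus_id=m.nucleus_id,
                             centroid_um=((by + wy0) * px, (bx + wx0) * px),
                             diameter_um=float(diam), peak_intensity=peak))
    return out


@dataclass(frozen=True)
class DiffuseConfig:
    channel: str = "53BP1"
    rel_threshold: float = 0.5    # half-maximum: focus-level intensity
    baseline_percentile: float = 5.0


def diffuse_metrics(field: ImageField, mask: NucleusMask,
                    cfg: DiffuseConfig = DiffuseConfig()
                    ) -> tuple[float, float]:
    """(coverage, heterogeneity) of the 53BP1 signal within one nucleus.

    Coverage is the fraction of nuclear pixels at or above the focus-level
    threshold, defined as baseline + ``rel_threshold`` x (max - baseline)
    with the baseline at a low percentile of nuclear intensity; for a
    flat-signal nucleus coverage is 1 when the signal is positive, else 0.
    Heterogeneity is the coefficient of variation (sd / mean).
    """
    img = field.channel(cfg.channel).astype(float)
    y0, x0, y1, x1 = mask.bbox
    vals = img[y0:y1, x0:x1][mask.image]
    if vals.size == 0:
        raise ValueError("empty nucleus mask")
    mean = float(vals.mean())
    lo = float(np.percentile(vals, cfg.baseline_percentile))
    hi = float(np.percentile(vals, 99.5))    # robust to isolated noise maxima
    dyn = hi - lo
    if dyn < 1e-9:
        coverage = 1.0 if mean > 1e-9 else 0.0
    else:
        thr = lo + cfg.rel_threshold * dyn
        coverage = float(np.mean(vals >= thr))
    heterogeneity = float(vals.std() / mean) if mean > 1e-12 else 0.0
    return coverage, heterogeneity
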