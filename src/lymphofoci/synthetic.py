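"""Synthetic cohorts and rendered fluorescence fields with per-nucleus ground truth.

The generator emulates the statistical structure of biopsy immunofluorescence
of lymphoid lesions: each lesion class has a characteristic distribution of
the per-case *abnormal fraction* (the percentage of nuclei whose 53BP1
staining is high-DDR, large-focus or diffuse), summarized in the source
cohort by a median and interquartile range.  Case-level fractions are drawn
from a scaled Beta distribution (support inside [0, 100]) whose quartiles
are fitted exactly to those summaries; nuclei
are then allocated to the five pattern classes multinomially and rendered as
2-D multichannel images (DAPI + 53BP1 for IF; DAPI + green/orange for FISH).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter

NORMAL_CLASSES = ("stable", "lowDDR")
ABNORMAL_CLASSES = ("highDDR", "largeFocus", "diffuse")
PATTERN_CLASSES = NORMAL_CLASSES + ABNORMAL_CLASSES

BENIGN_LABELS = frozenset({"GC", "PF", "MM", "LA"})


class GeneratorError(RuntimeError):
    """Raised when a field cannot be realized (e.g. overcrowded placement)."""


@dataclass(frozen=True)
class LesionClassParams:
    """Abnormal-fraction distribution and class mixes for one lesion type.

    ``abnormal_median`` and the IQR bounds are percentages of nuclei per case
    showing an abnormal 53BP1 pattern.  ``abnormal_mix`` splits the abnormal
    mass over (highDDR, largeFocus, diffuse); ``normal_mix`` splits the rest
    over (stable, lowDDR).
    """

    lesion_label: str
    abnormal_median: float
    abnormal_iqr_lo: float
    abnormal_iqr_hi: float
    abnormal_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)
    normal_mix: tuple[float, float] = (0.7, 0.3)

    def __post_init__(self) -> None:
        if not (0 <= self.abnormal_iqr_lo <= self.abnormal_median
                <= self.abnormal_iqr_hi <= 100):
            raise ValueError(
                f"{self.lesion_label}: need 0 <= iqr_lo <= median <= iqr_hi <= 100, "
                f"got ({self.abnormal_iqr_lo}, {self.abnormal_median}, "
                f"{self.abnormal_iqr_hi})")
        for name, mix in (("abnormal_mix", self.abnormal_mix),
                          ("normal_mix", self.normal_mix)):
            if abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
                raise ValueError(f"{self.lesion_label}: {name} must be a "
                                 f"probability vector, got {mix}")

    @property
    def is_malignant(self) -> bool:
        return self.lesion_label not in BENIGN_LABELS


def _p(label: str, med: float, lo: float, hi: float) -> LesionClassParams:
    return LesionClassParams(label, med, lo, hi)


#: Per-lesion abnormal-fraction summaries (median, IQR) of the reference cohort.
TABLE1_PARAMS: dict[str, LesionClassParams] = {p.lesion_label: p for p in [
    _p("GC", 15.6, 9.3, 19.9),
    _p("PF", 20.8, 18.9, 23.6),
    _p("MM", 23.9, 19.0, 26.3),
    _p("LA", 23.3, 18.8, 27.7),
    _p("MALT", 19.3, 14.7, 34.1),
    _p("MCL", 44.5, 32.0, 52.9),
    _p("FL1", 52.1, 40.6, 56.0),
    _p("FL2", 41.9, 35.2, 51.5),
    _p("FL3A", 29.8, 26.4, 33.0),
    _p("DLBCL", 27.6, 20.3, 34.8),
    _p("TS", 29.9, 25.5, 37.2),
    _p("TL", 30.0, 20.6, 38.8),
]}


@functools.lru_cache(maxsize=256)
def fit_beta_to_quantiles(median: float, iqr_lo: float, iqr_hi: float
                          ) -> tuple[float, float, float, float] | None:
    """Fit a scaled Beta whose (25th, 50th, 75th) percentiles equal
    ``(iqr_lo, median, iqr_hi)``, all in percent.

    Returns ``(a, b, support_lo, support_hi)`` with the support inside
    [0, 100], or ``None`` for a zero-width (degenerate) summary.  Two shape
    parameters alone cannot reproduce an asymmetric (median, IQR) triple, so
    one support endpoint is freed on the long-tail side — the lower end for
    a right-skewed summary, the upper end for a left-skewed one — giving
    three unknowns for the three quantile equations, solved numerically to
    machine precision.
    """
    if not (0 <= iqr_lo <= median <= iqr_hi <= 100):
        raise ValueError("quantiles must satisfy 0 <= lo <= median <= hi <= 100")
    if iqr_hi - iqr_lo < 1e-12:
        return None
    targets = np.array([iqr_lo, median, iqr_hi])
    left_skew = (iqr_hi - median) <= (median - iqr_lo)

    def unpack(x: np.ndarray) -> tuple[float, float, float, float]:
        a, b = np.exp(x[0]), np.exp(x[1])
        if left_skew:
            return a, b, 0.0, iqr_hi + x[2] * (100.0 - iqr_hi)
        return a, b, x[2] * iqr_lo, 100.0

    def resid(x: np.ndarray) -> np.ndarray:
        a, b, lo_s, hi_s = unpack(x)
        q = lo_s + (hi_s - lo_s) * stats.beta.ppf([0.25, 0.5, 0.75], a, b)
        return q - targets

    bounds = (([-4, -4, 1e-3], [7, 7, 1.0]) if left_skew
              else ([-4, -4, 0.0], [7, 7, 1 - 1e-3]))
    best = None
    for guess in (0.9, 0.5, 0.2, 0.05):
        sol = optimize.least_squares(
            resid, np.array([math.log(2), math.log(2), guess]),
            bounds=bounds, xtol=1e-15, ftol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16:
            break
    if math.sqrt(2 * best.cost) > 0.5:      # no admissible scaled Beta
        raise ValueError(
            f"cannot fit a scaled Beta to median {median}, "
            f"IQR ({iqr_lo}, {iqr_hi}); residual {math.sqrt(2 * best.cost):.3g}")
    a, b, lo_s, hi_s = unpack(best.x)
    return float(a), float(b), float(lo_s), float(hi_s)


@dataclass(frozen=True)
class CohortSpec:
    """Cases to simulate: ``cases`` is a list of (case_id, lesion_label, n_nuclei)."""

    cases: list[tuple[str, str, int]]
    params: dict[str, LesionClassParams] = field(
        default_factory=lambda: dict(TABLE1_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        for case_id, label, n in self.cases:
            if n < 1:
                raise ValueError(f"case {case_id}: n_nuclei must be >= 1")
            if label not in self.params:
                raise ValueError(f"case {case_id}: no params for lesion "
                                 f"label {label!r}")


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one true abnormal fraction per case.

    Returns a DataFrame with columns ``case_id, lesion_label, n_nuclei,
    true_abnormal_fraction, is_malignant``; reproducible for a fixed
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for case_id, label, n in spec.cases:
        p = spec.params[label]
        ab = fit_beta_to_quantiles(p.abnormal_median, p.abnormal_iqr_lo,
                                   p.abnormal_iqr_hi)
        if ab is None:
            frac = p.abnormal_median
        else:
            a, b, lo_s, hi_s = ab
            frac = lo_s + (hi_s - lo_s) * stats.beta.rvs(a, b, random_state=rng)
        rows.append({"case_id": case_id, "lesion_label": label, "n_nuclei": n,
                     "true_abnormal_fraction": float(frac),
                     "is_malignant": p.is_malignant})
    return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Per-nucleus truth for one case (IF) or one slide (FISH).

    ``nuclei`` rows: nucleus_id, true_class (IF) or true_genotype (FISH),
    plus geometry columns (center/radius in pixels) once rendered.
    ``foci`` rows (IF): nucleus_id, diameter_um and, after rendering,
    centroids.  ``signals`` rows (FISH): nucleus_id, color, positions.
    """

    case_id: str
    nuclei: pd.DataFrame
    foci: pd.DataFrame
    signals: pd.DataFrame | None = None

    def class_fractions(self) -> dict[str, float]:
        counts = self.nuclei["true_class"].value_counts()
        n = len(self.nuclei)
        return {c: 100.0 * counts.get(c, 0) / n for c in PATTERN_CLASSES}

    @property
    def true_abnormal_fraction(self) -> float:
        fr = self.class_fractions()
        return sum(fr[c] for c in ABNORMAL_CLASSES)


def compose_nucleus_truths(case_id: str, params: LesionClassParams,
                           true_abnormal_fraction: float, n_nuclei: int,
                           seed: int) -> GroundTruth:
    """Allocate nuclei to the five pattern classes and draw focus inventories.

    Abnormal nuclei occur with probability ``true_abnormal_fraction / 100``;
    class identity within the normal/abnormal arms follows the mixes in
    ``params``.  Focus counts and diameters are consistent with the class
    definitions: lowDDR 1-2 sub-micron foci, highDDR >= 3, largeFocus at
    least one focus >= 1 um, diffuse no discrete foci (pan-nuclear texture
    is added at render time).
    """
    if not 0 <= true_abnormal_fraction <= 100:
        raise ValueError("true_abnormal_fraction must be in [0, 100]")
    rng = np.random.default_rng(seed)
    p_ab = true_abnormal_fraction / 100.0
    probs = np.array([p * (1 - p_ab) for p in params.normal_mix]
                     + [p * p_ab for p in params.abnormal_mix])
    classes = rng.choice(len(PATTERN_CLASSES), size=n_nuclei, p=probs)

    nuc_rows, foci_rows = [], []
    for i, ci in enumerate(classes):
        cls = PATTERN_CLASSES[ci]
        diams: list[float] = []
        if cls == "lowDDR":
            diams = list(rng.uniform(0.35, 0.8, rng.integers(1, 3)))
        elif cls == "highDDR":
            diams = list(rng.uniform(0.35, 0.8, rng.integers(3, 8)))
        elif cls == "largeFocus":
            diams = [float(rng.uniform(1.15, 1.8))]
            diams += list(rng.uniform(0.35, 0.8, rng.integers(0, 3)))
        nuc_rows.append({"nucleus_id": i + 1, "true_class": cls,
                         "true_focus_count": len(diams),
                         "region_label": "unassigned"})
        for d in diams:
            foci_rows.append({"nucleus_id": i + 1, "diameter_um": float(d)})
    nuclei = pd.DataFrame(nuc_rows)
    foci = pd.DataFrame(foci_rows, columns=["nucleus_id", "diameter_um"])
    return GroundTruth(case_id=case_id, nuclei=nuclei, foci=foci)


@dataclass(frozen=True)
class RenderParams:
    """Geometry, intensity and noise settings for rendered fields.

    Default pixel size is 0.1 um/pixel (high-magnification oil objective);
    nuclei are lymphocyte-sized (2.5-3.5 um radius).  ``focus_amplitude`` over
    ``noise_sd`` sets the default signal-to-noise ratio of a focus.
    """

    pixel_size: float = 0.1                      # um / pixel
    image_shape: tuple[int, int] = (1024, 1024)
    nucleus_radius_range: tuple[float, float] = (2.5, 3.5)   # um
    focus_diameter_small: float = 0.5            # um, < 1
    focus_diameter_large: float = 1.4            # um, >= 1
    focus_amplitude: float = 150.0
    background_level: float = 20.0
    dapi_level: float = 120.0
    noise_sd: float = 5.0
    diffuse_coverage: float = 0.5                # min fraction of nuclear area
    min_gap_px: int = 2
    max_place_tries: int = 2000

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not (self.focus_diameter_large >= 1.0 > self.focus_diameter_small > 0):
            raise ValueError("need focus_diameter_large >= 1 um > "
                             "focus_diameter_small > 0")


def _place_nuclei(n: int, rp: RenderParams, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping nucleus centers; returns (centers, radii) in px."""
    h, w = rp.image_shape
    r_lo, r_hi = (r / rp.pixel_size for r in rp.nucleus_radius_range)
    centers = np.empty((n, 2))
    radii = rng.uniform(r_lo, r_hi, n)
    for i in range(n):
        r = radii[i]
        for _ in range(rp.max_place_tries):
            c = rng.uniform([r + 1, r + 1], [h - r - 1, w - r - 1])
            if i == 0:
                centers[i] = c
                break
            d = np.hypot(*(centers[:i] - c).T)
            if np.all(d > r + radii[:i] + rp.min_gap_px):
                centers[i] = c
                break
        else:
            raise GeneratorError(
                f"could not place nucleus {i + 1}/{n} after "
                f"{rp.max_place_tries} tries (field too crowded)")
    return centers, radii


def _disk_coords(center: np.ndarray, ry: float, rx: float,
                 shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    cy, cx = center
    y0, y1 = int(cy - ry) - 1, int(cy + ry) + 2
    x0, x1 = int(cx - rx) - 1, int(cx + rx) + 2
    yy, xx = np.mgrid[max(y0, 0):min(y1, shape[0]), max(x0, 0):min(x1, shape[1])]
    inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return yy[inside], xx[inside]


def _add_gaussian_spot(img: np.ndarray, cy: float, cx: float,
                       fwhm_px: float, amplitude: float) -> None:
    sigma = fwhm_px / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    half = int(math.ceil(4 * sigma)) + 1
    y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, img.shape[0])
    x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, img.shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


def _scatter_points(n: int, max_r: float, min_sep: np.ndarray | float,
                    rng: np.random.Generator) -> np.ndarray:
    """Points in a unit-disk-scaled region of radius ``max_r`` with pairwise
    separation >= per-point ``min_sep`` (averaged over each pair).  Separation
    is relaxed geometrically if the packing is infeasible."""
    sep = np.broadcast_to(np.asarray(min_sep, dtype=float), (n,)).copy()
    pts = np.empty((n, 2))
    for _ in range(8):
        ok = True
        for i in range(n):
            for _try in range(300):
                ang = rng.uniform(0, 2 * np.pi)
                rad = max_r * math.sqrt(rng.uniform())
                p = np.array([rad * math.cos(ang), rad * math.sin(ang)])
                if i == 0:
                    pts[i] = p
                    break
                d = np.hypot(*(pts[:i] - p).T)
                if np.all(d >= (sep[:i] + sep[i]) / 2):
                    pts[i] = p
                    break
            else:
                ok = False
                break
        if ok:
            return pts
        sep *= 0.8
    raise GeneratorError(f"could not scatter {n} points in radius {max_r}")


def _add_noise(img: np.ndarray, noise_sd: float,
               rng: np.random.Generator) -> np.ndarray:
    out = rng.poisson(np.clip(img, 0, None)).astype(float)
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, img.shape)
    return np.clip(out, 0, None)


_REGION_INTENSITY = {  # (FDC level, BCL2 level) painted over the nucleus footprint
    "GC": (1.0, 0.0), "PF": (1.0, 1.0), "MM": (0.0, 1.0),
    "LA": (0.0, 0.0), "unassigned": (0.0, 0.0),
}


def render_if_image(truth: GroundTruth, rp: RenderParams, seed: int,
                    with_region_channels: bool = False
                    ) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render one immunofluorescence field for ``truth``.

    DAPI holds filled elliptical nuclei; the 53BP1 channel holds per-class
    content: Gaussian spots at the true focus diameters (FWHM = diameter),
    or a heterogeneous supra-threshold texture for diffuse nuclei.  Poisson
    shot noise plus Gaussian read noise is applied to every channel.  The
    returned truth carries realized geometry (pixel centers/radii, focus
    centroids).
    """
    rng = np.random.default_rng(seed)
    n = len(truth.nuclei)
    centers, radii = _place_nuclei(n, rp, rng)
    aspect = rng.uniform(0.85, 1.0, n)           # mild ellipticity

    dapi = np.zeros(rp.image_shape)
    sig = np.full(rp.image_shape, rp.background_level, dtype=float)
    fdc = np.zeros(rp.image_shape)
    bcl2 = np.zeros(rp.image_shape)

    nuclei = truth.nuclei.copy()
    nuclei["center_y_px"] = centers[:, 0]
    nuclei["center_x_px"] = centers[:, 1]
    nuclei["radius_px"] = radii
    foci_out = []

    for i in range(n):
        row = nuclei.iloc[i]
        cy, cx = centers[i]
        ry, rx = radii[i], radii[i] * aspect[i]
        yy, xx = _disk_coords(centers[i], ry, rx, rp.image_shape)
        dapi[yy, xx] = rp.dapi_level * rng.uniform(0.9, 1.1)
        if with_region_channels:
            f_lvl, b_lvl = _REGION_INTENSITY[row["region_label"]]
            fdc[yy, xx] = 100.0 * f_lvl + 8.0
            bcl2[yy, xx] = 100.0 * b_lvl + 8.0

        cls = row["true_class"]
        if cls == "diffuse":
            y0, x0 = yy.min(), xx.min()
            tex = gaussian_filter(
                rng.normal(size=(yy.max() - y0 + 1, xx.max() - x0 + 1)), 3.0)
            t = tex[yy - y0, xx - x0]
            cov = rng.uniform(max(rp.diffuse_coverage, 0.55), 0.85)
            thr = np.quantile(t, 1 - cov)
            hot = t >= thr
            rank = (t[hot] - thr) / max(t.max() - thr, 1e-9)
            sig[yy[hot], xx[hot]] += rp.focus_amplitude * (0.7 + 0.45 * rank)
            continue
        diams = truth.foci.loc[truth.foci["nucleus_id"] == row["nucleus_id"],
                               "diameter_um"].to_numpy()
        if len(diams) == 0:
            continue
        sep_px = (diams / 2 + 0.65) / rp.pixel_size   # keep foci resolvable
        pts = _scatter_points(len(diams), 0.78 * min(ry, rx), sep_px, rng)
        for (dy, dx), d_um in zip(pts, diams):
            fy, fx = cy + dy, cx + dx
            _add_gaussian_spot(sig, fy, fx, d_um / rp.pixel_size,
                               rp.focus_amplitude * rng.uniform(0.9, 1.1))
            foci_out.append({"nucleus_id": row["nucleus_id"],
                             "diameter_um": float(d_um),
                             "y_px": fy, "x_px": fx})

    channels = {"DAPI": _add_noise(dapi, rp.noise_sd, rng),
                "53BP1": _add_noise(sig, rp.noise_sd, rng)}
    if with_region_channels:
        channels["FDC"] = _add_noise(fdc, rp.noise_sd, rng)
        channels["BCL2"] = _add_noise(bcl2, rp.noise_sd, rng)
    out = GroundTruth(case_id=truth.case_id, nuclei=nuclei,
                      foci=pd.DataFrame(
                          foci_out, columns=["nucleus_id", "diameter_um",
                                             "y_px", "x_px"]))
    return channels, out


FISH_GENOTYPES = ("wild", "fusion", "trisomy18q21")


def make_fish_truth(case_id: str, n_nuclei: int,
                    genotype_fractions: dict[str, float],
                    seed: int) -> GroundTruth:
    """Assign genotypes to nuclei: ``genotype_fractions`` maps genotype ->
    proportion (must sum to 1 over wild/fusion/trisomy18q21)."""
    probs = np.array([genotype_fractions.get(g, 0.0) for g in FISH_GENOTYPES])
    if abs(probs.sum() - 1.0) > 1e-9 or probs.min() < 0:
        raise ValueError("genotype_fractions must be a probability vector "
                         f"over {FISH_GENOTYPES}")
    rng = np.random.default_rng(seed)
    g = rng.choice(len(FISH_GENOTYPES), size=n_nuclei, p=probs)
    nuclei = pd.DataFrame({"nucleus_id": np.arange(1, n_nuclei + 1),
                           "true_genotype": [FISH_GENOTYPES[i] for i in g]})
    return GroundTruth(case_id=case_id, nuclei=nuclei,
                       foci=pd.DataFrame(columns=["nucleus_id", "diameter_um"]))


def render_fish_image(truth: GroundTruth, rp: RenderParams, seed: int,
                      signal_diameter: float = 0.5,
                      fusion_max_sep: float = 0.25,
                      singleton_min_sep: float = 1.3
                      ) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render a dual-color FISH field (DAPI + green + orange).

    Wild nuclei carry 2 green + 2 orange well-separated probe signals; fusion
    nuclei carry one green-orange pair within ``fusion_max_sep`` um (appearing
    yellow in overlay) plus one singleton of each color; trisomy nuclei carry
    three orange and two green separated signals.  Distances are in um.
    """
    rng = np.random.default_rng(seed)
    n = len(truth.nuclei)
    centers, radii = _place_nuclei(n, rp, rng)
    dapi = np.zeros(rp.image_shape)
    green = np.full(rp.image_shape, rp.background_level, dtype=float)
    orange = np.full(rp.image_shape, rp.background_level, dtype=float)

    nuclei = truth.nuclei.copy()
    nuclei["center_y_px"] = centers[:, 0]
    nuclei["center_x_px"] = centers[:, 1]
    nuclei["radius_px"] = radii
    sig_rows = []
    sep_px = singleton_min_sep / rp.pixel_size
    fwhm_px = signal_diameter / rp.pixel_size

    for i in range(n):
        row = nuclei.iloc[i]
        cy, cx = centers[i]
        r = radii[i]
        yy, xx = _disk_coords(centers[i], r, r, rp.image_shape)
        dapi[yy, xx] = rp.dapi_level * rng.uniform(0.9, 1.1)
        geno = row["true_genotype"]
        if geno == "wild":
            colors = ["green", "green", "orange", "orange"]
        elif geno == "trisomy18q21":
            colors = ["green", "green", "orange", "orange", "orange"]
        else:  # fusion: pair placed below; singletons here
            colors = ["green", "orange"]
        pts = _scatter_points(len(colors) + (1 if geno == "fusion" else 0),
                              0.7 * r, sep_px, rng)
        if geno == "fusion":
            pair_center, pts = pts[0], pts[1:]
            off = rng.uniform(0, fusion_max_sep / rp.pixel_size / 2)
            ang = rng.uniform(0, 2 * np.pi)
            dv = off * np.array([math.cos(ang), math.sin(ang)])
            for color, p in (("green", pair_center + dv),
                             ("orange", pair_center - dv)):
                sig_rows.append({"nucleus_id": row["nucleus_id"], "color": color,
                                 "y_px": cy + p[0], "x_px": cx + p[1],
                                 "diameter_um": signal_diameter,
                                 "is_fusion_member": True})
        for color, p in zip(colors, pts):
            sig_rows.append({"nucleus_id": row["nucleus_id"], "color": color,
                             "y_px": cy + p[0], "x_px": cx + p[1],
                             "diameter_um": signal_diameter,
                             "is_fusion_member": False})

    for s in sig_rows:
        img = green if s["color"] == "green" else orange
        _add_gaussian_spot(img, s["y_px"], s["x_px"], fwhm_px,
                           rp.focus_amplitude * rng.uniform(0.9, 1.1))

    channels = {"DAPI": _add_noise(dapi, rp.noise_sd, rng),
                "green": _add_noise(green, rp.noise_sd, rng),
                "orange": _add_noise(orange, rp.noise_sd, rng)}
    out = GroundTruth(case_id=truth.case_id, nuclei=nuclei,
                      foci=truth.foci,
                      signals=pd.DataFrame(sig_rows))
    return channels, out
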