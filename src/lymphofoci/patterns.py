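"""Five-class 53BP1 pattern assignment and per-case abnormal fractions.

Each nucleus receives exactly one expression type:

* ``stable``     — no discrete foci, sub-threshold diffuse staining
* ``lowDDR``     — one or two discrete foci, all < 1 um
* ``highDDR``    — three or more discrete foci, all < 1 um
* ``largeFocus`` — at least one focus >= 1 um
* ``diffuse``    — intense, heterogeneous pan-nuclear staining

The abnormal fraction of a case — the central diagnostic statistic — is the
percentage of nuclei in the highDDR, largeFocus or diffuse classes.  Where a
nucleus satisfies several definitions the precedence is
diffuse > largeFocus > focus-count classes, so the rarer high-grade
phenotypes dominate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import DiffuseConfig, Focus, ImageField, NucleusMask, diffuse_metrics
from .synthetic import ABNORMAL_CLASSES, PATTERN_CLASSES

REGION_LABELS = ("GC", "PF", "MM", "LA", "unassigned")


@dataclass(frozen=True)
class ClassifierParams:
    large_focus_min_diameter: float = 1.0   # um
    low_ddr_max_count: int = 2
    high_ddr_min_count: int = 3
    diffuse_min_coverage: float = 0.4
    diffuse_min_heterogeneity: float = 0.3

    def __post_init__(self) -> None:
        if self.high_ddr_min_count != self.low_ddr_max_count + 1:
            raise ValueError("high_ddr_min_count must equal low_ddr_max_count + 1")
        if self.large_focus_min_diameter <= 0:
            raise ValueError("large_focus_min_diameter must be > 0")


def classify_nucleus(focus_diameters_um, coverage: float, heterogeneity: float,
                     params: ClassifierParams = ClassifierParams()) -> str:
    """Assign one pattern class from a nucleus's foci and diffuse metrics."""
    diams = np.asarray(list(focus_diameters_um), dtype=float)
    if diams.size and diams.min() <= 0:
        raise ValueError("focus diameters must be positive (um)")
    if (coverage >= params.diffuse_min_coverage
            and heterogeneity >= params.diffuse_min_heterogeneity):
        return "diffuse"
    if diams.size and diams.max() >= params.large_focus_min_diameter:
        return "largeFocus"
    n = diams.size
    if n >= params.high_ddr_min_count:
        return "highDDR"
    if n >= 1:
        return "lowDDR"
    return "stable"


@dataclass(frozen=True)
class RegionConfig:
    fdc_channel: str = "FDC"
    bcl2_channel: str = "BCL2"
    fdc_threshold: float | None = None    # absolute mean intensity; None -> midpoint
    bcl2_threshold: float | None = None
    mm_ring_um: float = 30.0              # MM = BCL2+ within this distance of a GC


def _auto_threshold(means: np.ndarray) -> float:
    return float((means.min() + means.max()) / 2.0)


def assign_regions(field: ImageField, masks: list[NucleusMask],
                   cfg: RegionConfig = RegionConfig()) -> dict[int, str]:
    """Gate nuclei to anatomical regions from FDC/BCL2 staining.

    GC = FDC+/BCL2-, PF = FDC+/BCL2+, MM = FDC-/BCL2+ within ``mm_ring_um``
    of a GC nucleus, LA = FDC- otherwise.  Missing gating channels leave all
    nuclei unassigned with a warning.
    """
    if (cfg.fdc_channel not in field.channels
            or cfg.bcl2_channel not in field.channels):
        warnings.warn("FDC/BCL2 channels missing: regions unassigned",
                      stacklevel=2)
        return {m.nucleus_id: "unassigned" for m in masks}
    if not masks:
        return {}
    fdc_img = field.channel(cfg.fdc_channel).astype(float)
    bcl2_img = field.channel(cfg.bcl2_channel).astype(float)

    def nucleus_mean(img: np.ndarray, m: NucleusMask) -> float:
        y0, x0, y1, x1 = m.bbox
        return float(img[y0:y1, x0:x1][m.image].mean())

    fdc = np.array([nucleus_mean(fdc_img, m) for m in masks])
    bcl2 = np.array([nucleus_mean(bcl2_img, m) for m in masks])
    fdc_thr = cfg.fdc_threshold if cfg.fdc_threshold is not None else _auto_threshold(fdc)
    bcl2_thr = cfg.bcl2_threshold if cfg.bcl2_threshold is not None else _auto_threshold(bcl2)
    fdc_pos, bcl2_pos = fdc >= fdc_thr, bcl2 >= bcl2_thr

    out: dict[int, str] = {}
    gc_idx = [i for i in range(len(masks)) if fdc_pos[i] and not bcl2_pos[i]]
    gc_centers = np.array([masks[i].centroid_um for i in gc_idx]).reshape(-1, 2)
    gc_radii = np.array([np.sqrt(masks[i].area_um2 / np.pi) for i in gc_idx])
    for i, m in enumerate(masks):
        if fdc_pos[i]:
            out[m.nucleus_id] = "GC" if not bcl2_pos[i] else "PF"
        elif bcl2_pos[i] and len(gc_idx):
            d = np.hypot(*(gc_centers - np.asarray(m.centroid_um)).T) - gc_radii
            out[m.nucleus_id] = "MM" if d.min() <= cfg.mm_ring_um else "LA"
        else:
            out[m.nucleus_id] = "LA"
    return out


@dataclass
class CaseSummary:
    case_id: str
    lesion_label: str
    n_nuclei: int
    fractions: dict[str, float]     # percent per pattern class
    abnormal_fraction: float        # percent

    def as_row(self) -> dict:
        row = {"case_id": self.case_id, "lesion_label": self.lesion_label,
               "n_nuclei": self.n_nuclei}
        row.update({f"pct_{c}": self.fractions[c] for c in PATTERN_CLASSES})
        row["abnormal_fraction"] = self.abnormal_fraction
        return row


def make_nucleus_records(field: ImageField, masks: list[NucleusMask],
                         foci: list[Focus], case_id: str,
                         params: ClassifierParams = ClassifierParams(),
                         diffuse_cfg: DiffuseConfig = DiffuseConfig(),
                         regions: dict[int, str] | None = None) -> pd.DataFrame:
    """Classify every segmented nucleus of a field into a records table."""
    by_nucleus: dict[int, list[Focus]] = {}
    for f in foci:
        by_nucleus.setdefault(f.nucleus_id, []).append(f)
    rows = []
    for m in masks:
        flist = by_nucleus.get(m.nucleus_id, [])
        diams = [f.diameter_um for f in flist]
        cov, het = diffuse_metrics(field, m, diffuse_cfg)
        cls = classify_nucleus(diams, cov, het, params)
        n_large = sum(d >= params.large_focus_min_diameter for d in diams)
        rows.append({"case_id": case_id, "field_id": field.field_id,
                     "nucleus_id": m.nucleus_id,
                     "centroid_y_um": m.centroid_um[0],
                     "centroid_x_um": m.centroid_um[1],
                     "area_um2": m.area_um2,
                     "region_label": (regions or {}).get(m.nucleus_id,
                                                         "unassigned"),
                     "n_small_foci": len(diams) - n_large,
                     "n_large_foci": n_large,
                     "diffuse_coverage": cov,
                     "diffuse_heterogeneity": het,
                     "pattern_class": cls})
    return pd.DataFrame(rows)


def summarize_case(records: pd.DataFrame, case_id: str | None = None,
                   lesion_label: str = "") -> CaseSummary:
    """Per-case class percentages and the abnormal fraction."""
    if len(records) == 0:
        raise ValueError("cannot summarize a case with zero nuclei")
    if case_id is None:
        case_id = str(records["case_id"].iloc[0]) if "case_id" in records else ""
    counts = records["pattern_class"].value_counts()
    n = len(records)
    fractions = {c: 100.0 * counts.get(c, 0) / n for c in PATTERN_CLASSES}
    abnormal = sum(fractions[c] for c in ABNORMAL_CLASSES)
    return CaseSummary(case_id=case_id, lesion_label=lesion_label, n_nuclei=n,
                       fractions=fractions, abnormal_fraction=abnormal)
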