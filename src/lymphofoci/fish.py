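"""Dual-color interphase FISH scoring: fusion and trisomy genotyping.

Probes flank the two translocation partners (green on 11q22 / BIRC3, orange
on 18q21 / MALT1).  A nucleus harbouring t(11;18)(q21;q21) shows one or two
colocalized green-orange (yellow) fusion signals; trisomy of 18q21 shows
three orange and two green separated signals; wild type shows two of each,
separated.  A slide is informative only if at least ``min_nuclei`` nuclei
carry at least one hybridization signal, and the case call uses fractions
over informative nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import FociConfig, ImageField, NucleusMask, detect_foci

GENOTYPES = ("wild", "fusion", "trisomy18q21", "other", "uninformative")


@dataclass(frozen=True)
class FishConfig:
    green_channel: str = "green"
    orange_channel: str = "orange"
    max_pair_distance_um: float = 0.6   # colocalization radius for a fusion
    min_nuclei: int = 150               # informative nuclei needed per slide
    case_fraction_threshold: float = 10.0   # percent, case-level positivity
    signal_detection: FociConfig = field(default_factory=lambda: FociConfig(
        channel="", min_diameter_um=0.2, max_diameter_um=1.5))


def detect_signals(field_: ImageField, masks: list[NucleusMask],
                   cfg: FishConfig = FishConfig()) -> pd.DataFrame:
    """LoG spot detection per color channel within each nucleus.

    Returns a DataFrame (nucleus_id, color, y_um, x_um, diameter_um).
    """
    rows = []
    for color, channel in (("green", cfg.green_channel),
                           ("orange", cfg.orange_channel)):
        if channel not in field_.channels:
            raise KeyError(f"FISH channel {channel!r} missing")
        det = FociConfig(channel=channel,
                         min_diameter_um=cfg.signal_detection.min_diameter_um,
                         max_diameter_um=cfg.signal_detection.max_diameter_um,
                         num_scales=cfg.signal_detection.num_scales,
                         rel_threshold=cfg.signal_detection.rel_threshold,
                         log_threshold=cfg.signal_detection.log_threshold)
        for f in detect_foci(field_, masks, det):
            rows.append({"nucleus_id": f.nucleus_id, "color": color,
                         "y_um": f.centroid_um[0], "x_um": f.centroid_um[1],
                         "diameter_um": f.diameter_um})
    return pd.DataFrame(rows, columns=["nucleus_id", "color", "y_um", "x_um",
                                       "diameter_um"])


def pair_fusions(greens: np.ndarray, oranges: np.ndarray,
                 max_pair_distance_um: float) -> tuple[int, int, int]:
    """Greedy minimum-distance green-orange pairing within one nucleus.

    ``greens``/``oranges`` are (n, 2) centroid arrays in um.  Pairs are taken
    in increasing distance order, each signal used at most once, only if the
    distance is <= ``max_pair_distance_um``.  Returns
    (n_fusion, n_green_singleton, n_orange_singleton).
    """
    greens = np.asarray(greens, dtype=float).reshape(-1, 2)
    oranges = np.asarray(oranges, dtype=float).reshape(-1, 2)
    if len(greens) == 0 or len(oranges) == 0:
        return 0, len(greens), len(oranges)
    d = np.linalg.norm(greens[:, None, :] - oranges[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_g, used_o = set(), set()
    n_fusion = 0
    for gi, oi in order:
        if d[gi, oi] > max_pair_distance_um:
            break
        if gi in used_g or oi in used_o:
            continue
        used_g.add(int(gi))
        used_o.add(int(oi))
        n_fusion += 1
    return n_fusion, len(greens) - n_fusion, len(oranges) - n_fusion


@dataclass
class FishNucleusCall:
    nucleus_id: int
    n_green: int       # total green signals (fusion members included)
    n_orange: int
    n_fusion: int
    genotype: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")


def call_nucleus_genotype(n_green: int, n_orange: int, n_fusion: int) -> str:
    """Genotype one nucleus from its signal counts.

    ``uninformative`` when no signal hybridized; ``fusion`` with one or two
    colocalized pairs; ``trisomy18q21`` with the 3-orange/2-green pattern;
    ``wild`` with at most two separated signals of each color (one allowed,
    for nuclear truncation); anything else ``other``.
    """
    if min(n_green, n_orange, n_fusion) < 0:
        raise ValueError("signal counts must be non-negative")
    if n_green + n_orange == 0:
        return "uninformative"
    if n_fusion in (1, 2):
        return "fusion"
    if n_fusion == 0 and n_orange == 3 and n_green == 2:
        return "trisomy18q21"
    if n_fusion == 0 and n_green <= 2 and n_orange <= 2:
        return "wild"
    return "other"


def call_nuclei(signals: pd.DataFrame, masks: list[NucleusMask],
                cfg: FishConfig = FishConfig()) -> list[FishNucleusCall]:
    """Pair fusions and genotype every segmented nucleus of a slide."""
    calls = []
    for m in masks:
        sub = signals[signals["nucleus_id"] == m.nucleus_id]
        g = sub.loc[sub["color"] == "green", ["y_um", "x_um"]].to_numpy()
        o = sub.loc[sub["color"] == "orange", ["y_um", "x_um"]].to_numpy()
        n_fusion, _, _ = pair_fusions(g, o, cfg.max_pair_distance_um)
        calls.append(FishNucleusCall(
            nucleus_id=m.nucleus_id, n_green=len(g), n_orange=len(o),
            n_fusion=n_fusion,
            genotype=call_nucleus_genotype(len(g), len(o), n_fusion)))
    return calls


@dataclass
class FishCaseResult:
    case_id: str
    n_nuclei: int
    n_informative: int
    fusion_fraction: float      # percent of informative nuclei
    trisomy_fraction: float
    case_call: str              # translocation / trisomy / wild / NS
    trisomy_subthreshold: bool  # nonzero trisomy below the case threshold

    def as_row(self) -> dict:
        return {"case_id": self.case_id, "n_nuclei": self.n_nuclei,
                "n_informative": self.n_informative,
                "fusion_fraction": self.fusion_fraction,
                "trisomy_fraction": self.trisomy_fraction,
                "case_call": self.case_call,
                "trisomy_subthreshold": self.trisomy_subthreshold}


def summarize_fish_case(calls: list[FishNucleusCall], case_id: str = "",
                        cfg: FishConfig = FishConfig()) -> FishCaseResult:
    """Slide-level genotype call with the informativeness rule.

    A slide with fewer than ``min_nuclei`` informative nuclei is not scored
    (``NS``); otherwise the call is ``translocation`` or ``trisomy`` when the
    respective fraction reaches ``case_fraction_threshold`` percent, else
    ``wild``.  Sub-threshold but nonzero trisomy is flagged.
    """
    if not calls:
        raise ValueError("empty call list")
    informative = [c for c in calls if c.genotype != "uninformative"]
    n_inf = len(informative)
    if n_inf == 0:
        fus = tri = 0.0
    else:
        fus = 100.0 * sum(c.genotype == "fusion" for c in informative) / n_inf
        tri = 100.0 * sum(c.genotype == "trisomy18q21"
                          for c in informative) / n_inf
    if n_inf < cfg.min_nuclei:
        call = "NS"
    elif fus >= cfg.case_fraction_threshold:
        call = "translocation"
    elif tri >= cfg.case_fraction_threshold:
        call = "trisomy"
    else:
        call = "wild"
    return FishCaseResult(
        case_id=case_id, n_nuclei=len(calls), n_informative=n_inf,
        fusion_fraction=fus, trisomy_fraction=tri, case_call=call,
        trisomy_subthreshold=(0.0 < tri < cfg.case_fraction_threshold))
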