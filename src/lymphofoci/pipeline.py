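"""End-to-end pipelines: project, segment, detect, classify, summarize.

Both pipelines are deterministic for a fixed configuration and input set:
fields are processed in sorted path order and all outputs are written as
CSV (plus a JSON run report with a configuration hash for provenance).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import DiagnosticThresholds, roc_auc
from .fish import FishConfig, call_nuclei, detect_signals, summarize_fish_case
from .io import read_field
from .patterns import (ClassifierParams, RegionConfig, assign_regions,
                       make_nucleus_records, summarize_case)
from .segmentation import (DiffuseConfig, FociConfig, SegmentationConfig,
                           detect_foci, segment_nuclei)

log = logging.getLogger("lymphofoci")


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    pixel_size: float | None = None          # override sidecar if set
    channel_map: dict[str, int] | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    foci: FociConfig = field(default_factory=FociConfig)
    diffuse: DiffuseConfig = field(default_factory=DiffuseConfig)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    regions: RegionConfig = field(default_factory=RegionConfig)
    fish: FishConfig = field(default_factory=FishConfig)
    thresholds: DiagnosticThresholds = field(default_factory=DiagnosticThresholds)
    assign_region_labels: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        sub = {"segmentation": SegmentationConfig, "foci": FociConfig,
               "diffuse": DiffuseConfig, "classifier": ClassifierParams,
               "regions": RegionConfig, "fish": FishConfig,
               "thresholds": DiagnosticThresholds}
        kwargs = {}
        for k, v in raw.items():
            if k in sub:
                kwargs[k] = sub[k](**v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


@dataclass
class RunReport:
    kind: str
    n_fields: int
    n_nuclei: int
    case_summaries: list[dict]
    version: str
    config_hash: str
    timestamp: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _iter_fields(cfg: RunConfig):
    paths = sorted(Path(cfg.input_dir).glob("*.tif"))
    if not paths:
        raise FileNotFoundError(f"no .tif fields found in {cfg.input_dir}")
    for p in paths:
        yield read_field(p, channel_map=cfg.channel_map,
                         pixel_size=cfg.pixel_size)


def run_if_pipeline(cfg: RunConfig) -> RunReport:
    """Score an immunofluorescence run: per-nucleus classes, per-case summaries.

    Writes ``nuclei.csv``, ``foci.csv``, ``cases.csv`` and ``report.json``
    into the output directory.  Case identity comes from the ``case_id``
    sidecar key (falling back to the field id).
    """
    out = Path(cfg.output_dir)
    all_records, all_foci = [], []
    case_labels: dict[str, str] = {}
    n_fields = 0
    for field_, meta in _iter_fields(cfg):
        case_id = str(meta.get("case_id", field_.field_id))
        case_labels.setdefault(case_id, str(meta.get("lesion_label", "")))
        masks = segment_nuclei(field_, cfg.segmentation)
        foci = detect_foci(field_, masks, cfg.foci)
        regions = (assign_regions(field_, masks, cfg.regions)
                   if cfg.assign_region_labels else None)
        records = make_nucleus_records(field_, masks, foci, case_id,
                                       cfg.classifier, cfg.diffuse, regions)
        log.info("field %s: %d nuclei, %d foci", field_.field_id,
                 len(masks), len(foci))
        all_records.append(records)
        all_foci.extend(
            {"case_id": case_id, "field_id": field_.field_id,
             "nucleus_id": f.nucleus_id, "y_um": f.centroid_um[0],
             "x_um": f.centroid_um[1], "diameter_um": f.diameter_um,
             "peak_intensity": f.peak_intensity} for f in foci)
        n_fields += 1

    nuclei = (pd.concat(all_records, ignore_index=True) if all_records
              else pd.DataFrame())
    summaries = [summarize_case(g, case_id=cid,
                                lesion_label=case_labels.get(cid, ""))
                 for cid, g in nuclei.groupby("case_id", sort=True)]
    cases = pd.DataFrame([s.as_row() for s in summaries])

    out.mkdir(parents=True, exist_ok=True)
    nuclei.to_csv(out / "nuclei.csv", index=False)
    pd.DataFrame(all_foci).to_csv(out / "foci.csv", index=False)
    cases.to_csv(out / "cases.csv", index=False)
    report = RunReport(kind="if", n_fields=n_fields, n_nuclei=len(nuclei),
                       case_summaries=cases.to_dict("records"),
                       version=__version__, config_hash=cfg.config_hash(),
                       timestamp=datetime.now(timezone.utc).isoformat())
    report.write(out / "report.json")
    return report


def run_fish_pipeline(cfg: RunConfig) -> RunReport:
    """Score a FISH run: per-nucleus genotypes and per-case calls.

    Fields sharing a ``case_id`` are pooled into one slide before the
    informativeness rule is applied.  Writes ``fish_nuclei.csv``,
    ``fish_cases.csv`` and ``report.json``.
    """
    out = Path(cfg.output_dir)
    per_case_calls: dict[str, list] = {}
    nuc_rows = []
    n_fields = 0
    for field_, meta in _iter_fields(cfg):
        case_id = str(meta.get("case_id", field_.field_id))
        masks = segment_nuclei(field_, cfg.segmentation)
        signals = detect_signals(field_, masks, cfg.fish)
        calls = call_nuclei(signals, masks, cfg.fish)
        log.info("field %s: %d nuclei, %d signals", field_.field_id,
                 len(masks), len(signals))
        per_case_calls.setdefault(case_id, []).extend(calls)
        nuc_rows.extend({"case_id": case_id, "field_id": field_.field_id,
                         "nucleus_id": c.nucleus_id, "n_green": c.n_green,
                         "n_orange": c.n_orange, "n_fusion": c.n_fusion,
                         "genotype": c.genotype} for c in calls)
        n_fields += 1

    results = [summarize_fish_case(calls, case_id=cid, cfg=cfg.fish)
               for cid, calls in sorted(per_case_calls.items())]
    cases = pd.DataFrame([r.as_row() for r in results])
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(nuc_rows).to_csv(out / "fish_nuclei.csv", index=False)
    cases.to_csv(out / "fish_cases.csv", index=False)
    report = RunReport(kind="fish", n_fields=n_fields, n_nuclei=len(nuc_rows),
                       case_summaries=cases.to_dict("records"),
                       version=__version__, config_hash=cfg.config_hash(),
                       timestamp=datetime.now(timezone.utc).isoformat())
    report.write(out / "report.json")
    return report


def roc_from_cases(cases: pd.DataFrame, label_col: str = "is_malignant",
                   score_col: str = "abnormal_fraction"):
    """ROC of the abnormal fraction over a case table with a binary label."""
    return roc_auc(cases[score_col].to_numpy(),
                   cases[label_col].astype(int).to_numpy())


def match_masks_to_truth(masks, truth_nuclei: pd.DataFrame, pixel_size: float,
                         max_dist_um: float = 2.0) -> dict[int, int]:
    """Match segmented masks to rendered ground-truth nuclei by centroid.

    Returns {mask nucleus_id -> truth row position}; masks farther than
    ``max_dist_um`` from every truth centroid are left out.
    """
    centers = truth_nuclei[["center_y_px", "center_x_px"]].to_numpy() * pixel_size
    out: dict[int, int] = {}
    for m in masks:
        d = np.hypot(*(centers - np.asarray(m.centroid_um)).T)
        j = int(d.argmin())
        if d[j] <= max_dist_um:
            out[m.nucleus_id] = j
    return out


def score_synthetic_if_case(truth, rp, seed: int, nuclei_per_field: int = 50,
                            seg_cfg: SegmentationConfig = SegmentationConfig(),
                            foci_cfg: FociConfig = FociConfig(),
                            diffuse_cfg: DiffuseConfig = DiffuseConfig(),
                            classifier: ClassifierParams = ClassifierParams()
                            ) -> pd.DataFrame:
    """Render a ground-truth case field by field and score it in memory.

    Returns the per-nucleus records table with an extra ``true_class``
    column from centroid matching, for recovery measurements.
    """
    from .segmentation import ImageField
    from .synthetic import GroundTruth, render_if_image

    frames = []
    for fi, lo in enumerate(range(0, len(truth.nuclei), nuclei_per_field)):
        sub = truth.nuclei.iloc[lo:lo + nuclei_per_field].reset_index(drop=True)
        part = GroundTruth(
            case_id=truth.case_id, nuclei=sub,
            foci=truth.foci[truth.foci["nucleus_id"].isin(
                sub["nucleus_id"])].reset_index(drop=True))
        channels, rendered = render_if_image(part, rp, seed=seed + 101 * fi)
        field_ = ImageField(channels, rp.pixel_size, f"{truth.case_id}_f{fi}")
        masks = segment_nuclei(field_, seg_cfg)
        foci = detect_foci(field_, masks, foci_cfg)
        rec = make_nucleus_records(field_, masks, foci, truth.case_id,
                                   classifier, diffuse_cfg)
        match = match_masks_to_truth(masks, rendered.nuclei, rp.pixel_size)
        rec["true_class"] = [
            rendered.nuclei["true_class"].iloc[match[nid]]
            if nid in match else None for nid in rec["nucleus_id"]]
        frames.append(rec.dropna(subset=["true_class"]))
    return pd.concat(frames, ignore_index=True)


def score_synthetic_fish_slide(truth, rp, seed: int,
                               nuclei_per_field: int = 50,
                               seg_cfg: SegmentationConfig = SegmentationConfig(),
                               fish_cfg: FishConfig = FishConfig()
                               ) -> pd.DataFrame:
    """Render and genotype a synthetic FISH slide in memory.

    Returns per-nucleus calls with a ``true_genotype`` column.
    """
    from .segmentation import ImageField
    from .synthetic import GroundTruth, render_fish_image

    rows = []
    for fi, lo in enumerate(range(0, len(truth.nuclei), nuclei_per_field)):
        sub = truth.nuclei.iloc[lo:lo + nuclei_per_field].reset_index(drop=True)
        part = GroundTruth(case_id=truth.case_id, nuclei=sub, foci=truth.foci)
        channels, rendered = render_fish_image(part, rp, seed=seed + 101 * fi)
        field_ = ImageField(channels, rp.pixel_size, f"{truth.case_id}_f{fi}")
        masks = segment_nuclei(field_, seg_cfg)
        signals = detect_signals(field_, masks, fish_cfg)
        calls = call_nuclei(signals, masks, fish_cfg)
        match = match_masks_to_truth(masks, rendered.nuclei, rp.pixel_size)
        for c in calls:
            if c.nucleus_id not in match:
                continue
            rows.append({
                "nucleus_id": c.nucleus_id, "field": fi,
                "n_green": c.n_green, "n_orange": c.n_orange,
                "n_fusion": c.n_fusion, "genotype": c.genotype,
                "true_genotype": rendered.nuclei["true_genotype"].iloc[
                    match[c.nucleus_id]]})
    return pd.DataFrame(rows)
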