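"""Batch orchestration: match cases, rasterize, extract, publish.

Each case runs in fault isolation — a failing case is logged with its
reason and the batch continues.  All cases of a run merge into one RDF
graph and one CSV; subject IRIs stay distinct per patient/VOI/run.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from rdflib import Graph

from .dicom_io import match_cases, read_series, read_structset, select_rois
from .features import extract_all
from .preprocess import ExtractionConfig
from .rasterize import rasterize
from .semantic import CaseProvenance, build_graph, serialize, to_csv

log = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_batch"]


@dataclass
class RunManifest:
    attempted: int = 0
    succeeded: int = 0
    failed: int = 0
    failures: dict = field(default_factory=dict)  # case -> reason
    rois: dict = field(default_factory=dict)  # case -> roi names
    outputs: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def run_batch(
    root,
    cfg: ExtractionConfig | None = None,
    out: Path | str = "out",
    include_roi=(),
    exclude_roi=(),
    formats: tuple[str, ...] = ("rdf", "csv"),
) -> RunManifest:
    """Run the full pipeline over every matched case under ``root``."""
    cfg = cfg or ExtractionConfig()
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={**{k: v for k, v in asdict(cfg).items()}},
        started=datetime.datetime.now().isoformat(timespec="seconds"),
    )

    pairings = match_cases(root)
    if not pairings:
        raise FileNotFoundError(f"no DICOM series/RTSTRUCT pairs found under {root}")

    graph = Graph()
    frames: list[pd.DataFrame] = []
    settings = {
        "discretization": "fixed_bin_width" if cfg.bin_width is not None else "fixed_bin_count",
        "bin_width": cfg.bin_width,
        "bin_count": cfg.bin_count,
        "resample_spacing": cfg.resample_spacing,
        "reseg_range": cfg.reseg_range,
    }
    for pairing in pairings:
        case_name = str(pairing.rtstruct_path.parent.name) or str(pairing.series_dir)
        manifest.attempted += 1
        try:
            vol = read_series(pairing.series_dir)
            ss = select_rois(read_structset(pairing.rtstruct_path), include_roi, exclude_roi)
            if not ss.rois:
                raise ValueError("no ROI left after include/exclude filtering")
            manifest.rois[case_name] = ss.roi_names()
            for roi in ss.rois:
                log.info("case %s: extracting ROI %r", case_name, roi.name)
                mask = rasterize(roi, vol)
                feats = extract_all(vol, mask, cfg)
                prov = CaseProvenance(
                    patient_id=vol.patient_id,
                    voi_name=roi.name,
                    software_name=cfg.software_name,
                    software_version=cfg.software_version,
                    software_language=cfg.software_language,
                    settings=settings,
                )
                if "rdf" in formats:
                    build_graph(feats, prov, graph=graph)
                if "csv" in formats:
                    frames.append(to_csv(feats, prov))
            manifest.succeeded += 1
        except Exception as exc:  # fault isolation: log and continue
            log.error("case %s failed: %s", case_name, exc)
            manifest.failed += 1
            manifest.failures[case_name] = str(exc)

    if "rdf" in formats and len(graph):
        path = out / "features.ttl"
        serialize(graph, path, "turtle")
        manifest.outputs.append(str(path))
    if "csv" in formats and frames:
        path = out / "features.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        manifest.outputs.append(str(path))
    manifest.finished = datetime.datetime.now().isoformat(timespec="seconds")
    manifest.to_json(out / "manifest.json")
    return manifest
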