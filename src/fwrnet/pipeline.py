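"""End-to-end orchestration: image -> tiles -> networks -> cohort stats.

The CLI wraps these functions; they are equally usable from Python.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    AssociationResult,
    PatientRecord,
    RatioResult,
    SpecimenMetrics,
    aggregate_specimen,
    subgroup_association,
    survival_range_probability,
    tumor_biopsy_ratios,
)
from .config import RunConfig
from .imaging import MultiChannelImage, extract_features, tile_image
from .metrics import NetworkMetrics, compute_metrics
from .network import build_network

logger = logging.getLogger(__name__)


@dataclass
class TileMetricsResult:
    """Per-tile metrics of one image plus exclusion bookkeeping."""

    source_id: str
    tile_metrics: list[NetworkMetrics]
    n_tiles_total: int
    n_tiles_kept: int


def image_tile_metrics(
    image: MultiChannelImage,
    config: RunConfig,
    source_id: str = "",
) -> TileMetricsResult:
    """Tile an image, drop background tiles, and compute CC/CP per kept tile."""
    tiles = tile_image(image, config.tile_size).filter_background(
        config.white_luminance_frac, config.max_background_frac
    )
    metrics = []
    for idx, (tile, keep) in enumerate(zip(tiles.tiles, tiles.kept_flags)):
        if not keep:
            logger.info("%s tile %d excluded as background", source_id, idx)
            continue
        feats = extract_features(
            tile, config.window_config(), source_id=f"{source_id}:{idx}"
        )
        net = build_network(feats, config.fcm_config())
        metrics.append(
            compute_metrics(
                net, tau=config.tau, transform=config.length_transform
            )
        )
    return TileMetricsResult(
        source_id=source_id,
        tile_metrics=metrics,
        n_tiles_total=len(tiles),
        n_tiles_kept=len(metrics),
    )


@dataclass
class CohortReport:
    """Full cohort analysis output."""

    specimens: list[SpecimenMetrics]
    ratios: list[RatioResult]
    associations: dict[str, AssociationResult] = field(default_factory=dict)
    probabilities: dict[str, tuple[int, int, float]] = field(default_factory=dict)


def analyze_cohort(
    specimen_images: dict[tuple[str, str], list[MultiChannelImage]],
    records: list[PatientRecord],
    config: RunConfig,
) -> CohortReport:
    """Run the specimen-to-survival analysis.

    ``specimen_images`` maps (patient_id, specimen_type) to the images
    of that specimen (several slides pool into one mean).  Metrics are
    averaged per specimen, tumor/biopsy ratios formed per patient, and
    the shorter/longer survival subgroups correlated with survival.
    """
    specimens = []
    for (pid, stype), images in sorted(specimen_images.items()):
        tile_metrics: list[NetworkMetrics] = []
        for i, img in enumerate(images):
            res = image_tile_metrics(img, config, source_id=f"{pid}/{stype}/{i}")
            tile_metrics.extend(res.tile_metrics)
        specimens.append(aggregate_specimen(tile_metrics, pid, stype))

    ratios = tumor_biopsy_ratios(specimens)
    by_id = {r.patient_id: r for r in ratios}
    report = CohortReport(specimens=specimens, ratios=ratios)

    groups: dict[str, list[PatientRecord]] = {"shorter": [], "longer": []}
    for rec in records:
        if rec.patient_id in by_id and rec.group is not None:
            groups[rec.group].append(rec)
    for gname, members in groups.items():
        if len(members) < 3:
            logger.warning("group %r has %d patients; association skipped",
                           gname, len(members))
            continue
        surv = np.array([m.survival_months for m in members], dtype=float)
        for metric in ("cc_ratio", "cp_ratio"):
            vals = np.array([getattr(by_id[m.patient_id], metric) for m in members])
            report.associations[f"{gname}_{metric}"] = subgroup_association(vals, surv)

    for metric, rrange, srange in (
        ("cc_ratio", config.cc_ratio_range, config.cc_survival_range),
        ("cp_ratio", config.cp_ratio_range, config.cp_survival_range),
    ):
        try:
            report.probabilities[metric] = survival_range_probability(
                ratios, metric, rrange, srange, records
            )
        except Exception as err:  # empty window is a report-level condition
            logger.warning("probability for %s not computed: %s", metric, err)
    return report
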