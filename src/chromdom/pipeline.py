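"""End-to-end orchestration: enhance -> segment -> align -> detect ->
features, with a serializable configuration and a run manifest.

Every tunable of every stage lives in :class:`RunConfig` with the
pipeline's standard defaults; the manifest written by :func:`run_pipeline`
records the effective parameters and input checksums, so a run is fully
reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align as align_mod
from . import domains as domains_mod
from . import features as features_mod
from . import nucleus as nucleus_mod
from .enhance import interpolate_z
from .stack import DEFAULT_SPACING_XY, DEFAULT_SPACING_Z, MultiChannelStack, read_stack

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

CSV_HEADER = (
    "# chromdom feature table; coordinates 0-based (z, y, x); "
    "distances in micrometres, volumes in voxels and um^3\n"
)


@dataclass
class RunConfig:
    """All pipeline parameters, at their standard defaults."""

    input_path: str | None = None
    output_dir: str = "chromdom_out"
    channel_map: dict[str, int] | None = None
    dapi_channel: str = "dapi"
    h3k27ac_channel: str = "h3k27ac"
    er_channel: str | None = "er"
    spacing_xy: float = DEFAULT_SPACING_XY
    spacing_z: float = DEFAULT_SPACING_Z
    # nucleus segmentation
    dapi_cutoff: float = nucleus_mod.DAPI_CUTOFF
    top_k_components: int = nucleus_mod.TOP_K_COMPONENTS
    nucleus_dilations: int = nucleus_mod.REFINE_DILATIONS
    min_nucleus_px: int = nucleus_mod.MIN_NUCLEUS_PX
    min_circularity: float = nucleus_mod.MIN_CIRCULARITY
    # channel alignment
    max_shift: int = align_mod.MAX_SHIFT
    alignment_mode: str = "global"         # "global" | "per-slide"
    alignment_max_slides: int | None = 5
    # domain detection
    background_top_percentile: float = domains_mod.BACKGROUND_TOP_PERCENTILE
    domain_dilations: int = domains_mod.DOMAIN_DILATIONS
    domain_size_range: tuple[int, int] = (
        domains_mod.MIN_DOMAIN_VOXELS,
        domains_mod.MAX_DOMAIN_VOXELS,
    )
    # labels
    cell_id: str | int = 0
    condition: str = ""
    batch: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["domain_size_range"] = list(self.domain_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "domain_size_range" in d:
            d["domain_size_range"] = tuple(d["domain_size_range"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StackAnalysis:
    """In-memory result of analysing one stack."""

    features: pd.DataFrame
    nuclei: list
    domains: list
    shifts: pd.DataFrame
    threshold: domains_mod.BackgroundThreshold | None
    enhanced: MultiChannelStack


def analyze_stack(stack: MultiChannelStack, config: RunConfig) -> StackAnalysis:
    """Run enhancement, segmentation, alignment, detection and feature
    extraction on one in-memory stack."""
    for name in (config.dapi_channel, config.h3k27ac_channel):
        if name not in stack.channels:
            raise ValueError(
                f"missing channel {name!r}; available: {sorted(stack.channels)}"
            )
    use_er = config.er_channel is not None and config.er_channel in stack.channels

    enhanced = interpolate_z(stack) if not stack.is_enhanced else stack
    spacing = enhanced.spacing
    dapi = enhanced.channels[config.dapi_channel]
    h3 = enhanced.channels[config.h3k27ac_channel]

    nuclei = nucleus_mod.segment_nuclei(
        dapi,
        cutoff=config.dapi_cutoff,
        top_k=config.top_k_components,
        min_px=config.min_nucleus_px,
        min_shape=config.min_circularity,
        dilations=config.nucleus_dilations,
    )
    if not nuclei:
        logger.warning("no nucleus accepted; emitting empty feature table")
        return StackAnalysis(
            features=pd.DataFrame(), nuclei=[], domains=[],
            shifts=pd.DataFrame(), threshold=None, enhanced=enhanced,
        )

    er = er_valid = None
    shift_rows = []
    if use_er:
        er_raw = enhanced.channels[config.er_channel]
        shifts = align_mod.estimate_stack_shift(
            h3, er_raw,
            max_shift=config.max_shift,
            mode=config.alignment_mode,
            max_slides=config.alignment_max_slides,
        )
        er, er_valid = align_mod.apply_shift(er_raw, shifts)
        shift_rows = [
            {"slide": s.slide_index, "dy": s.dy, "dx": s.dx, "peak_corr": s.peak_corr}
            for s in shifts
        ]

    thr = domains_mod.background_threshold(
        h3, [n.mask for n in nuclei], config.background_top_percentile
    )
    all_domains = []
    next_label = 1
    for nuc in nuclei:
        doms = domains_mod.detect_domains(
            h3, thr, nuc, er=er, er_valid=er_valid,
            dilations=config.domain_dilations,
            size_range=config.domain_size_range,
            start_label=next_label,
        )
        next_label += len(doms)
        all_domains.extend(doms)

    features = features_mod.build_feature_table(
        all_domains,
        {n.label: n for n in nuclei},
        spacing,
        cell_id=config.cell_id,
        condition=config.condition,
        batch=config.batch,
    )
    return StackAnalysis(
        features=features, nuclei=nuclei, domains=all_domains,
        shifts=pd.DataFrame(shift_rows), threshold=thr, enhanced=enhanced,
    )


def analyze_cohort(members, config: RunConfig) -> pd.DataFrame:
    """Run :func:`analyze_stack` over a generated cohort and pool the
    per-domain feature tables with condition/batch/cell labels.

    Volume classes are reassigned from the pooled volume distribution
    (quartiles across all conditions) when at least four domains exist.
    """
    from dataclasses import replace as dc_replace

    from .features import assign_volume_classes

    frames = []
    for m in members:
        cfg = dc_replace(
            config, cell_id=m.cell, condition=m.condition, batch=m.batch
        )
        feats = analyze_stack(m.stack, cfg).features
        if len(feats):
            frames.append(feats)
    if not frames:
        return pd.DataFrame()
    pooled = pd.concat(frames, ignore_index=True)
    if len(pooled) >= 4:
        pooled["volume_class"] = assign_volume_classes(pooled["volume_vox"].to_numpy())
    return pooled


def _checksum(stack: MultiChannelStack) -> str:
    h = hashlib.sha256()
    for name in sorted(stack.channels):
        h.update(name.encode())
        h.update(np.ascontiguousarray(stack.channels[name]).tobytes())
    return h.hexdigest()


def write_tables(analysis: StackAnalysis, out_dir: str | Path) -> dict[str, str]:
    """Write feature, per-cell summary, nucleus and shift CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    fpath = out / "features.csv"
    with open(fpath, "w") as fh:
        fh.write(CSV_HEADER)
        analysis.features.to_csv(fh, index=False)
    paths["features"] = str(fpath)

    if len(analysis.features):
        spath = out / "cell_summary.csv"
        features_mod.summarize_cells(analysis.features).to_csv(spath, index=False)
        paths["cell_summary"] = str(spath)

    npath = out / "nuclei.csv"
    pd.DataFrame(
        [
            {
                "label": n.label,
                "n_voxels": n.n_voxels,
                "z_min": min(n.per_slide_areas) if n.per_slide_areas else -1,
                "z_max": max(n.per_slide_areas) if n.per_slide_areas else -1,
                "n_boundary_voxels": len(n.boundary),
            }
            for n in analysis.nuclei
        ]
    ).to_csv(npath, index=False)
    paths["nuclei"] = str(npath)

    if len(analysis.shifts):
        shpath = out / "shifts.csv"
        analysis.shifts.to_csv(shpath, index=False)
        paths["shifts"] = str(shpath)
    return paths


def run_pipeline(config: RunConfig, stack: MultiChannelStack | None = None) -> dict:
    """Run the full pipeline and write outputs plus a manifest.

    The stack is read from ``config.input_path`` unless given in memory.
    Returns the manifest (also written to ``<output_dir>/manifest.json``).
    """
    if stack is None:
        if config.input_path is None:
            raise ValueError("config.input_path not set and no stack given")
        stack = read_stack(
            config.input_path,
            channel_map=config.channel_map,
            default_spacing=(config.spacing_xy, config.spacing_z),
        )
    checksum = _checksum(stack)
    analysis = analyze_stack(stack, config)
    paths = write_tables(analysis, config.output_dir)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "input_checksum_sha256": checksum,
        "outputs": paths,
        "n_nuclei": len(analysis.nuclei),
        "n_domains": len(analysis.domains),
        "background_threshold": (
            analysis.threshold.value if analysis.threshold else None
        ),
        "background_n": (
            analysis.threshold.n_background if analysis.threshold else None
        ),
    }
    mpath = Path(config.output_dir) / "manifest.json"
    mpath.parent.mkdir(parents=True, exist_ok=True)
    mpath.write_text(json.dumps(manifest, indent=2))
    return manifest
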