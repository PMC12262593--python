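"""Seeded synthetic 3D-SIM nuclear stacks with known ground truth.

Real inputs to the pipeline are multi-channel super-resolution Z-stacks of
breast-cancer nuclei: a DAPI channel delineating the nucleus, an H3K27ac
channel whose bright connected regions are the chromatin domains under
study, and an ER (estrogen receptor) channel whose intensity co-varies with
H3K27ac to a condition-dependent degree. This module emulates exactly that
statistical structure on the acquisition voxel grid (0.06 um X/Y, 0.15 um
Z), with every generative choice exposed as a parameter and every generated
domain recorded as ground truth, so that each downstream stage can be
validated against known answers.

Condition presets mirror the two phenotypes the pipeline is built to
discriminate: an estradiol-stimulated state ("E2-like": fewer constraints
on placement, larger, elongated capsule-shaped domains, strong ER
colocalization) and an estrogen-deprived state ("ED-like": compact
spherical domains pulled toward the nuclear periphery, weak ER
colocalization).

No optics are simulated: there is no PSF convolution, photoswitching or
reconstruction artifact model; domains are rendered as clean geometric
solids plus camera-like integer noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .stack import DEFAULT_SPACING_XY, DEFAULT_SPACING_Z, MultiChannelStack

logger = logging.getLogger(__name__)

SPHERE = "sphere"
SPHEROCYLINDER = "spherocylinder"

#: DAPI levels (camera counts): the nucleus must sit far above the 500-count
#: segmentation cutoff and the outside far below it.
DAPI_INSIDE_MEAN = 2000.0
DAPI_INSIDE_SD = 150.0
DAPI_OUTSIDE_MEAN = 100.0
DAPI_OUTSIDE_SD = 50.0
#: brightness floor separating in- from out-of-nucleus DAPI signal
NUCLEUS_BRIGHTNESS_FLOOR = 500.0


@dataclass(frozen=True)
class ConditionSpec:
    """Generative parameters for one experimental condition.

    ``er_correlation`` is the target Pearson correlation between H3K27ac
    and ER intensities over in-domain voxels; it is realised exactly in
    expectation by mixing the H3K27ac signal with independent noise.
    ``boundary_bias`` in [0, 1] pulls domain placement toward the nuclear
    periphery (0 = uniform in the nuclear volume, 1 = all domains near the
    envelope), emulating the peripheral, lamina-associated positioning of
    repressed chromatin.
    """

    name: str
    n_domains_mean: float = 25.0
    domain_shape: str = SPHERE
    elongation_ratio: float = 1.0
    domain_radius_vox: float = 3.0
    intensity_mean: float = 1500.0
    intensity_sd: float = 250.0
    er_correlation: float = 0.5
    boundary_bias: float = 0.0
    background_mean: float = 120.0
    background_sd: float = 40.0
    # SIM reconstructions are noisiest outside the specimen; the diffuse
    # nucleoplasmic H3K27ac background is modelled with a tighter spread.
    nuclear_background_sd: float = 25.0
    er_background_mean: float = 120.0
    er_domain_mean: float = 1200.0
    er_domain_sd: float = 250.0
    channel_shift_xy: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.domain_shape not in (SPHERE, SPHEROCYLINDER):
            raise ValueError(f"unknown domain_shape {self.domain_shape!r}")
        if self.domain_shape == SPHERE and self.elongation_ratio != 1.0:
            raise ValueError("sphere requires elongation_ratio == 1")
        if self.domain_shape == SPHEROCYLINDER and self.elongation_ratio <= 1.0:
            raise ValueError("spherocylinder requires elongation_ratio > 1")
        if not -1.0 <= self.er_correlation <= 1.0:
            raise ValueError("er_correlation must lie in [-1, 1]")
        if self.intensity_sd < 0 or self.background_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.boundary_bias <= 1.0:
            raise ValueError("boundary_bias must lie in [0, 1]")
        if abs(self.er_correlation) < 1.0 and self.intensity_sd == 0:
            raise ValueError(
                "er_correlation is unreachable: partial correlation needs "
                "voxel-level H3K27ac variance (intensity_sd > 0)"
            )


@dataclass
class DomainTruth:
    """Ground truth for one generated chromatin domain."""

    centroid: np.ndarray          # (z, y, x) in voxels, float
    voxels: np.ndarray            # (n, 3) integer voxel coordinates
    shape_class: str              # sphere | spherocylinder
    axis: np.ndarray              # unit axis in physical (z, y, x) coords
    normalized_radius: float      # centroid position in ellipsoid coords, [0, 1)
    center_um: np.ndarray = None  # geometric centre, physical coords
    radius_um: float = 0.0        # capsule radius
    half_len_um: float = 0.0      # capsule cylinder half-length (0 = ball)


@dataclass
class GroundTruth:
    """Everything the generator knows about one stack."""

    domains: list[DomainTruth]
    channel_shift: tuple[int, int]          # (dy, dx) applied to the ER channel
    nucleus_center: np.ndarray              # (z, y, x) voxels
    nucleus_semiaxes: np.ndarray            # (z, y, x) voxels

    def nucleus_mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        zz, yy, xx = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
        c, a = self.nucleus_center, self.nucleus_semiaxes
        rho2 = (
            ((zz - c[0]) / a[0]) ** 2
            + ((yy - c[1]) / a[1]) ** 2
            + ((xx - c[2]) / a[2]) ** 2
        )
        return rho2 <= 1.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.domains):
            rows.append(
                {
                    "domain": i,
                    "shape_class": d.shape_class,
                    "n_voxels": len(d.voxels),
                    "centroid_z": d.centroid[0],
                    "centroid_y": d.centroid[1],
                    "centroid_x": d.centroid[2],
                    "normalized_radius": d.normalized_radius,
                }
            )
        return pd.DataFrame(rows)


def axis_extent_ratio(
    voxels: np.ndarray, spacing: tuple[float, float, float]
) -> float:
    """Elongation of a voxel set: extent along the first principal axis
    divided by extent along the last, measured in physical coordinates.

    For an ideal capsule this equals total length / diameter, i.e. the
    requested elongation ratio; for a ball it is 1.
    """
    pts = np.asarray(voxels, dtype=float) * np.asarray(spacing)
    pts = pts - pts.mean(axis=0)
    # principal axes from the covariance; extents measured along them
    _, vecs = np.linalg.eigh(np.cov(pts.T))
    proj = pts @ vecs  # columns ordered by ascending eigenvalue
    extents = proj.max(axis=0) - proj.min(axis=0)
    short = max(extents[0], 1e-9)
    return float(extents[2] / short)


# ---------------------------------------------------------------------------
# geometry helpers


def _rasterize_capsule(
    center_um: np.ndarray,
    axis: np.ndarray,
    half_len_um: float,
    radius_um: float,
    grid_shape: tuple[int, int, int],
    spacing: np.ndarray,
) -> np.ndarray:
    """Voxels whose centres lie within ``radius_um`` of the capsule's axis
    segment. ``half_len_um == 0`` gives a ball."""
    lo = np.maximum(
        0, np.floor((center_um - half_len_um - radius_um) / spacing - 1)
    ).astype(int)
    hi = np.minimum(
        np.asarray(grid_shape) - 1,
        np.ceil((center_um + half_len_um + radius_um) / spacing + 1),
    ).astype(int)
    axes = [np.arange(lo[d], hi[d] + 1) * spacing[d] for d in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1) - center_um
    t = np.clip(pts @ axis, -half_len_um, half_len_um)
    closest = t[..., None] * axis
    dist2 = ((pts - closest) ** 2).sum(axis=-1)
    inside = dist2 <= radius_um**2
    coords = np.argwhere(inside)
    coords += lo
    return coords


def _sample_unit_axis(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - measure-zero event
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _sample_normalized_radius(rng: np.random.Generator, boundary_bias: float) -> float:
    """Radial position of a domain centre in ellipsoid coordinates.

    With bias 0 the centre is uniform in the nuclear volume (density
    proportional to rho^2); with bias 1 it concentrates in a thin shell
    under the envelope. Intermediate biases mix the two.
    """
    if rng.random() < boundary_bias:
        return float(rng.uniform(0.78, 0.92))
    return float(rng.uniform(0.0, 1.0) ** (1.0 / 3.0) * 0.88)


# ---------------------------------------------------------------------------
# stack generation


def generate_stack(
    spec: ConditionSpec,
    grid_shape: tuple[int, int, int] = (10, 256, 256),
    spacing: tuple[float, float, float] = (
        DEFAULT_SPACING_Z,
        DEFAULT_SPACING_XY,
        DEFAULT_SPACING_XY,
    ),
    seed: int = 0,
    nucleus_semiaxes: tuple[float, float, float] | None = None,
) -> tuple[MultiChannelStack, GroundTruth]:
    """Generate one synthetic nucleus as a 3-channel acquisition-grid stack.

    Returns the stack (channels ``dapi``, ``h3k27ac``, ``er``; all slides
    flagged real) and the generating ground truth. The same seed and spec
    always produce bit-identical output.

    ``nucleus_semiaxes`` (voxels, z/y/x order) defaults to an ellipsoid
    filling most of the grid with a small seeded jitter. Domain geometry is
    computed in physical micrometres, so the anisotropic voxel grid yields
    the correct 3D shapes after Z-interpolation.
    """
    rng = np.random.default_rng(seed)
    grid_shape = tuple(int(g) for g in grid_shape)
    nz, ny, nx = grid_shape
    sp = np.asarray(spacing, dtype=float)

    if nucleus_semiaxes is None:
        jitter = rng.uniform(0.92, 1.0, size=3)
        nucleus_semiaxes = np.array(
            [0.33 * nz, 0.42 * ny, 0.37 * nx]
        ) * jitter
    semi = np.asarray(nucleus_semiaxes, dtype=float)
    center = np.array([nz, ny, nx], dtype=float) / 2.0 + np.array(
        [rng.uniform(-0.3, 0.3), rng.uniform(-1, 1), rng.uniform(-1, 1)]
    )

    for d, name in enumerate("zyx"):
        if center[d] - semi[d] < 0 or center[d] + semi[d] > grid_shape[d] - 1:
            raise ValueError(
                f"nucleus does not fit grid along the {name} dimension: "
                f"semiaxis {semi[d]:.1f} vox at centre {center[d]:.1f} "
                f"exceeds extent {grid_shape[d]}"
            )

    truth = GroundTruth(
        domains=[], channel_shift=tuple(spec.channel_shift_xy),
        nucleus_center=center, nucleus_semiaxes=semi,
    )
    nucleus = truth.nucleus_mask(grid_shape)

    # --- DAPI channel
    dapi = rng.normal(DAPI_OUTSIDE_MEAN, DAPI_OUTSIDE_SD, size=grid_shape)
    dapi[nucleus] = rng.normal(DAPI_INSIDE_MEAN, DAPI_INSIDE_SD, size=int(nucleus.sum()))

    # --- H3K27ac channel: background, then domains
    h3 = rng.normal(spec.background_mean, spec.background_sd, size=grid_shape)
    h3[nucleus] = rng.normal(
        spec.background_mean, spec.nuclear_background_sd, size=int(nucleus.sum())
    )

    n_domains = max(1, int(rng.poisson(spec.n_domains_mean)))
    radius_um = spec.domain_radius_vox * sp[1]
    half_len_um = radius_um * (spec.elongation_ratio - 1.0)
    center_um = center * sp
    semi_um = semi * sp

    placed = 0
    attempts = 0
    max_attempts = 200 * n_domains
    # keep-out map: domains are distinct bodies, so candidates must clear
    # existing ones by 1 voxel in-plane and 2 slides axially (interpolation
    # would otherwise bridge a single-slide gap and merge them)
    occupied = np.zeros(grid_shape, dtype=bool)
    keepout = np.ones((5, 3, 3), dtype=bool)
    while placed < n_domains and attempts < max_attempts:
        attempts += 1
        rho = _sample_normalized_radius(rng, spec.boundary_bias)
        direction = _sample_unit_axis(rng)
        c_um = center_um + rho * direction * semi_um
        axis = _sample_unit_axis(rng) if spec.domain_shape == SPHEROCYLINDER else np.array([0.0, 0.0, 1.0])
        # cheap sufficient containment test before rasterizing: both capsule
        # end-balls inside the ellipsoid shrunk by the capsule radius imply
        # (by convexity) the whole capsule is inside
        shrunk = semi_um - radius_um
        if (shrunk <= 0).any():
            raise ValueError("domain radius exceeds a nucleus semiaxis")
        ends = c_um + np.outer([-half_len_um, half_len_um], axis)
        if (((ends - center_um) / shrunk) ** 2).sum(axis=1).max() > 1.0:
            continue
        coords = _rasterize_capsule(
            c_um, axis, half_len_um, radius_um, grid_shape, sp
        )
        if len(coords) == 0:
            continue
        # ground-truth invariant: every domain voxel inside the nucleus
        rel = (coords * sp - center_um) / semi_um
        if ((rel**2).sum(axis=1) > 1.0).any():
            continue
        if occupied[coords[:, 0], coords[:, 1], coords[:, 2]].any():
            continue
        lo = np.maximum(coords.min(axis=0) - 3, 0)
        hi = np.minimum(coords.max(axis=0) + 4, grid_shape)
        crop = tuple(slice(l, h) for l, h in zip(lo, hi))
        stamp = np.zeros(tuple(hi - lo), dtype=bool)
        local = coords - lo
        stamp[local[:, 0], local[:, 1], local[:, 2]] = True
        occupied[crop] |= ndimage.binary_dilation(stamp, structure=keepout)
        level = rng.normal(spec.intensity_mean, spec.intensity_sd)
        vox_int = level + rng.normal(0.0, spec.intensity_sd, size=len(coords))
        h3[coords[:, 0], coords[:, 1], coords[:, 2]] = np.maximum(
            h3[coords[:, 0], coords[:, 1], coords[:, 2]], vox_int
        )
        truth.domains.append(
            DomainTruth(
                centroid=coords.mean(axis=0),
                voxels=coords,
                shape_class=spec.domain_shape,
                axis=axis,
                normalized_radius=rho,
                center_um=c_um,
                radius_um=radius_um,
                half_len_um=half_len_um,
            )
        )
        placed += 1
    if placed < n_domains:
        logger.warning(
            "placed only %d of %d requested domains (condition %s)",
            placed, n_domains, spec.name,
        )

    # --- ER channel: correlated with H3K27ac inside domains
    er = rng.normal(spec.er_background_mean, spec.background_sd, size=grid_shape)
    rho_t = spec.er_correlation
    for d in truth.domains:
        z, y, x = d.voxels.T
        h_vals = h3[z, y, x]
        if rho_t == 1.0:
            er[z, y, x] = h_vals
        elif rho_t == -1.0:
            er[z, y, x] = 2.0 * spec.intensity_mean - h_vals
        else:
            sd = h_vals.std()
            h_std = (h_vals - h_vals.mean()) / sd if sd > 0 else np.zeros_like(h_vals)
            noise = rng.normal(size=len(h_vals))
            mix = rho_t * h_std + np.sqrt(1.0 - rho_t**2) * noise
            er[z, y, x] = spec.er_domain_mean + spec.er_domain_sd * mix

    # rigid in-plane shift of the ER channel (systematic chromatic offset)
    dy, dx = spec.channel_shift_xy
    if (dy, dx) != (0, 0):
        shifted = np.zeros_like(er)
        src_y = slice(max(0, -dy), er.shape[1] - max(0, dy))
        dst_y = slice(max(0, dy), er.shape[1] - max(0, -dy))
        src_x = slice(max(0, -dx), er.shape[2] - max(0, dx))
        dst_x = slice(max(0, dx), er.shape[2] - max(0, -dx))
        shifted[:, dst_y, dst_x] = er[:, src_y, src_x]
        er = shifted

    channels = {}
    for name, arr in (("dapi", dapi), ("h3k27ac", h3), ("er", er)):
        if rho_t in (-1.0, 1.0) and name in ("h3k27ac", "er"):
            # keep the exact linear dependence of the degenerate case:
            # floor both channels identically instead of rounding noise
            arr = np.floor(arr)
        else:
            arr = np.round(arr)
        channels[name] = np.clip(arr, 0, None).astype(np.uint16)

    stack = MultiChannelStack(
        channels=channels, spacing_xy=float(sp[1]), spacing_z=float(sp[0])
    )
    return stack, truth


# ---------------------------------------------------------------------------
# condition presets: the two phenotypes the pipeline must tell apart


def ed_like_spec(**overrides) -> ConditionSpec:
    """Estrogen-deprived phenotype: compact spherical domains, peripheral
    placement, weak ER colocalization."""
    base = ConditionSpec(
        name="ED-like",
        domain_shape=SPHERE,
        elongation_ratio=1.0,
        domain_radius_vox=3.0,
        n_domains_mean=25.0,
        intensity_mean=1500.0,
        er_correlation=0.3,
        boundary_bias=0.7,
        channel_shift_xy=(3, -2),
    )
    return replace(base, **overrides)


def e2_like_spec(**overrides) -> ConditionSpec:
    """Estradiol-stimulated phenotype: larger, elongated (capsule) domains,
    central placement, strong ER colocalization."""
    base = ConditionSpec(
        name="E2-like",
        domain_shape=SPHEROCYLINDER,
        elongation_ratio=4.0,
        domain_radius_vox=3.0,
        n_domains_mean=25.0,
        intensity_mean=1800.0,
        er_correlation=0.6,
        boundary_bias=0.0,
        channel_shift_xy=(3, -2),
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortMember:
    condition: str
    batch: int
    cell: int
    seed: int
    stack: MultiChannelStack
    truth: GroundTruth


def subseed(master_seed: int, batch: int, cell: int) -> int:
    """Deterministic per-cell seed derived from the master seed."""
    seq = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(batch, cell))
    return int(seq.generate_state(1)[0] % (2**31))


def generate_cohort(
    specs: list[ConditionSpec],
    n_cells_per_condition: int = 10,
    n_batches: int = 2,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (10, 256, 256),
    spacing: tuple[float, float, float] = (
        DEFAULT_SPACING_Z,
        DEFAULT_SPACING_XY,
        DEFAULT_SPACING_XY,
    ),
    batch_intensity_offsets: list[float] | None = None,
) -> list[CohortMember]:
    """Generate a labelled cohort: conditions x batches x cells.

    Cells are distributed round-robin over batches so every batch contains
    every condition. Per-cell seeds derive deterministically from the
    master seed, so any member can be regenerated in isolation.
    ``batch_intensity_offsets`` adds a per-batch additive offset to the
    domain intensity mean, emulating staining/acquisition batch effects.
    """
    if n_cells_per_condition < 1:
        raise ValueError("n_cells_per_condition must be >= 1")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate condition names in {names}")
    if batch_intensity_offsets is not None and len(batch_intensity_offsets) != n_batches:
        raise ValueError("need one intensity offset per batch")

    members: list[CohortMember] = []
    for ci, spec in enumerate(specs):
        for cell in range(n_cells_per_condition):
            batch = cell % n_batches
            s = subseed(seed, batch, ci * n_cells_per_condition + cell)
            eff = spec
            if batch_intensity_offsets is not None:
                eff = replace(
                    spec,
                    intensity_mean=spec.intensity_mean + batch_intensity_offsets[batch],
                )
            stack, truth = generate_stack(
                eff, grid_shape=grid_shape, spacing=spacing, seed=s
            )
            members.append(
                CohortMember(
                    condition=spec.name, batch=batch, cell=cell,
                    seed=s, stack=stack, truth=truth,
                )
            )
    return members


def cohort_truth_table(members: list[CohortMember]) -> pd.DataFrame:
    """One row per ground-truth domain across the whole cohort."""
    frames = []
    for m in members:
        df = m.truth.to_frame()
        df.insert(0, "condition", m.condition)
        df.insert(1, "batch", m.batch)
        df.insert(2, "cell", m.cell)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
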