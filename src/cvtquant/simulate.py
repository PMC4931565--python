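"""Deterministic synthetic microscope and micrograph generator.

Everything the real study acquired by imaging is generated here from a
seed: two-channel fluorescence z-stacks with diffraction-limited
puncta planted on cellular background (Poisson shot noise, Gaussian
read noise), paired strain experiments with a planted fold-change, EM
coordinate fields with planted dodecamer chains, and ground-truth
ledgers for every planted quantity.

The virtual camera mimics the wide-field acquisitions this package is
built for: 21- or 23-frame z-stacks spaced 200 nm, a CCD at 100x
magnification.  Absolute intensities are arbitrary units anchored only
by the calibration reference; the conversion gain
(``photons_per_molecule``) cancels in every ratiometric read-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from cvtquant.imaging import ImageStack

__all__ = [
    "SceneConfig",
    "PlantedSpot",
    "ChainFieldConfig",
    "DEFAULT_SPOT_SIGMA_LOG",
    "REFERENCE_SIGMA_LOG",
    "cell_centers",
    "background_field",
    "expected_photon_field",
    "generate_stack_pair",
    "plant_spot_population",
    "sample_molecule_counts",
    "generate_two_strain_experiment",
    "generate_chain_field",
]

# Log-scale SD of per-spot molecule counts.  Cvt puncta are aggregates of
# variable size; a geometric SD of ~1.5x (sigma_log 0.4) is typical of
# punctate fluorescence intensity distributions.  Kinetochore reference
# clusters are stereotyped structures and scatter less.
DEFAULT_SPOT_SIGMA_LOG = 0.4
REFERENCE_SIGMA_LOG = 0.25


@dataclass
class SceneConfig:
    """Acquisition constants of the virtual microscope.

    ``image_shape`` is ``(z, y, x)``; intensities are photons.  With
    ``shot_noise`` off and ``read_noise_sd`` zero the camera is
    noise-free and every planted photon is conserved.
    """

    seed: int = 0
    image_shape: tuple[int, int, int] = (21, 256, 256)
    pixel_size: float = 129.0      # nm/px: 6.45 um CCD pixel, 100x, 2x2 binning
    z_spacing: float = 200.0       # nm between frames
    psf_sigma_xy: float = 1.5      # px
    psf_sigma_z: float = 2.0       # frames
    photons_per_molecule: float = 50.0
    cell_background: float = 200.0   # photons/px inside cells
    outside_background: float = 20.0
    read_noise_sd: float = 6.0       # photons
    shot_noise: bool = True
    n_cells: int = 9
    spots_per_cell: float = 3.0      # Poisson mean, used by scenario builders
    cell_radius: float = 28.0        # px
    cell_edge_sigma: float = 8.0     # px; out-of-focus softening of cell edges
    red_partner_photons: float = 20000.0  # total photons of an mCherry marker spot

    def validate(self) -> None:
        z, y, x = self.image_shape
        if z < 5:
            raise ValueError("need at least 5 z-frames")
        for name in ("pixel_size", "z_spacing", "psf_sigma_xy", "psf_sigma_z",
                     "photons_per_molecule", "cell_background", "cell_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.read_noise_sd < 0 or self.outside_background < 0:
            raise ValueError("noise and background levels must be non-negative")


@dataclass
class PlantedSpot:
    """Ground-truth record of one planted punctum.

    ``partner_offset`` is the in-plane displacement (nm, along x) of
    the red colocalization partner; ``None`` means the spot has no
    partner and should fail the colocalization gate.
    """

    spot_id: int
    cell_id: int
    true_molecules: float
    x: float
    y: float
    z: float
    channel: str = "green"
    partner_offset: float | None = None


def cell_centers(config: SceneConfig) -> np.ndarray:
    """Deterministic (y, x) centers of the disk-shaped cells.

    Cells sit on a jittered grid so the background shows the intensity
    plateaus that the median filter must cope with.  Derived only from
    the seed, so scene builders and the renderer agree on the layout.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))
    _, ny, nx = config.image_shape
    g = int(np.ceil(np.sqrt(config.n_cells)))
    margin = config.cell_radius + 4
    ys = np.linspace(margin, ny - margin, g)
    xs = np.linspace(margin, nx - margin, g)
    centers = []
    for iy in range(g):
        for ix in range(g):
            if len(centers) == config.n_cells:
                break
            jitter = rng.uniform(-4, 4, size=2)
            centers.append([ys[iy] + jitter[0], xs[ix] + jitter[1]])
    return np.array(centers)


def background_field(config: SceneConfig) -> np.ndarray:
    """Noise-free expected background: outside level plus cell disks.

    Cell edges are softened by a Gaussian of ``cell_edge_sigma`` px,
    emulating the out-of-focus light of a real cell body; a hard step
    would leave ring artifacts under median-filter subtraction that no
    real acquisition shows.
    """
    nz, ny, nx = config.image_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    plane = np.full((ny, nx), float(config.outside_background))
    for cy, cx in cell_centers(config):
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= config.cell_radius**2
        plane[inside] = config.cell_background
    if config.cell_edge_sigma > 0:
        plane = ndimage.gaussian_filter(plane, config.cell_edge_sigma, mode="nearest")
    return np.broadcast_to(plane, (nz, ny, nx)).copy()


def _axis_masses(center: float, sigma: float, n: int) -> tuple[int, np.ndarray]:
    """Integrated Gaussian mass per voxel along one axis.

    Uses the error function over voxel boundaries so that the rendered
    spot conserves its total photon count up to tail truncation.
    Returns the start index and the per-voxel masses of a +-5 sigma
    window clipped to the axis.
    """
    lo = max(0, int(np.floor(center - 5 * sigma)))
    hi = min(n - 1, int(np.ceil(center + 5 * sigma)))
    edges = np.arange(lo, hi + 2) - 0.5
    cdf = 0.5 * (1 + special.erf((edges - center) / (sigma * np.sqrt(2))))
    return lo, np.diff(cdf)


def _render_spot(image: np.ndarray, total_photons: float, x: float, y: float,
                 z: float, config: SceneConfig) -> None:
    nz, ny, nx = image.shape
    z0, mz = _axis_masses(z, config.psf_sigma_z, nz)
    y0, my = _axis_masses(y, config.psf_sigma_xy, ny)
    x0, mx = _axis_masses(x, config.psf_sigma_xy, nx)
    patch = total_photons * mz[:, None, None] * my[None, :, None] * mx[None, None, :]
    image[z0:z0 + len(mz), y0:y0 + len(my), x0:x0 + len(mx)] += patch


def expected_photon_field(
    config: SceneConfig, planted: list[PlantedSpot]
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expected photon images for both channels.

    Each spot contributes a 3D Gaussian of total expected photons
    ``true_molecules x photons_per_molecule``; red partners of green
    spots are rendered at the configured offset with a fixed marker
    brightness.  Spots outside the image bounds are rejected.
    """
    config.validate()
    nz, ny, nx = config.image_shape
    green = background_field(config)
    red = background_field(config)
    for spot in planted:
        if not (0 <= spot.x <= nx - 1 and 0 <= spot.y <= ny - 1 and 0 <= spot.z <= nz - 1):
            raise ValueError(
                f"spot {spot.spot_id} at ({spot.x:.1f}, {spot.y:.1f}, {spot.z:.1f}) "
                f"lies outside image bounds {(nz, ny, nx)}"
            )
        if spot.true_molecules < 0:
            raise ValueError(f"spot {spot.spot_id}: true_molecules must be >= 0")
        total = spot.true_molecules * config.photons_per_molecule
        target = green if spot.channel == "green" else red
        _render_spot(target, total, spot.x, spot.y, spot.z, config)
        if spot.channel == "green" and spot.partner_offset is not None:
            px = spot.x + spot.partner_offset / config.pixel_size
            px = min(max(px, 0.0), nx - 1.0)
            _render_spot(red, config.red_partner_photons, px, spot.y, spot.z, config)
    return green, red


def _apply_camera(expected: np.ndarray, config: SceneConfig,
                  rng: np.random.Generator) -> np.ndarray:
    vox = rng.poisson(expected).astype(np.float64) if config.shot_noise else expected.copy()
    if config.read_noise_sd > 0:
        vox += rng.normal(0.0, config.read_noise_sd, size=vox.shape)
    return np.clip(vox, 0.0, None)


def truth_table(planted: list[PlantedSpot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"spot_id": s.spot_id, "cell_id": s.cell_id, "channel": s.channel,
             "x": s.x, "y": s.y, "z": s.z, "true_molecules": s.true_molecules}
            for s in planted
        ],
        columns=["spot_id", "cell_id", "channel", "x", "y", "z", "true_molecules"],
    )


def generate_stack_pair(
    config: SceneConfig, planted: list[PlantedSpot]
) -> tuple[ImageStack, ImageStack, pd.DataFrame]:
    """Render a green/red stack pair with camera noise and the truth table.

    The same ``(config, planted)`` always produces bit-identical
    output: the noise generator is re-seeded from ``config.seed`` on
    every call.
    """
    green_exp, red_exp = expected_photon_field(config, planted)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
    green = ImageStack(_apply_camera(green_exp, config, rng),
                       pixel_size=config.pixel_size, z_spacing=config.z_spacing,
                       channel="green")
    red = ImageStack(_apply_camera(red_exp, config, rng),
                     pixel_size=config.pixel_size, z_spacing=config.z_spacing,
                     channel="red")
    return green, red, truth_table(planted)


def sample_molecule_counts(median: float, sigma_log: float, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Lognormal per-spot molecule counts with the given population median."""
    if median <= 0:
        raise ValueError("median must be positive")
    return median * np.exp(rng.normal(0.0, sigma_log, size=n))


def plant_spot_population(
    config: SceneConfig,
    n_spots: int,
    median_molecules: float,
    sigma_log: float = DEFAULT_SPOT_SIGMA_LOG,
    channel: str = "green",
    partner_offset: float | None = None,
    rng: np.random.Generator | None = None,
    min_separation: float = 14.0,
    start_id: int = 0,
) -> list[PlantedSpot]:
    """Place ``n_spots`` puncta inside cells with a minimum separation.

    Spot centers are uniform within cell disks (continuous
    coordinates), at least ``min_separation`` px from each other and
    clear of the image border; z centers are uniform over the interior
    frames so no planted spot is truncated by the stack.
    """
    if n_spots <= 0:
        raise ValueError("n_spots must be positive")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 13]))
    nz, ny, nx = config.image_shape
    centers = cell_centers(config)
    molecules = sample_molecule_counts(median_molecules, sigma_log, n_spots, rng)
    placed: list[PlantedSpot] = []
    xy: list[tuple[float, float]] = []
    border = 10.0
    # interior axial band: > 2.5 sigma_z from either stack end, so planted
    # spots are neither edge-flagged nor measurably truncated
    z_margin = max(4.0, np.ceil(2.5 * config.psf_sigma_z))
    z_lo, z_hi = z_margin, nz - 1 - z_margin
    if z_lo > z_hi:
        z_lo = z_hi = (nz - 1) / 2.0
    for i in range(n_spots):
        for _attempt in range(10_000):
            cell = int(rng.integers(len(centers)))
            cy, cx = centers[cell]
            r = (config.cell_radius - 5.0) * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            y, x = cy + r * np.sin(theta), cx + r * np.cos(theta)
            if not (border <= x <= nx - 1 - border and border <= y <= ny - 1 - border):
                continue
            if any((x - px) ** 2 + (y - py) ** 2 < min_separation**2 for px, py in xy):
                continue
            z = rng.uniform(z_lo, z_hi)
            placed.append(
                PlantedSpot(spot_id=start_id + i, cell_id=cell,
                            true_molecules=float(molecules[i]), x=x, y=y, z=z,
                            channel=channel, partner_offset=partner_offset)
            )
            xy.append((x, y))
            break
        else:
            raise ValueError(
                f"could not place spot {i} of {n_spots}: scene too crowded for "
                f"min_separation={min_separation}"
            )
    return placed


def generate_two_strain_experiment(
    config: SceneConfig,
    fold_change: float,
    n_spots: tuple[int, int] = (54, 52),
    seed: int | None = None,
    median_molecules: float = 3585.0,
    sigma_log: float = DEFAULT_SPOT_SIGMA_LOG,
) -> dict[str, tuple[ImageStack, ImageStack, pd.DataFrame]]:
    """Two strains differing by a planted fold-change in spot brightness.

    Strain ``"A"`` is the control (median ``median_molecules``); strain
    ``"B"`` carries ``fold_change`` times that median, emulating a
    receptor-knockout strain whose cargo puncta grow brighter.  Each
    strain gets its own independently seeded field.
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    nA, nB = n_spots
    if nA <= 0 or nB <= 0:
        raise ValueError("spot counts must be positive")
    base_seed = config.seed if seed is None else int(seed)
    out: dict[str, tuple[ImageStack, ImageStack, pd.DataFrame]] = {}
    for k, (label, n, median) in enumerate(
        [("A", nA, median_molecules), ("B", nB, fold_change * median_molecules)]
    ):
        child = int(np.random.SeedSequence([base_seed, 17 + k]).generate_state(1)[0] % 2**31)
        cfg = SceneConfig(**{**config.__dict__, "seed": child})
        rng = np.random.default_rng(np.random.SeedSequence([child, 13]))
        planted = plant_spot_population(cfg, n, median, sigma_log=sigma_log, rng=rng)
        out[label] = generate_stack_pair(cfg, planted)
    return out


def scene_config_for(n_spots: int, seed: int, z_frames: int = 21) -> SceneConfig:
    """A scene sized so ``n_spots`` fit at the default spot separation.

    Picks one of three field-of-view tiers; spot capacity is limited by
    the total cell area and the 14 px hard-core separation used by
    :func:`plant_spot_population`.
    """
    if n_spots <= 36:
        shape, n_cells, radius = (z_frames, 256, 256), 9, 28.0
    elif n_spots <= 120:
        shape, n_cells, radius = (z_frames, 384, 384), 16, 34.0
    else:
        shape, n_cells, radius = (z_frames, 448, 448), 25, 40.0
    return SceneConfig(seed=int(seed), image_shape=shape, n_cells=n_cells,
                       cell_radius=radius)


def generate_counting_stacks(
    n_spots: int,
    median_molecules: float,
    seed: int,
    sigma_log: float = DEFAULT_SPOT_SIGMA_LOG,
    with_partner: bool = True,
    z_frames: int = 21,
) -> tuple[ImageStack, ImageStack, pd.DataFrame]:
    """One molecule-counting field: ``n_spots`` green puncta at a given
    median copy number, optionally with coincident red marker partners
    (so the colocalization gate passes them)."""
    config = scene_config_for(n_spots, seed, z_frames)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    planted = plant_spot_population(
        config, n_spots, median_molecules, sigma_log=sigma_log,
        partner_offset=0.0 if with_partner else None, rng=rng)
    return generate_stack_pair(config, planted)


@dataclass
class ChainFieldConfig:
    """Layout parameters of a synthetic EM particle coordinate field.

    ``chain_length_pmf`` gives the probability of planting an assembly
    of 1, 2, 3 or "multiple" (>= 4) dodecamers; the multiple class
    draws its actual size as ``4 + Poisson(1)``.  Particles are 18 nm
    dodecamers; chained particles sit one diameter apart with Gaussian
    positional jitter.
    """

    seed: int = 0
    field_size: tuple[float, float] = (4000.0, 4000.0)  # nm (x, y)
    n_particles: int = 3100
    particle_diameter: float = 18.0
    chain_length_pmf: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.1, 4: 0.1}
    )
    jitter_sd: float = 1.0
    n_micrographs: int = 20

    def validate(self) -> None:
        if self.particle_diameter <= 0:
            raise ValueError("particle_diameter must be positive")
        if self.n_particles <= 0 or self.n_micrographs <= 0:
            raise ValueError("counts must be positive")
        if set(self.chain_length_pmf) - {1, 2, 3, 4}:
            raise ValueError("chain_length_pmf keys must be in {1, 2, 3, 4}")
        total = sum(self.chain_length_pmf.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"chain_length_pmf sums to {total}, expected 1")
        if any(p < 0 for p in self.chain_length_pmf.values()):
            raise ValueError("probabilities must be non-negative")


def _draw_assembly_sizes(config: ChainFieldConfig,
                         rng: np.random.Generator) -> list[int]:
    """Assembly sizes summing exactly to ``n_particles``.

    The last draw is truncated to the remaining particle budget so the
    field always carries the configured particle count.
    """
    classes = sorted(config.chain_length_pmf)
    probs = np.array([config.chain_length_pmf[c] for c in classes])
    sizes: list[int] = []
    remaining = config.n_particles
    while remaining > 0:
        cls = int(rng.choice(classes, p=probs))
        size = cls if cls < 4 else 4 + int(rng.poisson(1.0))
        sizes.append(min(size, remaining))
        remaining -= sizes[-1]
    return sizes


def generate_chain_field(config: ChainFieldConfig) -> pd.DataFrame:
    """Lay out particle chains on micrograph-like coordinate fields.

    Within an assembly, consecutive particles sit one particle diameter
    apart along a random direction (plus jitter); distinct assemblies
    are kept more than two diameters apart so single-linkage clustering
    at the default threshold recovers the planted partition exactly.

    Returns a table with columns ``micrograph_id, particle_id, x_nm,
    y_nm, assembly_id, assembly_size``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 19]))
    sizes = _draw_assembly_sizes(config, rng)
    w, h = config.field_size
    d = config.particle_diameter
    rows = []
    placed_xy: dict[int, list[np.ndarray]] = {m: [] for m in range(config.n_micrographs)}
    for aid, size in enumerate(sizes):
        mic = aid % config.n_micrographs
        half_len = (size - 1) * d / 2 + d
        if 2 * half_len >= min(w, h):
            raise ValueError(
                f"field {config.field_size} too small for an assembly of {size} particles"
            )
        existing = placed_xy[mic]
        arr = np.array(existing) if existing else None
        for _attempt in range(5_000):
            theta = rng.uniform(0, 2 * np.pi)
            u = np.array([np.cos(theta), np.sin(theta)])
            anchor = rng.uniform([half_len, half_len], [w - half_len, h - half_len])
            pts = anchor + np.arange(size)[:, None] * d * u
            pts = pts - (size - 1) * d / 2 * u  # center the chain on the anchor
            # jitter clipped at 1.5 sd: chain neighbours then never drift past
            # the 20%-tolerance link distance, keeping planted chains recoverable
            jitter = rng.normal(0, config.jitter_sd, size=pts.shape)
            np.clip(jitter, -1.5 * config.jitter_sd, 1.5 * config.jitter_sd, out=jitter)
            pts = pts + jitter
            if arr is not None:
                dmin = np.sqrt(
                    ((pts[:, None, :] - arr[None, :, :]) ** 2).sum(axis=2)
                ).min()
                if dmin <= 2 * d:
                    continue
            break
        else:
            raise ValueError(
                f"field {config.field_size} too small to place {config.n_particles} "
                f"particles without violating the separation constraint"
            )
        for p in pts:
            rows.append({"micrograph_id": mic, "particle_id": len(rows),
                         "x_nm": float(p[0]), "y_nm": float(p[1]),
                         "assembly_id": aid, "assembly_size": size})
        placed_xy[mic].extend(list(pts))
    return pd.DataFrame(
        rows, columns=["micrograph_id", "particle_id", "x_nm", "y_nm",
                       "assembly_id", "assembly_size"]
    )
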