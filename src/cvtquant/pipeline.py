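"""End-to-end pipeline: stacks -> spots -> molecule counts -> stoichiometry.

Ties the measurement chain together under a single configuration
object whose defaults are the package's recorded analysis choices
(median kernel 21 px, detection at 5 robust noise SDs with 4 px
minimum area, 300 nm colocalization gate, Nuf2 calibration standard,
dodecamer/tetramer/trimer oligomer states).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import cvtquant
from cvtquant import io as cio
from cvtquant.calibration import (
    CalibrationStandard,
    estimate_abundance,
    z_test,
)
from cvtquant.imaging import ImageStack, quantify_stack_pair
from cvtquant.stoichiometry import (
    OligomerSpec,
    fold_excess,
    oligomer_counts,
    stoichiometric_ratio,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "validate_config",
    "config_hash",
    "spot_intensities",
    "run_stoichiometry_pipeline",
    "simulate_study_bundle",
]


class PipelineError(RuntimeError):
    """A pipeline stage produced no usable data."""


@dataclass
class PipelineConfig:
    """All parameters of the stoichiometry pipeline, with defaults."""

    kernel: int = 21
    threshold_k: float = 5.0
    min_area: int = 4
    coloc_distance: float = 300.0   # nm
    link_distance: float = 21.6     # nm, EM aggregation
    method: str = "integrated"      # or "brightest"
    seed: int = 0
    calibration_name: str = "Nuf2"
    calibration_molecules: float = 280.6
    calibration_sd: float = 16.1
    oligomer_subunits: dict[str, int] = field(
        default_factory=lambda: {"prApe1": 12, "Ams1": 4, "Atg19": 3}
    )
    ratio_reference: str = "Atg19"
    # protein -> {"green": path, "red": path or None}
    proteins: dict[str, dict[str, str | None]] = field(default_factory=dict)
    reference_stack: str | None = None
    output_dir: str = "results"

    def standard(self) -> CalibrationStandard:
        return CalibrationStandard(self.calibration_name,
                                   self.calibration_molecules, self.calibration_sd)

    def specs(self) -> tuple[OligomerSpec, ...]:
        return tuple(OligomerSpec(p, k) for p, k in self.oligomer_subunits.items())

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def validate_config(path) -> PipelineConfig:
    """Load, default-fill and normalize a YAML pipeline config.

    An empty file yields all defaults; an even median kernel is
    normalized to the next odd size with a warning; negative distances
    are rejected.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = PipelineConfig(**raw)
    if cfg.kernel % 2 == 0:
        logger.warning("config kernel %d is even; normalized to %d",
                       cfg.kernel, cfg.kernel + 1)
        cfg.kernel += 1
    if cfg.coloc_distance < 0 or cfg.link_distance <= 0:
        raise ValueError("distances must be positive")
    if cfg.method not in ("integrated", "brightest"):
        raise ValueError(f"method must be 'integrated' or 'brightest', got {cfg.method!r}")
    return cfg


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the effective configuration, embedded in outputs."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def spot_intensities(spots: pd.DataFrame, method: str = "integrated",
                     require_coloc: bool = True) -> np.ndarray:
    """Usable intensities from a spot table: drop edge-of-stack spots,
    optionally keep only gated (colocalized) ones."""
    column = {"integrated": "intensity_integrated",
              "brightest": "intensity_brightest"}[method]
    keep = ~spots["edge_flag"].astype(bool)
    if require_coloc:
        keep &= spots["coloc_flag"].astype(bool)
    values = spots.loc[keep, column].to_numpy(dtype=float)
    return values[np.isfinite(values) & (values > 0)]


def _load_stack(path, what: str) -> ImageStack:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} stack not found: {p}")
    try:
        return ImageStack.from_tiff(p)
    except ValueError as exc:
        raise PipelineError(f"{what} stack unreadable: {exc}") from exc


def run_stoichiometry_pipeline(config: PipelineConfig) -> dict:
    """Run stacks -> gated intensities -> abundances -> stoichiometry.

    Writes per-protein spot tables, the abundance table and a JSON
    summary under ``config.output_dir`` and returns the summary dict.
    """
    if not config.proteins or config.reference_stack is None:
        raise PipelineError("config must list protein stacks and a reference stack")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    ref_stack = _load_stack(config.reference_stack, "reference")
    ref_spots = quantify_stack_pair(
        ref_stack, None, kernel=config.kernel, threshold_k=config.threshold_k,
        min_area=config.min_area, coloc_distance=config.coloc_distance)
    cio.write_table(ref_spots, out / "spots_reference.csv", cio.SPOT_SCHEMA)
    ref_intens = spot_intensities(ref_spots, config.method, require_coloc=False)
    if ref_intens.size < 2:
        raise PipelineError("empty reference spot set after gating")

    abundances = []
    for protein, paths in config.proteins.items():
        green = _load_stack(paths["green"], f"{protein} green")
        red = _load_stack(paths["red"], f"{protein} red") if paths.get("red") else None
        spots = quantify_stack_pair(
            green, red, kernel=config.kernel, threshold_k=config.threshold_k,
            min_area=config.min_area, coloc_distance=config.coloc_distance)
        cio.write_table(spots, out / f"spots_{protein}.csv", cio.SPOT_SCHEMA)
        intens = spot_intensities(spots, config.method, require_coloc=red is not None)
        if intens.size < 2:
            raise PipelineError(f"empty gated spot set for {protein}")
        abundances.append(
            estimate_abundance(intens, ref_intens, protein,
                               standard=config.standard(), method=config.method)
        )

    counts = oligomer_counts(abundances, config.specs())
    ratio = stoichiometric_ratio(counts, config.ratio_reference)
    by_protein = {a.protein: a for a in abundances}
    excesses = {}
    proteins = list(by_protein)
    for i, pa in enumerate(proteins):
        for pb in proteins[i + 1:]:
            f, r = fold_excess(by_protein[pa].molecules, by_protein[pb].molecules)
            excesses[f"{pa}_over_{pb}"] = {"fold": f, "rounded": r}
    ztests = {}
    for i, pa in enumerate(proteins):
        for pb in proteins[i + 1:]:
            z, p = z_test(by_protein[pa].molecules, by_protein[pa].sem,
                          by_protein[pb].molecules, by_protein[pb].sem)
            ztests[f"{pa}_vs_{pb}"] = {"z": z, "p": p}

    abundance_df = pd.DataFrame(
        [dataclasses.asdict(a) for a in abundances]
    )
    cio.write_table(abundance_df, out / "abundances.csv")
    summary = {
        "version": cvtquant.__version__,
        "config_hash": config_hash(config),
        "method": config.method,
        "abundances": {a.protein: {"molecules": a.molecules, "sem": a.sem,
                                   "n_spots": a.n_spots} for a in abundances},
        "oligomer_counts": {p: {"count": c, "sem": s} for p, (c, s) in counts.items()},
        "stoichiometric_ratios": ratio.ratios,
        "ratio_string": ratio.ratio_string,
        "fold_excess": excesses,
        "z_tests": ztests,
    }
    cio.write_json(summary, out / "stoichiometry_summary.json")
    logger.info("pipeline complete: %s", ratio.ratio_string)
    return summary


def simulate_study_bundle(out_dir, seed: int = 0, scale: float = 1.0,
                          sigma_log: float | None = None,
                          z_frames: int = 21) -> PipelineConfig:
    """Write a complete synthetic input bundle for the pipeline.

    Generates one stack pair per protein at the molecule abundances and
    spot counts of the in-vivo counting design, plus a reference stack
    of Nuf2-level spots, and a matching ``config.yaml``.  ``scale``
    shrinks the spot counts for quick runs.
    """
    from cvtquant import simulate as sim

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = {
        "prApe1": (217, 3585.0),
        "Ams1": (181, 501.0),
        "Atg19": (233, 332.0),
    }
    cfg = PipelineConfig(seed=int(seed), output_dir=str(out / "results"))
    proteins: dict[str, dict[str, str | None]] = {}
    for k, (protein, (n_full, median)) in enumerate(design.items()):
        n = max(8, int(round(n_full * scale)))
        green, red, truth = sim.generate_counting_stacks(
            n_spots=n, median_molecules=median,
            seed=int(np.random.SeedSequence([int(seed), 23 + k]).generate_state(1)[0] % 2**31),
            sigma_log=sim.DEFAULT_SPOT_SIGMA_LOG if sigma_log is None else sigma_log,
            with_partner=True, z_frames=z_frames)
        gpath, rpath = out / f"{protein}_green.tif", out / f"{protein}_red.tif"
        green.to_tiff(gpath)
        red.to_tiff(rpath)
        cio.write_table(truth, out / f"{protein}_truth.csv", cio.TRUTH_SCHEMA)
        proteins[protein] = {"green": str(gpath), "red": str(rpath)}
    n_ref = max(8, int(round(98 * scale)))
    ref_green, _, ref_truth = sim.generate_counting_stacks(
        n_spots=n_ref, median_molecules=280.6,
        seed=int(np.random.SeedSequence([int(seed), 29]).generate_state(1)[0] % 2**31),
        sigma_log=sim.REFERENCE_SIGMA_LOG, with_partner=False, z_frames=z_frames)
    ref_path = out / "reference_green.tif"
    ref_green.to_tiff(ref_path)
    cio.write_table(ref_truth, out / "reference_truth.csv", cio.TRUTH_SCHEMA)
    cfg.proteins = proteins
    cfg.reference_stack = str(ref_path)
    cfg.to_yaml(out / "config.yaml")
    return cfg
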