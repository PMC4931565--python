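"""Synthetic replications of the in-vivo quantification experiments.

Each function rebuilds one of the study designs entirely from the
synthetic generator — planting the reported effect as ground truth —
and runs the full measurement pipeline on the rendered stacks, so the
recovered numbers test the whole chain (background subtraction,
detection, gating, intensity measurement, calibration, robust
statistics) and not any single stage.
"""

from __future__ import annotations

import numpy as np

from cvtquant import simulate as sim
from cvtquant.calibration import (
    NUF2_STANDARD,
    estimate_abundance,
    fold_change,
)
from cvtquant.imaging import quantify_stack_pair
from cvtquant.pipeline import spot_intensities

__all__ = ["fold_change_recovery", "molecule_count_recovery"]


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % 2**31)


def _reference_intensities(n: int, seed: int, method: str,
                           z_frames: int) -> np.ndarray:
    green, _, _ = sim.generate_counting_stacks(
        n_spots=n, median_molecules=NUF2_STANDARD.molecules_per_structure,
        seed=seed, sigma_log=sim.REFERENCE_SIGMA_LOG, with_partner=False,
        z_frames=z_frames)
    spots = quantify_stack_pair(green, None)
    return spot_intensities(spots, method, require_coloc=False)


def fold_change_recovery(
    seed: int,
    planted_fold: float = 2.3,
    n_spots: tuple[int, int] = (54, 52),
    n_refs: tuple[int, int] = (80, 98),
    median_molecules: float = 3585.0,
    z_frames: int = 23,
) -> dict:
    """Two-strain brightness experiment with a planted fold-change.

    Renders a control strain and a knockout-like strain whose planted
    median spot brightness is ``planted_fold`` times higher, each with
    its own calibration field of Nuf2-level reference spots, then
    recovers the fold-change with the brightest-frame ROI method and
    per-strain reference normalization.
    """
    scene = sim.scene_config_for(max(n_spots), seed=0, z_frames=z_frames)
    strains = sim.generate_two_strain_experiment(
        scene, planted_fold, n_spots, seed=seed,
        median_molecules=median_molecules)
    measured = {}
    planted_median = {}
    for label, (green, _red, truth) in strains.items():
        spots = quantify_stack_pair(green, None)
        measured[label] = spot_intensities(spots, "brightest", require_coloc=False)
        planted_median[label] = float(np.median(truth["true_molecules"]))
    refs = [
        _reference_intensities(n, _child_seed(seed, 31 + k), "brightest", z_frames)
        for k, n in enumerate(n_refs)
    ]
    ratio, sem = fold_change(measured["A"], measured["B"], (refs[0], refs[1]))
    return {
        "recovered_fold": float(ratio),
        "sem": float(sem),
        "planted_fold": float(planted_fold),
        "planted_sample_fold": planted_median["B"] / planted_median["A"],
        "n_spots": [int(measured["A"].size), int(measured["B"].size)],
        "n_refs": [int(r.size) for r in refs],
    }


def molecule_count_recovery(
    seed: int,
    n_target: int = 217,
    median_molecules: float = 3585.0,
    n_ref: int = 98,
    protein: str = "prApe1",
    z_frames: int = 21,
) -> dict:
    """Calibrated molecule counting with a planted copy-number median.

    Plants ``n_target`` marker-colocalized puncta at the given median
    copy number next to a calibration field of reference spots at the
    standard's copy number, then runs detect -> gate -> integrate ->
    calibrate and reports the recovered median molecules per punctum.
    """
    green, red, truth = sim.generate_counting_stacks(
        n_spots=n_target, median_molecules=median_molecules,
        seed=_child_seed(seed, 37), with_partner=True, z_frames=z_frames)
    spots = quantify_stack_pair(green, red)
    intensities = spot_intensities(spots, "integrated", require_coloc=True)
    ref = _reference_intensities(n_ref, _child_seed(seed, 41), "integrated", z_frames)
    est = estimate_abundance(intensities, ref, protein, method="integrated")
    return {
        "molecules": est.molecules,
        "sem": est.sem,
        "planted_median": float(median_molecules),
        "planted_sample_median": float(np.median(truth["true_molecules"])),
        "n_spots": est.n_spots,
        "n_ref": int(ref.size),
    }
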