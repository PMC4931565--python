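"""Oligomer counts and stoichiometric ratios from molecule counts.

Per-punctum molecule counts divide by the known oligomeric state of
each protein (prApe1 dodecamer, Ams1 tetramer, Atg19 trimer) to give
oligomer counts, which are then expressed as ratios to a reference
protein and rounded half-up for the conventional "a:b:c" string.
Ratios describe population averages over many puncta, not
well-defined individual complexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from cvtquant.calibration import AbundanceEstimate

__all__ = [
    "OligomerSpec",
    "StoichiometryResult",
    "DEFAULT_OLIGOMER_SPECS",
    "round_half_up",
    "oligomer_counts",
    "stoichiometric_ratio",
    "fold_excess",
]


@dataclass(frozen=True)
class OligomerSpec:
    protein: str
    subunits_per_oligomer: int

    def __post_init__(self) -> None:
        if self.subunits_per_oligomer < 1:
            raise ValueError("subunits_per_oligomer must be >= 1")


DEFAULT_OLIGOMER_SPECS = (
    OligomerSpec("prApe1", 12),
    OligomerSpec("Ams1", 4),
    OligomerSpec("Atg19", 3),
)


@dataclass
class StoichiometryResult:
    """Oligomer counts per punctum, ratios to a reference protein and
    the rounded ratio string (e.g. ``"3:1:1"``)."""

    counts: dict[str, tuple[float, float]]   # protein -> (oligomers, sem)
    reference: str
    ratios: dict[str, float]
    ratio_string: str


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves going up (2.5 -> 3)."""
    return int(math.floor(x + 0.5))


def oligomer_counts(
    abundances: list[AbundanceEstimate] | dict[str, tuple[float, float]],
    specs: tuple[OligomerSpec, ...] = DEFAULT_OLIGOMER_SPECS,
) -> dict[str, tuple[float, float]]:
    """Molecules per punctum -> oligomers per punctum.

    Accepts either :class:`AbundanceEstimate` objects or a mapping
    ``protein -> (molecules, sem)``; the SEM scales by the same
    subunit divisor.
    """
    by_protein = {s.protein: s.subunits_per_oligomer for s in specs}
    if isinstance(abundances, dict):
        items = [(p, m, sem) for p, (m, sem) in abundances.items()]
    else:
        items = [(a.protein, a.molecules, a.sem) for a in abundances]
    out: dict[str, tuple[float, float]] = {}
    for protein, molecules, sem in items:
        if protein not in by_protein:
            raise KeyError(f"no oligomer spec for protein {protein!r}")
        k = by_protein[protein]
        out[protein] = (molecules / k, sem / k)
    return out


def stoichiometric_ratio(
    counts: dict[str, tuple[float, float]] | dict[str, float],
    reference: str,
) -> StoichiometryResult:
    """Express oligomer counts relative to ``reference``.

    The ratio string lists proteins in input order with each float
    ratio rounded half-up.
    """
    values = {
        p: (v[0] if isinstance(v, tuple) else float(v)) for p, v in counts.items()
    }
    if reference not in values:
        raise KeyError(f"reference protein {reference!r} not among counts")
    ref = values[reference]
    if ref <= 0:
        raise ValueError("reference count must be positive")
    ratios = {p: v / ref for p, v in values.items()}
    ratio_string = ":".join(str(round_half_up(r)) for r in ratios.values())
    norm_counts = {
        p: (v if isinstance(v, tuple) else (float(v), 0.0)) for p, v in counts.items()
    }
    return StoichiometryResult(counts=norm_counts, reference=reference,
                               ratios=ratios, ratio_string=ratio_string)


def fold_excess(molecules_a: float, molecules_b: float) -> tuple[float, int]:
    """Fold excess of a over b, as a float and its rounded integer."""
    if molecules_b <= 0:
        raise ValueError("molecules_b must be positive")
    r = molecules_a / molecules_b
    return r, round_half_up(r)
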