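"""Morphometric summaries of correlated light/EM vesicle sites.

Each correlated site carries a biogenesis category — cytoplasmic
aggregate without membrane, partially membrane-enwrapped aggregate,
double-membrane vesicle, autophagosome, or excluded (poorly
preserved) — and, where measurable, cross-section dimensions and the
double-membrane width.  Summaries report category fractions over the
non-excluded sites, mean cross-section dimensions, ellipticity
(flattening, ``(max - min) / max``), and membrane-width statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cvtquant.stoichiometry import round_half_up

__all__ = [
    "VesicleSite",
    "CATEGORIES",
    "MEMBRANOUS_CATEGORIES",
    "ellipticity",
    "summarize_sites",
    "mean_sd",
]

CATEGORIES = (
    "aggregate_no_membrane",
    "partial_membrane",
    "double_membrane_vesicle",
    "autophagosome",
)
#: Categories whose sites contain membrane structures.
MEMBRANOUS_CATEGORIES = ("partial_membrane", "double_membrane_vesicle", "autophagosome")


@dataclass
class VesicleSite:
    """One correlated CLEM site."""

    site_id: int
    category: str
    x_dim: float | None = None   # nm
    y_dim: float | None = None   # nm
    membrane_width: float | None = None  # nm

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES + ("excluded",):
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "excluded" and (self.x_dim or self.y_dim):
            raise ValueError("excluded sites carry no dimensions")
        for d in (self.x_dim, self.y_dim, self.membrane_width):
            if d is not None and d <= 0:
                raise ValueError("dimensions must be positive when present")


def ellipticity(x_dim: float, y_dim: float) -> float:
    """Flattening of a cross-section: ``(max - min) / max``, in [0, 1)."""
    if x_dim <= 0 or y_dim <= 0:
        raise ValueError("dimensions must be positive")
    lo, hi = sorted((x_dim, y_dim))
    return (hi - lo) / hi


def mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n - 1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a sample SD")
    return float(arr.mean()), float(arr.std(ddof=1))


def _to_sites(sites) -> list[VesicleSite]:
    if isinstance(sites, pd.DataFrame):
        out = []
        for _, row in sites.iterrows():
            def _get(col):
                v = row.get(col)
                return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
            out.append(VesicleSite(site_id=int(row["site_id"]),
                                   category=str(row["category"]),
                                   x_dim=_get("x_nm"), y_dim=_get("y_nm"),
                                   membrane_width=_get("membrane_width_nm")))
        return out
    return list(sites)


def summarize_sites(sites) -> dict:
    """Summary statistics over a collection of CLEM sites.

    Accepts :class:`VesicleSite` objects or a DataFrame with columns
    ``site_id, category, x_nm, y_nm, membrane_width_nm``.  Fractions
    are over non-excluded sites, with percentages rounded half-up to
    integers; dimensions are averaged over sites that carry them.
    """
    site_list = _to_sites(sites)
    if not site_list:
        raise ValueError("no sites given")
    kept = [s for s in site_list if s.category != "excluded"]
    if not kept:
        raise ValueError("all sites excluded")
    n = len(kept)
    cat_counts = {c: sum(1 for s in kept if s.category == c) for c in CATEGORIES}
    cat_pct = {c: round_half_up(100.0 * k / n) for c, k in cat_counts.items()}
    n_membranous = sum(cat_counts[c] for c in MEMBRANOUS_CATEGORIES)
    dims = [(s.x_dim, s.y_dim) for s in kept if s.x_dim and s.y_dim]
    widths = [s.membrane_width for s in kept if s.membrane_width]
    summary = {
        "n_sites_total": len(site_list),
        "n_sites_excluded": len(site_list) - n,
        "n_sites": n,
        "category_counts": cat_counts,
        "category_percent": cat_pct,
        "n_membranous": n_membranous,
        "membranous_percent": round_half_up(100.0 * n_membranous / n),
    }
    if dims:
        xs, ys = np.array([d[0] for d in dims]), np.array([d[1] for d in dims])
        summary["mean_x_nm"] = float(xs.mean())
        summary["mean_y_nm"] = float(ys.mean())
        summary["mean_ellipticity"] = float(
            np.mean([ellipticity(x, y) for x, y in dims])
        )
        summary["ellipticity_of_mean_dims"] = ellipticity(float(xs.mean()), float(ys.mean()))
    if len(widths) >= 2:
        m, sd = mean_sd(widths)
        summary["membrane_width_mean_nm"] = m
        summary["membrane_width_sd_nm"] = sd
        summary["n_membrane_width"] = len(widths)
    return summary
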