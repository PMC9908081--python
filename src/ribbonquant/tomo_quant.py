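"""Synaptic-vesicle pool classification and per-ribbon aggregation.

Vesicles annotated in electron tomograms of inner-hair-cell ribbon
synapses are classified against the active-zone (AZ) membrane, the
presynaptic density (PD) and the ribbon:

* **MP** (membrane-proximal): first-row vesicles with outer-edge
  distance ≤ 50 nm to the AZ membrane and lateral distance ≤ 100 nm to
  the PD; sub-pools *docked* (≤ 2 nm to the membrane), *tethered*
  (filament annotations present) and *non-tethered*.
* **RA** (ribbon-associated): first-row vesicles ≤ 80 nm from the ribbon
  surface, excluding vesicles already in the MP pool; sub-pools by
  filament targets (none / ribbon-attached / interconnected / both).

Distances are measured from the vesicle's outer layer (center distance
minus radius, floored at 0) to the exact nearest point of the structure.
"First row" is operationalized as an occlusion test: a candidate
qualifies iff the segment from its outer edge to its nearest point on
the target structure passes through no other vesicle's sphere.

All thresholds are closed intervals (≤) and configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MissingStructure, SplitUndefined
from .geometry import Surface, fit_plane, segment_intersects_sphere

__all__ = [
    "Vesicle",
    "SynapseModel",
    "PoolAssignment",
    "RibbonSummary",
    "PoolThresholds",
    "outer_edge_distance",
    "lateral_pd_distance",
    "classify_pools",
    "mp_tether_subpools",
    "ribbon_halves",
    "vesicle_diameter",
    "bin_diameters",
    "cc_census",
    "aggregate_condition",
    "DIAMETER_BIN_LABELS",
]

CONDITIONS = ("B6J_Light", "ChR2_NoLight", "ChR2_ShortStim", "ChR2_LongStim", "custom")

#: Valid filament/tether targets.
TETHER_TARGETS = ("membrane", "pd", "vesicle", "ribbon")


@dataclass
class Vesicle:
    """One annotated vesicle sphere (or irregular CC structure)."""

    id: str
    center_nm: np.ndarray
    radius_nm: float
    shape: str = "sphere"  # sphere | irregular
    long_axis_nm: float | None = None
    short_axis_nm: float | None = None
    tethers: list[str] = field(default_factory=list)  # tether targets
    clathrin_coated: bool = False

    def __post_init__(self) -> None:
        self.center_nm = np.asarray(self.center_nm, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.center_nm)):
            raise ValueError("vesicle center must be finite")
        if self.radius_nm <= 0:
            raise ValueError("vesicle radius must be > 0")
        if self.shape == "irregular":
            if self.long_axis_nm is None or self.short_axis_nm is None:
                raise ValueError("irregular vesicles need long and short axes")
            if self.long_axis_nm < self.short_axis_nm:
                raise ValueError("long axis must be >= short axis")
        bad = [t for t in self.tethers if t not in TETHER_TARGETS]
        if bad:
            raise ValueError(f"unknown tether targets: {bad}")


@dataclass
class SynapseModel:
    """3D annotation model of one ribbon synapse (coordinates in nm)."""

    model_id: str
    az_membrane: Surface
    pd: Surface | None = None
    ribbon: Surface | None = None
    vesicles: list[Vesicle] = field(default_factory=list)
    condition: str = "custom"
    voxel_nm: float = 1.18

    def __post_init__(self) -> None:
        if self.voxel_nm <= 0:
            raise ValueError("voxel_nm must be > 0")
        if self.az_membrane is None or self.az_membrane.is_empty:
            raise ValueError("az_membrane must be non-empty")


@dataclass(frozen=True)
class PoolThresholds:
    """Distance cutoffs (nm) for the pool definitions; closed intervals."""

    mp_membrane_max: float = 50.0
    mp_pd_lateral_max: float = 100.0
    docked_max: float = 2.0
    ra_ribbon_max: float = 80.0


@dataclass
class PoolAssignment:
    vesicle_id: str
    pool: str  # MP | RA | none
    mp_subpool: str | None = None  # docked | tethered | non_tethered
    ra_subpool: str | None = None  # no_filaments | ribbon_attached | interconnected | attached_and_interconnected
    d_membrane_nm: float | None = None
    d_pd_lateral_nm: float | None = None
    d_ribbon_nm: float | None = None
    ribbon_half: str | None = None  # proximal | distal (non-MP bookkeeping)
    diameter_nm: float | None = None
    clathrin_coated: bool = False


def vesicle_diameter(v: Vesicle) -> float:
    """Vesicle diameter D: 2r for spheres, mean of long and short axes
    for irregular structures."""
    if v.shape == "irregular":
        return (v.long_axis_nm + v.short_axis_nm) / 2.0
    return 2.0 * v.radius_nm


def outer_edge_distance(v: Vesicle, surface: Surface) -> float:
    """Distance (nm) from the vesicle's outer layer to the surface."""
    if surface is None or surface.is_empty:
        raise MissingStructure("surface is empty")
    _, d = surface.closest_points(v.center_nm[None, :])
    return max(0.0, float(d[0]) - v.radius_nm)


def lateral_pd_distance(
    v: Vesicle,
    pd: Surface,
    az_membrane: Surface,
    neighborhood_nm: float = 150.0,
) -> float:
    """Lateral (in-membrane-plane) distance from the vesicle's outer edge
    to the nearest PD point.

    The local AZ plane is a principal-component fit of the membrane
    vertices within ``neighborhood_nm`` of the vesicle (all vertices if
    too few); vesicle center and PD points are projected onto it and the
    2D distance, minus the vesicle radius, is reported (floored at 0).
    """
    if pd is None or pd.is_empty:
        raise MissingStructure("PD is empty")
    if az_membrane is None or az_membrane.is_empty:
        raise MissingStructure("az_membrane is empty")
    mem = az_membrane.vertices
    near = mem[np.linalg.norm(mem - v.center_nm, axis=1) <= neighborhood_nm]
    if near.shape[0] < 3:
        near = mem
    origin, u, w = fit_plane(near)

    def project(pts: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(pts) - origin
        return np.column_stack([rel @ u, rel @ w])

    c2d = project(v.center_nm)[0]
    pd2d = project(pd.vertices)
    d = float(np.min(np.linalg.norm(pd2d - c2d, axis=1)))
    return max(0.0, d - v.radius_nm)


def _outer_edge_segment(v: Vesicle, surface: Surface) -> tuple[np.ndarray, np.ndarray]:
    """Segment from the vesicle's nearest-to-surface point on its sphere
    to the nearest point on the surface."""
    closest, d = surface.closest_points(v.center_nm[None, :])
    target = closest[0]
    dist = float(d[0])
    if dist <= v.radius_nm or dist == 0:
        return v.center_nm.copy(), target
    start = v.center_nm + (target - v.center_nm) * (v.radius_nm / dist)
    return start, target


def _is_first_row(v: Vesicle, surface: Surface, others: Sequence[Vesicle]) -> bool:
    p0, p1 = _outer_edge_segment(v, surface)
    for o in others:
        if o is v:
            continue
        if segment_intersects_sphere(p0, p1, o.center_nm, o.radius_nm):
            return False
    return True


def classify_pools(
    model: SynapseModel,
    thresholds: PoolThresholds = PoolThresholds(),
    first_row: str = "occlusion",
) -> list[PoolAssignment]:
    """Assign every vesicle to MP, RA or no pool.

    ``first_row`` is ``"occlusion"`` (segment-to-structure occlusion
    test) or ``"none"`` (thresholds only).  Clathrin-coated structures
    are never pooled (they are censused separately).  A missing ribbon
    leaves the RA fields null; MP is still computed.
    """
    if first_row not in ("occlusion", "none"):
        raise ValueError("first_row must be 'occlusion' or 'none'")
    mem = model.az_membrane
    have_pd = model.pd is not None and not model.pd.is_empty
    have_ribbon = model.ribbon is not None and not model.ribbon.is_empty

    out: list[PoolAssignment] = []
    for v in model.vesicles:
        d_mem = outer_edge_distance(v, mem)
        d_pd = (
            lateral_pd_distance(v, model.pd, mem) if have_pd else None
        )
        d_rib = outer_edge_distance(v, model.ribbon) if have_ribbon else None

        a = PoolAssignment(
            vesicle_id=v.id,
            pool="none",
            d_membrane_nm=d_mem,
            d_pd_lateral_nm=d_pd,
            d_ribbon_nm=d_rib,
            diameter_nm=vesicle_diameter(v),
            clathrin_coated=v.clathrin_coated,
        )
        if v.clathrin_coated:
            out.append(a)
            continue

        is_mp = d_mem <= thresholds.mp_membrane_max and (
            d_pd is None or d_pd <= thresholds.mp_pd_lateral_max
        )
        if is_mp and first_row == "occlusion":
            is_mp = _is_first_row(v, mem, model.vesicles)
        if is_mp:
            a.pool = "MP"
            if d_mem <= thresholds.docked_max:
                a.mp_subpool = "docked"
            elif v.tethers:
                a.mp_subpool = "tethered"
            else:
                a.mp_subpool = "non_tethered"
        elif have_ribbon and d_rib is not None and d_rib <= thresholds.ra_ribbon_max:
            is_ra = True
            if first_row == "occlusion":
                is_ra = _is_first_row(v, model.ribbon, model.vesicles)
            if is_ra:
                a.pool = "RA"
                targets = set(v.tethers)
                attached = "ribbon" in targets
                inter = "vesicle" in targets
                if attached and inter:
                    a.ra_subpool = "attached_and_interconnected"
                elif attached:
                    a.ra_subpool = "ribbon_attached"
                elif inter:
                    a.ra_subpool = "interconnected"
                else:
                    a.ra_subpool = "no_filaments"
        out.append(a)
    return out


MP_TETHER_CATEGORIES = (
    "single_membrane_tethered",
    "single_pd_tethered",
    "interconnected",
    "multiple_tethered",
)


def mp_tether_subpools(
    model: SynapseModel, assignments: Sequence[PoolAssignment]
) -> dict[str, float]:
    """Fractions of tethered MP vesicles by tether count and target.

    Categories: single membrane-tethered, single PD-tethered,
    interconnected (tethered to other vesicles only), multiple-tethered
    (two or more tethers).  Fractions are over the tethered MP vesicles
    of this ribbon; all zeros when none are tethered.
    """
    by_id = {v.id: v for v in model.vesicles}
    counts = dict.fromkeys(MP_TETHER_CATEGORIES, 0)
    n = 0
    for a in assignments:
        if a.pool != "MP" or a.mp_subpool != "tethered":
            continue
        v = by_id[a.vesicle_id]
        n += 1
        if len(v.tethers) >= 2:
            counts["multiple_tethered"] += 1
        elif v.tethers == ["membrane"]:
            counts["single_membrane_tethered"] += 1
        elif v.tethers == ["pd"]:
            counts["single_pd_tethered"] += 1
        else:  # single tether to another vesicle (or the ribbon)
            counts["interconnected"] += 1
    if n == 0:
        return {k: 0.0 for k in counts}
    return {k: c / n for k, c in counts.items()}


def ribbon_halves(
    model: SynapseModel,
    assignments: Sequence[PoolAssignment],
) -> dict:
    """Split non-MP vesicles into proximal vs distal ribbon halves.

    The split plane passes through the ribbon centroid with its normal
    along the axis from the centroid to the nearest AZ-membrane point;
    the proximal half is the membrane side.  MP vesicles (and clathrin-
    coated structures) are excluded.  Updates ``ribbon_half`` on the
    assignments and returns per-half counts and mean diameters.
    """
    if model.ribbon is None or model.ribbon.is_empty:
        raise MissingStructure("ribbon is required for the half split")
    centroid = model.ribbon.centroid()
    closest, d = model.az_membrane.closest_points(centroid[None, :])
    axis = closest[0] - centroid
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise SplitUndefined("ribbon centroid lies on the membrane")
    axis = axis / norm
    extent = model.ribbon.vertices @ axis
    if np.ptp(extent) <= 1e-9:
        raise SplitUndefined("ribbon has no extent along the membrane axis")

    by_id = {v.id: v for v in model.vesicles}
    halves = {"proximal": [], "distal": []}
    for a in assignments:
        if a.pool == "MP" or a.clathrin_coated:
            continue
        v = by_id[a.vesicle_id]
        side = float((v.center_nm - centroid) @ axis)
        half = "proximal" if side > 0 else "distal"
        a.ribbon_half = half
        halves[half].append(vesicle_diameter(v))
    return {
        half: {
            "count": len(diams),
            "mean_diameter_nm": float(np.mean(diams)) if diams else None,
        }
        for half, diams in halves.items()
    }


#: Diameter histogram bin edges (nm): ≤40, (40,45], (45,50], (50,55], (55,60], >60
DIAMETER_BIN_LABELS = ("<=40", "(40,45]", "(45,50]", "(50,55]", "(55,60]", ">60")
_DIAMETER_EDGES = (40.0, 45.0, 50.0, 55.0, 60.0)


def bin_diameters(diameters: Sequence[float]) -> dict:
    """Histogram of vesicle diameters in the conventional 5-nm bins."""
    d = np.asarray(list(diameters), dtype=float)
    counts = dict.fromkeys(DIAMETER_BIN_LABELS, 0)
    for x in d:
        if x <= _DIAMETER_EDGES[0]:
            counts["<=40"] += 1
        elif x > _DIAMETER_EDGES[-1]:
            counts[">60"] += 1
        else:
            for lo, hi, lab in zip(
                _DIAMETER_EDGES[:-1], _DIAMETER_EDGES[1:], DIAMETER_BIN_LABELS[1:-1]
            ):
                if lo < x <= hi:
                    counts[lab] += 1
                    break
    n = int(d.size)
    fractions = {k: (c / n if n else 0.0) for k, c in counts.items()}
    return {"counts": counts, "fractions": fractions, "n": n}


def cc_census(
    model: SynapseModel,
    pd_max_nm: float = 500.0,
    near_bin_edge_nm: float = 200.0,
) -> pd.DataFrame:
    """Census of clathrin-coated structures within ``pd_max_nm`` of the PD.

    Reports, per structure, the diameter (outer leaflet, coat excluded —
    the stored radius/axes already exclude the coat), the outer-edge
    distance to the PD (3D) and to the AZ membrane, and the PD-distance
    bin (0–200 or 200–500 nm by default).
    """
    if model.pd is None or model.pd.is_empty:
        raise MissingStructure("PD is required for the CC census")
    rows = []
    for v in model.vesicles:
        if not v.clathrin_coated:
            continue
        d_pd = outer_edge_distance(v, model.pd)
        if d_pd > pd_max_nm:
            continue
        rows.append(
            {
                "model_id": model.model_id,
                "vesicle_id": v.id,
                "diameter_nm": vesicle_diameter(v),
                "d_pd_nm": d_pd,
                "d_membrane_nm": outer_edge_distance(v, model.az_membrane),
                "pd_bin": (
                    f"0-{near_bin_edge_nm:g}"
                    if d_pd <= near_bin_edge_nm
                    else f"{near_bin_edge_nm:g}-{pd_max_nm:g}"
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["model_id", "vesicle_id", "diameter_nm", "d_pd_nm", "d_membrane_nm", "pd_bin"],
    )


@dataclass
class RibbonSummary:
    """Per-condition aggregate of per-ribbon counts and fractions."""

    condition: str
    n_models: int
    per_ribbon: pd.DataFrame  # one row per model
    fraction_stats: dict  # subpool -> {mean, sem, n}
    docked_per_az: float
    mean_distances: dict  # per-vesicle means over MP vesicles
    diameter_hist: dict

    def report(self) -> dict:
        return {
            "condition": self.condition,
            "n_models": self.n_models,
            "docked_per_az": round(self.docked_per_az, 2),
            "total_docked": int(self.per_ribbon["n_docked"].sum()),
            "mp_count_mean": _none_if_nan(self.per_ribbon["n_mp"].mean()),
            "fractions": self.fraction_stats,
            "mean_distances": self.mean_distances,
            "diameter_hist": self.diameter_hist,
        }


def _none_if_nan(x):
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else float(x)


def _mean_sem(values: list[float]) -> dict:
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    n = vals.size
    return {
        "mean": float(vals.mean()) if n else None,
        "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
        "n": int(n),
    }


def aggregate_condition(
    models: Sequence[SynapseModel],
    assignments: Sequence[Sequence[PoolAssignment]] | None = None,
    condition: str | None = None,
    **classify_kwargs,
) -> RibbonSummary:
    """Aggregate pool statistics over the tomograms of one condition.

    Sub-pool fractions are computed per ribbon (null when a ribbon has
    no MP vesicles) and averaged over ribbons with SEM; distances and
    diameters are aggregated per vesicle; ``docked_per_az`` is the total
    docked count divided by the number of tomograms.
    """
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    if assignments is None:
        assignments = [classify_pools(m, **classify_kwargs) for m in models]
    if condition is None:
        condition = models[0].condition

    rows = []
    d_mem_all: list[float] = []
    d_pd_all: list[float] = []
    diam_all: list[float] = []
    for m, asg in zip(models, assignments):
        mp = [a for a in asg if a.pool == "MP"]
        ra = [a for a in asg if a.pool == "RA"]
        n_mp = len(mp)
        n_docked = sum(a.mp_subpool == "docked" for a in mp)
        n_teth = sum(a.mp_subpool == "tethered" for a in mp)
        n_nont = sum(a.mp_subpool == "non_tethered" for a in mp)
        rows.append(
            {
                "model_id": m.model_id,
                "n_vesicles": len(m.vesicles),
                "n_mp": n_mp,
                "n_ra": len(ra),
                "n_docked": n_docked,
                "n_tethered": n_teth,
                "n_non_tethered": n_nont,
                "frac_docked": n_docked / n_mp if n_mp else None,
                "frac_tethered": n_teth / n_mp if n_mp else None,
                "frac_non_tethered": n_nont / n_mp if n_mp else None,
            }
        )
        d_mem_all.extend(a.d_membrane_nm for a in mp)
        d_pd_all.extend(a.d_pd_lateral_nm for a in mp if a.d_pd_lateral_nm is not None)
        diam_all.extend(a.diameter_nm for a in mp)

    per_ribbon = pd.DataFrame(rows)
    fraction_stats = {
        sub: _mean_sem(list(per_ribbon[f"frac_{sub}"]))
        for sub in ("docked", "tethered", "non_tethered")
    }
    return RibbonSummary(
        condition=condition,
        n_models=len(models),
        per_ribbon=per_ribbon,
        fraction_stats=fraction_stats,
        docked_per_az=float(per_ribbon["n_docked"].sum()) / len(models),
        mean_distances={
            "d_membrane_nm": _mean_sem(d_mem_all),
            "d_pd_lateral_nm": _mean_sem(d_pd_all),
            "diameter_nm": _mean_sem(diam_all),
        },
        diameter_hist=bin_diameters(diam_all),
    )


def assignments_frame(
    model: SynapseModel, assignments: Sequence[PoolAssignment]
) -> pd.DataFrame:
    """Flat per-vesicle table (one row per vesicle) for CSV export."""
    return pd.DataFrame(
        [
            {
                "model_id": model.model_id,
                "condition": model.condition,
                "vesicle_id": a.vesicle_id,
                "pool": a.pool,
                "mp_subpool": a.mp_subpool,
                "ra_subpool": a.ra_subpool,
                "ribbon_half": a.ribbon_half,
                "d_membrane_nm": a.d_membrane_nm,
                "d_pd_nm": a.d_pd_lateral_nm,
                "d_ribbon_nm": a.d_ribbon_nm,
                "diameter_nm": a.diameter_nm,
                "clathrin_coated": a.clathrin_coated,
            }
            for a in assignments
        ]
    )
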