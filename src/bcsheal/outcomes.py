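"""Outcome metrics extracted from healing simulations.

Two scalar outcomes summarize each patient: the cavity-contraction
trajectory (cavity volume as a percentage of the initially excised volume)
and %BSD, the percentage of the breast skin area displaced by more than
1 mm at week 4 relative to the upright pre-excision surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import BreastMesh, CAVITY, SKIN, tet_volumes

__all__ = [
    "SimulationOutcome",
    "CohortSummary",
    "cavity_volume_deformed",
    "cavity_contraction",
    "percent_bsd",
    "cavity_depth",
    "summarize_cohort",
    "outcome_from_simulation",
]


@dataclass
class SimulationOutcome:
    """Per-patient outcome record."""

    days: np.ndarray  # output times, days
    contraction: np.ndarray  # % of initially excised volume, contraction[0] == 100
    pbsd: float  # % of skin area displaced > 1 mm at week 4
    week4_skin_displacement: np.ndarray  # per skin-vertex mm
    cavity_depth: float  # mm
    characteristics: object = None
    consensus_score: float | None = None

    def __post_init__(self):
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("outcome series must be strictly ordered in time")
        if not np.isclose(self.contraction[0], 100.0, atol=1e-6):
            raise ValueError("contraction must be normalized to 100% at day 0")
        if not (0.0 <= self.pbsd <= 100.0):
            raise ValueError("pbsd outside [0, 100]")


@dataclass
class CohortSummary:
    days: np.ndarray
    mean_contraction: np.ndarray
    lo95: np.ndarray  # 2.5th percentile across patients
    hi95: np.ndarray  # 97.5th percentile
    pbsd_bins: dict = field(default_factory=dict)  # {'<1%': n, '1-10%': n, '>10%': n}
    pbsd_values: np.ndarray | None = None


def cavity_volume_deformed(mesh: BreastMesh, u: np.ndarray) -> float:
    """Cavity volume in the deformed configuration (includes plastic
    compaction, which the total deformation embeds)."""
    if not np.any(mesh.region == CAVITY):
        raise ValueError("mesh has no cavity-labeled elements")
    x = mesh.points + u
    return float(tet_volumes(x, mesh.tets[mesh.region == CAVITY]).sum())


def cavity_contraction(states, mesh: BreastMesh, times=None):
    """Contraction series: deformed cavity volume normalized to 100 % at the
    first archived (post-excision) state."""
    vols = np.array([cavity_volume_deformed(mesh, s.u) for s in states])
    series = 100.0 * vols / vols[0]
    if times is not None:
        return np.asarray(times, dtype=float), series
    return series


def percent_bsd(
    reference_points: np.ndarray,
    deformed_points: np.ndarray,
    faces: np.ndarray,
    threshold: float = 1.0,
    area_weighted: bool = True,
) -> float:
    """Percentage of the skin surface displaced more than ``threshold`` mm.

    Vertex correspondence is by material point (same index).  A facet counts
    as deformed when the mean displacement magnitude of its vertices exceeds
    the threshold; facets are area-weighted by default (a vertex-counting
    variant is exposed for comparison).
    """
    if reference_points.shape != deformed_points.shape:
        raise ValueError("reference and deformed surfaces must share topology")
    disp = np.linalg.norm(deformed_points - reference_points, axis=1)
    face_disp = disp[faces].mean(axis=1)
    over = face_disp > threshold
    if not area_weighted:
        return 100.0 * float(over.mean())
    p = reference_points[faces]
    areas = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    total = areas.sum()
    if total <= 0:
        raise ValueError("degenerate skin surface")
    return 100.0 * float(areas[over].sum() / total)


def cavity_depth(mesh: BreastMesh, centroid=None) -> float:
    """Shortest distance from the cavity centroid to the skin surface
    (exact point-to-triangle minimum over all skin facets)."""
    skin = mesh.boundary_faces[mesh.boundary_label == SKIN]
    if len(skin) == 0:
        raise ValueError("mesh has no skin-labeled facets")
    if centroid is None:
        vols = mesh.volumes()
        cav = mesh.region == CAVITY
        w = vols[cav]
        cpts = mesh.points[mesh.tets[cav]].mean(axis=1)
        centroid = (cpts * w[:, None]).sum(axis=0) / w.sum()
    return float(_point_triangles_distance(np.asarray(centroid, dtype=float),
                                           mesh.points[skin]).min())


def _point_triangles_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from point ``p`` to each triangle in ``tri`` (k, 3, 3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    # barycentric interior projection, clamped to edges/vertices (Ericson)
    closest = np.empty_like(a)
    # vertex regions
    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)
    # edge regions
    v_ab = np.divide(d1, d1 - d3, out=np.zeros_like(d1), where=(d1 - d3) != 0)
    m_ab = (~m_a & ~m_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    w_ac = np.divide(d2, d2 - d6, out=np.zeros_like(d2), where=(d2 - d6) != 0)
    m_ac = (~m_a & ~m_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w_bc = np.divide(d4 - d3, (d4 - d3) + (d5 - d6), out=np.zeros_like(d4),
                     where=((d4 - d3) + (d5 - d6)) != 0)
    m_bc = (~m_b & ~m_c) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    closest[:] = a + v[:, None] * ab + w[:, None] * ac
    closest[m_bc] = (b + w_bc[:, None] * (c - b))[m_bc]
    closest[m_ac] = (a + w_ac[:, None] * ac)[m_ac]
    closest[m_ab] = (a + v_ab[:, None] * ab)[m_ab]
    closest[m_c] = c[m_c]
    closest[m_b] = b[m_b]
    closest[m_a] = a[m_a]
    return np.linalg.norm(closest - p, axis=1)


def outcome_from_simulation(sim: dict, threshold: float = 1.0) -> SimulationOutcome:
    """Assemble the outcome record from a :func:`bcsheal.fem.simulate_patient`
    result dict."""
    mesh: BreastMesh = sim["mesh"]
    times = sim["times"]
    states = sim["states"]
    contraction = cavity_contraction(states, mesh)
    skin_faces = mesh.boundary_faces[mesh.boundary_label == SKIN]
    skin_v = np.unique(skin_faces)
    remap = -np.ones(mesh.n_points, dtype=int)
    remap[skin_v] = np.arange(len(skin_v))
    faces_local = remap[skin_faces]
    x_ref = (mesh.points + sim["u_ref"])[skin_v]
    x_w4 = (mesh.points + states[-1].u)[skin_v]
    pbsd = percent_bsd(x_ref, x_w4, faces_local, threshold=threshold)
    disp = np.linalg.norm(x_w4 - x_ref, axis=1)
    return SimulationOutcome(
        days=np.asarray(times, dtype=float),
        contraction=contraction,
        pbsd=pbsd,
        week4_skin_displacement=disp,
        cavity_depth=cavity_depth(mesh),
        characteristics=sim["chars"],
    )


def summarize_cohort(outcomes: list[SimulationOutcome]) -> CohortSummary:
    """Per-day cohort mean and empirical 95 % interval, plus the %BSD
    histogram in the <1 / 1-10 / >10 % bins."""
    if len(outcomes) < 2:
        raise ValueError("need at least two outcomes to summarize")
    days = outcomes[0].days
    for o in outcomes[1:]:
        if len(o.days) != len(days) or not np.allclose(o.days, days):
            raise ValueError("outcomes are not on a common time grid")
    C = np.vstack([o.contraction for o in outcomes])
    pbsd = np.array([o.pbsd for o in outcomes])
    return CohortSummary(
        days=days,
        mean_contraction=C.mean(axis=0),
        lo95=np.percentile(C, 2.5, axis=0),
        hi95=np.percentile(C, 97.5, axis=0),
        pbsd_bins={
            "<1%": int((pbsd < 1.0).sum()),
            "1-10%": int(((pbsd >= 1.0) & (pbsd <= 10.0)).sum()),
            ">10%": int((pbsd > 10.0).sum()),
        },
        pbsd_values=pbsd,
    )


def outcomes_table(outcomes: list[SimulationOutcome]) -> pd.DataFrame:
    """One row per patient: characteristics, %BSD, week-4 contraction, and
    the trajectory minimum with its day."""
    rows = []
    for o in outcomes:
        ch = o.characteristics
        i_min = int(np.argmin(o.contraction))
        rows.append({
            "breast_density": ch.breast_density if ch else np.nan,
            "cavity_volume": ch.cavity_volume if ch else np.nan,
            "breast_volume": ch.breast_volume if ch else np.nan,
            "cavity_depth": ch.cavity_depth if ch else np.nan,
            "margin_width": ch.margin_width if ch else np.nan,
            "seed": ch.seed if ch else -1,
            "pbsd": o.pbsd,
            "week4_contraction": o.contraction[-1],
            "min_contraction": o.contraction[i_min],
            "min_day": o.days[i_min],
            "consensus_score": o.consensus_score if o.consensus_score is not None else np.nan,
        })
    return pd.DataFrame(rows)
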