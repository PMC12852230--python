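"""Synthetic patient cohorts emulating an MRI-derived lumpectomy population.

Each synthetic patient is described by four characteristics — breast density
(fibroglandular volume fraction), cavity (tumor) volume, breast volume, and
cavity depth — sampled by Latin hypercube design over the ranges observed in
a processed-MRI cohort, plus a uniform 0-5 mm surgical margin.  Geometries
are hemispherical breasts with spherical cavities (see :mod:`bcsheal.mesh`).

The Latin hypercube is implemented directly (one stratum per sample per
dimension) rather than through a library sampler because infeasible
combinations (a cavity too large for its depth) must be redrawn *within
their stratum* to preserve the stratification property.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "TABLE_RANGES",
    "TABLE_MEDIANS",
    "PatientCharacteristics",
    "CohortDesign",
    "InfeasibleSampleError",
    "cavity_radius",
    "is_feasible",
    "sample_characteristics",
    "build_geometry",
    "synthetic_consensus_labels",
    "cohort_table",
]

#: Observed cohort ranges: density (fraction), cavity volume (mm^3),
#: breast volume (mm^3), cavity depth (mm).
TABLE_RANGES = {
    "breast_density": (0.0439, 0.7113),
    "cavity_volume": (33.41, 35096.57),
    "breast_volume": (90_191.0, 3_208_695.0),
    "cavity_depth": (6.96, 54.58),
}

#: Observed cohort medians (same keys/units).
TABLE_MEDIANS = {
    "breast_density": 0.2595,
    "cavity_volume": 1485.32,
    "breast_volume": 755_890.0,
    "cavity_depth": 19.74,
}

#: Minimum tissue shell between the cavity sphere and any boundary (mm).
SHELL_MM = 2.0

MARGIN_RANGE = (0.0, 5.0)

# consensus-label model: p(visible) = logistic(alpha*(pbsd-p0) - beta*(depth-d0));
# alpha/p0 chosen so >10 %BSD is almost always judged visible
LABEL_ALPHA = 0.15  # per %BSD point
LABEL_P0 = 10.0  # %BSD midpoint
LABEL_BETA = 0.05  # per mm of depth
LABEL_D0 = 20.0  # mm depth midpoint
N_REVIEWERS = 5


class InfeasibleSampleError(ValueError):
    """A design stratum admits no feasible patient."""


@dataclass(frozen=True)
class PatientCharacteristics:
    """Surrogate inputs plus the sampled surgical margin for one patient."""

    breast_density: float  # fibroglandular fraction in [0, 1]
    cavity_volume: float  # mm^3 (excised tumor volume)
    breast_volume: float  # mm^3
    cavity_depth: float  # mm, skin surface to cavity center
    margin_width: float = 0.0  # mm in [0, 5]
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.breast_density <= 1.0):
            raise ValueError(f"breast_density {self.breast_density} outside [0, 1]")
        if self.cavity_volume <= 0 or self.breast_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.cavity_volume >= self.breast_volume:
            raise ValueError("cavity_volume must be smaller than breast_volume")
        if not (MARGIN_RANGE[0] <= self.margin_width <= MARGIN_RANGE[1]):
            raise ValueError(f"margin_width {self.margin_width} outside {MARGIN_RANGE}")

    def as_array(self) -> np.ndarray:
        """The 4-vector of surrogate inputs (density, V_cav, V_breast, depth)."""
        return np.array(
            [self.breast_density, self.cavity_volume, self.breast_volume, self.cavity_depth]
        )


@dataclass(frozen=True)
class CohortDesign:
    """Latin-hypercube design over the four patient characteristics."""

    n_samples: int
    ranges: dict | None = None
    seed: int = 0
    fidelity: str = "low"
    sample_margin: bool = True

    def resolved_ranges(self) -> dict:
        r = dict(TABLE_RANGES)
        if self.ranges:
            r.update(self.ranges)
        for k, (lo, hi) in r.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid range for {k}: ({lo}, {hi})")
        return r


def cavity_radius(cavity_volume: float, margin_width: float = 0.0) -> float:
    """Radius of the margin-expanded spherical cavity.

    ``r = (3 V / 4 pi)^(1/3) + margin`` — the sphere matching the excised
    tumor volume, expanded by the uniform negative surgical margin.
    """
    if cavity_volume <= 0:
        raise ValueError(f"cavity_volume must be positive, got {cavity_volume}")
    if not (MARGIN_RANGE[0] <= margin_width <= MARGIN_RANGE[1]):
        raise ValueError(f"margin_width {margin_width} outside {MARGIN_RANGE}")
    return (3.0 * cavity_volume / (4.0 * np.pi)) ** (1.0 / 3.0) + margin_width


def is_feasible(
    breast_density: float,
    cavity_volume: float,
    breast_volume: float,
    cavity_depth: float,
    margin_width: float = 0.0,
) -> bool:
    """Cavity sphere fully interior: at least ``SHELL_MM`` of tissue between
    the cavity and both the skin and the chest wall."""
    R = (3.0 * breast_volume / (2.0 * np.pi)) ** (1.0 / 3.0)
    r = cavity_radius(cavity_volume, margin_width)
    return (cavity_depth >= r + SHELL_MM) and (R - cavity_depth >= r + SHELL_MM)


def sample_characteristics(
    design: CohortDesign, max_retries: int = 200
) -> list[PatientCharacteristics]:
    """Latin-hypercube sample of patient characteristics.

    Each dimension is stratified into ``n_samples`` equal-width bins with one
    draw per bin; infeasible rows are redrawn within their own strata (the
    stratification survives).  A row whose stratum combination is inherently
    infeasible is dropped with a logged diagnostic.
    """
    if design.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ranges = design.resolved_ranges()
    keys = list(TABLE_RANGES)
    n, d = design.n_samples, len(keys)
    rng = np.random.default_rng(design.seed)

    strata = np.column_stack([rng.permutation(n) for _ in range(d)])
    u = (strata + rng.uniform(size=(n, d))) / n
    lo = np.array([ranges[k][0] for k in keys])
    hi = np.array([ranges[k][1] for k in keys])
    vals = lo + u * (hi - lo)
    margins = rng.uniform(*MARGIN_RANGE, size=n) if design.sample_margin else np.zeros(n)

    patients: list[PatientCharacteristics] = []
    for i in range(n):
        row, m = vals[i], margins[i]
        ok = is_feasible(*row, m)
        tries = 0
        while not ok and tries < max_retries:
            u_new = (strata[i] + rng.uniform(size=d)) / n
            row = lo + u_new * (hi - lo)
            if design.sample_margin:
                m = rng.uniform(*MARGIN_RANGE)
            ok = is_feasible(*row, m)
            tries += 1
        if not ok:
            log.warning(
                "dropping infeasible design row %d (strata %s) after %d redraws",
                i, strata[i].tolist(), max_retries,
            )
            continue
        patients.append(
            PatientCharacteristics(*row, margin_width=m, seed=int(design.seed * 100_003 + i))
        )
    if not patients:
        raise InfeasibleSampleError("every design row was infeasible")
    return patients


def build_geometry(chars: PatientCharacteristics, fidelity: str = "low"):
    """Tetrahedral mesh of the patient's breast-plus-cavity geometry."""
    from .mesh import build_breast_mesh

    return build_breast_mesh(
        breast_volume=chars.breast_volume,
        cavity_volume=chars.cavity_volume,
        cavity_depth=chars.cavity_depth,
        margin_width=chars.margin_width,
        fidelity=fidelity,
        seed=chars.seed,
    )


def visible_deformation_probability(pbsd: float, depth: float) -> float:
    """Per-reviewer probability of judging the deformation visible."""
    z = LABEL_ALPHA * (pbsd - LABEL_P0) - LABEL_BETA * (depth - LABEL_D0)
    return 1.0 / (1.0 + np.exp(-z))


def synthetic_consensus_labels(pbsd: float, depth: float, seed: int) -> float:
    """Synthetic reviewer-consensus score in [0, 1].

    Stand-in for a blinded multi-reviewer visibility assessment: five seeded
    Bernoulli "reviewers" vote with probability increasing in %BSD and
    decreasing in cavity depth; the score is the fraction voting visible.
    """
    if not (0.0 <= pbsd <= 100.0):
        raise ValueError(f"pbsd {pbsd} outside [0, 100]")
    p = visible_deformation_probability(pbsd, depth)
    rng = np.random.default_rng(seed)
    return float((rng.uniform(size=N_REVIEWERS) < p).mean())


def cohort_table(patients: list[PatientCharacteristics]) -> pd.DataFrame:
    """One row per patient (documented column names, units as sampled)."""
    return pd.DataFrame([asdict(p) for p in patients])
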