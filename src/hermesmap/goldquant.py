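"""Immunogold particle quantification on EM cryosection scenes.

A *scene* is one electron micrograph reduced to vector form: labelled membrane
polylines (plasma membrane, intracytoplasmic cisternae, flagellar components)
plus 12 nm colloidal-gold particle coordinates, all in nanometres (origin at
the image top-left, y increasing downward).

The quantification scheme follows classical immunogold stereology:

1. particles near the plasma membrane are histogrammed over demarcated 12 nm
   increments on either side of the membrane trace (``band_histogram``);
2. the symmetric span holding most membrane-proximal gold defines a reference
   band — 72 nm (36 nm each side) for well-behaved membrane antigens
   (``reference_band``);
3. every particle is classified into one of five areas — cross and oblique
   sections of plasma membrane, intracytoplasmic (cisternae), and cross and
   oblique sections of flagellar components (``classify_particles``);
4. per-micrograph counts are pooled by aggregation unit (antibody dilution by
   default) and reported as percentage distributions over the three reporting
   compartments, mean ± s.d. across units (``distribution``).

Clustered particles are counted as individual particles; scenes recorded with
no primary antibody (``is_control``) are summarised separately and never
pooled with labelled scenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .errors import GeometryError, ParameterError

__all__ = [
    "Structure",
    "Particle",
    "GoldScene",
    "BandHistogram",
    "ZoneDistribution",
    "GoldDistributionResult",
    "COMPARTMENTS",
    "REPORTING_COMPARTMENTS",
    "ZONES",
    "DEFAULT_INCREMENT_NM",
    "DEFAULT_BAND_HALF_WIDTH_NM",
    "signed_distance",
    "band_histogram",
    "reference_band",
    "classify_particles",
    "distribution",
]

#: structural compartments a polyline may be labelled with
COMPARTMENTS = ("plasma_membrane", "cisterna", "flagellum")

#: the three compartments used in reported percentage distributions
REPORTING_COMPARTMENTS = ("plasma_membrane", "intracytoplasmic_cisternae", "flagellum")

#: the five classification areas (plus the excluded bucket)
ZONES = (
    "plasma_membrane_cross",
    "plasma_membrane_oblique",
    "intracytoplasmic",
    "flagellum_cross",
    "flagellum_oblique",
)
UNASSIGNED = "unassigned"

DEFAULT_INCREMENT_NM = 12.0
#: 72 nm reference span = 36 nm on each side of the membrane trace
DEFAULT_BAND_HALF_WIDTH_NM = 36.0


@dataclass(frozen=True)
class Structure:
    """One labelled membrane trace in a scene."""

    compartment: str  # one of COMPARTMENTS
    section_kind: str  # "cross" | "oblique" (an input label, never inferred)
    points: tuple[tuple[float, float], ...]
    closed: bool = False

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ParameterError(f"unknown compartment {self.compartment!r}")
        if self.section_kind not in ("cross", "oblique"):
            raise ParameterError(f"unknown section kind {self.section_kind!r}")
        if len(self.points) < 2:
            raise GeometryError("polyline needs at least 2 vertices")
        for x, y in self.points:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise GeometryError("non-finite polyline coordinate")

    def line(self) -> LineString:
        pts = list(self.points)
        if self.closed and pts[0] != pts[-1]:
            pts = pts + [pts[0]]
        line = LineString(pts)
        if line.length == 0:
            raise GeometryError("zero-length polyline")
        return line

    def polygon(self) -> Polygon:
        if not self.closed:
            raise GeometryError("open polyline has no interior")
        poly = Polygon(self.points)
        if poly.area == 0:
            raise GeometryError("degenerate closed polyline")
        return poly


@dataclass(frozen=True)
class Particle:
    """One gold particle (nm coordinates, optional generation truth label)."""

    x: float
    y: float
    truth: Optional[str] = None


@dataclass
class GoldScene:
    """One micrograph: metadata, membrane traces and particle coordinates."""

    scene_id: str
    animal: str
    dilution: str
    is_control: bool
    structures: list[Structure]
    particles: list[Particle]

    def __post_init__(self):
        if not self.is_control and not any(
            s.compartment == "plasma_membrane" for s in self.structures
        ):
            raise ParameterError(
                f"scene {self.scene_id}: non-control scene lacks a plasma membrane"
            )
        for p in self.particles:
            if not (math.isfinite(p.x) and math.isfinite(p.y)):
                raise GeometryError(f"scene {self.scene_id}: non-finite particle")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def signed_distance(point: tuple[float, float], structure: Structure) -> float:
    """Signed Euclidean distance from a point to a membrane trace.

    Magnitude is the point-to-polyline distance. For *closed* plasma-membrane
    traces the sign encodes sidedness: negative on the intracellular side
    (inside the polygon), positive outside. Open polylines return the
    unsigned distance (no well-defined side).
    """
    d = structure.line().distance(Point(point))
    if structure.closed and structure.compartment == "plasma_membrane":
        if structure.polygon().covers(Point(point)):
            return -d
    return d


def _distance_matrix(scene: GoldScene) -> np.ndarray:
    """Particle x structure matrix of unsigned point-to-polyline distances."""
    import shapely

    pts = shapely.points(np.array([[p.x, p.y] for p in scene.particles]))
    return np.column_stack(
        [shapely.distance(pts, s.line()) for s in scene.structures]
    )


# ---------------------------------------------------------------------------
# band histogram and reference band
# ---------------------------------------------------------------------------

@dataclass
class BandHistogram:
    """Signed-offset increment histogram around the plasma membrane.

    Bin ``k`` counts particles with signed distance in the half-open interval
    ``[k*increment, (k+1)*increment)``; negative bins are intracellular.
    """

    increment: float
    bins: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.bins.values())


def band_histogram(
    scene: GoldScene,
    increment: float = DEFAULT_INCREMENT_NM,
    max_half_width: float = 120.0,
) -> BandHistogram:
    """Histogram particle offsets from the plasma membrane in fixed increments.

    Each particle within ``max_half_width`` of the nearest plasma-membrane
    trace is binned by its signed distance; particles farther away are not
    scored (they are not membrane-proximal).
    """
    if increment <= 0:
        raise ParameterError("increment must be positive")
    import shapely

    pms = [s for s in scene.structures if s.compartment == "plasma_membrane"]
    if not pms:
        raise ParameterError(f"scene {scene.scene_id} has no plasma membrane")
    hist = BandHistogram(increment=increment)
    if not scene.particles:
        return hist
    pts = shapely.points(np.array([[p.x, p.y] for p in scene.particles]))
    dmat = np.column_stack([shapely.distance(pts, s.line()) for s in pms])
    # sidedness per closed membrane: negative = intracellular
    signs = np.ones_like(dmat)
    for j, s in enumerate(pms):
        if s.closed:
            inside = shapely.covers(s.polygon(), pts)
            signs[inside, j] = -1.0
    nearest = np.argmin(dmat, axis=1)
    d = signs[np.arange(len(dmat)), nearest] * dmat[np.arange(len(dmat)), nearest]
    for di in d:
        if abs(di) > max_half_width:
            continue
        k = math.floor(di / increment)
        hist.bins[k] = hist.bins.get(k, 0) + 1
    return hist


def reference_band(hist: BandHistogram, coverage: float = 0.95) -> float:
    """Half-width (nm) of the smallest symmetric span holding ``coverage``
    of all membrane-proximal particles.

    The span is a whole number of increments on each side: half-width ``k*w``
    covers bins ``-k .. k-1``, i.e. the interval ``[-k*w, k*w)``. With 12 nm
    increments and a typical antibody-gold displacement this reproduces the
    72 nm reference span (36 nm each side).
    """
    if not 0 < coverage <= 1:
        raise ParameterError("coverage must be in (0, 1]")
    if hist.total == 0:
        raise ParameterError("empty histogram")
    kmax = max(abs(b) for b in hist.bins) + 1
    for k in range(1, kmax + 1):
        covered = sum(c for b, c in hist.bins.items() if -k <= b <= k - 1)
        if covered >= coverage * hist.total:
            return k * hist.increment
    return kmax * hist.increment


# ---------------------------------------------------------------------------
# five-area classification
# ---------------------------------------------------------------------------

def _zone_of(structure: Structure) -> str:
    if structure.compartment == "cisterna":
        return "intracytoplasmic"
    return f"{structure.compartment}_{structure.section_kind}"


def classify_particles(
    scene: GoldScene,
    band_half_width: float = DEFAULT_BAND_HALF_WIDTH_NM,
) -> list[str]:
    """Assign each particle to one of the five areas.

    A particle within the reference band of at least one structure is assigned
    to the *nearest* such structure (ties resolved in favour of the plasma
    membrane). A particle inside the plasma membrane but within no band is
    intracytoplasmic; a particle outside the cell and outside every band is
    ``"unassigned"`` and excluded from distributions.
    """
    import shapely

    if band_half_width <= 0:
        raise ParameterError("band_half_width must be positive")
    if not scene.particles:
        return []
    pm_polys = [
        s.polygon()
        for s in scene.structures
        if s.compartment == "plasma_membrane" and s.closed
    ]
    dmat = _distance_matrix(scene)
    pts = shapely.points(np.array([[p.x, p.y] for p in scene.particles]))
    inside_pm = np.zeros(len(scene.particles), dtype=bool)
    for poly in pm_polys:
        inside_pm |= shapely.covers(poly, pts)
    prio = np.array(
        [0 if s.compartment == "plasma_membrane" else 1 for s in scene.structures]
    )
    zone_names = [_zone_of(s) for s in scene.structures]

    zones: list[str] = []
    for i in range(len(scene.particles)):
        in_band = [
            (dmat[i, j], prio[j], zone_names[j])
            for j in range(len(scene.structures))
            if dmat[i, j] <= band_half_width
        ]
        if in_band:
            # nearest structure; plasma membrane wins ties at equal distance
            zones.append(min(in_band)[2])
        elif inside_pm[i]:
            zones.append("intracytoplasmic")
        else:
            zones.append(UNASSIGNED)
    return zones


# ---------------------------------------------------------------------------
# aggregated percentage distributions
# ---------------------------------------------------------------------------

_COLLAPSE = {
    "plasma_membrane_cross": "plasma_membrane",
    "plasma_membrane_oblique": "plasma_membrane",
    "intracytoplasmic": "intracytoplasmic_cisternae",
    "flagellum_cross": "flagellum",
    "flagellum_oblique": "flagellum",
}


@dataclass
class ZoneDistribution:
    """Counts and percentages over reporting compartments for one unit."""

    unit: str
    counts: dict[str, int]
    n_particles: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.n_particles == 0:
            return {c: 0.0 for c in REPORTING_COMPARTMENTS}
        return {
            c: 100.0 * self.counts.get(c, 0) / self.n_particles
            for c in REPORTING_COMPARTMENTS
        }


@dataclass
class GoldDistributionResult:
    """Pooled per-unit distributions with across-unit mean ± s.d."""

    units: list[ZoneDistribution]
    mean: dict[str, float]
    sd: dict[str, float]
    n_units: int
    n_particles: int
    n_unassigned: int
    control_counts: list[int]  # particle count of each control scene

    def per_unit_frame(self) -> pd.DataFrame:
        rows = []
        for u in self.units:
            row = {"unit": u.unit, "n_particles": u.n_particles}
            row.update({c: u.percentages[c] for c in REPORTING_COMPARTMENTS})
            rows.append(row)
        return pd.DataFrame(rows, columns=["unit", "n_particles", *REPORTING_COMPARTMENTS])


def _unit_key(scene: GoldScene, unit: str) -> str:
    if unit == "dilution":
        return scene.dilution
    if unit == "animal":
        return scene.animal
    if unit == "micrograph":
        return scene.scene_id
    raise ParameterError(f"unknown aggregation unit {unit!r}")


def distribution(
    scenes: Sequence[GoldScene],
    band_half_width: float = DEFAULT_BAND_HALF_WIDTH_NM,
    unit: str = "dilution",
) -> GoldDistributionResult:
    """Percentage gold distribution over reporting compartments.

    Five-area zone counts are collapsed onto the three reporting compartments,
    pooled within each aggregation unit (``dilution`` by default, matching the
    per-antibody n = 3 style of reporting; ``animal`` and ``micrograph`` are
    alternatives), then mean ± sample s.d. of the percentages is taken across
    units. Every particle counts once; unassigned particles are excluded.
    Control scenes are tallied separately and never pooled.
    """
    labelled = [s for s in scenes if not s.is_control]
    controls = [s for s in scenes if s.is_control]
    if not labelled:
        raise ParameterError("no non-control scenes")

    unit_counts: dict[str, dict[str, int]] = {}
    n_unassigned = 0
    for scene in labelled:
        key = _unit_key(scene, unit)
        counts = unit_counts.setdefault(key, {c: 0 for c in REPORTING_COMPARTMENTS})
        for zone in classify_particles(scene, band_half_width):
            if zone == UNASSIGNED:
                n_unassigned += 1
                continue
            counts[_COLLAPSE[zone]] += 1

    units = [
        ZoneDistribution(unit=k, counts=c, n_particles=sum(c.values()))
        for k, c in sorted(unit_counts.items())
    ]
    total = sum(u.n_particles for u in units)
    if total == 0:
        raise ParameterError("zero particles in every non-control scene")

    scored = [u for u in units if u.n_particles > 0]
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for c in REPORTING_COMPARTMENTS:
        vals = np.array([u.percentages[c] for u in scored], dtype=float)
        mean[c] = float(vals.mean())
        sd[c] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    return GoldDistributionResult(
        units=units,
        mean=mean,
        sd=sd,
        n_units=len(scored),
        n_particles=total,
        n_unassigned=n_unassigned,
        control_counts=[len(s.particles) for s in controls],
    )
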