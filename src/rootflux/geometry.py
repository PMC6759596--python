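"""Discretized root geometry and its connectivity graph.

The model root is a cylinder split into ``n_axial`` single-cell-high layers and
five concentric tissue rings (epidermis, cortex, endodermis, xylem parenchyma,
xylem, outermost to innermost).  The bottom ``apex_layers`` layers form the
developmental apex: no Casparian strip, no suberin lamellae, and a living
("non-functional") xylem.  In the mature zone the xylem ring is a purely
apoplastic conduit that carries the transpiration stream; its top face is the
``boundary_xylem_top`` interface to the shoot.

Every living cell ring contributes three compartments (apoplast, cytosol,
vacuole); the mature xylem conduit is a single apoplast compartment.
Compartment indexing is deterministic: layer-major (layer 0 at the tip), then
ring (outermost first), then kind in the order apoplast, cytosol, vacuole.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constants import WATER_DENSITY

TISSUE_NAMES = ("epidermis", "cortex", "endodermis", "xylem_parenchyma", "xylem")
KINDS = ("apoplast", "cytosol", "vacuole")

#: pseudo-indices for boundary nodes in the edge list
EXTERNAL = -1
SHOOT = -2

PATHWAYS = (
    "apoplast_radial",
    "apoplast_axial",
    "plasmodesma",
    "plasma_membrane",
    "tonoplast",
    "boundary_external",
    "boundary_xylem_top",
)


class GeometryValidationError(ValueError):
    """Raised when a geometric quantity violates its invariants."""


@dataclass(frozen=True)
class TissueRing:
    """One concentric tissue ring of the root cross-section."""

    name: str
    radial_index: int
    r_outer: float  # m
    r_inner: float  # m
    cell_height: float  # m

    def __post_init__(self):
        if self.name not in TISSUE_NAMES:
            raise GeometryValidationError(
                f"unknown tissue name {self.name!r}; expected one of {TISSUE_NAMES}"
            )
        for fld in ("r_outer", "cell_height"):
            if getattr(self, fld) <= 0:
                raise GeometryValidationError(f"{self.name}.{fld} must be > 0")
        if self.r_inner < 0:
            raise GeometryValidationError(f"{self.name}.r_inner must be >= 0")
        if self.r_inner >= self.r_outer:
            raise GeometryValidationError(
                f"{self.name}: r_inner must be < r_outer (got {self.r_inner} >= {self.r_outer})"
            )

    @property
    def r_mid(self) -> float:
        return 0.5 * (self.r_outer + self.r_inner)

    @property
    def annulus_area(self) -> float:
        return math.pi * (self.r_outer**2 - self.r_inner**2)

    @property
    def annulus_volume(self) -> float:
        return self.annulus_area * self.cell_height


@dataclass(frozen=True)
class Compartment:
    index: int
    layer: int
    ring: int  # radial index into RootGeometry.rings
    kind: str  # apoplast | cytosol | vacuole
    volume: float  # m^3
    pm_area: float  # m^2, plasma-membrane area of the owning cell (0 for apoplast)
    tonoplast_area: float  # m^2 (0 unless vacuole/cytosol pair exists)


@dataclass(frozen=True)
class Edge:
    a: int  # compartment index, or EXTERNAL / SHOOT
    b: int
    pathway: str
    area: float  # m^2
    length: float  # m (centre-to-centre path; nominal for membranes)
    blocked: bool = False


@dataclass
class RootGeometry:
    """The full discretized root: compartments plus static metadata."""

    n_axial: int
    apex_layers: int
    rings: list[TissueRing]
    compartments: list[Compartment]
    apoplast_fraction: float
    cytosol_fraction: float
    vacuole_fraction: float
    plasmodesma_fraction: float
    tonoplast_area_ratio: float
    apex_cell_height: float | None = None  # m; apex cells are much shorter
    fresh_weight_override: float | None = None
    _index: dict[tuple[int, int, str], int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {
                (c.layer, c.ring, c.kind): c.index for c in self.compartments
            }

    # -- queries -------------------------------------------------------------

    def zone_of_layer(self, layer: int) -> str:
        return "apex" if layer < self.apex_layers else "mature"

    def layer_height(self, layer: int) -> float:
        if layer < self.apex_layers and self.apex_cell_height is not None:
            return self.apex_cell_height
        return self.rings[0].cell_height

    @property
    def mature_layers(self) -> list[int]:
        return list(range(self.apex_layers, self.n_axial))

    def comp(self, layer: int, ring: int, kind: str) -> Compartment:
        return self.compartments[self._index[(layer, ring, kind)]]

    def has_comp(self, layer: int, ring: int, kind: str) -> bool:
        return (layer, ring, kind) in self._index

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def total_volume(self) -> float:
        return sum(c.volume for c in self.compartments)

    @property
    def total_fresh_weight(self) -> float:
        """Root fresh weight (kg): total compartment volume x water density."""
        if self.fresh_weight_override is not None:
            return self.fresh_weight_override
        return self.total_volume * WATER_DENSITY

    def zone_fresh_weight(self, zone: str) -> float:
        vol = sum(
            c.volume for c in self.compartments if self.zone_of_layer(c.layer) == zone
        )
        fw = vol * WATER_DENSITY
        if self.fresh_weight_override is not None:
            fw *= self.fresh_weight_override / (self.total_volume * WATER_DENSITY)
        return fw

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_axial": self.n_axial,
            "apex_layers": self.apex_layers,
            "rings": [asdict(r) for r in self.rings],
            "apoplast_fraction": self.apoplast_fraction,
            "cytosol_fraction": self.cytosol_fraction,
            "vacuole_fraction": self.vacuole_fraction,
            "plasmodesma_fraction": self.plasmodesma_fraction,
            "tonoplast_area_ratio": self.tonoplast_area_ratio,
            "apex_cell_height": self.apex_cell_height,
            "fresh_weight_override": self.fresh_weight_override,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RootGeometry":
        rings = [TissueRing(**r) for r in d["rings"]]
        return build_root_grid(
            n_axial=d["n_axial"],
            apex_layers=d["apex_layers"],
            ring_spec=rings,
            apoplast_fraction=d["apoplast_fraction"],
            cytosol_fraction=d["cytosol_fraction"],
            vacuole_fraction=d["vacuole_fraction"],
            plasmodesma_fraction=d["plasmodesma_fraction"],
            tonoplast_area_ratio=d["tonoplast_area_ratio"],
            apex_cell_height=d.get("apex_cell_height"),
            fresh_weight_override=d.get("fresh_weight_override"),
        )


@dataclass
class ConnectivityGraph:
    """Edge list over compartments plus the two boundary nodes.

    Every edge is traversable in both directions; fluxes are reported with the
    a->b direction positive.
    """

    edges: list[Edge]

    def by_pathway(self, pathway: str, include_blocked: bool = False) -> list[Edge]:
        return [
            e
            for e in self.edges
            if e.pathway == pathway and (include_blocked or not e.blocked)
        ]

    def incident(self, comp_index: int) -> list[Edge]:
        return [e for e in self.edges if comp_index in (e.a, e.b)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "a": e.a,
                    "b": e.b,
                    "pathway": e.pathway,
                    "area_m2": e.area,
                    "length_m": e.length,
                    "blocked": e.blocked,
                }
                for e in self.edges
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------


def default_ring_spec(cell_height: float = 1.0e-4) -> list[TissueRing]:
    """Arabidopsis-plausible ring radii (total root radius 110 um)."""
    radii = [
        ("epidermis", 110e-6, 88e-6),
        ("cortex", 88e-6, 55e-6),
        ("endodermis", 55e-6, 40e-6),
        ("xylem_parenchyma", 40e-6, 25e-6),
        ("xylem", 25e-6, 1e-6),
    ]
    return [
        TissueRing(name, i, r_out, r_in, cell_height)
        for i, (name, r_out, r_in) in enumerate(radii)
    ]


def build_root_grid(
    n_axial: int,
    apex_layers: int,
    ring_spec: list[TissueRing] | None = None,
    apoplast_fraction: float = 0.08,
    cytosol_fraction: float = 0.12,
    vacuole_fraction: float = 0.80,
    plasmodesma_fraction: float = 0.005,
    tonoplast_area_ratio: float = 0.8,
    apex_cell_height: float = 3.0e-5,
    fresh_weight_override: float | None = None,
) -> RootGeometry:
    """Build the discretized root cylinder.

    Layers 0..apex_layers-1 (root tip) are the apex; the rest are mature.  In
    mature layers the xylem ring is a single apoplastic conduit compartment;
    in apex layers it is a living cell (the "non-functional xylem").  Apex
    cells are shorter than mature cells (``apex_cell_height``, default 30 um
    vs the rings' mature height), which gives the apex its characteristically
    larger membrane area per unit fresh weight.
    """
    if n_axial < 1:
        raise GeometryValidationError("n_axial must be >= 1")
    if not (0 <= apex_layers <= n_axial):
        raise GeometryValidationError("apex_layers must be in [0, n_axial]")
    if ring_spec is None:
        ring_spec = default_ring_spec()
    names = [r.name for r in ring_spec]
    if names != list(TISSUE_NAMES):
        raise GeometryValidationError(
            f"ring_spec must contain the five tissues in order {TISSUE_NAMES}, got {names}"
        )
    for i in range(len(ring_spec) - 1):
        if not math.isclose(ring_spec[i].r_inner, ring_spec[i + 1].r_outer, rel_tol=1e-9):
            raise GeometryValidationError(
                f"rings {names[i]} and {names[i+1]} are not contiguous "
                f"({ring_spec[i].r_inner} vs {ring_spec[i+1].r_outer})"
            )
    fr = (apoplast_fraction, cytosol_fraction, vacuole_fraction)
    if any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
        raise GeometryValidationError(
            "apoplast/cytosol/vacuole volume fractions must be positive and sum to 1"
        )

    comps: list[Compartment] = []
    for layer in range(n_axial):
        zone_is_mature = layer >= apex_layers
        h_l = apex_cell_height if (layer < apex_layers and apex_cell_height) \
            else ring_spec[0].cell_height
        for ring in ring_spec:
            v_ring = ring.annulus_area * h_l
            pm_area = (
                2 * math.pi * ring.r_outer * h_l
                + 2 * math.pi * ring.r_inner * h_l
                + 2 * ring.annulus_area
            )
            conduit = zone_is_mature and ring.name == "xylem"
            if conduit:
                comps.append(
                    Compartment(len(comps), layer, ring.radial_index, "apoplast", v_ring, 0.0, 0.0)
                )
            else:
                ta = tonoplast_area_ratio * pm_area
                comps.append(
                    Compartment(
                        len(comps), layer, ring.radial_index, "apoplast",
                        apoplast_fraction * v_ring, 0.0, 0.0,
                    )
                )
                comps.append(
                    Compartment(
                        len(comps), layer, ring.radial_index, "cytosol",
                        cytosol_fraction * v_ring, pm_area, ta,
                    )
                )
                comps.append(
                    Compartment(
                        len(comps), layer, ring.radial_index, "vacuole",
                        vacuole_fraction * v_ring, 0.0, ta,
                    )
                )
    return RootGeometry(
        n_axial=n_axial,
        apex_layers=apex_layers,
        rings=list(ring_spec),
        compartments=comps,
        apoplast_fraction=apoplast_fraction,
        cytosol_fraction=cytosol_fraction,
        vacuole_fraction=vacuole_fraction,
        plasmodesma_fraction=plasmodesma_fraction,
        tonoplast_area_ratio=tonoplast_area_ratio,
        apex_cell_height=apex_cell_height,
        fresh_weight_override=fresh_weight_override,
    )


def passage_cell_layers(geometry: RootGeometry, passage_cell_fraction: float) -> set[int]:
    """Deterministic placement of endodermal passage cells.

    ``round(fraction * n_mature)`` mature layers keep an unsuberized
    endodermis; they are chosen evenly spaced over the mature zone (linspace
    rule), so rebuilding with identical inputs gives identical placement.
    """
    mature = geometry.mature_layers
    if not mature:
        return set()
    n_pass = int(round(passage_cell_fraction * len(mature)))
    if passage_cell_fraction > 0 and n_pass == 0:
        n_pass = 1  # a nonzero fraction always leaves at least one passage cell
    if n_pass == 0:
        return set()
    idx = np.unique(np.round(np.linspace(0, len(mature) - 1, n_pass)).astype(int))
    return {mature[i] for i in idx}


def apply_barriers(
    geometry: RootGeometry, passage_cell_fraction: float = 0.1
) -> ConnectivityGraph:
    """Construct the connectivity graph and apply the endodermal barriers.

    Mature-zone blocking only: the Casparian strip blocks the radial
    apoplastic path across the outer face of the mature endodermal wall
    (the inner face stays contiguous with the stelar apoplast), and suberin
    lamellae block mature endodermal plasma membranes except in passage-cell
    layers (default fraction 0.1).  The apex carries no barriers.
    """
    if not (0.0 <= passage_cell_fraction <= 1.0):
        raise GeometryValidationError("passage_cell_fraction must be in [0, 1]")
    if not geometry.mature_layers and passage_cell_fraction > 0:
        warnings.warn("geometry has no mature layers; passage_cell_fraction ignored")

    g = geometry
    endo_ring = next(r.radial_index for r in g.rings if r.name == "endodermis")
    xyl_ring = next(r.radial_index for r in g.rings if r.name == "xylem")
    epi = g.rings[0]
    f_wall = g.apoplast_fraction
    f_pd = g.plasmodesma_fraction
    passage = passage_cell_layers(g, passage_cell_fraction)

    edges: list[Edge] = []

    def add(a, b, pathway, area, length, blocked=False):
        edges.append(Edge(a, b, pathway, area, length, blocked))

    for layer in range(g.n_axial):
        mature = g.zone_of_layer(layer) == "mature"
        h_l = g.layer_height(layer)
        # external boundary at the epidermis wall
        apo_epi = g.comp(layer, 0, "apoplast")
        add(
            EXTERNAL, apo_epi.index, "boundary_external",
            2 * math.pi * epi.r_outer * h_l * f_wall,
            0.5 * (epi.r_outer - epi.r_inner),
        )
        # radial edges between adjacent rings
        for i in range(len(g.rings) - 1):
            ro, ri = g.rings[i], g.rings[i + 1]
            r_if = ro.r_inner
            a_apo = g.comp(layer, i, "apoplast")
            b_apo = g.comp(layer, i + 1, "apoplast")
            # Casparian strip: block the radial apoplast path across the outer
            # face of the mature endodermal wall; the inner face stays
            # contiguous with the stelar apoplast, so passage-cell membrane
            # transport can reach the stele
            blocked = mature and i + 1 == endo_ring
            add(
                a_apo.index, b_apo.index, "apoplast_radial",
                2 * math.pi * r_if * h_l * f_wall,
                ro.r_mid - ri.r_mid,
                blocked,
            )
            # plasmodesmata between adjacent cytosols
            if g.has_comp(layer, i, "cytosol") and g.has_comp(layer, i + 1, "cytosol"):
                add(
                    g.comp(layer, i, "cytosol").index,
                    g.comp(layer, i + 1, "cytosol").index,
                    "plasmodesma",
                    2 * math.pi * r_if * h_l * f_pd,
                    ro.r_mid - ri.r_mid,
                )
        # membranes
        for ring in g.rings:
            i = ring.radial_index
            if not g.has_comp(layer, i, "cytosol"):
                continue
            cyt = g.comp(layer, i, "cytosol")
            apo = g.comp(layer, i, "apoplast")
            vac = g.comp(layer, i, "vacuole")
            pm_blocked = (
                mature and i == endo_ring and layer not in passage
            )
            add(cyt.index, apo.index, "plasma_membrane", cyt.pm_area, 1e-8, pm_blocked)
            add(cyt.index, vac.index, "tonoplast", cyt.tonoplast_area, 1e-8)
        # axial edges to the layer above
        if layer + 1 < g.n_axial:
            h_lo = g.layer_height(layer)
            h_hi = g.layer_height(layer + 1)
            for ring in g.rings:
                i = ring.radial_index
                lo_apo = g.comp(layer, i, "apoplast")
                hi_apo = g.comp(layer + 1, i, "apoplast")
                lo_conduit = g.zone_of_layer(layer) == "mature" and ring.name == "xylem"
                hi_conduit = g.zone_of_layer(layer + 1) == "mature" and ring.name == "xylem"
                area = ring.annulus_area * (1.0 if (lo_conduit and hi_conduit) else f_wall)
                add(lo_apo.index, hi_apo.index, "apoplast_axial", area,
                    0.5 * (h_lo + h_hi))
                if g.has_comp(layer, i, "cytosol") and g.has_comp(layer + 1, i, "cytosol"):
                    add(
                        g.comp(layer, i, "cytosol").index,
                        g.comp(layer + 1, i, "cytosol").index,
                        "plasmodesma",
                        ring.annulus_area * f_pd,
                        0.5 * (h_lo + h_hi),
                    )
    # top of the xylem conduit -> shoot (only when the top layer is mature)
    top = g.n_axial - 1
    if g.zone_of_layer(top) == "mature":
        xyl = g.rings[xyl_ring]
        add(
            g.comp(top, xyl_ring, "apoplast").index, SHOOT, "boundary_xylem_top",
            xyl.annulus_area, g.layer_height(top),
        )
    return ConnectivityGraph(edges)
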