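"""Atrial surface maps and the synthetic left-atrium generator.

An :class:`AtriumMap` bundles a triangulated left-atrial shell with the
per-vertex scalars (bipolar voltage, cycle length, region label) and the
anatomical landmarks the regional analysis needs: the four pulmonary-vein
(PV) ostium loops, the left-atrial-appendage (LAA) apex, the mitral rim and
optionally the wide-area circumferential PV isolation (WACPVI) ablation
line.

The synthetic atrium is an ellipsoidal shell (semi-axes ~35 x 28 x 25 mm)
with four tubular PV stubs on its postero-superior aspect, one LAA
protrusion antero-laterally and a mitral "valve" pole; low-voltage
(fibrosis) patches override the base voltage inside spherical
neighbourhoods. It carries a planted region ground truth so segmentation
can be scored against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import trimesh

from .errors import InvalidParameterError


class RegionLabel(IntEnum):
    """The 9 anatomical areas of the left-atrial shell."""

    LAA = 0
    PV_ANTRA = 1
    POSTERIOR = 2
    ROOF = 3
    LATERAL = 4
    SEPTUM = 5
    ANTERIOR = 6
    FLOOR = 7
    MITRAL = 8


UNLABELED = -1


@dataclass
class AtriumMap:
    """Triangulated atrial shell with scalars and landmarks."""

    mesh: trimesh.Trimesh
    voltage_mv: np.ndarray | None = None  # NaN = unobserved
    cycle_length_ms: np.ndarray | None = None
    region: np.ndarray | None = None  # int, UNLABELED where unknown
    pv_ostia: list = field(default_factory=list)  # vertex-index loops, LS first
    laa_apex: int | None = None  # vertex index
    mitral_rim: np.ndarray | None = None  # vertex indices
    ablation_line: list = field(default_factory=list)  # vertex-index loops
    region_seeds: dict = field(default_factory=dict)  # RegionLabel -> vertex idx array

    @property
    def n_vertices(self) -> int:
        return len(self.mesh.vertices)

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices.view(np.ndarray)

    @property
    def faces(self) -> np.ndarray:
        return self.mesh.faces.view(np.ndarray)

    def vertex_areas(self) -> np.ndarray:
        """One-third of the summed areas of each vertex's incident triangles."""
        fa = self.mesh.area_faces
        va = np.zeros(self.n_vertices)
        np.add.at(va, self.faces.ravel(), np.repeat(fa / 3.0, 3))
        return va

    def copy(self) -> "AtriumMap":
        return AtriumMap(
            mesh=self.mesh.copy(),
            voltage_mv=None if self.voltage_mv is None else self.voltage_mv.copy(),
            cycle_length_ms=None
            if self.cycle_length_ms is None
            else self.cycle_length_ms.copy(),
            region=None if self.region is None else self.region.copy(),
            pv_ostia=[np.array(l) for l in self.pv_ostia],
            laa_apex=self.laa_apex,
            mitral_rim=None if self.mitral_rim is None else np.array(self.mitral_rim),
            ablation_line=[np.array(l) for l in self.ablation_line],
            region_seeds={k: np.array(v) for k, v in self.region_seeds.items()},
        )


# unit directions of the anatomical features on the sphere before scaling:
# +x septal/right, -x lateral/left, +y posterior, -y anterior, +z roof
_PV_DIRECTIONS = {
    "LS": np.array([-0.70, 0.42, 0.58]),  # left superior (listed first)
    "LI": np.array([-0.80, 0.55, -0.10]),  # left inferior
    "RS": np.array([0.70, 0.42, 0.58]),  # right superior
    "RI": np.array([0.80, 0.55, -0.10]),  # right inferior
}
_LAA_DIRECTION = np.array([-0.62, -0.58, 0.53])
_SEMI_AXES_MM = np.array([35.0, 28.0, 25.0])

# canonical anchor directions ("clicks") seeding each non-antral region;
# regions are the geodesic Voronoi cells of these anchors
_REGION_ANCHOR_DIRECTIONS = {
    RegionLabel.LAA: [_LAA_DIRECTION],
    RegionLabel.POSTERIOR: [(0, 1, 0), (0.1, 0.95, 0.3), (-0.1, 0.95, -0.3)],
    RegionLabel.ROOF: [(0, 0.1, 1), (-0.3, 0, 0.95), (0.3, 0, 0.95)],
    RegionLabel.LATERAL: [(-1, 0, 0), (-0.95, -0.25, -0.15)],
    RegionLabel.SEPTUM: [(1, 0, 0), (0.95, -0.25, -0.15)],
    RegionLabel.ANTERIOR: [(0, -1, 0), (0.35, -0.92, 0.2), (-0.15, -0.95, -0.3)],
    RegionLabel.FLOOR: [(0.5, 0.35, -0.8), (-0.5, 0.35, -0.8), (0, -0.45, -0.88)],
    RegionLabel.MITRAL: [(0, 0, -1), (0.3, -0.25, -0.92), (-0.3, 0.25, -0.92)],
}


def _unit(v):
    return v / np.linalg.norm(v)


def make_synthetic_atrium(
    n_vertices: int = 1500,
    pv_count: int = 4,
    laa: bool = True,
    fibrosis_patches=None,
    base_voltage_mv: float = 1.0,
    with_wacpvi: bool = True,
    seed: int = 0,
) -> AtriumMap:
    """Build a synthetic left atrium with planted region ground truth.

    Parameters
    ----------
    n_vertices : int
        Lower bound on vertex count (>= 500); the smallest icosphere
        subdivision meeting it is used, so the actual count is one of
        642/2562/10242.
    pv_count : int
        Number of PV stubs (<= 4), taken in the order LS, LI, RS, RI.
    laa : bool
        Add the LAA protrusion (and its apex landmark).
    fibrosis_patches : list of (center, radius_mm, voltage_mv)
        Spherical low-voltage patches overriding the base voltage; ``center``
        is a 3-D point. Negative patch voltage is rejected.
    base_voltage_mv : float
        Healthy-tissue bipolar voltage outside the patches.
    with_wacpvi : bool
        Attach two closed ablation-line loops encircling the left and right
        PV pairs (only when ``pv_count == 4``).
    seed : int
        Reserved for stochastic variants; the base construction is
        deterministic.
    """
    if n_vertices < 500:
        raise InvalidParameterError("n_vertices must be >= 500")
    if base_voltage_mv < 0:
        raise InvalidParameterError("base voltage must be non-negative")
    for p in fibrosis_patches or []:
        if p[2] < 0:
            raise InvalidParameterError("patch voltage must be non-negative")

    sub = 3
    while 10 * 4**sub + 2 < n_vertices and sub < 5:
        sub += 1
    sphere = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
    dirs = sphere.vertices.view(np.ndarray).copy()  # unit directions
    verts = dirs * _SEMI_AXES_MM

    pv_names = list(_PV_DIRECTIONS)[: int(pv_count)]
    alpha_pv, h_pv = 0.22, 8.0
    alpha_laa, h_laa = 0.30, 12.0

    angles = {}
    for name in pv_names:
        u = _unit(_PV_DIRECTIONS[name])
        angles[name] = np.arccos(np.clip(dirs @ u, -1, 1))
        inside = angles[name] < alpha_pv
        taper = np.cos(angles[name][inside] / alpha_pv * np.pi / 2.0)
        verts[inside] += np.outer(taper * h_pv, u)
    ang_laa = np.arccos(np.clip(dirs @ _unit(_LAA_DIRECTION), -1, 1))
    if laa:
        inside = ang_laa < alpha_laa
        taper = np.cos(ang_laa[inside] / alpha_laa * np.pi / 2.0)
        verts[inside] += np.outer(taper * h_laa, _unit(_LAA_DIRECTION))

    mesh = trimesh.Trimesh(vertices=verts, faces=sphere.faces, process=False)

    # landmarks -------------------------------------------------------------
    pv_ostia = []
    for name in pv_names:
        band = np.where((angles[name] >= 0.68 * alpha_pv) & (angles[name] < alpha_pv))[0]
        pv_ostia.append(band)
    laa_apex = int(np.argmin(ang_laa)) if laa else None
    z_unit = dirs[:, 2]
    mitral_mask = z_unit < -0.78
    mitral_rim = np.where((z_unit < -0.70) & (z_unit >= -0.78))[0]

    # planted region ground truth: regions are geodesic Voronoi cells around
    # canonical anatomical anchor vertices (the operator's clicks), the PV
    # antra overriding them as the 1-cm geodesic band around the ostium
    # loops, truncated at the LAA ridge on the left-superior vein -----------
    from ._geo import geodesic_from

    anchor_vertices = {}
    for lab, anchor_dirs in _REGION_ANCHOR_DIRECTIONS.items():
        if lab is RegionLabel.LAA and not laa:
            continue
        ids = [int(np.argmax(dirs @ _unit(np.asarray(a)))) for a in anchor_dirs]
        anchor_vertices[lab] = np.unique(ids)

    dists = {lab: geodesic_from(mesh, v) for lab, v in anchor_vertices.items()}
    labs = sorted(dists)
    region = np.array(labs, dtype=int)[
        np.argmin(np.vstack([dists[l] for l in labs]), axis=0)
    ]

    antra = np.zeros(len(verts), bool)
    if pv_ostia_nonempty := [l for l in pv_ostia if len(l)]:
        d_ost = geodesic_from(mesh, np.concatenate(pv_ostia_nonempty))
        antra = d_ost <= 10.0
    if laa and "LS" in angles and len(pv_ostia) and len(pv_ostia[0]):
        # LAA ridge: the left-superior antrum stops at the ridge toward the LAA
        d_laa = geodesic_from(mesh, [int(np.argmin(ang_laa))])
        d_ls = geodesic_from(mesh, pv_ostia[0])
        antra &= ~(d_laa < d_ls)
    region[antra] = RegionLabel.PV_ANTRA

    # the stored landmarks are the same anchor clicks
    region_seeds = {lab: v.copy() for lab, v in anchor_vertices.items()}

    # voltage ---------------------------------------------------------------
    voltage = np.full(len(verts), float(base_voltage_mv))
    for center, radius_mm, v_mv in fibrosis_patches or []:
        d = np.linalg.norm(verts - np.asarray(center, dtype=float), axis=1)
        voltage[d <= radius_mm] = float(v_mv)

    # WACPVI ablation loops -------------------------------------------------
    ablation = []
    if with_wacpvi and pv_count == 4:
        for pair in (("LS", "LI"), ("RS", "RI")):
            wac_extra = 1.4 * 10.0 / float(_SEMI_AXES_MM.mean())  # just outside the antra
            enc = np.minimum(angles[pair[0]], angles[pair[1]]) < alpha_pv + wac_extra
            boundary = _boundary_vertices(mesh, enc)
            ablation.append(boundary)

    return AtriumMap(
        mesh=mesh,
        voltage_mv=voltage,
        region=region,
        pv_ostia=pv_ostia,
        laa_apex=laa_apex,
        mitral_rim=mitral_rim,
        ablation_line=ablation,
        region_seeds=region_seeds,
    )


def _boundary_vertices(mesh: trimesh.Trimesh, inside_mask: np.ndarray) -> np.ndarray:
    """Vertices of ``inside_mask`` with at least one neighbour outside it."""
    edges = mesh.edges_unique
    a, b = edges[:, 0], edges[:, 1]
    cross = inside_mask[a] != inside_mask[b]
    boundary = np.unique(np.concatenate([a[cross & inside_mask[a]], b[cross & inside_mask[b]]]))
    return boundary
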