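"""Mesh merging and regional analysis of atrial maps.

Patient shells are pre-aligned by centering at the origin, merged onto a
reference shell by non-rigid ICP, and scalars (voltage, cycle length,
driver locations) are projected onto the reference vertices. The reference
is segmented into the 9 anatomical areas from explicit landmarks, and
driver sites are classified against the WACPVI ablation line.

The non-rigid ICP runs a rigid Kabsch ICP first, then alternates
closest-point correspondence with a locally-smooth (Gaussian-kernel
regularized) displacement update under a decreasing stiffness schedule:
large kernels move the shell almost rigidly, small ones fit local shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from ._geo import SurfaceQuery
from ._geo import edge_graph as _edge_graph
from ._geo import geodesic_from
from .errors import ClassificationError, SegmentationError, UndefinedMetricError
from .meshes import UNLABELED, AtriumMap, RegionLabel


def _as_mesh(m) -> trimesh.Trimesh:
    return m.mesh if isinstance(m, AtriumMap) else m


def center_mesh(m):
    """Translate so the vertex centroid sits exactly at the origin.

    Accepts and returns an :class:`AtriumMap` or a raw ``trimesh.Trimesh``
    (a new object either way).
    """
    if isinstance(m, AtriumMap):
        out = m.copy()
        v = out.mesh.vertices.view(np.ndarray)
        out.mesh = trimesh.Trimesh(
            vertices=v - v.mean(axis=0), faces=out.mesh.faces, process=False
        )
        return out
    v = m.vertices.view(np.ndarray)
    return trimesh.Trimesh(vertices=v - v.mean(axis=0), faces=m.faces, process=False)


@dataclass
class Registration:
    """Result of merging a source shell onto the reference."""

    displacement: np.ndarray  # (n_source, 3), applied to source vertices
    correspondence: np.ndarray  # source vertex -> reference vertex index
    rms_pre_mm: float
    rms_post_mm: float
    converged: bool
    stage_rms_mm: list = field(default_factory=list)
    stiffness_schedule: tuple = ()

    def apply(self, points: np.ndarray, source_vertices: np.ndarray) -> np.ndarray:
        """Carry arbitrary points through the fitted deformation by
        nearest-source-vertex displacement."""
        tree = cKDTree(source_vertices)
        _, idx = tree.query(np.atleast_2d(points))
        return np.atleast_2d(points) + self.displacement[idx]


def _rms_to_surface(points: np.ndarray, query: SurfaceQuery) -> float:
    _, dist = query.closest(points)
    return float(np.sqrt(np.mean(dist**2)))


def _kabsch(src: np.ndarray, dst: np.ndarray):
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cd - r @ cs
    return r, t


def nonrigid_icp(
    source,
    reference,
    stiffness_schedule=(16.0, 8.0, 4.0, 2.0),
    iters_per_stage: int = 5,
    rigid_iters: int = 25,
    step: float = 0.8,
    tol_mm: float = 1e-3,
) -> Registration:
    """Register a source shell onto the reference (both centered).

    Stage 0 is rigid ICP (Kabsch on closest-vertex correspondences). Each
    non-rigid stage then repeats: find the closest reference surface point
    of every source vertex, smooth the resulting displacement field with a
    Gaussian kernel of width ``stiffness`` mm over the *original* source
    vertices, and take a relaxed step. Stops early when the mean update
    drops below ``tol_mm``.
    """
    src_mesh, ref_mesh = _as_mesh(source), _as_mesh(reference)
    v0 = src_mesh.vertices.view(np.ndarray).copy()
    ref_v = ref_mesh.vertices.view(np.ndarray)
    ref_tree = cKDTree(ref_v)
    ref_query = SurfaceQuery(ref_mesh)
    v = v0.copy()

    rms_pre = _rms_to_surface(v, ref_query)

    for _ in range(rigid_iters):
        _, idx = ref_tree.query(v)
        r, t = _kabsch(v, ref_v[idx])
        v_new = v @ r.T + t
        if np.abs(v_new - v).mean() < tol_mm:
            v = v_new
            break
        v = v_new

    stage_rms = [_rms_to_surface(v, ref_query)]
    converged = False
    for stiffness in stiffness_schedule:
        w = np.exp(
            -((np.linalg.norm(v0[:, None, :] - v0[None, :, :], axis=2)) ** 2)
            / (2.0 * stiffness**2)
        )
        w /= w.sum(axis=1, keepdims=True)
        for _ in range(iters_per_stage):
            closest, _ = ref_query.closest(v)
            d = closest - v
            upd = step * (w @ d)
            v = v + upd
            if np.abs(upd).mean() < tol_mm:
                converged = True
                break
        stage_rms.append(_rms_to_surface(v, ref_query))

    rms_post = stage_rms[-1]
    _, corr = ref_tree.query(v)
    return Registration(
        displacement=v - v0,
        correspondence=corr,
        rms_pre_mm=rms_pre,
        rms_post_mm=min(rms_post, rms_pre),
        converged=converged,
        stage_rms_mm=stage_rms,
        stiffness_schedule=tuple(stiffness_schedule),
    )


def project_scalars(
    points: np.ndarray,
    values: np.ndarray,
    reference,
    max_distance_mm: float = 10.0,
):
    """Project point-attached values onto the nearest reference vertices.

    Multiple values landing on one vertex are averaged; points farther than
    ``max_distance_mm`` from any vertex are dropped and counted. Returns
    ``(vertex_values, counts, n_dropped)`` with NaN at unobserved vertices.
    """
    ref_v = _as_mesh(reference).vertices.view(np.ndarray)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vals = np.asarray(values, dtype=float)
    tree = cKDTree(ref_v)
    dist, idx = tree.query(pts)
    keep = dist <= max_distance_mm
    n_dropped = int((~keep).sum())
    sums = np.zeros(len(ref_v))
    counts = np.zeros(len(ref_v), dtype=int)
    np.add.at(sums, idx[keep], vals[keep])
    np.add.at(counts, idx[keep], 1)
    out = np.full(len(ref_v), np.nan)
    obs = counts > 0
    out[obs] = sums[obs] / counts[obs]
    return out, counts, n_dropped


# ---------------------------------------------------------------------------
# geodesics


def geodesic_distance(mesh, seeds) -> np.ndarray:
    """Shortest-path distance (mm) along mesh edges from a seed vertex set."""
    return geodesic_from(_as_mesh(mesh), seeds)


def segment_regions(
    atrium: AtriumMap,
    antra_radius_mm: float = 10.0,
) -> np.ndarray:
    """Label every vertex with one of the 9 anatomical regions.

    Needs the map's landmarks: PV ostium loops (left-superior first), the
    LAA apex, the mitral rim, and seed vertices per region. Base labels
    come from a nearest-seed geodesic partition; the PV antra then override
    any vertex within ``antra_radius_mm`` geodesic distance of an ostium
    loop, except on the left-superior vein where the ridge toward the LAA
    truncates the antrum (vertices geodesically closer to the LAA apex
    than to the LS ostium keep their base label).
    """
    if not atrium.pv_ostia:
        raise SegmentationError("missing landmark: pv_ostia")
    if atrium.laa_apex is None:
        raise SegmentationError("missing landmark: laa_apex")
    if atrium.mitral_rim is None or len(atrium.mitral_rim) == 0:
        raise SegmentationError("missing landmark: mitral_rim")
    if not atrium.region_seeds:
        raise SegmentationError("missing landmark: region_seeds")

    mesh = atrium.mesh
    n = len(mesh.vertices)
    dist_by_region = {}
    for lab, seeds in atrium.region_seeds.items():
        dist_by_region[int(lab)] = geodesic_distance(mesh, seeds)
    labs = sorted(dist_by_region)
    stack = np.vstack([dist_by_region[l] for l in labs])
    labels = np.array(labs)[np.argmin(stack, axis=0)]

    d_ost = geodesic_distance(mesh, np.concatenate(atrium.pv_ostia))
    antra = d_ost <= antra_radius_mm
    d_laa = geodesic_distance(mesh, [atrium.laa_apex])
    d_ls = geodesic_distance(mesh, atrium.pv_ostia[0])
    ridge_block = antra & (d_laa < d_ls)
    antra &= ~ridge_block
    labels[antra] = int(RegionLabel.PV_ANTRA)
    assert not np.any(labels == UNLABELED)
    return labels


def classify_driver_location(site_position, atrium: AtriumMap) -> str:
    """Classify one driver site as ``inside`` or ``outside`` the WACPVI line.

    The encircled region is found by cutting the vertex graph along the
    ablation-line vertices and keeping the connected components that
    contain PV ostium vertices. A site whose nearest vertex lies on the
    line itself counts as inside (on-line tissue is presumed ablated). An
    ablation line that fails to separate the PVs from the mitral pole is
    rejected as open.
    """
    if not atrium.ablation_line:
        raise ClassificationError("no ablation line on this map")
    mesh = atrium.mesh
    line = np.unique(np.concatenate(atrium.ablation_line))
    g = _edge_graph(mesh).tolil()
    g[line, :] = 0
    g[:, line] = 0
    _, comp = connected_components(csr_matrix(g), directed=False)

    ost = np.setdiff1d(np.concatenate(atrium.pv_ostia), line)
    inside_comps = set(comp[ost])
    # openness check: the mitral rim must not share a component with the PVs
    rim = np.setdiff1d(np.asarray(atrium.mitral_rim), line)
    if len(rim) and inside_comps & set(comp[rim]):
        raise ClassificationError("ablation line is open: PVs reach the mitral rim")

    tree = cKDTree(mesh.vertices.view(np.ndarray))
    _, v = tree.query(np.asarray(site_position, dtype=float))
    if v in set(line):
        return "inside"
    return "inside" if comp[v] in inside_comps else "outside"


def classify_patient_rac_location(site_positions, atrium: AtriumMap) -> str:
    """Patient-level class: ``none`` / ``inside_only`` / ``outside``."""
    sites = np.atleast_2d(np.asarray(site_positions, dtype=float)) if len(site_positions) else []
    if len(sites) == 0:
        return "none"
    classes = [classify_driver_location(s, atrium) for s in sites]
    return "outside" if "outside" in classes else "inside_only"


@dataclass(frozen=True)
class VoltageMetrics:
    mean_mv: float
    area_fraction_below: dict  # threshold mV -> percent of observed area
    per_region_mean_mv: dict
    observed_area_mm2: float


def voltage_metrics(
    atrium: AtriumMap,
    thresholds_mv=(0.5, 0.35, 0.1),
) -> VoltageMetrics:
    """Area-weighted voltage summary of a map.

    Vertex weights are one-third of the summed incident triangle areas;
    fractions are of observed (non-NaN) area strictly below each threshold,
    reported in percent. Low-voltage area below 0.5/0.35/0.1 mV is the
    standard surrogate of structural remodeling.
    """
    if atrium.voltage_mv is None:
        raise UndefinedMetricError("map has no voltage")
    v = np.asarray(atrium.voltage_mv, dtype=float)
    w = atrium.vertex_areas()
    obs = ~np.isnan(v)
    if not np.any(obs):
        raise UndefinedMetricError("no observed vertices")
    wt = w[obs]
    vv = v[obs]
    total = wt.sum()
    fractions = {
        float(th): float(100.0 * wt[vv < th].sum() / total) for th in thresholds_mv
    }
    per_region = {}
    if atrium.region is not None:
        for lab in np.unique(atrium.region[obs]):
            m = obs & (atrium.region == lab)
            per_region[RegionLabel(lab).name if lab != UNLABELED else "UNLABELED"] = float(
                np.average(v[m], weights=w[m])
            )
    return VoltageMetrics(
        mean_mv=float(np.average(vv, weights=wt)),
        area_fraction_below=fractions,
        per_region_mean_mv=per_region,
        observed_area_mm2=float(total),
    )
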