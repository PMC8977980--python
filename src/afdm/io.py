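"""Reading and writing acquisition bundles, atrial meshes and cohorts.

The on-disk acquisition bundle is a documented open directory layout (the
vendor export format of clinical systems is proprietary and is not
parsed):

``meta.json``
    map/patient identifiers and per-acquisition metadata (rate, sample
    count, map position, optional ground truth).
``geometry.json``
    shared catheter geometry: electrode positions, ring/spline/bipole maps.
``unipolar_000.csv`` / ``bipolar_000.csv``
    one file pair per acquisition, one column per channel, headers
    "Penta k" / "Penta a-b", values with 10 significant digits.

Meshes travel as PLY (via trimesh) with per-vertex ``voltage`` and
``region`` properties plus a ``<name>.landmarks.json`` sidecar for ostium
loops, apex, rim and ablation line. Cohorts are plain CSV with the column
dictionary of :data:`afdm.cohort.COHORT_COLUMNS`.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .catheter import CatheterGeometry, N_ELECTRODES
from .cohort import COHORT_COLUMNS
from .errors import DataError, MissingInputError, SchemaError
from .meshes import UNLABELED, AtriumMap
from .simulate import Acquisition, ActivationField


@dataclass
class AcquisitionBundle:
    """A set of acquisitions from one mapping session."""

    acquisitions: list
    map_id: str = "map-0"
    patient_id: str = "patient-0"
    path: Path | None = None


# ---------------------------------------------------------------------------
# geometry / field serialization helpers


def _geometry_to_dict(g: CatheterGeometry) -> dict:
    return dict(
        electrode_positions=g.electrode_positions.tolist(),
        spline_index=g.spline_index.tolist(),
        ring_index=g.ring_index.tolist(),
        bipole_pairs=[list(p) for p in g.bipole_pairs],
        ring_radii_mm=g.ring_radii_mm.tolist(),
        deployment=g.deployment,
    )


def _geometry_from_dict(d: dict) -> CatheterGeometry:
    return CatheterGeometry(
        electrode_positions=np.asarray(d["electrode_positions"], dtype=float),
        spline_index=np.asarray(d["spline_index"], dtype=int),
        ring_index=np.asarray(d["ring_index"], dtype=int),
        bipole_pairs=tuple(tuple(p) for p in d["bipole_pairs"]),
        ring_radii_mm=np.asarray(d["ring_radii_mm"], dtype=float),
        deployment=float(d.get("deployment", 0.0)),
    )


def _field_to_dict(f: ActivationField) -> dict:
    return dict(
        pattern=f.pattern,
        cycle_length_ms=f.cycle_length_ms,
        n_beats=f.n_beats,
        lat_table={str(k): np.asarray(v).tolist() for k, v in f.lat_table.items()},
        source_position=None if f.source_position is None else f.source_position.tolist(),
        chirality=f.chirality,
        jitter_sd_ms=f.jitter_sd_ms,
    )


def _field_from_dict(d: dict) -> ActivationField:
    return ActivationField(
        pattern=d["pattern"],
        cycle_length_ms=float(d["cycle_length_ms"]),
        n_beats=int(d["n_beats"]),
        lat_table={int(k): np.asarray(v, dtype=float) for k, v in d["lat_table"].items()},
        source_position=None
        if d.get("source_position") is None
        else np.asarray(d["source_position"], dtype=float),
        chirality=int(d.get("chirality", 0)),
        jitter_sd_ms=float(d.get("jitter_sd_ms", 0.0)),
    )


def _unipolar_headers() -> list:
    return [f"Penta {k}" for k in range(1, N_ELECTRODES + 1)]


def _bipolar_headers(geometry: CatheterGeometry) -> list:
    return [f"Penta {a}-{b}" for a, b in geometry.bipole_pairs]


# ---------------------------------------------------------------------------
# acquisition bundles


def write_acquisition_bundle(bundle: AcquisitionBundle, path, force: bool = False) -> Path:
    """Write a bundle directory; refuses to overwrite unless ``force``."""
    path = Path(path)
    if path.exists():
        if not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
        shutil.rmtree(path)
    path.mkdir(parents=True)

    meta = dict(
        map_id=bundle.map_id,
        patient_id=bundle.patient_id,
        n_acquisitions=len(bundle.acquisitions),
        acquisitions=[],
    )
    if bundle.acquisitions:
        geom = bundle.acquisitions[0].geometry
        (path / "geometry.json").write_text(json.dumps(_geometry_to_dict(geom), indent=1))
    for k, acq in enumerate(bundle.acquisitions):
        meta["acquisitions"].append(
            dict(
                id=acq.acquisition_id,
                sampling_rate_hz=acq.sampling_rate_hz,
                n_samples=acq.n_samples,
                duration_s=acq.duration_s,
                map_position=np.asarray(acq.map_position).tolist(),
                ground_truth=None
                if acq.ground_truth is None
                else _field_to_dict(acq.ground_truth),
            )
        )
        pd.DataFrame(acq.unipolar, columns=_unipolar_headers()).to_csv(
            path / f"unipolar_{k:03d}.csv", index=False, float_format="%.10g"
        )
        pd.DataFrame(acq.bipolar, columns=_bipolar_headers(acq.geometry)).to_csv(
            path / f"bipolar_{k:03d}.csv", index=False, float_format="%.10g"
        )
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    bundle.path = path
    return path


def read_acquisition_bundle(path) -> AcquisitionBundle:
    """Read and validate a bundle directory.

    Raises :class:`MissingInputError` for absent files,
    :class:`SchemaError` when channel counts disagree with the geometry and
    :class:`DataError` (naming channel and sample indices) on NaN samples.
    """
    path = Path(path)
    if not path.is_dir():
        raise MissingInputError(f"bundle directory not found: {path}")
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise MissingInputError(f"missing file: {meta_path}")
    meta = json.loads(meta_path.read_text())
    n_acq = int(meta.get("n_acquisitions", 0))

    geometry = None
    if n_acq:
        geom_path = path / "geometry.json"
        if not geom_path.exists():
            raise MissingInputError(f"missing file: {geom_path}")
        geometry = _geometry_from_dict(json.loads(geom_path.read_text()))

    acquisitions = []
    for k in range(n_acq):
        am = meta["acquisitions"][k]
        uni_path = path / f"unipolar_{k:03d}.csv"
        bip_path = path / f"bipolar_{k:03d}.csv"
        for p in (uni_path, bip_path):
            if not p.exists():
                raise MissingInputError(f"missing file: {p}")
        uni = pd.read_csv(uni_path)
        bip = pd.read_csv(bip_path)
        if uni.shape[1] != N_ELECTRODES:
            raise SchemaError(
                f"{uni_path.name}: expected {N_ELECTRODES} unipolar columns, got {uni.shape[1]}"
            )
        if bip.shape[1] != len(geometry.bipole_pairs):
            raise SchemaError(
                f"{bip_path.name}: expected {len(geometry.bipole_pairs)} bipolar "
                f"columns, got {bip.shape[1]}"
            )
        for name, frame in ((uni_path.name, uni), (bip_path.name, bip)):
            vals = frame.to_numpy(dtype=float)
            if np.isnan(vals).any():
                ch, smp = np.where(np.isnan(vals.T))
                locs = ", ".join(
                    f"(channel {c + 1}, sample {s})" for c, s in list(zip(ch, smp))[:5]
                )
                raise DataError(f"{name}: NaN samples at {locs}")
        acquisitions.append(
            Acquisition(
                unipolar=uni.to_numpy(dtype=float),
                bipolar=bip.to_numpy(dtype=float),
                sampling_rate_hz=float(am["sampling_rate_hz"]),
                geometry=geometry,
                map_position=np.asarray(am["map_position"], dtype=float),
                ground_truth=None
                if am.get("ground_truth") is None
                else _field_from_dict(am["ground_truth"]),
                acquisition_id=str(am["id"]),
            )
        )
    return AcquisitionBundle(
        acquisitions=acquisitions,
        map_id=str(meta.get("map_id", "map-0")),
        patient_id=str(meta.get("patient_id", "patient-0")),
        path=path,
    )


# ---------------------------------------------------------------------------
# meshes


def write_mesh(atrium: AtriumMap, path, encoding: str = "ascii") -> Path:
    """Write an atrial map as PLY (+ landmarks sidecar)."""
    from trimesh.exchange.ply import export_ply

    path = Path(path)
    mesh = atrium.mesh.copy()
    n = len(mesh.vertices)
    mesh.vertex_attributes["voltage"] = (
        np.full(n, np.nan) if atrium.voltage_mv is None else np.asarray(atrium.voltage_mv, float)
    )
    mesh.vertex_attributes["region"] = (
        np.full(n, UNLABELED, dtype=np.int32)
        if atrium.region is None
        else np.asarray(atrium.region, dtype=np.int32)
    )
    if atrium.cycle_length_ms is not None:
        mesh.vertex_attributes["cycle_length"] = np.asarray(atrium.cycle_length_ms, float)
    path.write_bytes(export_ply(mesh, encoding=encoding, include_attributes=True))

    sidecar = dict(
        pv_ostia=[np.asarray(l).tolist() for l in atrium.pv_ostia],
        laa_apex=atrium.laa_apex,
        mitral_rim=None if atrium.mitral_rim is None else np.asarray(atrium.mitral_rim).tolist(),
        ablation_line=[np.asarray(l).tolist() for l in atrium.ablation_line],
        region_seeds={str(int(k)): np.asarray(v).tolist() for k, v in atrium.region_seeds.items()},
    )
    path.with_suffix(path.suffix + ".landmarks.json").write_text(json.dumps(sidecar))
    return path


def read_mesh(path) -> AtriumMap:
    """Read a PLY atrial map; missing ``voltage`` loads as absent (None)."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"mesh not found: {path}")
    try:
        mesh = trimesh.load(path, file_type="ply", process=False)
    except Exception as exc:
        raise SchemaError(f"cannot parse PLY {path}: {exc}") from exc
    raw = mesh.metadata.get("_ply_raw", {})
    vert = raw.get("vertex", {}).get("data", {})

    def _col(name):
        if isinstance(vert, dict) and name in vert:
            return np.asarray(vert[name]).ravel()
        if hasattr(vert, "dtype") and name in (vert.dtype.names or ()):
            return np.asarray(vert[name]).ravel()
        return None

    voltage = _col("voltage")
    region = _col("region")
    cl = _col("cycle_length")
    atrium = AtriumMap(
        mesh=trimesh.Trimesh(
            vertices=mesh.vertices.view(np.ndarray),
            faces=mesh.faces.view(np.ndarray),
            process=False,
        ),
        voltage_mv=None if voltage is None else voltage.astype(float),
        region=None if region is None else region.astype(int),
        cycle_length_ms=None if cl is None else cl.astype(float),
    )
    sidecar = path.with_suffix(path.suffix + ".landmarks.json")
    if sidecar.exists():
        lm = json.loads(sidecar.read_text())
        atrium.pv_ostia = [np.asarray(l, dtype=int) for l in lm.get("pv_ostia", [])]
        atrium.laa_apex = lm.get("laa_apex")
        atrium.mitral_rim = (
            None if lm.get("mitral_rim") is None else np.asarray(lm["mitral_rim"], dtype=int)
        )
        atrium.ablation_line = [np.asarray(l, dtype=int) for l in lm.get("ablation_line", [])]
        from .meshes import RegionLabel

        atrium.region_seeds = {
            RegionLabel(int(k)): np.asarray(v, dtype=int)
            for k, v in lm.get("region_seeds", {}).items()
        }
    return atrium


# ---------------------------------------------------------------------------
# cohorts


def write_cohort(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort(path, require_columns=("gender", "recurrence")) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"cohort file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in require_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort missing columns: {missing} (see COHORT_COLUMNS)")
    return df
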