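"""Geometry of the 20-pole mapping catheter (5 splines x 4 electrodes).

Electrodes are numbered 1..20 along splines: spline ``s`` (0-based) carries
electrodes ``4s+1 .. 4s+4`` from the outermost to the innermost ring, so the
four concentric rings are

* ring 1 (external):        1, 5, 9, 13, 17
* ring 2 (external middle): 2, 6, 10, 14, 18
* ring 3 (internal middle): 3, 7, 11, 15, 19
* ring 4 (internal):        4, 8, 12, 16, 20

Bipolar channels pair adjacent electrodes on a spline: the external bipolar
ring is (1-2), (5-6), ..., (17-18) and the internal one (3-4), (7-8), ...,
(19-20), ten bipoles in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_SPLINES = 5
N_RINGS = 4
N_ELECTRODES = N_SPLINES * N_RINGS

#: default nominal ring radii in mm, external to internal (configurable; the
#: clinical catheter's exact spacing is not standardized here)
DEFAULT_RING_RADII_MM = (10.0, 7.0, 4.0, 2.0)


class InvalidGeometryError(ValueError):
    """Raised when catheter construction parameters are inconsistent."""


@dataclass(frozen=True)
class CatheterGeometry:
    """Electrode positions and index maps for the 5x4 mapping catheter.

    Attributes
    ----------
    electrode_positions : (20, 3) float array, mm
        Positions indexed by electrode number - 1.
    spline_index : (20,) int array
        0-based spline of each electrode.
    ring_index : (20,) int array
        Ring 1..4 of each electrode (1 = external).
    bipole_pairs : tuple of (int, int)
        1-based adjacent-electrode pairs forming the bipolar channels.
    ring_radii_mm : (4,) float array
        Ring radii, strictly decreasing external to internal.
    """

    electrode_positions: np.ndarray
    spline_index: np.ndarray
    ring_index: np.ndarray
    bipole_pairs: tuple
    ring_radii_mm: np.ndarray
    deployment: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.electrode_positions, dtype=float)
        if pos.shape != (N_ELECTRODES, 3):
            raise InvalidGeometryError(
                f"expected {N_ELECTRODES} electrode positions, got {pos.shape}"
            )
        rings = np.asarray(self.ring_index)
        for r in range(1, N_RINGS + 1):
            if (rings == r).sum() != N_SPLINES:
                raise InvalidGeometryError(f"ring {r} must hold {N_SPLINES} electrodes")

    @property
    def center(self) -> np.ndarray:
        """Geometric center of the catheter (mean electrode position)."""
        return self.electrode_positions.mean(axis=0)

    def ring_electrodes(self, ring: int) -> np.ndarray:
        """1-based electrode numbers of ``ring`` (1..4), in spline order."""
        return np.where(self.ring_index == ring)[0] + 1

    def electrode_azimuth(self, about: np.ndarray | None = None) -> np.ndarray:
        """Azimuthal angle (rad, in [0, 2pi)) of each electrode in the
        catheter plane, measured about ``about`` (default: catheter center)."""
        c = self.center if about is None else np.asarray(about, dtype=float)
        rel = self.electrode_positions - c
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        return np.mod(theta, 2.0 * np.pi)

    def pairwise_distance(self, e1: int, e2: int) -> float:
        """Euclidean distance (mm) between 1-based electrodes ``e1``, ``e2``."""
        return float(
            np.linalg.norm(
                self.electrode_positions[e1 - 1] - self.electrode_positions[e2 - 1]
            )
        )

    @property
    def inter_electrode_spacing_mm(self) -> float:
        """Median distance between along-spline electrode neighbours."""
        d = [
            self.pairwise_distance(4 * s + k, 4 * s + k + 1)
            for s in range(N_SPLINES)
            for k in (1, 2, 3)
        ]
        return float(np.median(d))


def _bipole_pairs() -> tuple:
    # external ring (1-2),(5-6),... then internal (3-4),(7-8),...
    ext = [(4 * s + 1, 4 * s + 2) for s in range(N_SPLINES)]
    inn = [(4 * s + 3, 4 * s + 4) for s in range(N_SPLINES)]
    return tuple(ext + inn)


def make_catheter_geometry(
    ring_radii_mm=DEFAULT_RING_RADII_MM, deployment: float = 0.0
) -> CatheterGeometry:
    """Build the catheter with 5 equally spaced splines and 4 concentric rings.

    Parameters
    ----------
    ring_radii_mm : sequence of 4 positive floats
        Ring radii external to internal; must be strictly decreasing.
    deployment : float
        Planarity parameter. 0 gives a flat (fully deployed, in-contact)
        catheter; positive values dome the splines out of plane by
        ``deployment * (r_max - r)`` mm, producing partially deployed
        geometries that acquisition screening can reject.

    Returns
    -------
    CatheterGeometry
    """
    radii = np.asarray(ring_radii_mm, dtype=float)
    if radii.shape != (N_RINGS,):
        raise InvalidGeometryError(f"need {N_RINGS} ring radii, got {radii.shape}")
    if np.any(radii <= 0):
        raise InvalidGeometryError("ring radii must be positive")
    if np.any(np.diff(radii) >= 0):
        raise InvalidGeometryError(
            "ring radii must be strictly decreasing from external to internal"
        )

    pos = np.zeros((N_ELECTRODES, 3))
    spline = np.zeros(N_ELECTRODES, dtype=int)
    ring = np.zeros(N_ELECTRODES, dtype=int)
    for s in range(N_SPLINES):
        phi = 2.0 * np.pi * s / N_SPLINES
        for r in range(N_RINGS):
            e = 4 * s + r  # 0-based electrode index
            rad = radii[r]
            z = deployment * (radii[0] - rad)
            pos[e] = (rad * np.cos(phi), rad * np.sin(phi), z)
            spline[e] = s
            ring[e] = r + 1
    return CatheterGeometry(
        electrode_positions=pos,
        spline_index=spline,
        ring_index=ring,
        bipole_pairs=_bipole_pairs(),
        ring_radii_mm=radii,
        deployment=float(deployment),
    )
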