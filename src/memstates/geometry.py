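"""Conformer geometry in a fixed membrane frame.

The membrane is modelled as a plane with outward normal +z; the phosphate
plane of the protein-side (cis) leaflet defines z = 0, so every height in
the package is "distance above the phosphorous plane".  A conformer is a
rigid snapshot of the protein carrying point reporters (methyl carbons),
each tagged as belonging to the G domain or to the membrane-anchoring
N-terminal helix.

Orientation of the G domain is described by two angles extracted from the
least-squares (Kabsch) rotation R that superposes a reference conformer
onto the conformer of interest:

* beta  — polar tilt: angle between R·ẑ and the membrane normal, [0, 180]°
* gamma — azimuthal spin: azimuth of R·x̂ about the normal, measured from
  the membrane x̂ axis, [0, 360)°

The reference's stored pose therefore defines the zero orientation.  When a
shape-anchored convention is wanted, :func:`canonicalize_reference` rotates
a reference into its principal-axes pose first (largest-variance axis to ẑ,
sign toward +z).  ``gamma_offset_deg`` / ``beta_offset_deg`` allow
calibrating the azimuth/tilt origin against an external convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import KB_KCAL_MOL

__all__ = [
    "MembraneFrame",
    "Conformer",
    "Orientation",
    "StateDefinition",
    "PMFSurface",
    "DEFAULT_STATES",
    "compute_orientation",
    "com_height",
    "assign_state",
    "validate_states",
    "pmf_from_orientations",
    "principal_frame",
    "canonicalize_reference",
    "rotation_from_orientation",
]

G_DOMAIN = "g_domain"
N_HELIX = "n_helix"


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent conformer geometry."""


@dataclass(frozen=True)
class MembraneFrame:
    """Fixed laboratory frame: +z is the outward normal of the cis leaflet.

    ``phosphate_plane_z`` is the z-coordinate (in the coordinates of the
    input files) of the cis-leaflet phosphate plane; heights are reported
    relative to it.
    """

    phosphate_plane_z: float = 0.0
    leaflet_sign: int = +1

    def __post_init__(self) -> None:
        if not np.isfinite(self.phosphate_plane_z):
            raise GeometryError("phosphate_plane_z must be finite")


@dataclass
class Conformer:
    """One rigid snapshot: reporter coordinates (angstrom) in the membrane frame."""

    id: str
    reporter_table: dict[str, np.ndarray]
    reporter_roles: dict[str, str]
    g_domain_residue_range: tuple[int, int] = (17, 181)

    def __post_init__(self) -> None:
        table = {}
        for rid, xyz in self.reporter_table.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise GeometryError(f"reporter {rid!r} has invalid coordinates")
            table[rid] = arr
        self.reporter_table = table
        missing = set(self.reporter_table) - set(self.reporter_roles)
        if missing:
            raise GeometryError(f"reporters without roles: {sorted(missing)}")
        if not any(r == G_DOMAIN for r in self.reporter_roles.values()):
            raise GeometryError("conformer has no g_domain reporters")

    def reporter_ids(self, role: str | None = None) -> list[str]:
        if role is None:
            return list(self.reporter_table)
        return [r for r in self.reporter_table if self.reporter_roles[r] == role]

    def coords(self, role: str | None = None) -> np.ndarray:
        ids = self.reporter_ids(role)
        return np.array([self.reporter_table[r] for r in ids])

    def transformed(
        self,
        rotation: Rotation | None = None,
        translation: np.ndarray | None = None,
        pivot: np.ndarray | None = None,
        role: str | None = None,
        new_id: str | None = None,
    ) -> "Conformer":
        """Rigid transform (rotation about ``pivot``, then translation).

        ``role`` restricts the transform to reporters of that role (the
        others keep their coordinates) — used to reorient the G domain
        while the membrane-anchored helix stays put.
        """
        pivot = np.zeros(3) if pivot is None else np.asarray(pivot, float)
        translation = np.zeros(3) if translation is None else np.asarray(translation, float)
        table = {}
        for rid, xyz in self.reporter_table.items():
            if role is None or self.reporter_roles[rid] == role:
                p = xyz - pivot
                if rotation is not None:
                    p = rotation.apply(p)
                table[rid] = p + pivot + translation
            else:
                table[rid] = xyz.copy()
        return Conformer(
            id=new_id or self.id,
            reporter_table=table,
            reporter_roles=dict(self.reporter_roles),
            g_domain_residue_range=self.g_domain_residue_range,
        )


@dataclass(frozen=True)
class Orientation:
    """G-domain orientation: polar tilt beta, azimuthal spin gamma (degrees)."""

    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 180.0):
            raise GeometryError(f"beta={self.beta} outside [0, 180]")
        object.__setattr__(self, "gamma", float(self.gamma) % 360.0)


def _wrap_interval(lo: float, hi: float) -> tuple[float, float]:
    return lo % 360.0, hi % 360.0


def _gamma_in_arc(gamma: float, lo: float, hi: float) -> bool:
    g = gamma % 360.0
    lo, hi = _wrap_interval(lo, hi)
    if lo <= hi:
        return lo <= g <= hi
    return g >= lo or g <= hi  # arc wraps past 360


def _arc_overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Length of the intersection of two circular arcs (degrees)."""

    def segments(lo: float, hi: float) -> list[tuple[float, float]]:
        lo, hi = _wrap_interval(lo, hi)
        if lo <= hi:
            return [(lo, hi)]
        return [(lo, 360.0), (0.0, hi)]

    total = 0.0
    for a0, a1 in segments(*a):
        for b0, b1 in segments(*b):
            total += max(0.0, min(a1, b1) - max(a0, b0))
    return total


@dataclass(frozen=True)
class StateDefinition:
    """Named rectangular (beta, gamma) bin; gamma honours circular wraparound."""

    name: str
    beta_range: tuple[float, float]
    gamma_range: tuple[float, float]
    tag: str | None = None

    def __post_init__(self) -> None:
        b0, b1 = self.beta_range
        if not b0 < b1:
            raise GeometryError(f"state {self.name!r}: empty beta interval")
        g0, g1 = self.gamma_range
        if g0 == g1:
            raise GeometryError(f"state {self.name!r}: empty gamma interval")

    def contains(self, o: Orientation) -> bool:
        b0, b1 = self.beta_range
        return b0 <= o.beta <= b1 and _gamma_in_arc(o.gamma, *self.gamma_range)


#: The three membrane-proximal orientational states of the G domain.
DEFAULT_STATES: tuple[StateDefinition, ...] = (
    StateDefinition("S1", (57.0, 73.0), (115.0, 187.0), tag="occluded"),
    StateDefinition("S2", (8.0, 20.0), (64.0, 118.0), tag="exposed-swI"),
    StateDefinition("S3", (20.0, 30.0), (0.0, 50.0), tag="exposed"),
)

UNASSIGNED = "unassigned"


def validate_states(states: Sequence[StateDefinition]) -> None:
    """Reject state sets whose (beta, gamma) bins overlap with positive area."""
    names = [s.name for s in states]
    if len(set(names)) != len(names):
        raise GeometryError("duplicate state names")
    for i, a in enumerate(states):
        for b in states[i + 1 :]:
            db = min(a.beta_range[1], b.beta_range[1]) - max(a.beta_range[0], b.beta_range[0])
            if db > 0 and _arc_overlap(a.gamma_range, b.gamma_range) > 0:
                raise GeometryError(f"states {a.name!r} and {b.name!r} overlap")


def assign_state(o: Orientation, states: Sequence[StateDefinition]) -> str:
    """Name of the unique state containing ``o``, else ``"unassigned"``."""
    validate_states(states)
    for s in states:
        if s.contains(o):
            return s.name
    return UNASSIGNED


def _common_gdomain_points(
    conformer: Conformer, reference: Conformer
) -> tuple[np.ndarray, np.ndarray]:
    common = sorted(
        set(conformer.reporter_ids(G_DOMAIN)) & set(reference.reporter_ids(G_DOMAIN))
    )
    if len(common) < 3:
        raise GeometryError(
            f"conformer {conformer.id!r}: fewer than 3 common g_domain reporters"
        )
    a = np.array([conformer.reporter_table[r] for r in common])
    b = np.array([reference.reporter_table[r] for r in common])
    return a, b


def compute_orientation(
    conformer: Conformer,
    reference: Conformer,
    beta_offset_deg: float = 0.0,
    gamma_offset_deg: float = 0.0,
) -> Orientation:
    """Tilt/spin angles of ``conformer`` relative to ``reference``.

    The optimal rotation R superposing the reference onto the conformer
    (common G-domain reporters, translations removed) is extracted with
    Kabsch superposition; beta is the polar angle of R·ẑ against the
    membrane normal and gamma the azimuth of R·x̂ about the normal.  The
    offsets shift the angle origins for calibration against an external
    orientation convention.
    """
    a, b = _common_gdomain_points(conformer, reference)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sv = np.linalg.svd(b, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise GeometryError(f"conformer {conformer.id!r}: collinear reporter geometry")
    rot, _ = Rotation.align_vectors(a, b)
    z_img = rot.apply([0.0, 0.0, 1.0])
    beta = float(np.degrees(np.arccos(np.clip(z_img[2], -1.0, 1.0))))
    x_img = rot.apply([1.0, 0.0, 0.0])
    gamma = float(np.degrees(np.arctan2(x_img[1], x_img[0]))) % 360.0
    beta = min(max(beta + beta_offset_deg, 0.0), 180.0)
    return Orientation(beta=beta, gamma=(gamma + gamma_offset_deg) % 360.0)


def rotation_from_orientation(beta_deg: float, gamma_deg: float) -> Rotation:
    """Canonical rotation R_z(gamma)·R_y(beta) carrying the given angles.

    For beta < 90° this is the unique tilt-then-spin rotation whose
    (beta, gamma) read-out by :func:`compute_orientation` round-trips.
    """
    return Rotation.from_euler("yz", [beta_deg, gamma_deg], degrees=True)


def com_height(
    conformer: Conformer,
    role: str = G_DOMAIN,
    frame: MembraneFrame = MembraneFrame(),
) -> float:
    """Centroid z of the role's reporters, relative to the phosphate plane (A)."""
    ids = conformer.reporter_ids(role)
    if not ids:
        raise GeometryError(f"conformer {conformer.id!r}: no reporters with role {role!r}")
    z = np.array([conformer.reporter_table[r][2] for r in ids])
    return float(z.mean() - frame.phosphate_plane_z)


def principal_frame(conformer: Conformer, role: str = G_DOMAIN) -> Rotation:
    """Rotation taking the conformer's principal axes onto the membrane axes.

    Largest-variance axis maps to ẑ, second to x̂; eigenvalue ties are
    broken by descending eigenvalue then lexicographic axis preference,
    and axis signs point toward the positive membrane axes (ẑ preferred).
    """
    pts = conformer.coords(role)
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(-evals, kind="stable")
    axes = evecs[:, order]  # columns: body z-candidate first
    z_ax, x_ax = axes[:, 0], axes[:, 1]
    if z_ax[2] < 0 or (z_ax[2] == 0 and (z_ax[0] < 0 or (z_ax[0] == 0 and z_ax[1] < 0))):
        z_ax = -z_ax
    if x_ax[0] < 0 or (x_ax[0] == 0 and (x_ax[1] < 0 or (x_ax[1] == 0 and x_ax[2] < 0))):
        x_ax = -x_ax
    x_ax = x_ax - z_ax * (x_ax @ z_ax)
    x_ax = x_ax / np.linalg.norm(x_ax)
    y_ax = np.cross(z_ax, x_ax)
    body = np.column_stack([x_ax, y_ax, z_ax])  # body axes in membrane coords
    return Rotation.from_matrix(body.T)


def canonicalize_reference(reference: Conformer) -> Conformer:
    """Rotate a reference into its principal-axes pose (body axes = membrane axes)."""
    rot = principal_frame(reference)
    centroid = reference.coords(G_DOMAIN).mean(axis=0)
    return reference.transformed(rotation=rot, pivot=centroid, new_id=reference.id)


UNVISITED = float("nan")


@dataclass
class PMFSurface:
    """Potential of mean force over (beta, gamma) bins, kcal/mol.

    Empty bins hold NaN (an explicit "unvisited" marker), never 0 or inf;
    the minimum over occupied bins is exactly 0.
    """

    beta_bin_edges: np.ndarray
    gamma_bin_edges: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray
    temperature: float
    empty_bin_policy: str = "nan"

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


def pmf_from_orientations(
    orientations: Iterable[Orientation],
    bin_width_beta: float = 5.0,
    bin_width_gamma: float = 5.0,
    temperature: float = 298.15,
) -> PMFSurface:
    """Histogram orientations and convert to F = -kT ln(n/n_max), min = 0."""
    os_ = list(orientations)
    if not os_:
        raise GeometryError("empty orientation list")
    if temperature <= 0:
        raise GeometryError("temperature must be positive")
    if 180.0 % bin_width_beta != 0 or 360.0 % bin_width_gamma != 0:
        raise GeometryError("bin widths must divide the angular ranges")
    beta = np.array([o.beta for o in os_])
    gamma = np.array([o.gamma for o in os_])
    b_edges = np.arange(0.0, 180.0 + bin_width_beta / 2, bin_width_beta)
    g_edges = np.arange(0.0, 360.0 + bin_width_gamma / 2, bin_width_gamma)
    counts, _, _ = np.histogram2d(beta, gamma, bins=[b_edges, g_edges])
    kt = KB_KCAL_MOL * temperature
    free = np.full_like(counts, UNVISITED)
    occ = counts > 0
    free[occ] = -kt * np.log(counts[occ] / counts.max())
    return PMFSurface(
        beta_bin_edges=b_edges,
        gamma_bin_edges=g_edges,
        counts=counts,
        free_energy=free,
        temperature=float(temperature),
    )
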