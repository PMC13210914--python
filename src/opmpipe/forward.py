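"""Sensor-array geometry, sphere head model, and Sarvas forward fields.

The head is a homogeneous conducting sphere.  The magnetic field of a
current dipole inside such a sphere has the Sarvas closed form; its key
property is that radially oriented dipoles are externally silent, and the
radial field component outside the sphere equals that of the primary
current alone.  Sources live on an inner spherical shell, oriented
tangentially (a radial orientation — "normal to the cortex" on a sphere —
would be invisible), so the default tangential direction is the local
anterior–posterior unit vector, emulating sulcal-bank generators.

Coordinate frame: x through the preauricular axis (+x right), y through
the nasion (+y anterior), z up, origin at the sphere center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MU0_OVER_4PI = 1e-7  # T·m/A

#: Six sensorimotor regions of interest, ordered anterior → posterior.
ROI_NAMES = (
    "superior precentral sulcus",
    "precentral gyrus",
    "central sulcus",
    "postcentral gyrus",
    "postcentral sulcus",
    "superior parietal lobule",
)

#: Scalp sensor labels (extended 10-05, modified combinatorial nomenclature:
#: FC7 ≡ FT7, C7 ≡ T7, CP7 ≡ TP7, C9 ≡ T9).
SCALP_LABELS = (
    "FC1", "C1", "CP1",
    "FC3", "C3", "CP3",
    "FC5", "C5", "CP5",
    "FC7", "C7", "CP7",
    "C9",
)

REFERENCE_LABELS = ("REF_SUP", "REF_POST", "REF_LEFT")


@dataclass(frozen=True)
class SphereHeadModel:
    """Homogeneous conducting sphere standing in for a head model.

    Parameters
    ----------
    center : array-like of 3 floats
        Sphere center in head coordinates [m].
    scalp_radius : float
        Outer (scalp) radius [m].
    source_radius : float
        Radius of the source shell [m]; must be strictly inside the scalp.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scalp_radius: float = 0.09
    source_radius: float = 0.07

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("center must be a finite 3-vector")
        object.__setattr__(self, "center", c)
        if not (0.0 < self.source_radius < self.scalp_radius):
            raise ValueError("require 0 < source_radius < scalp_radius")


@dataclass
class SensorArray:
    """Magnetometer array: positions, sensitive axes, reference flags."""

    names: list[str]
    positions: np.ndarray  # (n, 3) [m]
    orientations: np.ndarray  # (n, 3) unit vectors
    is_reference: np.ndarray  # (n,) bool

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, float))
        self.is_reference = np.asarray(self.is_reference, bool)
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValueError("channel names must be unique")
        if self.positions.shape != (n, 3) or self.orientations.shape != (n, 3):
            raise ValueError("positions/orientations must be (n, 3)")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must be unit vectors")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    @property
    def scalp_names(self) -> list[str]:
        return [n for n, r in zip(self.names, self.is_reference) if not r]

    def scalp(self) -> "SensorArray":
        """Sub-array of the non-reference channels."""
        keep = ~self.is_reference
        return SensorArray(
            [n for n, k in zip(self.names, keep) if k],
            self.positions[keep],
            self.orientations[keep],
            self.is_reference[keep],
        )

    def pick(self, names: list[str]) -> "SensorArray":
        idx = [self.names.index(n) for n in names]
        return SensorArray(
            [self.names[i] for i in idx],
            self.positions[idx],
            self.orientations[idx],
            self.is_reference[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "ox": self.orientations[:, 0],
                "oy": self.orientations[:, 1],
                "oz": self.orientations[:, 2],
                "is_reference": self.is_reference.astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "SensorArray":
        df = pd.read_csv(path, sep="\t")
        return cls(
            df["name"].tolist(),
            df[["x", "y", "z"]].to_numpy(float),
            df[["ox", "oy", "oz"]].to_numpy(float),
            df["is_reference"].to_numpy(bool),
        )


@dataclass
class SourceGrid:
    """Tangentially oriented dipole grid on the source shell, ROI-labelled."""

    vertices: np.ndarray  # (m, 3) [m]
    orientations: np.ndarray  # (m, 3) unit tangential vectors
    roi_labels: list[str]

    def __post_init__(self):
        self.vertices = np.atleast_2d(np.asarray(self.vertices, float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, float))
        if len(self.roi_labels) != self.vertices.shape[0]:
            raise ValueError("one ROI label per vertex required")

    @property
    def n_sources(self) -> int:
        return self.vertices.shape[0]

    def roi_index(self, roi: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roi_labels) if r == roi])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [f"src{i:03d}" for i in range(self.n_sources)],
                "x": self.vertices[:, 0],
                "y": self.vertices[:, 1],
                "z": self.vertices[:, 2],
                "ox": self.orientations[:, 0],
                "oy": self.orientations[:, 1],
                "oz": self.orientations[:, 2],
                "roi_label": self.roi_labels,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class LeadField:
    """Forward solution: scalp channels × sources, tesla per A·m."""

    matrix: np.ndarray  # (n_channels, m_sources)
    channel_names: list[str]
    source_index: np.ndarray

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, float))
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead field must be finite")

    def pick_channels(self, names: list[str]) -> "LeadField":
        idx = [self.channel_names.index(n) for n in names]
        return LeadField(self.matrix[idx], names, self.source_index)


@dataclass
class SensitivityMap:
    """Per-vertex field norm for a unit source, with per-ROI summaries."""

    values: np.ndarray  # (m,) [T per A·m]
    per_roi_mean: dict[str, float]
    per_roi_sd: dict[str, float]


# ---------------------------------------------------------------------------
# Idealized 10-05 layout (arc-division construction on the unit sphere)

def _slerp(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    omega = math.acos(float(np.clip(np.dot(a, b), -1.0, 1.0)))
    if omega < 1e-12:
        return a.copy()
    return (math.sin((1 - frac) * omega) * a + math.sin(frac * omega) * b) / math.sin(omega)


def _unit_sphere_1005() -> dict[str, np.ndarray]:
    """Unit vectors for the supported 10-05 labels on an idealized sphere.

    Construction: the C row runs along the ear-to-ear coronal arc at 18°
    steps from the vertex (C1=18°, C3=36°, C5=54°, C7=72°, C9=90°); the FC
    and CP rows are great-circle arcs from FCz/CPz (18° anterior/posterior
    of the vertex on the midline) to FC7/CP7 on the 10% circumferential
    circle (polar 72°, azimuth 72°/108° from the nasion), divided at
    quarters — the textbook idealized layout.
    """
    def pol(theta_deg: float, az_deg: float) -> np.ndarray:
        # polar angle from +z; azimuth from +y (nasion) rotating toward -x (left)
        t, a = math.radians(theta_deg), math.radians(az_deg)
        return np.array([-math.sin(t) * math.sin(a), math.sin(t) * math.cos(a), math.cos(t)])

    table: dict[str, np.ndarray] = {}
    cz = pol(0, 0)
    c7 = pol(72, 90)
    for lab, f in (("C1", 0.25), ("C3", 0.5), ("C5", 0.75), ("C7", 1.0)):
        table[lab] = _slerp(cz, c7, f)
    table["C9"] = pol(90, 90)
    for row, mid_theta, az in (("FC", 18, 72), ("CP", 18, 108)):
        sign = 1.0 if row == "FC" else -1.0
        mid = np.array([0.0, sign * math.sin(math.radians(mid_theta)),
                        math.cos(math.radians(mid_theta))])
        end = pol(72, az)
        for k, f in ((1, 0.25), (3, 0.5), (5, 0.75), (7, 1.0)):
            table[f"{row}{k}"] = _slerp(mid, end, f)
    return table


_LAYOUT_1005 = _unit_sphere_1005()


def label_direction(label: str) -> np.ndarray:
    """Unit vector (sphere-center origin) of a supported 10-05 label."""
    try:
        return _LAYOUT_1005[label].copy()
    except KeyError:
        raise KeyError(f"label {label!r} is not in the idealized 10-05 table") from None


def build_default_array(
    head: SphereHeadModel | None = None,
    standoff: float = 0.01,
    reference_distance: float = 0.37,
) -> SensorArray:
    """Default 16-channel array: 13 left-hemisphere scalp sensors + 3 references.

    Scalp sensors sit radially at ``scalp_radius + standoff`` over the
    idealized 10-05 sites FC1, C1, CP1, FC3, C3, CP3, FC5, C5, CP5, FC7,
    C7, CP7 and C9.  Three reference magnetometers with mutually orthogonal
    sensitive axes sit ``reference_distance`` (default 0.37 m, inside the
    stated 0.35–0.40 m band) superior, posterior and left of the vertex.
    """
    head = head or SphereHeadModel()
    names, pos, ori, ref = [], [], [], []
    r = head.scalp_radius + standoff
    for lab in SCALP_LABELS:
        u = label_direction(lab)
        names.append(lab)
        pos.append(head.center + r * u)
        ori.append(u)
        ref.append(False)
    vertex = head.center + head.scalp_radius * np.array([0.0, 0.0, 1.0])
    ref_dirs = {
        "REF_SUP": np.array([0.0, 0.0, 1.0]),
        "REF_POST": np.array([0.0, -1.0, 0.0]),
        "REF_LEFT": np.array([-1.0, 0.0, 0.0]),
    }
    for lab in REFERENCE_LABELS:
        d = ref_dirs[lab]
        names.append(lab)
        pos.append(vertex + reference_distance * d)
        ori.append(d)
        ref.append(True)
    return SensorArray(names, np.array(pos), np.array(ori), np.array(ref))


def build_default_grid(
    head: SphereHeadModel | None = None,
    n_lateral: int = 5,
    n_ap_per_roi: int = 4,
    lateral_span: tuple[float, float] = (15.0, 80.0),
    ap_span: tuple[float, float] = (35.0, -25.0),
) -> SourceGrid:
    """Source grid: six equal-width anterior→posterior strips under the array.

    The spherical cap beneath the scalp sensors is parametrized by a
    lateral tilt ``a`` (degrees from the vertex toward the left ear) and an
    anterior–posterior tilt ``b``.  The six ROIs are contiguous
    equal-width strips in ``b`` spanning ``ap_span`` (degrees, anterior
    positive), ordered anterior → posterior
    with the standard sensorimotor names; each strip holds
    ``n_lateral × n_ap_per_roi`` vertices (default 6 × 20 grid).
    Orientations are tangential, along the local anterior–posterior
    direction.  The default span places the postcentral-gyrus strip
    directly beneath the C sensor row (the array targets the postcentral
    hand area), with the patch extending further anteriorly.
    """
    head = head or SphereHeadModel()
    a_vals = np.radians(np.linspace(*lateral_span, n_lateral))
    strip_edges = np.linspace(ap_span[0], ap_span[1], len(ROI_NAMES) + 1)
    verts, oris, labels = [], [], []
    yhat = np.array([0.0, 1.0, 0.0])
    for roi, b_hi, b_lo in zip(ROI_NAMES, strip_edges[:-1], strip_edges[1:]):
        b_vals = np.radians(np.linspace(b_hi, b_lo, n_ap_per_roi + 2)[1:-1])
        for b in b_vals:
            for a in a_vals:
                # tilt the vertex direction left by a, then anterior(+)/posterior(-) by b
                u = np.array(
                    [-math.sin(a), math.cos(a) * math.sin(b), math.cos(a) * math.cos(b)]
                )
                u /= np.linalg.norm(u)
                verts.append(head.center + head.source_radius * u)
                t = yhat - np.dot(yhat, u) * u
                oris.append(t / np.linalg.norm(t))
                labels.append(roi)
    return SourceGrid(np.array(verts), np.array(oris), labels)


# ---------------------------------------------------------------------------
# Sarvas closed-form field

def sarvas_field(
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    field_point: np.ndarray,
    head: SphereHeadModel,
) -> np.ndarray:
    """Magnetic field [T] of a current dipole in a conducting sphere.

    Closed-form solution for a homogeneous conducting sphere; the result
    is linear in ``dipole_moment`` and vanishes identically for radial
    moments.  ``field_point`` must lie strictly outside the scalp.
    """
    r0 = np.asarray(dipole_pos, float) - head.center
    r = np.asarray(field_point, float) - head.center
    q = np.asarray(dipole_moment, float)
    rn = np.linalg.norm(r)
    if rn <= head.scalp_radius:
        raise ValueError("field point must lie outside the scalp sphere")
    if np.linalg.norm(r0) >= head.scalp_radius:
        raise ValueError("dipole must lie strictly inside the sphere")
    a_vec = r - r0
    a = np.linalg.norm(a_vec)
    F = a * (rn * a + rn**2 - np.dot(r0, r))
    grad_F = (a**2 / rn + np.dot(a_vec, r) / a + 2.0 * a + 2.0 * rn) * r - (
        a + 2.0 * rn + np.dot(a_vec, r) / a
    ) * r0
    q_x_r0 = np.cross(q, r0)
    return MU0_OVER_4PI / F**2 * (F * q_x_r0 - np.dot(q_x_r0, r) * grad_F)


def biot_savart_dipole_field(
    dipole_pos: np.ndarray, dipole_moment: np.ndarray, field_point: np.ndarray
) -> np.ndarray:
    """Free-space field of the primary current element alone (no volume
    currents): B = μ0/4π · Q × a / |a|³.  Used as the independent oracle
    for the radial-field identity of the sphere model."""
    a_vec = np.asarray(field_point, float) - np.asarray(dipole_pos, float)
    a = np.linalg.norm(a_vec)
    return MU0_OVER_4PI * np.cross(np.asarray(dipole_moment, float), a_vec) / a**3


def compute_lead_field(
    array: SensorArray, grid: SourceGrid, head: SphereHeadModel
) -> LeadField:
    """Lead field: entry (i, j) is the field of a unit dipole at vertex j
    (along its orientation) projected on scalp channel i's sensitive axis."""
    scalp = array.scalp()
    radii = np.linalg.norm(grid.vertices - head.center, axis=1)
    if not np.allclose(radii, head.source_radius, atol=1e-9):
        raise ValueError("grid vertices must lie on the source shell")
    L = np.empty((scalp.n_channels, grid.n_sources))
    for j in range(grid.n_sources):
        for i in range(scalp.n_channels):
            b = sarvas_field(grid.vertices[j], grid.orientations[j],
                             scalp.positions[i], head)
            L[i, j] = float(np.dot(scalp.orientations[i], b))
    return LeadField(L, scalp.names, np.arange(grid.n_sources))


def sensitivity_map(
    lead: LeadField,
    grid: SourceGrid,
    unit_moment: float = 1.0,
    subject_leads: list[LeadField] | None = None,
) -> SensitivityMap:
    """Column-norm sensitivity map for a unit (default 1.0 A·m) source.

    ``values[j]`` is the Euclidean norm over channels of lead-field column
    j, scaled by ``unit_moment``; per-ROI means average the member
    vertices.  If per-subject lead fields are given, the map is their mean
    and the per-ROI SD is taken across subjects (otherwise SD is 0).
    """
    leads = subject_leads if subject_leads else [lead]
    maps = np.array([np.linalg.norm(lf.matrix, axis=0) * unit_moment for lf in leads])
    values = maps.mean(axis=0)
    per_mean, per_sd = {}, {}
    for roi in ROI_NAMES:
        idx = grid.roi_index(roi)
        if idx.size == 0:
            raise ValueError(f"ROI {roi!r} has no vertices")
        roi_means = maps[:, idx].mean(axis=1)
        per_mean[roi] = float(roi_means.mean())
        per_sd[roi] = float(roi_means.std(ddof=1)) if len(leads) > 1 else 0.0
    return SensitivityMap(values, per_mean, per_sd)
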