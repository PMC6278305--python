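"""Nitrite-local coordinate frame, binding angles and coordination geometry.

The orientation of a nitrite ion bound to a type-2 copper centre is described
in a coordinate system anchored on the ligand itself: the nitrite centre of
mass sits at the origin, the nitrogen atom points along +X, and both oxygens
lie in the XY plane.  Two angles locate the copper ion in that frame:

* the altitudinal angle theta — the angle between the projection of Cu onto
  the XZ plane and the X axis; the "pitch" of the ligand, running from
  N-bound (0 deg) through side-on (90 deg) to top-hat (180 deg);
* the azimuthal angle psi — the angle between the projection of Cu onto the
  XY plane and the X axis; the "yaw", separating symmetrical N-bound,
  l-shaped, monodentate top-hat and bidentate top-hat orientations.

A third angle phi (the coordination twist) measures the dihedral between the
N(NO2)-Cu-N(His_axial) plane and the plane of the two equatorial histidine
nitrogens: near 0/180 deg for tetragonal copper coordination, near 90 deg for
trigonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structures_io import ActiveSite, atomic_mass

__all__ = [
    "LigandFrame",
    "BindingMode",
    "CoordinationGeometry",
    "ClassificationThresholds",
    "SiteReport",
    "build_ligand_frame",
    "compute_theta",
    "compute_psi",
    "classify_mode",
    "compute_phi",
    "analyze_site",
]

_TOL = 1e-9

#: Cu-O distance asymmetry (Angstrom) above which the two oxygens are
#: considered inequivalent (monodentate rather than bidentate character).
CU_O_ASYMMETRY_CUTOFF = 0.3


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n <= _TOL:
        raise ValueError(f"degenerate geometry: {what} has zero length")
    return v / n


@dataclass(frozen=True)
class LigandFrame:
    """Orthonormal frame anchored on the nitrite ion, plus Cu in that frame."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    cu_local: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """World-to-local rotation matrix (rows are the frame axes)."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])


@dataclass(frozen=True)
class BindingMode:
    """(theta, psi) with altitudinal/azimuthal class labels."""

    theta: float
    psi: float
    altitudinal_class: str  # N-bound | top-hat | side-on | borderline
    azimuthal_class: str  # symmetrical | l-shaped | bidentate | monodentate | unclassified | n/a
    mode_label: str


@dataclass(frozen=True)
class CoordinationGeometry:
    """Twist angle phi, axial His, Cu-centred angles and shape label."""

    phi: float
    axial_his: str
    angles: dict[str, float]  # six Cu-centred pairwise angles, degrees
    shape_label: str  # tetragonal | trigonal | intermediate
    cu_o_distances: tuple[float, float]
    o_asymmetric: bool


@dataclass(frozen=True)
class SiteReport:
    frame: LigandFrame
    mode: BindingMode
    coordination: CoordinationGeometry
    chain_id: str = "A"
    frame_index: int = 1


@dataclass(frozen=True)
class ClassificationThresholds:
    """Angular windows (degrees) for the binding-orientation classes.

    Altitudinal windows are closed intervals of theta; azimuthal windows are
    intervals of psi evaluated only within a resolved altitudinal class.  The
    shared boundaries psi=10 (symmetrical vs l-shaped) and psi=170
    (monodentate vs bidentate) belong to the symmetrical/bidentate class.
    Twist-angle windows define the tetragonal/trigonal shape labels; values
    between the windows are labelled intermediate.
    """

    nbound: tuple[float, float] = (0.0, 20.0)
    tophat: tuple[float, float] = (160.0, 180.0)
    sideon: tuple[float, float] = (70.0, 110.0)
    symmetrical: tuple[float, float] = (0.0, 10.0)
    lshaped: tuple[float, float] = (10.0, 30.0)  # lower bound open (ties to symmetrical)
    bidentate: tuple[float, float] = (170.0, 180.0)
    monodentate: tuple[float, float] = (140.0, 170.0)  # upper bound open (ties to bidentate)
    phi_tetragonal: tuple[float, float] = (30.0, 150.0)  # OUTSIDE this window
    phi_trigonal: tuple[float, float] = (60.0, 120.0)

    def validate(self) -> None:
        for name in ("nbound", "tophat", "sideon", "symmetrical", "lshaped",
                     "bidentate", "monodentate", "phi_tetragonal", "phi_trigonal"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 180.0):
                raise ValueError(f"threshold {name}: invalid window ({lo}, {hi})")
        for a, b in (("nbound", "sideon"), ("sideon", "tophat")):
            if getattr(self, a)[1] >= getattr(self, b)[0]:
                raise ValueError(f"altitudinal windows {a} and {b} overlap")


DEFAULT_THRESHOLDS = ClassificationThresholds()

_NITRITE_MASSES = {"N": atomic_mass("N"), "O": atomic_mass("O")}


def nitrite_com(site: ActiveSite) -> np.ndarray:
    """Mass-weighted centre of mass of the three nitrite atoms."""
    m_n, m_o = _NITRITE_MASSES["N"], _NITRITE_MASSES["O"]
    total = m_n + 2.0 * m_o
    return (m_n * site.nitrite_n + m_o * (site.nitrite_o1 + site.nitrite_o2)) / total


def build_ligand_frame(site: ActiveSite) -> LigandFrame:
    """Construct the nitrite-anchored orthonormal frame.

    Origin: nitrite centre of mass.  X: toward the nitrogen.  Z: normal of
    the nitrite plane, signed so Cu has a non-negative Z component (the two
    oxygens are chemically equivalent, so the normal's sign carries no
    physics).  Y completes a right-handed set; when Cu lies exactly in the
    nitrite plane the Z sign is chosen so Cu's Y component is non-negative.
    """
    origin = nitrite_com(site)
    x_axis = _unit(site.nitrite_n - origin, "nitrite N - COM vector")
    normal = np.cross(site.nitrite_o1 - origin, site.nitrite_o2 - origin)
    if np.linalg.norm(normal) <= _TOL:
        raise ValueError("degenerate ligand plane: nitrite atoms are collinear")
    z_axis = normal / np.linalg.norm(normal)

    v_cu = site.cu - origin
    z_comp = float(z_axis @ v_cu)
    if abs(z_comp) <= _TOL:
        # Cu in the nitrite plane: disambiguate via the Y-component sign.
        if float(np.cross(z_axis, x_axis) @ v_cu) < 0.0:
            z_axis = -z_axis
    elif z_comp < 0.0:
        z_axis = -z_axis
    y_axis = np.cross(z_axis, x_axis)

    R = np.vstack([x_axis, y_axis, z_axis])
    return LigandFrame(
        origin=origin,
        x_axis=x_axis,
        y_axis=y_axis,
        z_axis=z_axis,
        cu_local=R @ v_cu,
    )


def compute_theta(frame: LigandFrame) -> float:
    """Altitudinal angle theta (degrees in [0, 180]).

    atan2(|z|, x) of Cu in the ligand frame: 0 on the +X axis (N-bound),
    90 on the Z axis (side-on), 180 on the -X axis (top-hat).
    """
    x, _, z = frame.cu_local
    if np.hypot(x, z) <= _TOL:
        raise ValueError("altitude undefined: Cu projects to the frame origin in the XZ plane")
    return float(np.degrees(np.arctan2(abs(z), x)))


def compute_psi(frame: LigandFrame) -> float:
    """Azimuthal angle psi (degrees in [0, 180]).

    atan2(|y|, x) of Cu in the ligand frame; the sign of y is non-physical
    because relabelling the two oxygens flips it.
    """
    x, y, _ = frame.cu_local
    if np.hypot(x, y) <= _TOL:
        raise ValueError("azimuth undefined: Cu projects to the frame origin in the XY plane")
    return float(np.degrees(np.arctan2(abs(y), x)))


def _in(value: float, window: tuple[float, float]) -> bool:
    return window[0] <= value <= window[1]


def classify_mode(
    theta: float, psi: float, thresholds: ClassificationThresholds | None = None
) -> BindingMode:
    """Assign altitudinal and azimuthal class labels from (theta, psi).

    Structures outside every altitudinal window are labelled ``borderline``
    and given no azimuthal class; side-on structures have no azimuthal
    sub-classification either (``n/a``).
    """
    th = thresholds or DEFAULT_THRESHOLDS
    if not (0.0 <= theta <= 180.0) or not (0.0 <= psi <= 180.0):
        raise ValueError(f"angles out of range: theta={theta}, psi={psi}")

    if _in(theta, th.nbound):
        altitudinal = "N-bound"
        if _in(psi, th.symmetrical):
            azimuthal = "symmetrical"
        elif th.symmetrical[1] < psi <= th.lshaped[1] and psi >= th.lshaped[0]:
            azimuthal = "l-shaped"
        else:
            azimuthal = "unclassified"
    elif _in(theta, th.tophat):
        altitudinal = "top-hat"
        if _in(psi, th.bidentate):
            azimuthal = "bidentate"
        elif th.monodentate[0] <= psi < min(th.monodentate[1], th.bidentate[0]):
            azimuthal = "monodentate"
        else:
            azimuthal = "unclassified"
    elif _in(theta, th.sideon):
        altitudinal, azimuthal = "side-on", "n/a"
    else:
        altitudinal, azimuthal = "borderline", "n/a"

    if altitudinal == "side-on":
        label = "side-on"
    elif altitudinal == "borderline":
        label = "borderline"
    elif azimuthal == "unclassified":
        label = f"unclassified {altitudinal}"
    else:
        label = f"{azimuthal} {altitudinal}"
    return BindingMode(float(theta), float(psi), altitudinal, azimuthal, label)


def _angle_at(center: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    va = _unit(a - center, "ligand-Cu vector")
    vb = _unit(b - center, "ligand-Cu vector")
    return float(np.degrees(np.arccos(np.clip(va @ vb, -1.0, 1.0))))


def compute_phi(
    site: ActiveSite, thresholds: ClassificationThresholds | None = None
) -> CoordinationGeometry:
    """Twist angle phi and the Cu-centred coordination report.

    The axial histidine (His1) is the one with the largest N(NO2)-Cu-N(His)
    angle; the remaining two (ordered by residue number) are equatorial.
    phi is the angle between the normal of the N(NO2)-Cu-N(His1) plane and
    the normal of the N(His2)-Cu-N(His3) plane, in [0, 180]: ~0/180 deg for
    tetragonal coordination, ~90 deg for trigonal.
    """
    th = thresholds or DEFAULT_THRESHOLDS
    cu = site.cu
    nit = site.nitrite_n

    his_angles = {h.residue_number: _angle_at(cu, nit, h.position) for h in site.his_n}
    by_res = {h.residue_number: h for h in site.his_n}
    ordered = sorted(his_angles, key=lambda r: (-his_angles[r], r))
    if abs(his_angles[ordered[0]] - his_angles[ordered[1]]) <= 1e-6:
        warnings.warn(
            "ambiguous axial His assignment (two largest N(NO2)-Cu-N(His) angles equal); "
            "choosing the lower residue number",
            stacklevel=2,
        )
        tied = sorted(r for r in ordered[:2])
        ordered = tied[:1] + [r for r in ordered if r != tied[0]]
    axial = by_res[ordered[0]]
    equatorial = sorted((by_res[ordered[1]], by_res[ordered[2]]), key=lambda h: h.residue_number)

    n1 = np.cross(nit - cu, axial.position - cu)
    n2 = np.cross(equatorial[0].position - cu, equatorial[1].position - cu)
    for n, what in ((n1, "nitrite/axial-His plane"), (n2, "equatorial-His plane")):
        if np.linalg.norm(n) <= _TOL:
            raise ValueError(f"degenerate {what}: atoms collinear with Cu")
    phi = float(
        np.degrees(np.arccos(np.clip(n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2)), -1, 1)))
    )

    ligands = [("NO2", nit)] + [(h.label, h.position) for h in site.his_n]
    angles = {
        f"{ligands[i][0]}-{ligands[j][0]}": _angle_at(cu, ligands[i][1], ligands[j][1])
        for i in range(4)
        for j in range(i + 1, 4)
    }

    if _in(phi, th.phi_trigonal):
        shape = "trigonal"
    elif phi <= th.phi_tetragonal[0] or phi >= th.phi_tetragonal[1]:
        shape = "tetragonal"
    else:
        shape = "intermediate"

    d1 = float(np.linalg.norm(cu - site.nitrite_o1))
    d2 = float(np.linalg.norm(cu - site.nitrite_o2))
    return CoordinationGeometry(
        phi=phi,
        axial_his=axial.label,
        angles=angles,
        shape_label=shape,
        cu_o_distances=(d1, d2),
        o_asymmetric=abs(d1 - d2) > CU_O_ASYMMETRY_CUTOFF,
    )


def analyze_site(
    site: ActiveSite, thresholds: ClassificationThresholds | None = None
) -> SiteReport:
    """Full geometric report for one active site: frame, mode and twist."""
    try:
        frame = build_ligand_frame(site)
        mode = classify_mode(compute_theta(frame), compute_psi(frame), thresholds)
        coordination = compute_phi(site, thresholds)
    except ValueError as exc:
        raise ValueError(
            f"site chain {site.chain_id}, frame {site.frame_index}: {exc}"
        ) from exc
    return SiteReport(
        frame=frame,
        mode=mode,
        coordination=coordination,
        chain_id=site.chain_id,
        frame_index=site.frame_index,
    )
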