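"""Biomechanical measurements of turtle-like mandibles.

Six dimensionless measurements are computed per specimen from named 3D
landmarks plus the ellipse axes of a mid-ramus cross-section:

* **AMA** — anterior mechanical advantage: closing in-lever (jaw joint to
  coronoid tip) over the anterior out-lever (jaw joint to anterior tip).
* **PMA** — posterior mechanical advantage: same in-lever over the out-lever
  ending at the posterior end of the triturating surface. Values above 1
  (second-order lever) are legitimate and never clamped.
* **OMA** — opening mechanical advantage: depressor in-lever (jaw joint to
  posteriormost point, i.e. the retroarticular process) over the anterior
  out-lever.
* **SMOI** — standardized second moment of inertia of the cross-section
  ellipse relative to an equal-area circle; algebraically ``b / a``.
* **LWR** — mandible length over maximum bilateral width.
* **RTW** — maximum triturating-surface width over mandible length.

Lever distances are straight lines measured in a configurable sagittal
plane (default: the x–z plane, discarding the mediolateral y axis); the
two width measurements are genuinely transverse and use full 3D distances.
All six measurements are ratios, hence invariant under rigid motion and
uniform scaling of the landmark set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np

from .errors import DegenerateGeometryError, InputError, MissingLandmarkError

__all__ = [
    "AXES",
    "LEVER_LANDMARKS",
    "WIDTH_LANDMARKS",
    "LANDMARK_NAMES",
    "SagittalConfig",
    "LandmarkSet",
    "CrossSection",
    "FunctionalProfile",
    "project_sagittal",
    "sagittal_distance",
    "anterior_mechanical_advantage",
    "posterior_mechanical_advantage",
    "opening_mechanical_advantage",
    "second_moment_ratio",
    "length_width_ratio",
    "relative_triturating_width",
    "profile_species",
    "classify_jaw_type",
]

AXES = {"x": 0, "y": 1, "z": 2}

LEVER_LANDMARKS = (
    "jaw_joint",
    "coronoid_tip",
    "anterior_tip",
    "posterior_tip",
    "triturating_posterior",
)
WIDTH_LANDMARKS = ("width_left", "width_right", "trit_width_left", "trit_width_right")
LANDMARK_NAMES = LEVER_LANDMARKS + WIDTH_LANDMARKS


@dataclass(frozen=True)
class SagittalConfig:
    """Axis pair defining the sagittal plane used for lever distances.

    The default ``("x", "z")`` reads x as anteroposterior and z as
    dorsoventral, discarding the mediolateral y component. Whether the
    original distances were projected or taken between midline points is
    ambiguous in the source data convention; the projection reading is
    used here and is exact whenever landmarks lie on the midline.
    """

    plane_axes: tuple[str, str] = ("x", "z")

    def __post_init__(self) -> None:
        a, b = self.plane_axes
        if a not in AXES or b not in AXES:
            raise InputError(f"unknown axis names in {self.plane_axes!r}")
        if a == b:
            raise InputError("sagittal plane axes must be distinct")

    @property
    def indices(self) -> tuple[int, int]:
        return AXES[self.plane_axes[0]], AXES[self.plane_axes[1]]


DEFAULT_SAGITTAL = SagittalConfig()


def _as_point(value, name: str) -> np.ndarray | None:
    if value is None:
        return None
    p = np.asarray(value, dtype=float)
    if p.shape != (3,):
        raise InputError(f"landmark {name!r} must be a 3-vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise InputError(f"landmark {name!r} has non-finite coordinates: {p}")
    return p


@dataclass
class LandmarkSet:
    """Named 3D landmarks of one mandible.

    Landmarks may be ``None`` (e.g. partially digitized specimens); any
    measurement that needs an absent landmark raises
    :class:`MissingLandmarkError` naming it.
    """

    specimen_id: str
    jaw_joint: np.ndarray | None = None
    coronoid_tip: np.ndarray | None = None
    anterior_tip: np.ndarray | None = None
    posterior_tip: np.ndarray | None = None
    triturating_posterior: np.ndarray | None = None
    width_left: np.ndarray | None = None
    width_right: np.ndarray | None = None
    trit_width_left: np.ndarray | None = None
    trit_width_right: np.ndarray | None = None
    length_unit: str = "mm"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("specimen_id", "length_unit"):
                continue
            object.__setattr__(self, f.name, _as_point(getattr(self, f.name), f.name))
        jj, at = self.jaw_joint, self.anterior_tip
        if jj is not None and at is not None and np.array_equal(jj, at):
            raise InputError(
                f"specimen {self.specimen_id!r}: jaw_joint coincides with anterior_tip"
            )
        wl, wr = self.width_left, self.width_right
        if wl is not None and wr is not None and np.array_equal(wl, wr):
            raise InputError(
                f"specimen {self.specimen_id!r}: width_left coincides with width_right"
            )

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise MissingLandmarkError(self.specimen_id, missing)


@dataclass(frozen=True)
class CrossSection:
    """Ellipse fitted to the mid-ramus cross-section.

    ``a`` is the axis perpendicular to the applied (bite) force, i.e. the
    mediolateral width; ``b`` is parallel to the force, i.e. the
    dorsoventral height. The location of the section along the ramus is
    a data-collection convention and is recorded as metadata only.
    """

    a: float
    b: float
    location: str = "dentary ramus midpoint"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise InputError("cross-section axes must be finite")
        if self.a <= 0 or self.b <= 0:
            raise InputError(f"cross-section axes must be positive (a={self.a}, b={self.b})")


@dataclass(frozen=True)
class FunctionalProfile:
    """The six functional measurements of one species/specimen."""

    species_id: str
    ama: float
    pma: float
    oma: float
    smoi: float
    lwr: float
    rtw: float

    MEASUREMENTS = ("ama", "pma", "oma", "smoi", "lwr", "rtw")

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in self.MEASUREMENTS}


def project_sagittal(p, cfg: SagittalConfig = DEFAULT_SAGITTAL) -> np.ndarray:
    """Orthogonally project a 3D point onto the configured sagittal plane."""
    q = _as_point(p, "point")
    i, j = cfg.indices
    return np.array([q[i], q[j]])


def sagittal_distance(p, q, cfg: SagittalConfig = DEFAULT_SAGITTAL) -> float:
    return float(np.linalg.norm(project_sagittal(p, cfg) - project_sagittal(q, cfg)))


def _distance_3d(p, q) -> float:
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))


def anterior_mechanical_advantage(
    lm: LandmarkSet, cfg: SagittalConfig = DEFAULT_SAGITTAL
) -> float:
    """Closing in-lever over the anterior out-lever (third-order lever)."""
    lm.require("jaw_joint", "coronoid_tip", "anterior_tip")
    out = sagittal_distance(lm.jaw_joint, lm.anterior_tip, cfg)
    if out == 0.0:
        raise DegenerateGeometryError(
            f"specimen {lm.specimen_id!r}: zero anterior out-lever"
        )
    return sagittal_distance(lm.jaw_joint, lm.coronoid_tip, cfg) / out


def posterior_mechanical_advantage(
    lm: LandmarkSet, cfg: SagittalConfig = DEFAULT_SAGITTAL
) -> float:
    """Closing in-lever over the out-lever at the posterior end of the
    triturating surface.

    May exceed 1 when the triturating surface ends closer to the joint
    than the coronoid tip (second-order lever); such values are reported
    as-is.
    """
    lm.require("jaw_joint", "coronoid_tip", "triturating_posterior")
    out = sagittal_distance(lm.jaw_joint, lm.triturating_posterior, cfg)
    if out == 0.0:
        raise DegenerateGeometryError(
            f"specimen {lm.specimen_id!r}: zero posterior out-lever"
        )
    return sagittal_distance(lm.jaw_joint, lm.coronoid_tip, cfg) / out


def opening_mechanical_advantage(
    lm: LandmarkSet, cfg: SagittalConfig = DEFAULT_SAGITTAL
) -> float:
    """Depressor in-lever over the anterior out-lever (first-order lever).

    Zero is a valid value (no retroarticular process).
    """
    lm.require("jaw_joint", "posterior_tip", "anterior_tip")
    out = sagittal_distance(lm.jaw_joint, lm.anterior_tip, cfg)
    if out == 0.0:
        raise DegenerateGeometryError(
            f"specimen {lm.specimen_id!r}: zero opening out-lever"
        )
    return sagittal_distance(lm.jaw_joint, lm.posterior_tip, cfg) / out


def second_moment_ratio(cs: CrossSection) -> float:
    """Area moment of the section ellipse over that of the equal-area circle.

    The ellipse moment is pi*a*b^3/4 and the equal-area circle (radius
    sqrt(a*b)) has moment pi*(a*b)^2/4, so the quotient reduces to b/a.
    Values below 1 mean the ramus beam is wider than tall.
    """
    return cs.b / cs.a


def _mandible_length(lm: LandmarkSet, cfg: SagittalConfig) -> float:
    lm.require("anterior_tip", "posterior_tip")
    return sagittal_distance(lm.anterior_tip, lm.posterior_tip, cfg)


def length_width_ratio(lm: LandmarkSet, cfg: SagittalConfig = DEFAULT_SAGITTAL) -> float:
    """Sagittal mandible length over the 3D bilateral width."""
    lm.require("anterior_tip", "posterior_tip", "width_left", "width_right")
    width = _distance_3d(lm.width_left, lm.width_right)
    if width == 0.0:
        raise DegenerateGeometryError(f"specimen {lm.specimen_id!r}: zero jaw width")
    return _mandible_length(lm, cfg) / width


def relative_triturating_width(
    lm: LandmarkSet, cfg: SagittalConfig = DEFAULT_SAGITTAL
) -> float:
    """3D maximum triturating-surface width over sagittal mandible length."""
    lm.require("anterior_tip", "posterior_tip", "trit_width_left", "trit_width_right")
    length = _mandible_length(lm, cfg)
    if length == 0.0:
        raise DegenerateGeometryError(f"specimen {lm.specimen_id!r}: zero mandible length")
    rtw = _distance_3d(lm.trit_width_left, lm.trit_width_right) / length
    if rtw == 0.0:
        warnings.warn(
            f"specimen {lm.specimen_id!r}: zero triturating width", stacklevel=2
        )
    elif rtw >= 1.0:
        warnings.warn(
            f"specimen {lm.specimen_id!r}: relative triturating width {rtw:.3g} >= 1 "
            "is implausible for a jaw",
            stacklevel=2,
        )
    return rtw


def profile_species(
    lm: LandmarkSet, cs: CrossSection, cfg: SagittalConfig = DEFAULT_SAGITTAL
) -> FunctionalProfile:
    """Compute all six measurements for one specimen.

    Raises a single :class:`MissingLandmarkError` itemizing every absent
    landmark before any measurement is attempted.
    """
    lm.require(*LANDMARK_NAMES)
    return FunctionalProfile(
        species_id=lm.specimen_id,
        ama=anterior_mechanical_advantage(lm, cfg),
        pma=posterior_mechanical_advantage(lm, cfg),
        oma=opening_mechanical_advantage(lm, cfg),
        smoi=second_moment_ratio(cs),
        lwr=length_width_ratio(lm, cfg),
        rtw=relative_triturating_width(lm, cfg),
    )


def classify_jaw_type(
    landmarks: list[LandmarkSet], cfg: SagittalConfig = DEFAULT_SAGITTAL
) -> list[str]:
    """Heuristic lever-proportion jaw types, relative to the sample.

    Per specimen the rules below are applied in order, first match wins
    (quartiles are sample quartiles of the input):

    1. ``trionychid`` — relative depressor in-lever (joint to posterior
       tip, over mandible length) above the 75th percentile while AMA is
       below the sample median (hypertrophied retroarticular process).
    2. ``pelomedusoid`` — both AMA and OMA above their 75th percentiles
       (short pre-coronoid out-lever raises both).
    3. ``chelid`` — AMA above its 75th percentile while OMA lies within
       the interquartile range (elongated post-coronoid region only).
    4. ``none`` otherwise.

    Samples smaller than 8 make the percentile cutoffs meaningless; every
    specimen is then labelled ``none``. Fewer than 2 specimens is an error.
    """
    if len(landmarks) < 2:
        raise InputError("jaw-type classification needs at least 2 specimens")
    ama = np.array([anterior_mechanical_advantage(lm, cfg) for lm in landmarks])
    oma = np.array([opening_mechanical_advantage(lm, cfg) for lm in landmarks])
    rel_in = np.array(
        [
            sagittal_distance(lm.jaw_joint, lm.posterior_tip, cfg)
            / _mandible_length(lm, cfg)
            for lm in landmarks
        ]
    )
    if len(landmarks) < 8:
        return ["none"] * len(landmarks)

    ama_med = np.median(ama)
    ama_q75 = np.percentile(ama, 75)
    oma_q25, oma_q75 = np.percentile(oma, [25, 75])
    rel_q75 = np.percentile(rel_in, 75)

    labels = []
    for a, o, r in zip(ama, oma, rel_in):
        if r > rel_q75 and a < ama_med:
            labels.append("trionychid")
        elif a > ama_q75 and o > oma_q75:
            labels.append("pelomedusoid")
        elif a > ama_q75 and oma_q25 <= o <= oma_q75:
            labels.append("chelid")
        else:
            labels.append("none")
    return labels
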