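"""Examination catalog: sensor sites and the 40-angle whole-body RoM catalog.

The examination methodology screens active spine RoM (cervical,
thoraco-lumbar) and diagnoses passive RoM at shoulder, elbow, wrist, hip and
knee by the neutral-zero method.  Each catalog entry names the joint, the
anatomical angle, the sensor sites involved, the joint-coordinate-system
component that carries the motion, and two literature reference ranges used
for validity flags.

The default catalog ships as a versioned YAML resource; distance-based items
(finger-floor, chin-jugulum) are deliberately absent — the catalog is
angle-only.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SensorSite",
    "ExaminationAngle",
    "Catalog",
    "CatalogError",
    "load_catalog",
    "write_catalog",
]

N_SITES = 13
N_EXAMINATIONS = 40
JCS_AXES = ("flexion", "abduction", "rotation")
MODES = ("active", "passive")
METHODS = ("two_imu_relative", "single_imu_vs_start")


class CatalogError(ValueError):
    """Malformed or invariant-violating catalog."""


@dataclass(frozen=True)
class SensorSite:
    """One IMU placement site with its segment's neutral-posture frame.

    ``long_axis`` and ``sagittal_axis`` are the segment's long (distal→
    proximal, vertical in neutral standing) and anterior axes in the world
    frame at the neutral posture; together with their cross product they
    define the anatomical segment frame (x = flexion/mediolateral,
    y = long, z = sagittal).
    """

    site_id: str
    segment: str
    placement_note: str
    long_axis: tuple[float, float, float]
    sagittal_axis: tuple[float, float, float]

    def __post_init__(self):
        la = np.asarray(self.long_axis, dtype=float)
        sa = np.asarray(self.sagittal_axis, dtype=float)
        if abs(np.linalg.norm(la) - 1) > 1e-9 or abs(np.linalg.norm(sa) - 1) > 1e-9:
            raise CatalogError(f"site {self.site_id}: neutral axes must be unit vectors")
        if abs(float(la @ sa)) > 1e-9:
            raise CatalogError(f"site {self.site_id}: neutral axes must be orthogonal")

    @property
    def neutral_rotation(self) -> np.ndarray:
        """3x3 rotation mapping segment-frame vectors to world at neutral."""
        y = np.asarray(self.long_axis, dtype=float)
        z = np.asarray(self.sagittal_axis, dtype=float)
        x = np.cross(y, z)
        return np.column_stack([x, y, z])


@dataclass(frozen=True)
class ExaminationAngle:
    angle_id: str
    joint: str
    nomenclature: str
    side: str  # L | R | midline
    mode: str  # active | passive
    method: str  # two_imu_relative | single_imu_vs_start
    proximal_site: str | None
    distal_site: str
    jcs_axis: str  # flexion | abduction | rotation
    sign: int  # which signed direction of the JCS component this name reports
    ref_range_1: tuple[float, float]
    ref_range_2: tuple[float, float]

    def __post_init__(self):
        problems = []
        if self.mode not in MODES:
            problems.append(f"mode {self.mode!r}")
        if self.method not in METHODS:
            problems.append(f"method {self.method!r}")
        if self.jcs_axis not in JCS_AXES:
            problems.append(f"jcs_axis {self.jcs_axis!r}")
        if self.sign not in (-1, 1):
            problems.append(f"sign {self.sign!r}")
        if (self.proximal_site is None) != (self.method == "single_imu_vs_start"):
            problems.append("proximal_site must be absent iff method=single_imu_vs_start")
        if self.method == "two_imu_relative" and self.proximal_site == self.distal_site:
            problems.append("proximal and distal sites must differ")
        for rr in (self.ref_range_1, self.ref_range_2):
            if rr[0] > rr[1]:
                problems.append(f"reference range {rr} has low > high")
        if problems:
            raise CatalogError(f"examination {self.angle_id}: " + "; ".join(problems))

    @property
    def family(self) -> str:
        """Joint + nomenclature without the side, e.g. 'cervical_spine:Rotation'."""
        return f"{self.joint}:{self.nomenclature}"

    @property
    def sites(self) -> tuple[str, ...]:
        if self.proximal_site is None:
            return (self.distal_site,)
        return (self.proximal_site, self.distal_site)


@dataclass
class Catalog:
    sites: dict[str, SensorSite] = field(default_factory=dict)
    examinations: dict[str, ExaminationAngle] = field(default_factory=dict)
    version: int = 1

    def lookup(self, angle_id: str) -> ExaminationAngle:
        try:
            return self.examinations[angle_id]
        except KeyError:
            raise KeyError(f"unknown examination angle {angle_id!r}") from None

    def site(self, site_id: str) -> SensorSite:
        try:
            return self.sites[site_id]
        except KeyError:
            raise KeyError(f"unknown sensor site {site_id!r}") from None

    @property
    def angle_ids(self) -> list[str]:
        return list(self.examinations)

    def validate(self) -> None:
        errs = []
        if len(self.sites) != N_SITES:
            errs.append(f"expected {N_SITES} sensor sites, found {len(self.sites)}")
        if len(self.examinations) != N_EXAMINATIONS:
            errs.append(f"expected {N_EXAMINATIONS} examinations, found {len(self.examinations)}")
        n_active = sum(e.mode == "active" for e in self.examinations.values())
        if self.examinations and n_active != 10:
            errs.append(f"expected 10 active examinations, found {n_active}")
        for e in self.examinations.values():
            for s in e.sites:
                if s not in self.sites:
                    errs.append(f"examination {e.angle_id} references unknown site {s!r}")
        if errs:
            raise CatalogError("catalog invariants violated: " + "; ".join(errs))


def _parse_site(raw: dict) -> SensorSite:
    return SensorSite(
        site_id=str(raw["site_id"]),
        segment=str(raw["segment"]),
        placement_note=str(raw.get("placement_note", "")),
        long_axis=tuple(float(v) for v in raw["long_axis"]),
        sagittal_axis=tuple(float(v) for v in raw["sagittal_axis"]),
    )


def _parse_examination(raw: dict) -> ExaminationAngle:
    rr1 = raw["ref_range_1"]
    rr2 = raw["ref_range_2"]
    rr1 = (float(rr1[0]), float(rr1[1])) if isinstance(rr1, (list, tuple)) else (float(rr1), float(rr1))
    rr2 = (float(rr2[0]), float(rr2[1])) if isinstance(rr2, (list, tuple)) else (float(rr2), float(rr2))
    prox = raw.get("proximal_site")
    return ExaminationAngle(
        angle_id=str(raw["angle_id"]),
        joint=str(raw["joint"]),
        nomenclature=str(raw["nomenclature"]),
        side=str(raw["side"]),
        mode=str(raw["mode"]),
        method=str(raw["method"]),
        proximal_site=None if prox is None else str(prox),
        distal_site=str(raw["distal_site"]),
        jcs_axis=str(raw["jcs_axis"]),
        sign=int(raw["sign"]),
        ref_range_1=rr1,
        ref_range_2=rr2,
    )


def default_catalog_path() -> Path:
    return Path(str(importlib.resources.files("romexam") / "data" / "catalog.yaml"))


def load_catalog(path: str | Path | None = None, validate: bool = True) -> Catalog:
    """Load and validate a catalog YAML file (the bundled default if ``path``
    is None).  Duplicate ids are rejected; structural invariants (13 sites,
    40 examinations, 10 of them active, all referenced sites known) are
    checked unless ``validate=False``.
    """
    path = default_catalog_path() if path is None else Path(path)
    if not path.exists():
        raise FileNotFoundError(f"catalog file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # yaml errors carry line/column marks
        raise CatalogError(f"cannot parse catalog {path}: {exc}") from exc
    if not isinstance(raw, dict) or "sites" not in raw or "examinations" not in raw:
        raise CatalogError(f"catalog {path} must contain 'sites:' and 'examinations:' lists")
    cat = Catalog(version=int(raw.get("version", 1)))
    for entry in raw["sites"]:
        site = _parse_site(entry)
        if site.site_id in cat.sites:
            raise CatalogError(f"duplicate site_id {site.site_id!r}")
        cat.sites[site.site_id] = site
    for entry in raw["examinations"]:
        exam = _parse_examination(entry)
        if exam.angle_id in cat.examinations:
            raise CatalogError(f"duplicate angle_id {exam.angle_id!r}")
        cat.examinations[exam.angle_id] = exam
    if validate:
        cat.validate()
    return cat


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Serialize a catalog back to YAML; load_catalog(write_catalog(c)) is an
    identity round trip."""
    sites = []
    for s in catalog.sites.values():
        d = asdict(s)
        d["long_axis"] = list(d["long_axis"])
        d["sagittal_axis"] = list(d["sagittal_axis"])
        sites.append(d)
    exams = []
    for e in catalog.examinations.values():
        d = asdict(e)
        d["ref_range_1"] = list(d["ref_range_1"])
        d["ref_range_2"] = list(d["ref_range_2"])
        exams.append(d)
    payload = {"version": catalog.version, "sites": sites, "examinations": exams}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
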