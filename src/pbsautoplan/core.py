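"""Domain types, coordinate conventions, and file I/O.

Coordinate convention (right-handed, patient-centric):

* ``x``: lateral, positive toward the patient's left
* ``y``: anterior-posterior, positive anterior
* ``z``: craniocaudal, positive superior

Arrays are indexed ``values[ix, iy, iz]``; the world position of voxel
``(i, j, k)`` is ``origin + (i, j, k) * spacing`` (voxel centers; masks are
voxel-center membership). Dose is stored in CGE for the full course.

Gantry angle convention: 0 deg enters from anterior, increasing clockwise
viewed from superior; a beam is *anterior* iff its gantry angle lies in
(270, 360] or [0, 90), which puts 30/330 deg anterior and 135/225 deg
posterior.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CaseValidationError",
    "PlanSchemaError",
    "ImageGrid",
    "StructureSet",
    "Prescription",
    "Beam",
    "Spot",
    "Plan",
    "Scenario",
    "DVHCurve",
    "beam_is_anterior",
    "beam_unit_vectors",
    "read_volume",
    "write_volume",
    "read_case",
    "write_case",
    "read_case_dir",
    "read_plan",
    "write_plan",
    "write_dvh_csv",
]


class CaseValidationError(ValueError):
    """A case (grid + structure set) violates a structural contract."""


class PlanSchemaError(ValueError):
    """A plan file violates the documented JSON schema."""


# --------------------------------------------------------------------------
# grids and structures
# --------------------------------------------------------------------------


@dataclass
class ImageGrid:
    """Regular 3-D voxel lattice of relative stopping power (water = 1)."""

    origin: np.ndarray  # mm, (3,)
    spacing: np.ndarray  # mm, (3,)
    values: np.ndarray  # RSP, shape (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise CaseValidationError("grid values must be 3-D")
        if not np.all(self.spacing > 0):
            raise CaseValidationError("grid spacing must be positive on all axes")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise CaseValidationError("stopping power must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_centers(self, flat_idx: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (n, 3) of voxel centers for flat indices (or all)."""
        if flat_idx is None:
            flat_idx = np.arange(int(np.prod(self.shape)))
        ijk = np.column_stack(np.unravel_index(np.asarray(flat_idx), self.shape))
        return self.origin + ijk * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points (n, 3)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def congruent_with(self, other: "ImageGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )


#: valid structure role tags
ROLES = ("target", "oar", "external", "automation")


@dataclass
class StructureSet:
    """Named binary masks congruent with one :class:`ImageGrid`."""

    grid: ImageGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, mask: np.ndarray, role: str = "oar") -> None:
        mask = np.asarray(mask)
        if mask.shape != self.grid.shape:
            raise CaseValidationError(
                f"structure '{name}' has shape {mask.shape}, expected {self.grid.shape}"
            )
        if role not in ROLES:
            raise CaseValidationError(f"structure '{name}': unknown role '{role}'")
        self.masks[name] = mask.astype(bool)
        self.roles[name] = role

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self, role: str | None = None) -> list[str]:
        if role is None:
            return list(self.masks)
        return [n for n, r in self.roles.items() if r == role]

    def validate(self, dental_name: str = "dental") -> None:
        """Check the structure-set invariants.

        ``external`` must be present and non-empty, every mask congruent with
        the grid, and every mask a subset of external (dental hardware is
        allowed to touch the external boundary).
        """
        if "external" not in self.masks:
            raise CaseValidationError("structure set is missing 'external'")
        external = self.masks["external"]
        if not external.any():
            raise CaseValidationError("'external' is empty")
        for name, mask in self.masks.items():
            if mask.shape != self.grid.shape:
                raise CaseValidationError(
                    f"structure '{name}' has shape {mask.shape}, expected {self.grid.shape}"
                )
            if name in ("external", dental_name):
                continue
            if np.any(mask & ~external):
                raise CaseValidationError(f"structure '{name}' extends outside 'external'")


@dataclass
class Prescription:
    """Course prescription: total dose (CGE) over a number of fractions."""

    dose_cge: float = 50.0
    fractions: int = 25

    def __post_init__(self) -> None:
        if self.dose_cge <= 0:
            raise ValueError("prescription dose must be > 0")
        if self.fractions < 1:
            raise ValueError("fraction count must be >= 1")


# --------------------------------------------------------------------------
# beams, spots, plans
# --------------------------------------------------------------------------


def beam_is_anterior(gantry_deg: float) -> bool:
    """True iff the gantry angle is in (270, 360] or [0, 90)."""
    g = float(gantry_deg) % 360.0
    return g < 90.0 or g > 270.0 or g == 0.0


def beam_unit_vectors(gantry_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal beam axes ``(lat, up, dir)`` in world coordinates.

    ``dir`` is the direction of travel (source -> patient), ``lat`` the
    in-plane lateral axis and ``up`` the craniocaudal axis (+z for axial
    beams). Spot lateral coordinates are (u along ``lat``, v along ``up``).
    """
    g = np.deg2rad(gantry_deg)
    source = np.array([np.sin(g), np.cos(g), 0.0])
    d = -source
    lat = np.array([-d[1], d[0], 0.0])
    lat /= np.linalg.norm(lat)
    up = np.cross(d, lat)
    return lat, up, d


@dataclass
class Beam:
    """One PBS field: gantry angle, range shifter, air gap, avoidance bindings."""

    gantry_deg: float
    isocenter_mm: np.ndarray
    range_shifter_wet_cm: float = 7.5
    air_gap_cm: float = 5.0
    avoidance: tuple[str, ...] = ()
    sigma_air_mm: float = 16.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    snout_t_mm: float | None = None  # snout position along the beam axis (depth coord)

    def __post_init__(self) -> None:
        self.isocenter_mm = np.asarray(self.isocenter_mm, dtype=float)
        if self.range_shifter_wet_cm < 0:
            raise ValueError("range shifter WET must be >= 0")

    @property
    def is_anterior(self) -> bool:
        return beam_is_anterior(self.gantry_deg)

    @property
    def classification(self) -> str:
        return "anterior" if self.is_anterior else "posterior"

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return beam_unit_vectors(self.gantry_deg)


@dataclass
class Spot:
    """One scanned pencil beamlet: beam index, energy, lateral position, MU."""

    beam: int
    energy_mev: float
    x_mm: float  # u, along the beam's lateral axis at the isocenter plane
    y_mm: float  # v, along the beam's up axis
    weight_mu: float = 1.0

    def __post_init__(self) -> None:
        if self.weight_mu < 0:
            raise ValueError("spot weight must be >= 0")


@dataclass
class Plan:
    """Beams + spots + prescription, with provenance metadata."""

    beams: list[Beam]
    spots: list[Spot]
    prescription: Prescription
    weight_ratio_cap: float = 150.0
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        nb = len(self.beams)
        for i, s in enumerate(self.spots):
            if not (0 <= s.beam < nb):
                raise PlanSchemaError(f"spots[{i}].beam: index {s.beam} has no beam")
            if s.weight_mu < 0:
                raise PlanSchemaError(f"spots[{i}].weight_mu: negative weight")
        w = self.weights()
        nz = w[w > 0]
        if nz.size and nz.max() / nz.min() > self.weight_ratio_cap * (1 + 1e-12):
            raise PlanSchemaError(
                f"nonzero spot weight ratio {nz.max() / nz.min():.1f} exceeds "
                f"cap {self.weight_ratio_cap}"
            )

    def weights(self) -> np.ndarray:
        return np.array([s.weight_mu for s in self.spots], dtype=float)

    def set_weights(self, w: np.ndarray) -> None:
        if len(w) != len(self.spots):
            raise ValueError("weight vector length mismatch")
        for s, wi in zip(self.spots, w):
            s.weight_mu = float(wi)

    def spot_beam_indices(self) -> np.ndarray:
        return np.array([s.beam for s in self.spots], dtype=int)

    def drop_zero_weight_spots(self) -> "Plan":
        spots = [s for s in self.spots if s.weight_mu > 0]
        return dataclasses.replace(self, spots=spots)


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------


@dataclass
class Scenario:
    """One error scenario: rigid patient shift/rotation, range scaling,
    and optional per-beam independent shifts.

    The identity scenario has zero translation/rotations, range scale 1 and
    no per-beam shifts.
    """

    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    roll_deg: float = 0.0  # about y (anterior-posterior axis)
    yaw_deg: float = 0.0  # about z (craniocaudal axis)
    range_scale: float = 1.0  # multiplier on stopping power
    per_beam_mm: dict[int, np.ndarray] = field(default_factory=dict)
    tag: str = ""
    category: str = ""  # shift | range | rotation | beam_shift | nominal

    def __post_init__(self) -> None:
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)
        self.per_beam_mm = {int(k): np.asarray(v, dtype=float) for k, v in self.per_beam_mm.items()}

    @property
    def is_identity(self) -> bool:
        return (
            not self.translation_mm.any()
            and self.roll_deg == 0.0
            and self.yaw_deg == 0.0
            and self.range_scale == 1.0
            and not any(v.any() for v in self.per_beam_mm.values())
        )

    def neg(self) -> "Scenario":
        return Scenario(
            translation_mm=-self.translation_mm,
            roll_deg=-self.roll_deg,
            yaw_deg=-self.yaw_deg,
            range_scale=1.0 / self.range_scale,
            per_beam_mm={k: -v for k, v in self.per_beam_mm.items()},
            tag=f"neg({self.tag})",
        )

    def compose(self, other: "Scenario") -> "Scenario":
        """Scenario equivalent to applying ``self`` then ``other``.

        Valid for the small rigid perturbations used here (rotations about
        the shared isocenter commute to first order; translations add).
        """
        beams = set(self.per_beam_mm) | set(other.per_beam_mm)
        return Scenario(
            translation_mm=self.translation_mm + other.translation_mm,
            roll_deg=self.roll_deg + other.roll_deg,
            yaw_deg=self.yaw_deg + other.yaw_deg,
            range_scale=self.range_scale * other.range_scale,
            per_beam_mm={
                b: self.per_beam_mm.get(b, np.zeros(3)) + other.per_beam_mm.get(b, np.zeros(3))
                for b in beams
            },
            tag=f"{self.tag}+{other.tag}",
        )


IDENTITY_SCENARIO = Scenario(tag="nominal", category="nominal")


# --------------------------------------------------------------------------
# DVH curves
# --------------------------------------------------------------------------


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve: fraction of volume receiving >= dose."""

    structure: str
    dose_edges_cge: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.dose_edges_cge = np.asarray(self.dose_edges_cge, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        d = np.diff(self.volume_fraction)
        if d.size and d.max() > 1e-12:
            raise ValueError("DVH volume fraction must be monotone non-increasing")

    def volume_at_dose(self, dose_cge: float) -> float:
        """V(dose): fraction of the structure receiving at least ``dose_cge``."""
        return float(
            np.interp(dose_cge, self.dose_edges_cge, self.volume_fraction, left=1.0, right=0.0)
        )

    def dose_at_volume(self, volume_fraction: float) -> float:
        """D(v): the highest dose received by at least fraction ``volume_fraction``
        of the volume (plateaus resolve to their far, high-dose edge)."""
        v = float(np.clip(volume_fraction, 0.0, 1.0))
        vf = self.volume_fraction
        de = self.dose_edges_cge
        idx = np.nonzero(vf >= v)[0]
        if idx.size == 0:
            return float(de[0])
        i = int(idx[-1])
        if i == de.size - 1 or vf[i] <= v:
            return float(de[i])
        f = (vf[i] - v) / (vf[i] - vf[i + 1])
        return float(de[i] + f * (de[i + 1] - de[i]))


# --------------------------------------------------------------------------
# volume I/O (NRRD primary via SimpleITK; NIfTI read via nibabel)
# --------------------------------------------------------------------------


def read_volume(path: str | Path) -> ImageGrid:
    """Read a volume (NRRD/NIfTI) as an :class:`ImageGrid`."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        aff = img.affine
        spacing = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
        origin = aff[:3, 3]
        return ImageGrid(origin=origin, spacing=spacing, values=data)
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.transpose(arr, (2, 1, 0)).astype(float)
    return ImageGrid(
        origin=np.array(img.GetOrigin()), spacing=np.array(img.GetSpacing()), values=values
    )


def write_volume(path: str | Path, grid_or_mask, origin=None, spacing=None) -> Path:
    """Write a volume as NRRD (compressed). Accepts an ImageGrid or an array."""
    import SimpleITK as sitk

    path = Path(path)
    if isinstance(grid_or_mask, ImageGrid):
        values, origin, spacing = grid_or_mask.values, grid_or_mask.origin, grid_or_mask.spacing
    else:
        values = np.asarray(grid_or_mask)
        if origin is None or spacing is None:
            raise ValueError("origin and spacing required when writing a bare array")
    arr = np.transpose(values, (2, 1, 0))
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(np.float32)
    img = sitk.GetImageFromArray(arr)
    img.SetOrigin(tuple(float(x) for x in origin))
    img.SetSpacing(tuple(float(x) for x in spacing))
    sitk.WriteImage(img, str(path), useCompression=True)
    return path


# --------------------------------------------------------------------------
# case I/O
# --------------------------------------------------------------------------


def read_case(
    grid_path: str | Path,
    structure_paths: Mapping[str, str | Path],
    roles: Mapping[str, str] | None = None,
) -> tuple[ImageGrid, StructureSet]:
    """Read a case from a grid volume plus per-structure mask volumes.

    Masks are binarized at 0.5. Shape/spacing mismatches raise
    :class:`CaseValidationError` naming the offending structure; a missing
    ``external`` structure is a hard error.
    """
    grid = read_volume(grid_path)
    structures = StructureSet(grid=grid)
    roles = dict(roles or {})
    for name, p in structure_paths.items():
        vol = read_volume(p)
        if vol.values.shape != grid.shape:
            raise CaseValidationError(
                f"structure '{name}' has shape {vol.values.shape}, expected {grid.shape}"
            )
        if not np.allclose(vol.spacing, grid.spacing) or not np.allclose(vol.origin, grid.origin):
            raise CaseValidationError(f"structure '{name}' lattice differs from the grid")
        role = roles.get(name) or _default_role(name)
        structures.add(name, vol.values >= 0.5, role=role)
    structures.validate()
    return grid, structures


def _default_role(name: str) -> str:
    low = name.lower()
    if low == "external":
        return "external"
    if low.startswith("ctv"):
        return "target"
    if low in ("ant_avoid", "post_avoid", "postneck", "skin_rind", "sfo_region",
               "external_minus_target"):
        return "automation"
    return "oar"


def write_case(
    out_dir: str | Path,
    grid: ImageGrid,
    structures: StructureSet,
    extra_manifest: dict | None = None,
) -> Path:
    """Write a case directory: RSP grid + mask NRRDs + ``case.json`` manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(out / "rsp.nrrd", grid)
    manifest: dict = {
        "format": "pbsautoplan-case",
        "version": 1,
        "grid": "rsp.nrrd",
        "structures": {},
    }
    for name in structures.names():
        fname = f"mask_{name}.nrrd"
        write_volume(out / fname, structures[name], origin=grid.origin, spacing=grid.spacing)
        manifest["structures"][name] = {"file": fname, "role": structures.roles[name]}
    if extra_manifest:
        manifest.update(extra_manifest)
    (out / "case.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_case_dir(case_dir: str | Path) -> tuple[ImageGrid, StructureSet, dict]:
    """Read a case directory written by :func:`write_case`."""
    case_dir = Path(case_dir)
    manifest = json.loads((case_dir / "case.json").read_text())
    paths = {n: case_dir / meta["file"] for n, meta in manifest["structures"].items()}
    roles = {n: meta["role"] for n, meta in manifest["structures"].items()}
    grid, structures = read_case(case_dir / manifest["grid"], paths, roles)
    return grid, structures, manifest


# --------------------------------------------------------------------------
# plan I/O (documented JSON schema)
# --------------------------------------------------------------------------

PLAN_FORMAT = "pbsautoplan-plan"


def write_plan(plan: Plan, path: str | Path) -> Path:
    """Write a plan as JSON. Refuses plans violating the Plan invariants."""
    plan.validate()
    doc = {
        "format": PLAN_FORMAT,
        "version": 1,
        "prescription": {"dose_cge": plan.prescription.dose_cge,
                         "fractions": plan.prescription.fractions},
        "weight_ratio_cap": plan.weight_ratio_cap,
        "beams": [
            {
                "gantry_deg": b.gantry_deg,
                "isocenter_mm": list(map(float, b.isocenter_mm)),
                "range_shifter_wet_cm": b.range_shifter_wet_cm,
                "air_gap_cm": b.air_gap_cm,
                "avoidance": list(b.avoidance),
                "sigma_air_mm": b.sigma_air_mm,
                "snout_t_mm": b.snout_t_mm,
            }
            for b in plan.beams
        ],
        "spots": {
            "beam": [s.beam for s in plan.spots],
            "energy_mev": [s.energy_mev for s in plan.spots],
            "x_mm": [s.x_mm for s in plan.spots],
            "y_mm": [s.y_mm for s in plan.spots],
            "weight_mu": [s.weight_mu for s in plan.spots],
        },
        "provenance": plan.provenance,
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def _require(doc: dict, key: str, typ, where: str):
    if key not in doc:
        raise PlanSchemaError(f"{where}.{key}: missing")
    val = doc[key]
    if typ is float:
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise PlanSchemaError(f"{where}.{key}: expected a number, got {type(val).__name__}")
        return float(val)
    if not isinstance(val, typ):
        raise PlanSchemaError(f"{where}.{key}: expected {typ.__name__}, got {type(val).__name__}")
    return val


def read_plan(path: str | Path) -> Plan:
    """Read a plan JSON file, validating the schema.

    Schema violations raise :class:`PlanSchemaError` with the JSON path of the
    offending field.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != PLAN_FORMAT:
        raise PlanSchemaError("$.format: not a pbsautoplan plan file")
    presc_doc = _require(doc, "prescription", dict, "$")
    prescription = Prescription(
        dose_cge=_require(presc_doc, "dose_cge", float, "$.prescription"),
        fractions=int(_require(presc_doc, "fractions", float, "$.prescription")),
    )
    beams = []
    for i, b in enumerate(_require(doc, "beams", list, "$")):
        where = f"$.beams[{i}]"
        if not isinstance(b, dict):
            raise PlanSchemaError(f"{where}: expected an object")
        iso = _require(b, "isocenter_mm", list, where)
        if len(iso) != 3:
            raise PlanSchemaError(f"{where}.isocenter_mm: expected 3 values")
        beams.append(
            Beam(
                gantry_deg=_require(b, "gantry_deg", float, where),
                isocenter_mm=np.array(iso, dtype=float),
                range_shifter_wet_cm=_require(b, "range_shifter_wet_cm", float, where),
                air_gap_cm=_require(b, "air_gap_cm", float, where),
                avoidance=tuple(_require(b, "avoidance", list, where)),
                sigma_air_mm=_require(b, "sigma_air_mm", float, where),
                snout_t_mm=b.get("snout_t_mm"),
            )
        )
    sp = _require(doc, "spots", dict, "$")
    cols = {k: _require(sp, k, list, "$.spots")
            for k in ("beam", "energy_mev", "x_mm", "y_mm", "weight_mu")}
    n = len(cols["beam"])
    for k, v in cols.items():
        if len(v) != n:
            raise PlanSchemaError(f"$.spots.{k}: length {len(v)} != {n}")
    spots = [
        Spot(beam=int(cols["beam"][i]), energy_mev=float(cols["energy_mev"][i]),
             x_mm=float(cols["x_mm"][i]), y_mm=float(cols["y_mm"][i]),
             weight_mu=float(cols["weight_mu"][i]))
        for i in range(n)
    ]
    plan = Plan(
        beams=beams,
        spots=spots,
        prescription=prescription,
        weight_ratio_cap=float(doc.get("weight_ratio_cap", 150.0)),
        provenance=doc.get("provenance", {}),
    )
    plan.validate()
    return plan


def write_dvh_csv(curves: Iterable[DVHCurve], path: str | Path) -> Path:
    """Write DVH curves as CSV with structure, dose, volume-fraction columns."""
    import pandas as pd

    frames = [
        pd.DataFrame(
            {"structure": c.structure, "dose_cge": c.dose_edges_cge,
             "volume_fraction": c.volume_fraction}
        )
        for c in curves
    ]
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
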