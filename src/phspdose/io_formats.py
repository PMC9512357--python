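"""Plan, phantom and dose I/O, plus the synthetic fixture generator.

The primary plan dialect is a small documented YAML schema (structured
text) so the whole pipeline is testable without binary fixtures::

    name: demo
    prescription_dose_cgy: 200.0
    beams:
      - quality: flattened          # or FFF
        gantry_angle_deg: 0.0
        isocenter_mm: [0.0, 0.0, 0.0]
        segments:
          - monitor_units: 100.0
            y_jaws_mm: [-50.0, 50.0]
            mlc_bank_a_mm: [ ... 80 leaf tips, mm at isocenter ... ]
            mlc_bank_b_mm: [ ... 80 leaf tips ... ]

Leaf arrays are bank A (negative-x tips) then bank B, IEC61217 axes, mm at
the isocenter plane.  DICOM-RT Plan import (Elekta 160-leaf geometry only)
and DICOM-RT Dose export are optional conveniences built on pydicom.

The fixture generator recreates the benchmarking geometries: centered and
offset square fields on a 300 mm water cube, and toy step-and-shoot IMRT
plans (7 beams / 28 segments around a central target; 15 beams / 30
segments with a low-density shell) that match the published beam and
segment counts but not any patient anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .aperture import N_LEAF_PAIRS, Aperture, Segment, make_square_field
from .transport import DoseGrid, Phantom, water_cube_phantom

__all__ = [
    "Beam",
    "Plan",
    "read_plan",
    "write_plan",
    "read_dicom_plan",
    "generate_fixture",
    "write_dose",
    "read_dose",
    "write_dicom_dose",
]

FIXTURE_KINDS = ("square_field", "offset_field", "toy_prostate_imrt", "toy_lung_imrt")


@dataclass
class Beam:
    """One treatment beam: a gantry angle with its step-and-shoot segments."""

    quality: str
    segments: list[Segment]
    gantry_angle_deg: float = 0.0
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a beam needs at least one segment")

    @property
    def total_mu(self) -> float:
        return sum(s.monitor_units for s in self.segments)


@dataclass
class Plan:
    """A treatment plan: beams with metadata."""

    beams: list[Beam]
    name: str = ""
    prescription_dose_cgy: float | None = None

    def __post_init__(self) -> None:
        if not self.beams:
            raise ValueError("a plan needs at least one beam")
        if self.total_mu <= 0:
            raise ValueError("total plan MU must be positive")

    @property
    def total_mu(self) -> float:
        return sum(b.total_mu for b in self.beams)

    @property
    def n_segments(self) -> int:
        return sum(len(b.segments) for b in self.beams)


# ---------------------------------------------------------------------------
# YAML plan dialect

def read_plan(path) -> Plan:
    """Read a plan from the YAML dialect (or a DICOM-RT Plan file).

    Files ending in ``.dcm`` are dispatched to :func:`read_dicom_plan`.
    All apertures are validated; malformed files raise descriptive errors.
    """
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        return read_dicom_plan(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed plan file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "beams" not in doc:
        raise ValueError(f"plan file {path} has no 'beams' list")
    beams = []
    for bi, b in enumerate(doc["beams"]):
        segments = []
        for si, s in enumerate(b.get("segments", [])):
            for bank in ("mlc_bank_a_mm", "mlc_bank_b_mm"):
                if len(s.get(bank, ())) != N_LEAF_PAIRS:
                    raise ValueError(
                        f"beam {bi} segment {si}: {bank} must have {N_LEAF_PAIRS} leaf tips"
                    )
            try:
                aperture = Aperture(
                    y_jaws_mm=tuple(s["y_jaws_mm"]),
                    mlc_bank_a_mm=np.asarray(s["mlc_bank_a_mm"], dtype=float),
                    mlc_bank_b_mm=np.asarray(s["mlc_bank_b_mm"], dtype=float),
                    transmission=float(s.get("transmission", 0.0)),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"beam {bi} segment {si}: {exc}") from exc
            segments.append(
                Segment(
                    aperture=aperture,
                    monitor_units=float(s["monitor_units"]),
                    gantry_angle_deg=float(b.get("gantry_angle_deg", 0.0)),
                )
            )
        beams.append(
            Beam(
                quality=str(b.get("quality", "flattened")),
                segments=segments,
                gantry_angle_deg=float(b.get("gantry_angle_deg", 0.0)),
                isocenter_mm=tuple(b.get("isocenter_mm", (0.0, 0.0, 0.0))),
            )
        )
    return Plan(
        beams=beams,
        name=str(doc.get("name", path.stem)),
        prescription_dose_cgy=doc.get("prescription_dose_cgy"),
    )


def write_plan(plan: Plan, path) -> None:
    """Serialize a plan to the YAML dialect (round-trips with read_plan)."""
    doc = {
        "name": plan.name,
        "prescription_dose_cgy": plan.prescription_dose_cgy,
        "beams": [
            {
                "quality": b.quality,
                "gantry_angle_deg": b.gantry_angle_deg,
                "isocenter_mm": [float(v) for v in b.isocenter_mm],
                "segments": [
                    {
                        "monitor_units": s.monitor_units,
                        "y_jaws_mm": [float(v) for v in s.aperture.y_jaws_mm],
                        "mlc_bank_a_mm": [float(v) for v in s.aperture.mlc_bank_a_mm],
                        "mlc_bank_b_mm": [float(v) for v in s.aperture.mlc_bank_b_mm],
                        "transmission": s.aperture.transmission,
                    }
                    for s in b.segments
                ],
            }
            for b in plan.beams
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_dicom_plan(path) -> Plan:
    """Import a DICOM-RT Plan (Elekta 160-leaf MLC geometry only).

    Jaw (ASYMY) and leaf (MLCX) positions are taken from the first control
    point of each beam and interpreted as mm at the isocenter plane,
    IEC61217 axes; beam meterset comes from the referenced fraction group.
    """
    import pydicom

    ds = pydicom.dcmread(path, force=True)
    metersets = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)
    beams = []
    for b in getattr(ds, "BeamSequence", []):
        cp = b.ControlPointSequence[0]
        jaws = None
        bank_a = bank_b = None
        for dev in getattr(cp, "BeamLimitingDevicePositionSequence", []):
            kind = dev.RTBeamLimitingDeviceType
            pos = [float(v) for v in dev.LeafJawPositions]
            if kind in ("ASYMY", "Y"):
                jaws = (pos[0], pos[1])
            elif kind in ("MLCX", "MLCY"):
                if len(pos) != 2 * N_LEAF_PAIRS:
                    raise ValueError(
                        f"beam {b.BeamNumber}: expected {2 * N_LEAF_PAIRS} leaf positions, "
                        f"got {len(pos)}"
                    )
                bank_a = np.asarray(pos[:N_LEAF_PAIRS])
                bank_b = np.asarray(pos[N_LEAF_PAIRS:])
        if jaws is None or bank_a is None:
            raise ValueError(f"beam {b.BeamNumber}: missing jaw or MLC positions")
        mu = metersets.get(int(b.BeamNumber), 0.0)
        if mu <= 0:
            raise ValueError(f"beam {b.BeamNumber}: no positive meterset found")
        aperture = Aperture(y_jaws_mm=jaws, mlc_bank_a_mm=bank_a, mlc_bank_b_mm=bank_b)
        gantry = float(getattr(cp, "GantryAngle", 0.0))
        beams.append(
            Beam(
                quality="FFF" if "FFF" in str(getattr(b, "BeamName", "")).upper() else "flattened",
                segments=[Segment(aperture=aperture, monitor_units=mu, gantry_angle_deg=gantry)],
                gantry_angle_deg=gantry,
            )
        )
    return Plan(beams=beams, name=str(getattr(ds, "RTPlanLabel", "dicom-plan")))


# ---------------------------------------------------------------------------
# Fixture generator

def _random_blocky_aperture(
    rng: np.random.Generator, half_extent_mm: float, jitter_mm: float
) -> Aperture:
    """Rectangular-ish segment aperture with leaf-tip jitter around a target."""
    w = half_extent_mm
    y_lo, y_hi = -w, w
    band_lo = -200.0 + 5.0 * np.arange(N_LEAF_PAIRS)
    band_hi = band_lo + 5.0
    covered = (band_hi > y_lo) & (band_lo < y_hi)
    bank_a = np.full(N_LEAF_PAIRS, -w)
    bank_b = np.full(N_LEAF_PAIRS, -w)
    n_cov = int(covered.sum())
    bank_a[covered] = -w + rng.uniform(-jitter_mm, jitter_mm, size=n_cov)
    bank_b[covered] = w + rng.uniform(-jitter_mm, jitter_mm, size=n_cov)
    bank_b[covered] = np.maximum(bank_b[covered], bank_a[covered] + 1.0)
    return Aperture(y_jaws_mm=(y_lo, y_hi), mlc_bank_a_mm=bank_a, mlc_bank_b_mm=bank_b)


def _lung_phantom(side_mm: float = 300.0, voxel_mm: float = 2.0) -> Phantom:
    """Water cube with a 0.26 g/cm^3 shell around a unit-density 20 mm target."""
    ph = water_cube_phantom(side_mm=side_mm, voxel_mm=voxel_mm, iso_depth_mm=side_mm / 2)
    x = ph.voxel_centers(0)
    y = ph.voxel_centers(1)
    z = ph.voxel_centers(2)
    r = np.sqrt(
        x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
    )
    shell = (r > 10.0) & (r < 60.0)
    ph.density[shell] = 0.26
    return ph


def generate_fixture(kind: str, parameters: dict | None = None, seed: int = 0):
    """Deterministic synthetic plan + phantom for the benchmarking protocol.

    Kinds: ``square_field`` (width_mm, quality, monitor_units),
    ``offset_field`` (plus offset_x_mm / offset_y_mm), ``toy_prostate_imrt``
    (7 coplanar beams, 28 segments, water cube), ``toy_lung_imrt`` (15
    coplanar beams, 30 segments, low-density shell phantom).  All fixtures
    are pure functions of (kind, parameters, seed).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    p = dict(parameters or {})
    rng = np.random.default_rng(seed)
    quality = p.get("quality", "flattened")
    voxel = p.get("voxel_mm", 2.0)

    if kind in ("square_field", "offset_field"):
        width = float(p.get("width_mm", 100.0))
        ox = float(p.get("offset_x_mm", 0.0)) if kind == "offset_field" else 0.0
        oy = float(p.get("offset_y_mm", 0.0)) if kind == "offset_field" else 0.0
        mu = float(p.get("monitor_units", 100.0))
        aperture = make_square_field(width, ox, oy)
        beam = Beam(quality=quality, segments=[Segment(aperture=aperture, monitor_units=mu)])
        plan = Plan(beams=[beam], name=f"{kind}_{width:g}mm")
        phantom = water_cube_phantom(side_mm=300.0, voxel_mm=voxel, iso_depth_mm=100.0)
        return plan, phantom

    if kind == "toy_prostate_imrt":
        n_beams, seg_per_beam = 7, 4
        beams = []
        for k in range(n_beams):
            gantry = 360.0 * k / n_beams
            segments = [
                Segment(
                    aperture=_random_blocky_aperture(rng, half_extent_mm=30.0, jitter_mm=8.0),
                    monitor_units=float(rng.uniform(15.0, 35.0)),
                    gantry_angle_deg=gantry,
                )
                for _ in range(seg_per_beam)
            ]
            beams.append(Beam(quality=quality, segments=segments, gantry_angle_deg=gantry))
        plan = Plan(beams=beams, name="toy_prostate_imrt", prescription_dose_cgy=3625.0)
        phantom = water_cube_phantom(side_mm=300.0, voxel_mm=voxel, iso_depth_mm=150.0)
        return plan, phantom

    # toy_lung_imrt
    n_beams, seg_per_beam = 15, 2
    beams = []
    for k in range(n_beams):
        gantry = 360.0 * k / n_beams
        segments = [
            Segment(
                aperture=_random_blocky_aperture(rng, half_extent_mm=15.0, jitter_mm=4.0),
                monitor_units=float(rng.uniform(20.0, 40.0)),
                gantry_angle_deg=gantry,
            )
            for _ in range(seg_per_beam)
        ]
        beams.append(Beam(quality=quality, segments=segments, gantry_angle_deg=gantry))
    plan = Plan(beams=beams, name="toy_lung_imrt", prescription_dose_cgy=5400.0)
    return plan, _lung_phantom(voxel_mm=voxel)


# ---------------------------------------------------------------------------
# Dose containers

def write_dose(dose: DoseGrid, path, format: str = "npz") -> None:
    """Write a dose grid: ``npz`` (native, lossless) or ``dicom`` (RT Dose)."""
    if format == "npz":
        np.savez_compressed(
            path,
            values=dose.values,
            uncertainty=np.array([]) if dose.uncertainty is None else dose.uncertainty,
            voxel_size_mm=dose.voxel_size_mm,
            origin_mm=np.asarray(dose.origin_mm),
            histories=dose.histories,
            unit=np.bytes_(dose.unit.encode()),
        )
    elif format == "dicom":
        write_dicom_dose(dose, path)
    else:
        raise ValueError(f"unknown dose format {format!r}")


def read_dose(path) -> DoseGrid:
    """Read a native .npz dose container (bit-identical round trip)."""
    with np.load(path) as f:
        unc = f["uncertainty"]
        return DoseGrid(
            values=f["values"],
            uncertainty=None if unc.size == 0 else unc,
            voxel_size_mm=float(f["voxel_size_mm"]),
            origin_mm=tuple(f["origin_mm"]),
            histories=int(f["histories"]),
            unit=bytes(f["unit"]).decode(),
        )


def write_dicom_dose(dose: DoseGrid, path) -> None:
    """Export as a DICOM-RT Dose object (uint32 pixels, GridFrameOffsetVector).

    Frames run along z; within a frame, rows are y and columns x.  Read-back
    agrees with the written grid to within half a DoseGridScaling step.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.2")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "CGY" if "cGy" in dose.unit else "RELATIVE"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    nx, ny, nz = dose.values.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [dose.voxel_size_mm, dose.voxel_size_mm]
    ds.SliceThickness = dose.voxel_size_mm
    half = dose.voxel_size_mm / 2
    ds.ImagePositionPatient = [
        dose.origin_mm[0] + half,
        dose.origin_mm[1] + half,
        dose.origin_mm[2] + half,
    ]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [k * dose.voxel_size_mm for k in range(nz)]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    vmax = float(dose.values.max())
    scaling = vmax / (2**32 - 1) if vmax > 0 else 1.0
    ds.DoseGridScaling = scaling
    pixels = np.round(dose.values / scaling) if vmax > 0 else np.zeros_like(dose.values)
    # (x, y, z) -> frames (z), rows (y), cols (x)
    ds.PixelData = np.ascontiguousarray(
        pixels.transpose(2, 1, 0).astype(np.uint32)
    ).tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_dicom_dose(path) -> DoseGrid:
    """Read back a DICOM-RT Dose written by :func:`write_dicom_dose`."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64) * float(ds.DoseGridScaling)
    values = arr.transpose(2, 1, 0)  # frames, rows, cols -> x, y, z
    voxel = float(ds.PixelSpacing[0])
    half = voxel / 2
    origin = tuple(float(v) - half for v in ds.ImagePositionPatient)
    return DoseGrid(
        values=values,
        uncertainty=None,
        voxel_size_mm=voxel,
        origin_mm=origin,
        unit="cGy" if str(getattr(ds, "DoseUnits", "")) == "CGY" else "arbitrary",
    )
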