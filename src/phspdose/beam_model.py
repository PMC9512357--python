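"""Virtual-source beam model of the accelerator head.

The head is represented by a small number of Gaussian-shaped virtual photon
sources on the beam axis, together with a radial primary-fluence profile, a
discrete energy spectrum, collimator scatter factors and an absolute fluence
calibration.  All parameters for one beam quality live in a :class:`BeamModel`
which is read from a structured-text config file; the two packaged models
(``versahd_6mv.cfg``, ``versahd_6fff.cfg``) describe the 6 MV flattened and
flattening-filter-free beams of an Elekta Versa HD head.

Coordinate conventions
----------------------
The origin is at the nominal source (the target), the +z axis points along
the beam axis toward the patient, and x/y follow IEC61217 rotated 180 degrees
about x.  Apertures, grids and off-axis positions are always expressed at the
isocenter plane (z = d); the phase-space plane sits at z = p and the bottom of
the collimator at z = c, with 0 < c < p < d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "MachineGeometry",
    "VirtualSource",
    "FluenceProfile",
    "EnergySpectrum",
    "ScatterFactorTable",
    "BeamModel",
    "BeamModelError",
    "load_beam_model",
    "save_beam_model",
    "interp_profile",
    "packaged_model_path",
]

QUALITIES = ("flattened", "FFF")


class BeamModelError(ValueError):
    """Raised when a beam-model config violates a model invariant."""


@dataclass(frozen=True)
class MachineGeometry:
    """Source-independent head geometry and phase-space grid layout."""

    source_to_isocenter_mm: float = 1000.0
    phase_plane_mm: float = 548.0
    collimator_mm: float = 401.8
    grid_size_i: int = 800
    grid_size_j: int = 800
    grid_resolution_x_mm: float = 0.5
    grid_resolution_y_mm: float = 0.5
    grid_edge_x_mm: float = -200.0
    grid_edge_y_mm: float = -200.0
    fixed_x_jaw_mm: float = 200.0
    mlc_leaf_count: int = 160
    mlc_leaf_width_mm: float = 5.0

    def __post_init__(self) -> None:
        d, p, c = self.source_to_isocenter_mm, self.phase_plane_mm, self.collimator_mm
        if not (0.0 < c < p < d):
            raise BeamModelError(
                f"machine geometry requires 0 < c < p < d, got c={c}, p={p}, d={d}"
            )
        if self.grid_size_i <= 0 or self.grid_size_j <= 0:
            raise BeamModelError("grid size must be positive")
        if self.grid_resolution_x_mm <= 0 or self.grid_resolution_y_mm <= 0:
            raise BeamModelError("grid resolution must be positive")
        if self.mlc_leaf_count <= 0 or self.mlc_leaf_count % 2:
            raise BeamModelError("MLC leaf count must be a positive even number")

    @property
    def n_leaf_pairs(self) -> int:
        return self.mlc_leaf_count // 2


@dataclass(frozen=True)
class VirtualSource:
    """One Gaussian source on the beam axis.

    ``position_mm`` is measured from the nominal source along +z; the width is
    the standard deviation of the Gaussian source distribution in its own
    plane.  Weights are relative units (they need not sum to one).
    """

    position_mm: float
    weight: float
    sigma_x_mm: float
    sigma_y_mm: float

    def validate(self, geometry: MachineGeometry) -> None:
        if not (0.0 <= self.position_mm < geometry.collimator_mm):
            raise BeamModelError(
                f"source position {self.position_mm} mm must lie in [0, c={geometry.collimator_mm})"
            )
        if self.weight <= 0:
            raise BeamModelError("source weight must be positive")
        if self.sigma_x_mm <= 0 or self.sigma_y_mm <= 0:
            raise BeamModelError("source widths must be positive")


def _as_table(rows, name: str) -> np.ndarray:
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise BeamModelError(f"{name}: expected >=2 rows of (x, value) pairs")
    return arr


@dataclass(frozen=True)
class FluenceProfile:
    """Radial primary-fluence profile phi(r) at the isocenter plane."""

    table: np.ndarray  # (N, 2): off_axis_mm, relative_intensity

    def __post_init__(self) -> None:
        t = _as_table(self.table, "fluence_profile")
        object.__setattr__(self, "table", t)
        r, phi = t[:, 0], t[:, 1]
        if r[0] != 0.0 or np.any(np.diff(r) <= 0):
            raise BeamModelError(
                "fluence_profile: off-axis positions must strictly increase from 0"
            )
        if np.any(phi < 0):
            raise BeamModelError("fluence_profile: intensities must be >= 0")
        if phi[-1] != 0.0:
            raise BeamModelError("fluence_profile: profile must fall to 0 at its end")

    @property
    def r_mm(self) -> np.ndarray:
        return self.table[:, 0]

    @property
    def values(self) -> np.ndarray:
        return self.table[:, 1]


@dataclass(frozen=True)
class EnergySpectrum:
    """Discrete photon energy spectrum lambda(e): energy lines with intensities."""

    table: np.ndarray  # (N, 2): energy_MeV, relative_intensity

    def __post_init__(self) -> None:
        t = _as_table(self.table, "spectrum")
        object.__setattr__(self, "table", t)
        e, lam = t[:, 0], t[:, 1]
        if np.any(np.diff(e) <= 0):
            raise BeamModelError("spectrum: energies must strictly increase")
        if e[0] < 0.05 or e[-1] > 10.0:
            raise BeamModelError("spectrum: energies out of the supported 0.05-10 MeV range")
        if np.any(lam <= 0):
            raise BeamModelError("spectrum: intensities must be positive")

    @property
    def energies_mev(self) -> np.ndarray:
        return self.table[:, 0]

    @property
    def intensities(self) -> np.ndarray:
        return self.table[:, 1]

    @property
    def probabilities(self) -> np.ndarray:
        lam = self.intensities
        return lam / lam.sum()


@dataclass(frozen=True)
class ScatterFactorTable:
    """Collimator scatter factor F(A) indexed by equivalent-square field width."""

    table: np.ndarray  # (N, 2): square_field_width_mm, factor

    def __post_init__(self) -> None:
        t = _as_table(self.table, "scatter_factors")
        object.__setattr__(self, "table", t)
        w, f = t[:, 0], t[:, 1]
        if np.any(np.diff(w) <= 0):
            raise BeamModelError("scatter_factors: field widths must strictly increase")
        if np.any(f <= 0):
            raise BeamModelError("scatter_factors: factors must be positive")
        f100 = float(np.interp(100.0, w, f))
        if not math.isclose(f100, 1.0, abs_tol=1e-9):
            raise BeamModelError(
                f"scatter_factors: F(100 mm) must equal 1.000 (normalization), got {f100}"
            )

    def factor_for_area(self, area_mm2: float) -> float:
        """F at the equivalent-square width sqrt(area) of an arbitrary aperture."""
        if area_mm2 < 0:
            raise ValueError("aperture area must be >= 0")
        return interp_profile(self, math.sqrt(area_mm2))


@dataclass(frozen=True)
class BeamModel:
    """All head-model parameters for one beam quality."""

    quality: str
    geometry: MachineGeometry
    sources: tuple[VirtualSource, ...]
    fluence_profile: FluenceProfile
    spectrum: EnergySpectrum
    scatter_factors: ScatterFactorTable
    calibration: float  # C, particles per MU mm^2 (model units)
    mlc_transmission: float = 0.0
    cgy_per_unit: float = 1.0  # commissioning constant: scaled dose -> cGy

    def __post_init__(self) -> None:
        if self.quality not in QUALITIES:
            raise BeamModelError(f"unknown beam quality {self.quality!r}")
        if not self.sources:
            raise BeamModelError("beam model needs at least one source")
        for s in self.sources:
            s.validate(self.geometry)
        if self.calibration <= 0:
            raise BeamModelError("calibration constant C must be positive")
        if not (0.0 <= self.mlc_transmission < 1.0):
            raise BeamModelError("MLC transmission must lie in [0, 1)")
        if self.cgy_per_unit <= 0:
            raise BeamModelError("cgy_per_unit must be positive")

    def with_calibration(self, calibration: float) -> "BeamModel":
        return replace(self, calibration=calibration)


def interp_profile(profile, x: float):
    """Piecewise-linear lookup in a tabulated radial profile or factor table.

    Works for :class:`FluenceProfile` and :class:`ScatterFactorTable` (or any
    object with a ``(N, 2)`` ``table`` attribute).  Beyond the last tabulated
    point the last value is returned (profiles end at 0, so they stay 0).
    Scalar or array ``x`` is accepted; ``x`` must be >= 0.
    """
    t = profile.table
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("off-axis position / field width must be >= 0")
    out = np.interp(xa, t[:, 0], t[:, 1])
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


# ---------------------------------------------------------------------------
# Config parsing

def _parse_cfg_text(text: str) -> dict:
    """Parse the key/value + table sections of a beam-model config."""
    sections: dict[str, object] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip()
            # table sections hold row lists, key/value sections hold dicts;
            # decide lazily on the first content line
            sections[current] = None
            continue
        if current is None:
            raise BeamModelError(f"config line {lineno}: content outside any section")
        if "=" in line:
            if sections[current] is None:
                sections[current] = {}
            if not isinstance(sections[current], dict):
                raise BeamModelError(f"config line {lineno}: key/value in a table section")
            key, val = (s.strip() for s in line.split("=", 1))
            sections[current][key] = val
        else:
            if sections[current] is None:
                sections[current] = []
            if not isinstance(sections[current], list):
                raise BeamModelError(f"config line {lineno}: table row in a key/value section")
            try:
                sections[current].append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise BeamModelError(f"config line {lineno}: bad table row {line!r}") from exc
    return {k: v for k, v in sections.items() if v is not None}


def packaged_model_path(quality: str) -> Path:
    """Path of the packaged beam-model config for ``quality``."""
    names = {"flattened": "versahd_6mv.cfg", "FFF": "versahd_6fff.cfg"}
    if quality not in names:
        raise BeamModelError(f"unknown beam quality {quality!r}; expected one of {QUALITIES}")
    return Path(resources.files("phspdose.data") / names[quality])


def load_beam_model(path=None, quality: str | None = None) -> BeamModel:
    """Load a :class:`BeamModel` from a config file.

    With ``path=None`` the packaged model for ``quality`` is loaded.  All type
    invariants are validated; a violated one raises :class:`BeamModelError`
    naming the offending table.
    """
    if path is None:
        if quality is None:
            raise BeamModelError("either a config path or a quality tag is required")
        path = packaged_model_path(quality)
    text = Path(path).read_text()
    cfg = _parse_cfg_text(text)

    machine = cfg.get("machine")
    if not isinstance(machine, dict):
        raise BeamModelError("config is missing its [machine] section")
    file_quality = machine.pop("quality", None)
    if quality is not None and file_quality is not None and file_quality != quality:
        raise BeamModelError(
            f"config declares quality {file_quality!r} but {quality!r} was requested"
        )
    q = file_quality or quality
    if q not in QUALITIES:
        raise BeamModelError(f"unknown beam quality {q!r}")

    geo_kwargs = {}
    for key, val in machine.items():
        if key in ("grid_size_i", "grid_size_j", "mlc_leaf_count"):
            geo_kwargs[key] = int(float(val))
        else:
            geo_kwargs[key] = float(val)
    geometry = MachineGeometry(**geo_kwargs)

    sources = []
    for name in sorted(k for k in cfg if k.startswith("source.")):
        s = cfg[name]
        if not isinstance(s, dict):
            raise BeamModelError(f"[{name}] must be a key/value section")
        sources.append(
            VirtualSource(
                position_mm=float(s["position_mm"]),
                weight=float(s["weight"]),
                sigma_x_mm=float(s["sigma_x_mm"]),
                sigma_y_mm=float(s["sigma_y_mm"]),
            )
        )
    if not sources:
        raise BeamModelError("config defines no [source.N] sections")

    for table_name in ("fluence_profile", "spectrum", "scatter_factors"):
        if table_name not in cfg:
            raise BeamModelError(f"config is missing its [{table_name}] table")

    cal = cfg.get("calibration", {})
    if not isinstance(cal, dict):
        raise BeamModelError("[calibration] must be a key/value section")

    return BeamModel(
        quality=q,
        geometry=geometry,
        sources=tuple(sources),
        fluence_profile=FluenceProfile(np.asarray(cfg["fluence_profile"])),
        spectrum=EnergySpectrum(np.asarray(cfg["spectrum"])),
        scatter_factors=ScatterFactorTable(np.asarray(cfg["scatter_factors"])),
        calibration=float(cal.get("particles_per_mu_mm2", 0.0)),
        mlc_transmission=float(cal.get("mlc_transmission", 0.0)),
        cgy_per_unit=float(cal.get("cgy_per_unit", 1.0)),
    )


def save_beam_model(model: BeamModel, path) -> None:
    """Serialize a beam model back to the structured-text config format."""
    g = model.geometry
    lines = ["[machine]", f"quality = {model.quality}"]
    for key in (
        "source_to_isocenter_mm",
        "phase_plane_mm",
        "collimator_mm",
        "grid_size_i",
        "grid_size_j",
        "grid_resolution_x_mm",
        "grid_resolution_y_mm",
        "grid_edge_x_mm",
        "grid_edge_y_mm",
        "fixed_x_jaw_mm",
        "mlc_leaf_count",
        "mlc_leaf_width_mm",
    ):
        lines.append(f"{key} = {getattr(g, key)!r}")
    for n, s in enumerate(model.sources, start=1):
        lines += [
            "",
            f"[source.{n}]",
            f"position_mm = {s.position_mm!r}",
            f"weight = {s.weight!r}",
            f"sigma_x_mm = {s.sigma_x_mm!r}",
            f"sigma_y_mm = {s.sigma_y_mm!r}",
        ]
    lines += [
        "",
        "[calibration]",
        f"particles_per_mu_mm2 = {model.calibration!r}",
        f"mlc_transmission = {model.mlc_transmission!r}",
        f"cgy_per_unit = {model.cgy_per_unit!r}",
    ]
    for name, table in (
        ("fluence_profile", model.fluence_profile.table),
        ("spectrum", model.spectrum.table),
        ("scatter_factors", model.scatter_factors.table),
    ):
        lines += ["", f"[{name}]"]
        lines += [f"{float(row[0])!r}  {float(row[1])!r}" for row in table]
    Path(path).write_text("\n".join(lines) + "\n")
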