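"""Beam-segment collimation: jaws, MLC leaves and the aperture function.

An :class:`Aperture` holds one segment's collimator state at the isocenter
plane: the variable y-jaws and the tip positions of 80 opposed leaf pairs
(160 leaves, 5 mm pitch at isocenter, leaf 0 band starting at -200 mm; the
x-jaws of the modeled head are fixed at +/-200 mm).  The aperture function
omega(x, y) evaluates to 1 inside the opening and to the MLC transmission
outside; its integral is the open area A used by the collimator scatter
factor and the fluence calibration.

Boundary convention: every interval is half-open, [low, high), so a point on
a shared leaf boundary belongs to exactly one leaf and areas are additive.
Leaf ends are straight; closed pairs are parked with zero gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Aperture", "Segment", "make_square_field"]

N_LEAF_PAIRS = 80
LEAF_PITCH_MM = 5.0
TRAVEL_MM = 200.0  # leaf travel / fixed x-jaw half width
_LEAF_EDGE0 = -TRAVEL_MM  # low edge of leaf band 0


@dataclass(frozen=True)
class Aperture:
    """Jaw + MLC opening of one segment, at the isocenter plane (mm)."""

    y_jaws_mm: tuple[float, float]  # (y1, y2), y1 < y2
    mlc_bank_a_mm: np.ndarray  # tip positions, negative-x bank, one per pair
    mlc_bank_b_mm: np.ndarray  # tip positions, positive-x bank
    transmission: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.mlc_bank_a_mm, dtype=float)
        b = np.asarray(self.mlc_bank_b_mm, dtype=float)
        object.__setattr__(self, "mlc_bank_a_mm", a)
        object.__setattr__(self, "mlc_bank_b_mm", b)
        y1, y2 = self.y_jaws_mm
        if not y1 < y2:
            raise ValueError(f"y-jaws must satisfy y1 < y2, got ({y1}, {y2})")
        if a.shape != (N_LEAF_PAIRS,) or b.shape != (N_LEAF_PAIRS,):
            raise ValueError(f"each MLC bank needs exactly {N_LEAF_PAIRS} leaf tips")
        if np.any(a > b):
            raise ValueError("bank A tip must not exceed bank B tip for any pair")
        for name, arr in (("bank A", a), ("bank B", b), ("y-jaws", np.array([y1, y2]))):
            if np.any(np.abs(arr) > TRAVEL_MM):
                raise ValueError(f"{name} positions must lie within +/-{TRAVEL_MM} mm")
        if not (0.0 <= self.transmission < 1.0):
            raise ValueError("transmission must lie in [0, 1)")

    # -- aperture function ---------------------------------------------------
    def mask(self, x_iso, y_iso):
        """Aperture function omega at isocenter-plane coordinates (mm).

        Returns 1.0 where (x, y) lies inside the y-jaws and between the leaf
        tips of the pair whose 5 mm band contains y, and ``transmission``
        otherwise (including beyond the fixed x-jaws).  Accepts scalars or
        broadcastable arrays; intervals are half-open [low, high).
        """
        x = np.asarray(x_iso, dtype=float)
        y = np.asarray(y_iso, dtype=float)
        x, y = np.broadcast_arrays(x, y)
        y1, y2 = self.y_jaws_mm
        leaf = np.floor((y - _LEAF_EDGE0) / LEAF_PITCH_MM).astype(np.int64)
        inside_bands = (leaf >= 0) & (leaf < N_LEAF_PAIRS)
        leaf_c = np.clip(leaf, 0, N_LEAF_PAIRS - 1)
        tip_a = self.mlc_bank_a_mm[leaf_c]
        tip_b = self.mlc_bank_b_mm[leaf_c]
        open_ = (
            inside_bands
            & (y >= y1)
            & (y < y2)
            & (x >= np.maximum(tip_a, -TRAVEL_MM))
            & (x < np.minimum(tip_b, TRAVEL_MM))
        )
        out = np.where(open_, 1.0, self.transmission)
        return float(out) if out.ndim == 0 else out

    def open_area_mm2(self) -> float:
        """Open area A (mm^2 at isocenter): the integral of the binary omega."""
        y1, y2 = self.y_jaws_mm
        lo = _LEAF_EDGE0 + LEAF_PITCH_MM * np.arange(N_LEAF_PAIRS)
        hi = lo + LEAF_PITCH_MM
        dy = np.maximum(0.0, np.minimum(hi, y2) - np.maximum(lo, y1))
        xa = np.maximum(self.mlc_bank_a_mm, -TRAVEL_MM)
        xb = np.minimum(self.mlc_bank_b_mm, TRAVEL_MM)
        dx = np.maximum(0.0, xb - xa)
        return float(np.sum(dx * dy))


def aperture_mask(aperture: Aperture, x_iso, y_iso):
    """Functional alias for :meth:`Aperture.mask`."""
    return aperture.mask(x_iso, y_iso)


def open_area(aperture: Aperture) -> float:
    """Functional alias for :meth:`Aperture.open_area_mm2`."""
    return aperture.open_area_mm2()


@dataclass(frozen=True)
class Segment:
    """One step-and-shoot segment: an aperture delivered with M monitor units."""

    aperture: Aperture
    monitor_units: float
    gantry_angle_deg: float = 0.0
    collimator_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.monitor_units <= 0:
            raise ValueError("monitor units must be positive")


def make_square_field(
    width_mm: float,
    offset_x_mm: float = 0.0,
    offset_y_mm: float = 0.0,
    transmission: float = 0.0,
) -> Aperture:
    """Square field of the given width centered at (offset_x, offset_y).

    Jaws close to offset_y +/- width/2; leaf pairs whose band intersects the
    field open to offset_x +/- width/2, all other pairs are parked closed
    (zero gap) behind the y-jaws.
    """
    if width_mm <= 0:
        raise ValueError("field width must be positive")
    x_lo, x_hi = offset_x_mm - width_mm / 2, offset_x_mm + width_mm / 2
    y_lo, y_hi = offset_y_mm - width_mm / 2, offset_y_mm + width_mm / 2
    if max(abs(x_lo), abs(x_hi), abs(y_lo), abs(y_hi)) > TRAVEL_MM:
        raise ValueError(f"field exceeds the +/-{TRAVEL_MM} mm travel range")
    band_lo = _LEAF_EDGE0 + LEAF_PITCH_MM * np.arange(N_LEAF_PAIRS)
    band_hi = band_lo + LEAF_PITCH_MM
    covered = (band_hi > y_lo) & (band_lo < y_hi)
    park = max(-TRAVEL_MM, min(x_lo, 0.0))
    bank_a = np.full(N_LEAF_PAIRS, park)
    bank_b = np.full(N_LEAF_PAIRS, park)
    bank_a[covered] = x_lo
    bank_b[covered] = x_hi
    return Aperture(
        y_jaws_mm=(y_lo, y_hi),
        mlc_bank_a_mm=bank_a,
        mlc_bank_b_mm=bank_b,
        transmission=transmission,
    )
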