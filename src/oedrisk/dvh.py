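"""Dose-volume histogram containers and transforms.

A differential DVH tabulates, per dose bin, the organ volume receiving a dose
in that bin; a cumulative DVH tabulates the volume receiving at least each
dose level.  Bins are half-open ``[edge_i, edge_{i+1})`` and every integral
over the distribution (mean dose, organ equivalent dose) evaluates the
integrand at bin centers, which is the convention of planning-system exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ORGANS",
    "GROUPS",
    "DifferentialDVH",
    "CumulativeDVH",
    "PatientRecord",
    "cumulative_to_differential",
    "differential_to_cumulative",
    "rebin",
    "mean_dose",
    "max_dose",
]

#: Organs at risk evaluated by the pipeline, in report order.
ORGANS = (
    "breast_contralateral",
    "lungs_both",
    "lung_ipsilateral",
    "lung_contralateral",
    "thyroid",
    "esophagus",
)

#: Treatment groups: partial-breast irradiation at the MR-linac, partial-breast
#: irradiation at the conventional linac, whole-breast irradiation at the
#: conventional linac.
GROUPS = ("PBI_MRL", "PBI_CTL", "WBI_CTL")

# Volume below this (cm^3) is numerical zero when locating the maximum dose.
VOLUME_FLOOR = 1e-9

_VOLUME_RTOL = 1e-6


@dataclass(frozen=True)
class DifferentialDVH:
    """Binned dose distribution of one organ.

    Parameters
    ----------
    organ : str
        Organ label.
    bin_edges : array of shape (B + 1,)
        Ascending bin edges in Gy; ``bin_edges[0] >= 0``.
    bin_volumes : array of shape (B,)
        Volume (cm^3) receiving a dose within each bin.
    total_volume : float, optional
        Organ volume in cm^3; defaults to ``sum(bin_volumes)`` and must agree
        with it to 1e-6 relative.
    """

    organ: str
    bin_edges: np.ndarray
    bin_volumes: np.ndarray
    total_volume: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        vols = np.asarray(self.bin_volumes, dtype=float)
        if edges.ndim != 1 or vols.ndim != 1 or edges.size != vols.size + 1:
            raise ValueError(
                f"{self.organ}: need B+1 edges for B bins, got "
                f"{edges.size} edges and {vols.size} volumes"
            )
        if edges[0] < 0:
            raise ValueError(f"{self.organ}: bin_edges[0] must be >= 0 Gy")
        if np.any(np.diff(edges) <= 0):
            raise ValueError(f"{self.organ}: bin_edges must be strictly increasing")
        if np.any(vols < 0):
            raise ValueError(f"{self.organ}: bin volumes must be non-negative")
        total = float(vols.sum()) if self.total_volume is None else float(self.total_volume)
        if total <= 0:
            raise ValueError(f"{self.organ}: total volume must be positive")
        if abs(vols.sum() - total) > _VOLUME_RTOL * total:
            raise ValueError(
                f"{self.organ}: sum(bin_volumes)={vols.sum():g} does not match "
                f"total_volume={total:g}"
            )
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_volumes", vols)
        object.__setattr__(self, "total_volume", total)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)


@dataclass(frozen=True)
class CumulativeDVH:
    """Volume-at-or-above-dose curve of one organ.

    ``volume_at_or_above[i]`` is the volume (cm^3) receiving at least
    ``dose_points[i]`` Gy; the curve is monotone non-increasing and equals the
    total volume at 0 Gy.
    """

    organ: str
    dose_points: np.ndarray
    volume_at_or_above: np.ndarray
    total_volume: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        doses = np.asarray(self.dose_points, dtype=float)
        vols = np.asarray(self.volume_at_or_above, dtype=float)
        if doses.ndim != 1 or vols.shape != doses.shape:
            raise ValueError(f"{self.organ}: dose and volume arrays must match")
        if doses[0] < 0 or np.any(np.diff(doses) <= 0):
            raise ValueError(f"{self.organ}: dose_points must be ascending and >= 0")
        if np.any(np.diff(vols) > _VOLUME_RTOL * max(vols[0], 1.0)):
            raise ValueError(
                f"{self.organ}: volume_at_or_above must be monotone non-increasing"
            )
        if np.any(vols < 0):
            raise ValueError(f"{self.organ}: volumes must be non-negative")
        total = float(vols[0]) if self.total_volume is None else float(self.total_volume)
        if total <= 0:
            raise ValueError(f"{self.organ}: total volume must be positive")
        if abs(vols[0] - total) > _VOLUME_RTOL * total:
            raise ValueError(
                f"{self.organ}: volume at the lowest dose ({vols[0]:g}) must equal "
                f"total_volume ({total:g})"
            )
        object.__setattr__(self, "dose_points", doses)
        object.__setattr__(self, "volume_at_or_above", vols)
        object.__setattr__(self, "total_volume", total)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: id, treatment group and per-organ differential DVHs."""

    patient_id: str
    group: str
    dvhs: Mapping[str, DifferentialDVH]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"patient {self.patient_id}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )
        d = dict(self.dvhs)
        object.__setattr__(self, "dvhs", d)
        if {"lungs_both", "lung_ipsilateral", "lung_contralateral"} <= d.keys():
            both = d["lungs_both"].total_volume
            parts = (
                d["lung_ipsilateral"].total_volume
                + d["lung_contralateral"].total_volume
            )
            if abs(both - parts) > 0.01 * parts:
                raise ValueError(
                    f"patient {self.patient_id}: lungs_both volume {both:g} cm^3 "
                    f"differs from ipsilateral+contralateral {parts:g} cm^3 by >1%"
                )

    def with_dvhs(self, dvhs: Mapping[str, DifferentialDVH]) -> "PatientRecord":
        return replace(self, dvhs=dvhs)


def cumulative_to_differential(c: CumulativeDVH) -> DifferentialDVH:
    """Convert a cumulative DVH to differential by successive differences.

    ``bin_volumes[i] = V(>= dose_i) - V(>= dose_{i+1})``.  If the curve does
    not reach zero at the last dose point, a final bin of the trailing grid
    spacing is appended to hold the residual volume, so total volume is
    preserved exactly.
    """
    vols = -np.diff(c.volume_at_or_above)
    vols = np.clip(vols, 0.0, None)  # guard tiny negative fp noise
    edges = c.dose_points
    residual = c.volume_at_or_above[-1]
    if residual > 0:
        width = edges[-1] - edges[-2] if edges.size > 1 else 1.0
        edges = np.append(edges, edges[-1] + width)
        vols = np.append(vols, residual)
    return DifferentialDVH(c.organ, edges, vols, c.total_volume)


def differential_to_cumulative(d: DifferentialDVH) -> CumulativeDVH:
    """Convert a differential DVH to the volume-at-or-above-dose curve.

    The curve is evaluated at the bin edges; a leading 0 Gy point carrying the
    total volume is prepended when the histogram does not start at 0 Gy.
    """
    vols = np.concatenate([np.cumsum(d.bin_volumes[::-1])[::-1], [0.0]])
    doses = d.bin_edges
    if doses[0] > 0:
        doses = np.concatenate([[0.0], doses])
        vols = np.concatenate([[vols[0]], vols])
    return CumulativeDVH(d.organ, doses, vols, d.total_volume)


def rebin(d: DifferentialDVH, new_width: float) -> DifferentialDVH:
    """Rebin onto a uniform grid of width ``new_width`` Gy starting at 0.

    Each source bin's volume is distributed over the target bins in
    proportion to interval overlap (i.e. dose is uniform within a source
    bin).  Total volume is conserved exactly; the mean dose moves by at most
    half of ``new_width``.
    """
    if new_width <= 0:
        raise ValueError("new_width must be positive")
    lo = np.floor(d.bin_edges[0] / new_width) * new_width
    n_new = int(np.ceil((d.bin_edges[-1] - lo) / new_width - 1e-12))
    new_edges = lo + new_width * np.arange(n_new + 1)
    new_vols = np.zeros(n_new)
    for left, right, v in zip(d.bin_edges[:-1], d.bin_edges[1:], d.bin_volumes):
        if v == 0:
            continue
        overlap = np.clip(np.minimum(new_edges[1:], right) - np.maximum(new_edges[:-1], left), 0, None)
        frac = overlap / (right - left)
        # force exact conservation per source bin
        new_vols += v * frac / frac.sum()
    return DifferentialDVH(d.organ, new_edges, new_vols, d.total_volume)


def mean_dose(d: DifferentialDVH) -> float:
    """Volume-weighted mean dose in Gy, evaluated at bin centers."""
    return float(np.dot(d.bin_volumes, d.bin_centers) / d.total_volume)


def max_dose(d: DifferentialDVH) -> float:
    """Upper edge of the highest bin holding more than numerical-zero volume."""
    occupied = np.nonzero(d.bin_volumes > VOLUME_FLOOR)[0]
    if occupied.size == 0:
        raise ValueError(f"{d.organ}: all bin volumes are zero")
    return float(d.bin_edges[occupied[-1] + 1])
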