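"""Core/entire RMSD series and the two-step knob offset analysis.

The central readout: how far, and by what kind of motion, the knob domain
departs from the starting (crystal) structure once the core's own motion
has been removed.

Per frame the *two-step fit* does:

1. superpose the frame onto the reference using the core selection and
   apply that transform to the whole frame (removes global tumbling and
   core breathing);
2. superpose the core-aligned knob onto the reference knob — the centroid
   shift of the knob before this second fit is the **translational
   offset** (Å), the rotation magnitude of the second fit is the
   **rotational offset** (deg, in [0, 180]).

The translational offset is defined as the centroid displacement after
core alignment: for a rigid body, the net translation required to fit it
equals its centroid shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain_model import AtomSelection
from .errors import AggregationError, DimensionError
from .structure_io import Trajectory
from .superpose import kabsch_fit, rmsd_nofit, rotation_angle

__all__ = [
    "RmsdSeries",
    "OffsetSeries",
    "MotionSummary",
    "compute_rmsd_series",
    "compute_knob_offsets",
    "summarize_motion",
]


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) against the reference for one selection."""

    selection_label: str  # "core" | "entire" (free-form allowed)
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise DimensionError("times and values length mismatch")
        if (self.values < 0).any():
            raise DimensionError("RMSD values must be >= 0")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class OffsetSeries:
    """Per-frame knob translational (Å) and rotational (deg) offsets."""

    times: np.ndarray
    translational: np.ndarray
    rotational: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.translational = np.asarray(self.translational, dtype=float)
        self.rotational = np.asarray(self.rotational, dtype=float)
        if not (len(self.times) == len(self.translational) == len(self.rotational)):
            raise DimensionError("offset series length mismatch")
        if (self.translational < 0).any():
            raise DimensionError("translational offsets must be >= 0")
        if ((self.rotational < 0) | (self.rotational > 180)).any():
            raise DimensionError("rotational offsets must lie in [0, 180] deg")

    def __len__(self) -> int:
        return len(self.times)


def compute_rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    selection: AtomSelection,
    fit_selection: AtomSelection,
    label: str | None = None,
) -> RmsdSeries:
    """RMSD over ``selection`` after fitting each frame on ``fit_selection``.

    For the core series both selections are the core backbone; for the
    entire-system series the fit stays on the core backbone while the RMSD
    runs over the entire backbone, so that knob excursions register
    instead of being averaged away by the fit.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise DimensionError(
            f"reference shape {reference.shape} does not match trajectory "
            f"({traj.n_atoms} atoms)"
        )
    fit_idx = fit_selection.indices
    sel_idx = selection.indices
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        transform, _ = kabsch_fit(traj.frames[f, fit_idx], reference[fit_idx])
        aligned = transform.apply(traj.frames[f, sel_idx])
        values[f] = rmsd_nofit(aligned, reference[sel_idx])
    return RmsdSeries(
        selection_label=label or selection.domain_name,
        times=traj.times.copy(),
        values=values,
    )


def compute_knob_offsets(
    traj: Trajectory,
    reference: np.ndarray,
    core_sel: AtomSelection,
    knob_sel: AtomSelection,
) -> OffsetSeries:
    """Two-step fit: core alignment, then knob translational/rotational offset."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise DimensionError(
            f"reference shape {reference.shape} does not match trajectory "
            f"({traj.n_atoms} atoms)"
        )
    if np.intersect1d(core_sel.indices, knob_sel.indices).size:
        raise DimensionError("core and knob selections must be disjoint")
    ref_knob = reference[knob_sel.indices]
    ref_knob_centroid = ref_knob.mean(axis=0)
    trans = np.empty(traj.n_frames)
    rot = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        core_fit, _ = kabsch_fit(
            traj.frames[f, core_sel.indices], reference[core_sel.indices]
        )
        knob_aligned = core_fit.apply(traj.frames[f, knob_sel.indices])
        trans[f] = np.linalg.norm(knob_aligned.mean(axis=0) - ref_knob_centroid)
        knob_fit, _ = kabsch_fit(knob_aligned, ref_knob)
        rot[f] = rotation_angle(knob_fit)
    return OffsetSeries(times=traj.times.copy(), translational=trans, rotational=rot)


@dataclass
class MotionSummary:
    """Time-means per run and the unweighted cross-run means.

    Keys of each inner mapping: core_rmsd_A, entire_rmsd_A,
    translational_offset_A, rotational_offset_deg. Every frame (frame 0
    included) enters the time mean; no equilibration discard. The cross-run
    mean is the arithmetic mean of the per-run means. Rounding to two
    decimals happens only at presentation.
    """

    per_run: dict[str, dict[str, float]]
    overall: dict[str, float]

    COLUMNS = (
        "core_rmsd_A",
        "entire_rmsd_A",
        "translational_offset_A",
        "rotational_offset_deg",
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"run": run, **{c: vals[c] for c in self.COLUMNS}}
            for run, vals in self.per_run.items()
        ]
        rows.append({"run": "Average", **{c: self.overall[c] for c in self.COLUMNS}})
        return pd.DataFrame(rows, columns=["run", *self.COLUMNS])


def summarize_motion(
    runs: dict[str, dict[str, object]],
) -> MotionSummary:
    """Aggregate per-run series into a stability summary.

    ``runs`` maps run label → dict with keys ``core`` and ``entire``
    (:class:`RmsdSeries`) and ``offsets`` (:class:`OffsetSeries`). All runs
    must describe the same system (equal atom counts are not checked here,
    but series lengths per run must be consistent).
    """
    if not runs:
        raise AggregationError("need at least one run")
    per_run: dict[str, dict[str, float]] = {}
    for label, series in runs.items():
        core: RmsdSeries = series["core"]
        entire: RmsdSeries = series["entire"]
        offsets: OffsetSeries = series["offsets"]
        if not (len(core) == len(entire) == len(offsets)):
            raise AggregationError(
                f"run '{label}': core/entire/offset series lengths differ"
            )
        per_run[label] = {
            "core_rmsd_A": float(np.mean(core.values)),
            "entire_rmsd_A": float(np.mean(entire.values)),
            "translational_offset_A": float(np.mean(offsets.translational)),
            "rotational_offset_deg": float(np.mean(offsets.rotational)),
        }
    overall = {
        c: float(np.mean([v[c] for v in per_run.values()]))
        for c in MotionSummary.COLUMNS
    }
    return MotionSummary(per_run=per_run, overall=overall)
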