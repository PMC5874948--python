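"""Domain model for fixed-beam IMRT plans and patient-specific QA records.

All geometry is stored in millimetres at the isocenter plane.  A plan is a
sequence of beams; a beam is a sequence of MLC control points, each carrying
the cumulative monitor-unit (MU) fraction delivered up to that point, the
per-leaf-pair positions of the two leaf banks, and the jaw rectangle.

QA outcomes are stored as detector counts: ``detectors_total`` (D_i) and
``detectors_failing`` (y_i), from which the failing rate fr_i = y_i / D_i and
the observation weight w_i = D_i / D_max follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ENERGIES",
    "MACHINE_TYPES",
    "MLC_MODELS",
    "QA_DEVICES",
    "ControlPoint",
    "Beam",
    "Plan",
    "QARecord",
    "QADataset",
    "ValidationFinding",
    "ValidationReport",
    "validate_plan",
    "PlanValidationError",
]

ENERGIES = ("6MV", "15MV")
MACHINE_TYPES = ("TrueBeam", "Trilogy", "21IX", "21EX", "6EX")
MLC_MODELS = ("HD", "M120_pre2007", "M120_post2007")
QA_DEVICES = ("MapCHECK2", "PortalDosimetry")

#: Cumulative MU fractions may deviate from exact [0, 1] endpoints by this much
#: (DICOM meterset weights are stored at finite precision).
_MU_TOL = 1e-6


class PlanValidationError(ValueError):
    """Raised when a plan violates a structural invariant."""


@dataclass(frozen=True)
class ControlPoint:
    """A single MLC/jaw state with its cumulative MU fraction."""

    index: int
    cumulative_mu_fraction: float
    leaf_positions_bank_a: np.ndarray  # mm, lower/left bank (B in Varian terms)
    leaf_positions_bank_b: np.ndarray  # mm, must be >= bank_a per pair
    jaw_x1: float
    jaw_x2: float
    jaw_y1: float
    jaw_y2: float
    collimator_angle: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "leaf_positions_bank_a",
            np.asarray(self.leaf_positions_bank_a, dtype=float))
        object.__setattr__(
            self, "leaf_positions_bank_b",
            np.asarray(self.leaf_positions_bank_b, dtype=float))

    @property
    def n_pairs(self) -> int:
        return len(self.leaf_positions_bank_a)

    @property
    def gaps(self) -> np.ndarray:
        """Per-pair leaf gap (mm); >= 0 on a valid control point."""
        return self.leaf_positions_bank_b - self.leaf_positions_bank_a


@dataclass
class Beam:
    """One fixed-gantry IMRT beam: delivery metadata plus its control points."""

    beam_id: str
    energy: str
    machine_type: str
    mlc_model: str
    leaf_boundaries: np.ndarray  # mm, length n_pairs + 1, strictly increasing
    total_mu: float
    control_points: Sequence[ControlPoint]

    def __post_init__(self):
        self.leaf_boundaries = np.asarray(self.leaf_boundaries, dtype=float)

    @property
    def n_pairs(self) -> int:
        return len(self.leaf_boundaries) - 1

    @property
    def leaf_widths(self) -> np.ndarray:
        return np.diff(self.leaf_boundaries)

    def mu_fractions(self) -> np.ndarray:
        return np.array([cp.cumulative_mu_fraction for cp in self.control_points])

    def interval_weights(self) -> np.ndarray:
        """ΔMU fraction per control-point interval (length n_cp - 1)."""
        return np.diff(self.mu_fractions())

    def control_point_weights(self) -> np.ndarray:
        """Trapezoidal ΔMU weight per control point (sums to 1).

        Each control point carries half the MU of its adjacent intervals, so
        per-control-point scalar metrics can be averaged with weights that sum
        to one regardless of the number of control points.
        """
        d = self.interval_weights()
        w = np.zeros(len(self.control_points))
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
        return w


@dataclass
class Plan:
    """A complete plan: beams plus prescription and QA-device context."""

    plan_id: str
    beams: Sequence[Beam]
    dose_per_fraction: float  # cGy
    qa_device: str
    allow_mixed_energy: bool = False

    @property
    def total_mu(self) -> float:
        return float(sum(b.total_mu for b in self.beams))


@dataclass
class QARecord:
    """One QA measurement: total and failing detector counts for a unit.

    A *unit* is whatever granularity the QA programme measured — a composite
    plan (diode arrays) or a single beam (portal dosimetry).
    """

    unit_id: str
    detectors_total: int
    detectors_failing: int

    def __post_init__(self):
        if self.detectors_total <= 0:
            raise ValueError(
                f"{self.unit_id}: detectors_total must be > 0, "
                f"got {self.detectors_total}")
        if not 0 <= self.detectors_failing <= self.detectors_total:
            raise ValueError(
                f"{self.unit_id}: detectors_failing must lie in "
                f"[0, {self.detectors_total}], got {self.detectors_failing}")

    @property
    def failing_rate(self) -> float:
        return self.detectors_failing / self.detectors_total

    @property
    def passing_rate(self) -> float:
        """Measured gamma passing rate in percent."""
        return 100.0 * (1.0 - self.failing_rate)

    def weight(self, d_max: float) -> float:
        return self.detectors_total / d_max


@dataclass
class QADataset:
    """Aligned QA records and feature vectors — the training set S.

    ``d_max`` is the weight-normalisation constant; it defaults to the largest
    ``detectors_total`` in the dataset but is kept explicit so that a model
    trained on one dataset reproduces its weights when applied elsewhere.
    """

    records: list[QARecord]
    feature_names: list[str]
    X: np.ndarray  # (n, 1 + p); column 0 is the intercept (all ones)
    d_max: float | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if len(self.records) != self.X.shape[0]:
            raise ValueError(
                f"{len(self.records)} records but {self.X.shape[0]} feature rows")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.X.shape[1]} feature columns but "
                f"{len(self.feature_names)} names")
        if self.d_max is None:
            self.d_max = float(max(r.detectors_total for r in self.records))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def failing_rates(self) -> np.ndarray:
        return np.array([r.failing_rate for r in self.records])

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.weight(self.d_max) for r in self.records])

    @property
    def detectors(self) -> np.ndarray:
        return np.array([r.detectors_total for r in self.records], dtype=float)

    def subset(self, idx) -> "QADataset":
        """Row subset sharing this dataset's d_max (weights stay comparable)."""
        idx = np.asarray(idx)
        return QADataset(
            records=[self.records[i] for i in idx],
            feature_names=list(self.feature_names),
            X=self.X[idx],
            d_max=self.d_max,
        )


@dataclass(frozen=True)
class ValidationFinding:
    location: str   # e.g. "beam B1 / control point 3 / pair 12"
    message: str

    def __str__(self) -> str:
        return f"{self.location}: {self.message}"


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, location: str, message: str) -> None:
        self.findings.append(ValidationFinding(location, message))

    def raise_if_invalid(self) -> None:
        if not self.ok:
            raise PlanValidationError(
                "; ".join(str(f) for f in self.findings[:10]))


def _validate_control_point(cp: ControlPoint, loc: str, rep: ValidationReport,
                            n_pairs: int | None) -> None:
    a, b = cp.leaf_positions_bank_a, cp.leaf_positions_bank_b
    if len(a) != len(b):
        rep.add(loc, f"bank lengths differ ({len(a)} vs {len(b)})")
        return
    if n_pairs is not None and len(a) != n_pairs:
        rep.add(loc, f"expected {n_pairs} leaf pairs, got {len(a)}")
    bad = np.nonzero(b - a < -1e-9)[0]
    for j in bad:
        # leaf pairs reported 1-based, clinical convention
        rep.add(f"{loc} / pair {j + 1}",
                f"bank_b < bank_a (gap {b[j] - a[j]:.3f} mm)")
    if cp.jaw_x2 < cp.jaw_x1:
        rep.add(loc, f"jaw_x2 < jaw_x1 ({cp.jaw_x2} < {cp.jaw_x1})")
    if cp.jaw_y2 < cp.jaw_y1:
        rep.add(loc, f"jaw_y2 < jaw_y1 ({cp.jaw_y2} < {cp.jaw_y1})")
    if not 0.0 <= cp.collimator_angle < 360.0:
        rep.add(loc, f"collimator angle {cp.collimator_angle} outside [0, 360)")


def validate_plan(plan: Plan) -> ValidationReport:
    """Check every structural invariant; return a report of violations.

    The report is empty iff the plan is well formed.  Nothing is raised —
    callers that want an exception use ``report.raise_if_invalid()``.
    """
    rep = ValidationReport()
    if not plan.beams:
        rep.add(f"plan {plan.plan_id}", "no beams")
    if plan.dose_per_fraction <= 0:
        rep.add(f"plan {plan.plan_id}",
                f"dose_per_fraction must be > 0, got {plan.dose_per_fraction}")
    if plan.qa_device not in QA_DEVICES:
        rep.add(f"plan {plan.plan_id}", f"unknown QA device {plan.qa_device!r}")
    energies = {b.energy for b in plan.beams}
    if len(energies) > 1 and not plan.allow_mixed_energy:
        rep.add(f"plan {plan.plan_id}",
                f"mixed energies {sorted(energies)} without allow_mixed_energy")
    for beam in plan.beams:
        loc = f"beam {beam.beam_id}"
        if beam.energy not in ENERGIES:
            rep.add(loc, f"unknown energy {beam.energy!r}")
        if beam.machine_type not in MACHINE_TYPES:
            rep.add(loc, f"unknown machine type {beam.machine_type!r}")
        if beam.mlc_model not in MLC_MODELS:
            rep.add(loc, f"unknown MLC model {beam.mlc_model!r}")
        if beam.total_mu <= 0:
            rep.add(loc, f"total_mu must be > 0, got {beam.total_mu}")
        if np.any(np.diff(beam.leaf_boundaries) <= 0):
            rep.add(loc, "leaf boundaries not strictly increasing")
        cps = list(beam.control_points)
        if len(cps) < 2:
            rep.add(loc, f"needs >= 2 control points, has {len(cps)}")
        mu = np.array([cp.cumulative_mu_fraction for cp in cps])
        if len(mu):
            if abs(mu[0]) > _MU_TOL:
                rep.add(loc, f"first cumulative MU fraction {mu[0]} != 0")
            if abs(mu[-1] - 1.0) > _MU_TOL:
                rep.add(loc, f"last cumulative MU fraction {mu[-1]} != 1")
            if np.any(np.diff(mu) < -_MU_TOL):
                rep.add(loc, "cumulative MU fractions decrease")
        for k, cp in enumerate(cps):
            _validate_control_point(
                cp, f"{loc} / control point {k}", rep, beam.n_pairs)
    return rep
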