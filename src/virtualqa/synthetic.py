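"""Synthetic plans, QA datasets, and dose-grid pairs with known ground truth.

Everything downstream (feature extraction, the penalized Poisson model, gamma
analysis, evaluation experiments) is testable offline against data generated
here.  Failing counts follow the model's own generative story: a unit with
feature vector x fails at rate fr = exp(beta' x); over D detectors the failing
count is Poisson(D * fr), truncated at D.

Two generation modes:

* ``abstract`` — draws feature vectors directly (one-hot groups plus uniform
  continuous metrics) for fast statistical tests and solver validation;
* ``geometric`` — generates physically valid beams (monotone MU fractions,
  non-negative leaf gaps, jaws enclosing apertures), runs the real feature
  pipeline, and derives failing rates from the assembled features, exercising
  the full chain.

Defaults emulate a per-beam portal-dosimetry QA programme: mean failing rate
3% (most QA passes around 97%), per-unit failing rates spanning roughly
1-10%, and 700-1700 evaluated pixels per unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .features import DEFAULT_CONFIG, FeatureConfig, assemble_feature_vector
from .gamma import DoseGrid
from .plans import Beam, ControlPoint, Plan, QADataset, QARecord

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_beam",
    "generate_plan",
    "generate_qa_dataset",
    "generate_dose_pair",
    "make_rtplan_dataset",
    "abstract_feature_names",
    "DEFAULT_TRUE_EFFECTS_ABSTRACT",
    "DEFAULT_TRUE_EFFECTS_GEOMETRIC",
]

# Effects on the log failing rate.  Abstract mode places one effect on a
# 5-level one-hot group (2-level groups are not identifiable under L1 up to
# intercept shifts) and the rest on continuous metrics in [0, 1].
DEFAULT_TRUE_EFFECTS_ABSTRACT = {
    "g2_b": 0.5,
    "c01": 0.6,
    "c02": -0.6,
    "c03": 0.5,
    "c04": -0.5,
    "c05": 0.6,
}

# Geometric mode: complexity drives failure, mirroring the selected-feature
# story (small gaps, low-fluence area, penumbra exposure raise failing rates).
DEFAULT_TRUE_EFFECTS_GEOMETRIC = {
    "small_aperture_lt_5mm": 0.8,
    "fluence_lt_50pct": 0.6,
    "penumbra_fraction": 0.8,
    "irregularity_outside_5cm": 0.5,
    "std_gap_mm": 0.02,        # per mm of gap spread
    "duty_cycle_mu_per_cgy": 0.1,   # per MU/cGy
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducible recipe for a synthetic QA study (same seed, same data)."""

    n_units: int = 500
    seed: int = 0
    mode: str = "abstract"               # "abstract" | "geometric"
    target_mean_fr: float = 0.03
    true_effects: dict | None = None     # None -> mode default
    d_range: tuple[int, int] = (700, 1700)
    overdispersion: float = 1.0          # 1.0 = pure Poisson
    fr_max: float = 0.8                  # config error above this

    # abstract-mode design
    n_features: int = 90                 # non-intercept columns
    onehot_group_sizes: tuple = (2, 5, 3, 7, 6)

    # geometric-mode beam geometry
    n_pairs: int = 40
    leaf_width_mm: float = 5.0
    n_control_points: int = 8
    field_size_range_mm: tuple = (60.0, 160.0)
    modulation: float = 0.5              # 0 = open fields, 1 = highly modulated
    energy: str = "6MV"
    machine_type: str = "Trilogy"
    mlc_model: str = "M120_post2007"
    qa_device: str = "PortalDosimetry"
    dose_per_fraction: float = 200.0
    feature_config: FeatureConfig = field(default=DEFAULT_CONFIG)


@dataclass
class GroundTruth:
    feature_names: list[str]
    beta: np.ndarray          # aligned to feature_names, intercept included
    fr_true: np.ndarray       # per-unit true failing rate
    mode: str


# ---------------------------------------------------------------------------
# Geometric beams and plans
# ---------------------------------------------------------------------------

def generate_beam(config: GeneratorConfig, rng=None, beam_id: str = "B1"
                  ) -> Beam:
    """One physically valid IMRT beam of controllable complexity.

    The ``modulation`` knob moves the typical leaf gap from nearly the full
    field width (0: open, simple apertures) down to a few millimetres
    (1: heavily modulated), which monotonically raises the small-aperture
    scores and low-fluence-area fractions.
    """
    if not 0.0 <= config.modulation <= 1.0:
        raise ValueError("modulation must lie in [0, 1]")
    lo, hi = config.field_size_range_mm
    if lo <= 0 or hi < lo:
        raise ValueError("infeasible field_size_range_mm")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    half_span = config.n_pairs * config.leaf_width_mm / 2.0
    boundaries = (np.arange(config.n_pairs + 1) * config.leaf_width_mm
                  - half_span)
    fx = rng.uniform(lo, hi)
    fy = min(rng.uniform(lo, hi), 2 * half_span)
    jaw_x = (-fx / 2.0, fx / 2.0)
    jaw_y = (-fy / 2.0, fy / 2.0)
    centers = 0.5 * (boundaries[:-1] + boundaries[1:])
    active = (centers >= jaw_y[0]) & (centers <= jaw_y[1])

    n_cp = max(config.n_control_points, 2)
    mu = np.concatenate([[0.0], np.sort(rng.uniform(size=n_cp - 2)), [1.0]])
    # typical gap shrinks as modulation rises
    gap_scale = (1.0 - config.modulation) * 0.8 * fx + config.modulation * 6.0
    angle = float(rng.choice([0.0, 90.0, 270.0]))

    cps = []
    for k in range(n_cp):
        a = np.full(config.n_pairs, jaw_x[0])   # parked closed at x1
        b = np.full(config.n_pairs, jaw_x[0])
        gaps = rng.lognormal(np.log(gap_scale), 0.5, size=config.n_pairs)
        gaps = np.clip(gaps, 1.0, fx)
        for i in np.nonzero(active)[0]:
            g = gaps[i]
            c = rng.uniform(jaw_x[0] + g / 2.0, jaw_x[1] - g / 2.0) \
                if g < fx else 0.0
            a[i], b[i] = c - g / 2.0, c + g / 2.0
        cps.append(ControlPoint(
            index=k, cumulative_mu_fraction=float(mu[k]),
            leaf_positions_bank_a=a, leaf_positions_bank_b=b,
            jaw_x1=jaw_x[0], jaw_x2=jaw_x[1],
            jaw_y1=jaw_y[0], jaw_y2=jaw_y[1],
            collimator_angle=angle,
        ))
    duty = 2.0 + 4.0 * config.modulation + rng.uniform(-0.5, 0.5)
    total_mu = max(duty, 0.5) * config.dose_per_fraction
    return Beam(
        beam_id=beam_id,
        energy=config.energy,
        machine_type=config.machine_type,
        mlc_model=config.mlc_model,
        leaf_boundaries=boundaries,
        total_mu=float(total_mu),
        control_points=cps,
    )


def generate_plan(config: GeneratorConfig, rng=None, plan_id: str = "plan",
                  n_beams: int = 1) -> Plan:
    rng = np.random.default_rng(config.seed) if rng is None else rng
    beams = [generate_beam(config, rng, beam_id=f"B{i + 1}")
             for i in range(n_beams)]
    for b in beams:  # beams share the fraction dose: split the duty cycle
        b.total_mu /= n_beams
    return Plan(plan_id=plan_id, beams=beams,
                dose_per_fraction=config.dose_per_fraction,
                qa_device=config.qa_device)


# ---------------------------------------------------------------------------
# QA datasets from the generative model
# ---------------------------------------------------------------------------

def abstract_feature_names(config: GeneratorConfig) -> list[str]:
    names = ["intercept"]
    for g, size in enumerate(config.onehot_group_sizes, start=1):
        names += [f"g{g}_{chr(ord('a') + j)}" for j in range(size)]
    n_cont = config.n_features - sum(config.onehot_group_sizes)
    if n_cont < 0:
        raise ValueError("one-hot groups exceed n_features")
    names += [f"c{j + 1:02d}" for j in range(n_cont)]
    return names


def _abstract_design(config: GeneratorConfig, rng) -> tuple[np.ndarray, list[str]]:
    names = abstract_feature_names(config)
    n = config.n_units
    cols = [np.ones(n)]
    for size in config.onehot_group_sizes:
        draw = rng.integers(0, size, size=n)
        block = np.zeros((n, size))
        block[np.arange(n), draw] = 1.0
        cols.append(block)
    n_cont = config.n_features - sum(config.onehot_group_sizes)
    cols.append(rng.uniform(0.0, 1.0, size=(n, n_cont)))
    return np.column_stack(cols), names


def _geometric_design(config: GeneratorConfig, rng):
    fc = config.feature_config
    names = fc.feature_names()
    rows = []
    for _ in range(config.n_units):
        # modulation varies across units so complexity metrics have spread
        m = float(np.clip(rng.uniform(0.1, 0.95), 0.0, 1.0))
        unit_cfg = replace(config, modulation=m)
        beam = generate_beam(unit_cfg, rng)
        plan = Plan(plan_id="unit", beams=[beam],
                    dose_per_fraction=config.dose_per_fraction,
                    qa_device=config.qa_device)
        rows.append(assemble_feature_vector(plan, fc).values)
    return np.asarray(rows), names


def generate_qa_dataset(config: GeneratorConfig
                        ) -> tuple[QADataset, GroundTruth]:
    """Draw a QA dataset from the generative model.

    The intercept of the true coefficient vector is calibrated so the mean
    true failing rate equals ``target_mean_fr``; a unit whose true rate would
    reach ``fr_max`` is a configuration error (effects too large).
    """
    rng = np.random.default_rng(config.seed)
    if config.mode == "abstract":
        X, names = _abstract_design(config, rng)
    elif config.mode == "geometric":
        X, names = _geometric_design(config, rng)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    effects = config.true_effects
    if effects is None:
        effects = (DEFAULT_TRUE_EFFECTS_ABSTRACT if config.mode == "abstract"
                   else DEFAULT_TRUE_EFFECTS_GEOMETRIC)
    beta = np.zeros(len(names))
    for name, val in effects.items():
        if name not in names:
            raise ValueError(f"true effect on unknown feature {name!r}")
        beta[names.index(name)] = val

    eta_rest = X[:, 1:] @ beta[1:]
    beta[0] = np.log(config.target_mean_fr) - np.log(np.mean(np.exp(eta_rest)))
    fr = np.exp(X @ beta)
    if np.any(fr >= config.fr_max):
        raise ValueError(
            f"true failing rate reaches {fr.max():.3f} >= fr_max "
            f"{config.fr_max}; reduce effect sizes or target_mean_fr")

    D = rng.integers(config.d_range[0], config.d_range[1] + 1,
                     size=config.n_units)
    lam = D * fr
    if config.overdispersion > 1.0:
        k = lam / (config.overdispersion - 1.0)
        lam = lam * rng.gamma(k, 1.0 / k)
    y = np.minimum(rng.poisson(lam), D)

    records = [QARecord(unit_id=f"unit{i:04d}",
                        detectors_total=int(D[i]),
                        detectors_failing=int(y[i]))
               for i in range(config.n_units)]
    dataset = QADataset(records=records, feature_names=names, X=X)
    return dataset, GroundTruth(feature_names=names, beta=beta,
                                fr_true=fr, mode=config.mode)


# ---------------------------------------------------------------------------
# Dose-grid pairs for gamma analysis
# ---------------------------------------------------------------------------

def generate_dose_pair(seed: int = 0, size_mm: float = 120.0,
                       spacing: float = 2.0, blur_mm: float = 5.0,
                       scale: float = 1.0,
                       shift_mm: tuple[float, float] = (0.0, 0.0),
                       noise_sigma: float = 0.0
                       ) -> tuple[DoseGrid, DoseGrid]:
    """A smooth synthetic reference field and a perturbed evaluated copy.

    The reference is a jaw-sized rectangle softened by a Gaussian penumbra.
    The evaluated grid applies, in order: a multiplicative ``scale`` error, a
    rigid ``shift_mm`` translation, and localized Gaussian noise of standard
    deviation ``noise_sigma`` (fraction of the local dose).
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    n = int(round(size_mm / spacing))
    half = size_mm / 2.0
    xs = -half + (np.arange(n) + 0.5) * spacing
    X, Y = np.meshgrid(xs, xs)
    rect = ((np.abs(X) < 0.65 * half) & (np.abs(Y) < 0.65 * half)).astype(float)
    ref = ndimage.gaussian_filter(rect, blur_mm / spacing)
    ref /= ref.max()

    ev = scale * ref
    if shift_mm != (0.0, 0.0):
        ev = ndimage.shift(ev, (shift_mm[1] / spacing, shift_mm[0] / spacing),
                           order=1, mode="nearest")
    if noise_sigma > 0:
        ev = ev * (1.0 + noise_sigma * rng.standard_normal(ev.shape))
    ev = np.clip(ev, 0.0, None)
    origin = (float(xs[0]), float(xs[0]))
    return (DoseGrid(origin=origin, spacing=spacing, values=ref),
            DoseGrid(origin=origin, spacing=spacing, values=ev))


# ---------------------------------------------------------------------------
# DICOM RT Plan fixtures
# ---------------------------------------------------------------------------

def make_rtplan_dataset(plan: Plan):
    """Build an in-memory DICOM RT Plan dataset mirroring ``plan``.

    Intended for round-trip testing of the RTPLAN reader; save with
    ``ds.save_as(path, enforce_file_format=True)``.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTPlanStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.plan_id
    ds.PatientName = "SYNTHETIC^FIXTURE"
    ds.PatientID = "SYN000"

    dr = Dataset()
    dr.TargetPrescriptionDose = plan.dose_per_fraction / 100.0  # 1 fraction
    ds.DoseReferenceSequence = [dr]

    fg = Dataset()
    fg.NumberOfFractionsPlanned = 1
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]

    ds.BeamSequence = []
    for num, beam in enumerate(plan.beams, start=1):
        rb = Dataset()
        rb.ReferencedBeamNumber = num
        rb.BeamMeterset = beam.total_mu
        fg.ReferencedBeamSequence.append(rb)

        bs = Dataset()
        bs.BeamNumber = num
        bs.BeamName = beam.beam_id
        bs.TreatmentMachineName = beam.machine_type
        bs.TreatmentDeliveryType = "TREATMENT"
        bs.FinalCumulativeMetersetWeight = 1.0

        bld = Dataset()
        bld.RTBeamLimitingDeviceType = "MLCX"
        bld.NumberOfLeafJawPairs = beam.n_pairs
        bld.LeafPositionBoundaries = [float(v) for v in beam.leaf_boundaries]
        bs.BeamLimitingDeviceSequence = [bld]

        bs.ControlPointSequence = []
        for cp in beam.control_points:
            c = Dataset()
            c.ControlPointIndex = cp.index
            c.CumulativeMetersetWeight = cp.cumulative_mu_fraction
            if cp.index == 0:
                c.NominalBeamEnergy = float(beam.energy.replace("MV", ""))
                c.BeamLimitingDeviceAngle = cp.collimator_angle
            jx = Dataset()
            jx.RTBeamLimitingDeviceType = "ASYMX"
            jx.LeafJawPositions = [cp.jaw_x1, cp.jaw_x2]
            jy = Dataset()
            jy.RTBeamLimitingDeviceType = "ASYMY"
            jy.LeafJawPositions = [cp.jaw_y1, cp.jaw_y2]
            ml = Dataset()
            ml.RTBeamLimitingDeviceType = "MLCX"
            ml.LeafJawPositions = (
                [float(v) for v in cp.leaf_positions_bank_a]
                + [float(v) for v in cp.leaf_positions_bank_b])
            c.BeamLimitingDevicePositionSequence = [jx, jy, ml]
            bs.ControlPointSequence.append(c)
        ds.BeamSequence.append(bs)
    return ds
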