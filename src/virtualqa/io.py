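"""Readers and writers: DICOM RT Plan, the portable plan text format, QA
record tables, and dose-grid text files.

The portable plan format is a line-based sectioned text file (``[plan]``,
``[beam]``, ``[control_point]`` sections of ``key = value`` lines) with the
length unit declared in the header; only millimetres are accepted — a ``cm``
header is an error rather than a silent conversion.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .plans import (
    Beam,
    ControlPoint,
    Plan,
    QARecord,
    validate_plan,
)

__all__ = [
    "read_rtplan",
    "read_plan_table",
    "write_plan_table",
    "read_qa_records",
    "qa_records_to_csv",
    "read_dose_grid",
    "write_dose_grid",
    "FormatError",
    "SchemaError",
    "UnitError",
]


class FormatError(ValueError):
    """File is not what the reader expects (wrong modality, bad section)."""


class SchemaError(FormatError):
    """A required column/key is missing."""


class UnitError(FormatError):
    """Declared unit differs from the required one."""


# ---------------------------------------------------------------------------
# DICOM RT Plan
# ---------------------------------------------------------------------------

def _infer_mlc_model(boundaries: np.ndarray) -> str:
    """Guess the Varian MLC model from leaf widths (HD has 2.5 mm central
    leaves; Millennium 120 has 5 mm).  Falls back to M120_post2007."""
    widths = np.diff(boundaries)
    central = widths[len(widths) // 2]
    if np.isclose(central, 2.5, atol=0.1):
        return "HD"
    return "M120_post2007"


def read_rtplan(path, qa_device: str = "MapCHECK2",
                mlc_model: str | None = None,
                validate: bool = True) -> Plan:
    """Read a DICOM RT Plan file into a :class:`Plan`.

    Leaf and jaw positions are taken from the MLCX / ASYMX / ASYMY (or X / Y)
    beam-limiting-device sequences; DICOM stores them in mm at isocenter
    already.  Cumulative meterset weights are normalised to [0, 1] by each
    beam's final cumulative meterset weight.

    ``qa_device`` and (optionally) ``mlc_model`` supply context DICOM does not
    carry; when ``mlc_model`` is None it is inferred from the leaf widths.
    """
    import pydicom

    ds = pydicom.dcmread(str(path), force=True)
    modality = getattr(ds, "Modality", None)
    if modality != "RTPLAN":
        raise FormatError(f"{path}: modality {modality!r}, expected RTPLAN")

    # Beam meterset lives in the fraction group, keyed by beam number.
    metersets: dict[int, float] = {}
    n_fractions = 1
    for fg in getattr(ds, "FractionGroupSequence", []):
        n_fractions = int(getattr(fg, "NumberOfFractionsPlanned", 1) or 1)
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(rb, "BeamMeterset"):
                metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    dose_per_fraction = 200.0
    for dr in getattr(ds, "DoseReferenceSequence", []):
        if hasattr(dr, "TargetPrescriptionDose"):
            # Gy total -> cGy per fraction
            dose_per_fraction = (
                float(dr.TargetPrescriptionDose) * 100.0 / n_fractions)
            break

    beams = []
    for bs in getattr(ds, "BeamSequence", []):
        if getattr(bs, "TreatmentDeliveryType", "TREATMENT") != "TREATMENT":
            continue
        beam_id = str(getattr(bs, "BeamName", None) or bs.BeamNumber)
        boundaries = None
        for bld in getattr(bs, "BeamLimitingDeviceSequence", []):
            if bld.RTBeamLimitingDeviceType.startswith("MLC"):
                boundaries = np.asarray(bld.LeafPositionBoundaries, dtype=float)
        if boundaries is None:
            raise FormatError(
                f"beam {beam_id}: no MLC beam-limiting device sequence "
                "(unsupported plan)")
        n_pairs = len(boundaries) - 1

        cps = []
        final_w = float(getattr(bs, "FinalCumulativeMetersetWeight", 1.0) or 1.0)
        jaws = {"x": (-200.0, 200.0), "y": (-200.0, 200.0)}
        energy = None
        coll = 0.0
        for k, cp in enumerate(bs.ControlPointSequence):
            if hasattr(cp, "NominalBeamEnergy"):
                energy = f"{int(cp.NominalBeamEnergy)}MV"
            if hasattr(cp, "BeamLimitingDeviceAngle"):
                coll = float(cp.BeamLimitingDeviceAngle)
            mlc = None
            for pos in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                t = pos.RTBeamLimitingDeviceType
                vals = np.asarray(pos.LeafJawPositions, dtype=float)
                if t.startswith("MLC"):
                    mlc = vals
                elif t in ("ASYMX", "X"):
                    jaws["x"] = (float(vals[0]), float(vals[1]))
                elif t in ("ASYMY", "Y"):
                    jaws["y"] = (float(vals[0]), float(vals[1]))
            if mlc is None:
                if not cps:
                    raise FormatError(
                        f"beam {beam_id}: control point 0 has no MLC positions")
                mlc = np.concatenate([cps[-1].leaf_positions_bank_a,
                                      cps[-1].leaf_positions_bank_b])
            if len(mlc) != 2 * n_pairs:
                raise FormatError(
                    f"beam {beam_id}: control point {k} has {len(mlc)} leaf "
                    f"positions, expected {2 * n_pairs}")
            cps.append(ControlPoint(
                index=k,
                cumulative_mu_fraction=(
                    float(cp.CumulativeMetersetWeight) / final_w),
                leaf_positions_bank_a=mlc[:n_pairs],
                leaf_positions_bank_b=mlc[n_pairs:],
                jaw_x1=jaws["x"][0], jaw_x2=jaws["x"][1],
                jaw_y1=jaws["y"][0], jaw_y2=jaws["y"][1],
                collimator_angle=coll % 360.0,
            ))
        machine = str(getattr(bs, "TreatmentMachineName", "TrueBeam"))
        beams.append(Beam(
            beam_id=beam_id,
            energy=energy or "6MV",
            machine_type=machine,
            mlc_model=mlc_model or _infer_mlc_model(boundaries),
            leaf_boundaries=boundaries,
            total_mu=metersets.get(int(bs.BeamNumber), 100.0),
            control_points=cps,
        ))

    plan = Plan(
        plan_id=str(getattr(ds, "RTPlanLabel", None)
                    or getattr(ds, "SOPInstanceUID", "plan")),
        beams=beams,
        dose_per_fraction=dose_per_fraction,
        qa_device=qa_device,
    )
    if validate:
        validate_plan(plan).raise_if_invalid()
    return plan


# ---------------------------------------------------------------------------
# Portable plan text format
# ---------------------------------------------------------------------------

_FMT_HEADER = "# virtualqa plan format v1"


def _fmt(x: float) -> str:
    # shortest representation that round-trips the float exactly
    return repr(float(x))


def write_plan_table(plan: Plan, path) -> None:
    """Write a plan in the portable sectioned text format (mm everywhere)."""
    lines = [_FMT_HEADER, "[plan]",
             f"plan_id = {plan.plan_id}",
             f"dose_per_fraction_cGy = {_fmt(plan.dose_per_fraction)}",
             f"qa_device = {plan.qa_device}",
             "units = mm"]
    for beam in plan.beams:
        lines += ["[beam]",
                  f"beam_id = {beam.beam_id}",
                  f"energy = {beam.energy}",
                  f"machine_type = {beam.machine_type}",
                  f"mlc_model = {beam.mlc_model}",
                  f"total_mu = {_fmt(beam.total_mu)}",
                  "leaf_boundaries = " + ",".join(
                      _fmt(v) for v in beam.leaf_boundaries)]
        for cp in beam.control_points:
            lines += ["[control_point]",
                      f"index = {cp.index}",
                      f"cumulative_mu_fraction = {_fmt(cp.cumulative_mu_fraction)}",
                      f"collimator_angle = {_fmt(cp.collimator_angle)}",
                      f"jaw_x1 = {_fmt(cp.jaw_x1)}",
                      f"jaw_x2 = {_fmt(cp.jaw_x2)}",
                      f"jaw_y1 = {_fmt(cp.jaw_y1)}",
                      f"jaw_y2 = {_fmt(cp.jaw_y2)}",
                      "bank_a = " + ",".join(_fmt(v)
                                             for v in cp.leaf_positions_bank_a),
                      "bank_b = " + ",".join(_fmt(v)
                                             for v in cp.leaf_positions_bank_b)]
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_sections(text: str):
    sections = []
    current = None
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = (line[1:-1], {})
            sections.append(current)
            continue
        if "=" not in line:
            raise FormatError(f"line {ln}: expected 'key = value', got {raw!r}")
        if current is None:
            raise FormatError(f"line {ln}: key/value outside any section")
        key, _, value = line.partition("=")
        current[1][key.strip()] = value.strip()
    return sections


def _require(d: dict, key: str, section: str) -> str:
    if key not in d:
        raise SchemaError(f"[{section}] section missing required key {key!r}")
    return d[key]


def _floats(s: str) -> np.ndarray:
    return np.array([float(v) for v in s.split(",") if v.strip() != ""])


def read_plan_table(path, validate: bool = True) -> Plan:
    """Read the portable plan text format written by :func:`write_plan_table`."""
    text = Path(path).read_text()
    sections = _parse_sections(text)
    if not sections or sections[0][0] != "plan":
        raise FormatError(f"{path}: first section must be [plan]")
    head = sections[0][1]
    units = _require(head, "units", "plan").lower()
    if units != "mm":
        raise UnitError(
            f"{path}: declared units {units!r}; only 'mm' is supported "
            "(no silent conversion)")
    beams: list[Beam] = []
    pending_cps: list[ControlPoint] = []
    beam_meta: dict | None = None

    def flush_beam():
        if beam_meta is None:
            return
        beams.append(Beam(
            beam_id=_require(beam_meta, "beam_id", "beam"),
            energy=_require(beam_meta, "energy", "beam"),
            machine_type=_require(beam_meta, "machine_type", "beam"),
            mlc_model=_require(beam_meta, "mlc_model", "beam"),
            leaf_boundaries=_floats(_require(beam_meta, "leaf_boundaries", "beam")),
            total_mu=float(_require(beam_meta, "total_mu", "beam")),
            control_points=list(pending_cps),
        ))

    for name, kv in sections[1:]:
        if name == "beam":
            flush_beam()
            beam_meta, pending_cps = kv, []
        elif name == "control_point":
            for req in ("cumulative_mu_fraction", "jaw_x1", "jaw_x2",
                        "jaw_y1", "jaw_y2", "bank_a", "bank_b"):
                _require(kv, req, "control_point")
            pending_cps.append(ControlPoint(
                index=int(kv.get("index", len(pending_cps))),
                cumulative_mu_fraction=float(kv["cumulative_mu_fraction"]),
                leaf_positions_bank_a=_floats(kv["bank_a"]),
                leaf_positions_bank_b=_floats(kv["bank_b"]),
                jaw_x1=float(kv["jaw_x1"]), jaw_x2=float(kv["jaw_x2"]),
                jaw_y1=float(kv["jaw_y1"]), jaw_y2=float(kv["jaw_y2"]),
                collimator_angle=float(kv.get("collimator_angle", 0.0)),
            ))
        else:
            raise FormatError(f"unknown section [{name}]")
    flush_beam()

    plan = Plan(
        plan_id=_require(head, "plan_id", "plan"),
        beams=beams,
        dose_per_fraction=float(_require(head, "dose_per_fraction_cGy", "plan")),
        qa_device=_require(head, "qa_device", "plan"),
    )
    if validate:
        validate_plan(plan).raise_if_invalid()
    return plan


# ---------------------------------------------------------------------------
# QA records
# ---------------------------------------------------------------------------

def read_qa_records(path) -> list[QARecord]:
    """Read QA records from CSV with columns
    ``unit_id, detectors_total, detectors_failing``.

    Range violations (y_i > D_i, D_i <= 0) raise ValueError via QARecord.
    """
    df = pd.read_csv(path)
    required = {"unit_id", "detectors_total", "detectors_failing"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        QARecord(unit_id=str(r.unit_id),
                 detectors_total=int(r.detectors_total),
                 detectors_failing=int(r.detectors_failing))
        for r in df.itertuples(index=False)
    ]


def qa_records_to_csv(records: list[QARecord], path) -> None:
    pd.DataFrame(
        {"unit_id": [r.unit_id for r in records],
         "detectors_total": [r.detectors_total for r in records],
         "detectors_failing": [r.detectors_failing for r in records]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dose grids (plain text)
# ---------------------------------------------------------------------------

def write_dose_grid(grid, path) -> None:
    """Write a DoseGrid as a commented-header text array."""
    buf = _io.StringIO()
    buf.write("# virtualqa dosegrid v1\n")
    buf.write(f"# origin_mm: {_fmt(grid.origin[0])} {_fmt(grid.origin[1])}\n")
    buf.write(f"# spacing_mm: {_fmt(grid.spacing)}\n")
    np.savetxt(buf, grid.values, fmt="%.8g")
    Path(path).write_text(buf.getvalue())


def read_dose_grid(path):
    from .gamma import DoseGrid

    origin = None
    spacing = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "origin_mm:" in line:
                parts = line.split("origin_mm:")[1].split()
                origin = (float(parts[0]), float(parts[1]))
            elif "spacing_mm:" in line:
                spacing = float(line.split("spacing_mm:")[1])
    if origin is None or spacing is None:
        raise SchemaError(f"{path}: missing origin_mm/spacing_mm header")
    values = np.loadtxt(path)
    return DoseGrid(origin=origin, spacing=spacing, values=np.atleast_2d(values))


# ---------------------------------------------------------------------------
# Feature tables and dataset assembly
# ---------------------------------------------------------------------------

def write_feature_table(df, path, config_hash: str, extra_comments=()) -> None:
    """Feature CSV with the encoding-config hash embedded as a comment header,
    so a model can refuse tables built under a different encoding."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        for c in extra_comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, index=False)


def read_feature_table(path):
    """Returns (DataFrame, config_hash or None)."""
    config_hash = None
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if "config_hash:" in line:
                config_hash = line.split("config_hash:")[1].strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if "unit_id" not in df.columns:
        raise SchemaError(f"{path}: missing unit_id column")
    return df, config_hash


def build_dataset(features_df, records: list[QARecord], d_max=None):
    """Join a feature table with QA records on unit_id into a QADataset.

    Raises on units present on only one side, listing the mismatches.
    """
    from .plans import QADataset

    by_id = {r.unit_id: r for r in records}
    feat_ids = list(features_df["unit_id"].astype(str))
    missing_qa = [u for u in feat_ids if u not in by_id]
    missing_feat = [u for u in by_id if u not in set(feat_ids)]
    if missing_qa or missing_feat:
        raise ValueError(
            f"unit_id mismatch: {len(missing_qa)} without QA records "
            f"(e.g. {missing_qa[:3]}), {len(missing_feat)} without features "
            f"(e.g. {missing_feat[:3]})")
    names = [c for c in features_df.columns if c != "unit_id"]
    X = features_df[names].to_numpy(dtype=float)
    return QADataset(records=[by_id[u] for u in feat_ids],
                     feature_names=names, X=X, d_max=d_max)
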