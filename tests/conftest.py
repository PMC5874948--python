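import numpy as np
import pytest

from virtualqa.plans import Beam, ControlPoint, Plan
from virtualqa.synthetic import GeneratorConfig, generate_qa_dataset


def square_control_point(half_mm: float, index: int = 0, mu: float = 0.0,
                         n_pairs: int = 20, leaf_width: float = 5.0,
                         jaw_half: float | None = None) -> ControlPoint:
    """A control point whose aperture is a centered square of side 2*half_mm."""
    jaw_half = half_mm if jaw_half is None else jaw_half
    boundaries = np.arange(n_pairs + 1) * leaf_width - n_pairs * leaf_width / 2
    centers = 0.5 * (boundaries[:-1] + boundaries[1:])
    a = np.where(np.abs(centers) < half_mm, -half_mm, 0.0)
    b = np.where(np.abs(centers) < half_mm, half_mm, 0.0)
    return ControlPoint(
        index=index, cumulative_mu_fraction=mu,
        leaf_positions_bank_a=a, leaf_positions_bank_b=b,
        jaw_x1=-jaw_half, jaw_x2=jaw_half,
        jaw_y1=-jaw_half, jaw_y2=jaw_half,
    )


def static_square_beam(half_mm: float = 20.0, total_mu: float = 300.0,
                       n_pairs: int = 20, leaf_width: float = 5.0) -> Beam:
    boundaries = np.arange(n_pairs + 1) * leaf_width - n_pairs * leaf_width / 2
    cps = [square_control_point(half_mm, 0, 0.0, n_pairs, leaf_width),
           square_control_point(half_mm, 1, 1.0, n_pairs, leaf_width)]
    return Beam(beam_id="B1", energy="6MV", machine_type="Trilogy",
                mlc_model="M120_post2007", leaf_boundaries=boundaries,
                total_mu=total_mu, control_points=cps)


def wrap_plan(*beams, dose=200.0, qa_device="PortalDosimetry",
              plan_id="p") -> Plan:
    return Plan(plan_id=plan_id, beams=list(beams), dose_per_fraction=dose,
                qa_device=qa_device)


@pytest.fixture(scope="session")
def small_abstract_dataset():
    """200 units, 10 continuous features, 2 true effects."""
    cfg = GeneratorConfig(n_units=200, seed=3, n_features=10,
                          onehot_group_sizes=(),
                          true_effects={"c01": 0.5, "c02": -0.5})
    return generate_qa_dataset(cfg)


@pytest.fixture(scope="session")
def signal_dataset():
    """Default abstract study conditions at moderate n for solver tests."""
    return generate_qa_dataset(GeneratorConfig(n_units=400, seed=7))
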