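import numpy as np
import pytest

from atlastcp import (
    HistopathReport,
    Lesion,
    PhantomSpec,
    RadiosensitivityParams,
    SegmentFinding,
    TreatmentSchedule,
    VoxelGrid,
    make_phantom,
    segment_prostate,
)


@pytest.fixture(scope="session")
def ref_params() -> RadiosensitivityParams:
    """Packaged reference radiosensitivity parameter set."""
    return RadiosensitivityParams.reference()


@pytest.fixture(scope="session")
def schedule_60_20() -> TreatmentSchedule:
    return TreatmentSchedule.weekday(20, 60.0)


@pytest.fixture(scope="session")
def small_grid() -> VoxelGrid:
    return VoxelGrid((5, 5, 5), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def phantom():
    """Default demo phantom with one large relapsed lesion."""
    spec = PhantomSpec(
        lesions=(
            Lesion((48.0, 48.0, 30.0), 10.0, "4+3", 3.0, relapse=True),
            Lesion((30.0, 48.0, 24.0), 5.0, "3+4", 2.0, relapse=False),
        ),
        seed=3,
    )
    return spec, make_phantom(spec)


@pytest.fixture(scope="session")
def labelmap6(phantom):
    _, ph = phantom
    return segment_prostate(ph.mask, 6)


@pytest.fixture(scope="session")
def extensive_report() -> HistopathReport:
    """Multifocal high-grade report typical of a recurrence cohort: most
    segments carry substantial adenocarcinoma involvement."""
    F = SegmentFinding
    return HistopathReport(
        "case-hr",
        (
            F("left base", 4, 4, 60.0),
            F("left mid", 4, 3, 50.0),
            F("left apex", 3, 4, 30.0),
            F("right base", 4, 3, 45.0),
            F("right mid", 3, 4, 40.0),
            F("right apex", None, None, 0.0),
        ),
    )


def single_voxel_model(
    clonogens: float,
    dose_per_fraction: float,
    ab: float,
    fixed_alpha=None,
):
    """1-voxel ProstateModel helper used across test modules."""
    from atlastcp import ProstateModel

    grid = VoxelGrid((1, 1, 1), (1.0, 1.0, 1.0))
    mask = np.ones((1, 1, 1), dtype=bool)
    return ProstateModel.homogeneous(
        grid, mask, clonogens, dose_per_fraction, ab, fixed_alpha
    )
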