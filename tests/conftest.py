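import hypothesis
import pytest

from microdrive.gears import DriveConfig, GearStage, GearTrain, ScrewSpec
from microdrive.ledger import DepthLedger, ImplantGeometry

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=100
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def kit_screw() -> ScrewSpec:
    return ScrewSpec(pitch_mm=0.3)


@pytest.fixture
def kit_drive(kit_screw) -> DriveConfig:
    stage = GearStage(sun_teeth=8, ring_teeth=32, planet_teeth=12)
    return DriveConfig(screw=kit_screw, train=GearTrain(stages=(stage, stage)))


@pytest.fixture
def fresh_ledger(kit_drive) -> DepthLedger:
    return DepthLedger(
        dv0_mm=-1.5,
        geometry=ImplantGeometry(skull_thickness_mm=0.7, base_wall_mm=0.5),
        drive=kit_drive,
    )
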