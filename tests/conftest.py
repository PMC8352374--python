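import numpy as np
import pytest

from hifuplan.phantom import (
    AirDefectSpec,
    BodySpec,
    BoneRingSpec,
    EllipsoidSpec,
    GelPadSpec,
    PhantomSpec,
    generate_phantom,
)


def small_spec(**overrides) -> PhantomSpec:
    """Desk-scale phantom (96 x 96 x 64 @ 2 mm) with full couch hardware."""
    defaults = dict(
        shape=(96, 96, 64),
        spacing=(2.0, 2.0, 2.0),
        ap_min=-96.0,
        body=BodySpec(half_lr=80.0, half_ap=85.0),
        gelpad=GelPadSpec(half_width_lr=80.0),
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size tilted treatment phantom with a coupling air defect."""
    spec = PhantomSpec(
        tilt_deg=22.0,
        seed=3,
        air_defects=(AirDefectSpec(center_lr=-20.0, radius=25.0, depth=3.0),),
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Full-size tilted treatment phantom with perfect coupling."""
    return generate_phantom(PhantomSpec(tilt_deg=22.0, seed=3))


@pytest.fixture(scope="session")
def mini_phantom():
    """Tiny 48^3 phantom, unobstructed ball target at the isocentre."""
    return generate_phantom(PhantomSpec.mini(seed=1))


@pytest.fixture(scope="session")
def blocked_mini_phantom():
    """48^3 phantom with a partial bone slab under the left of the target."""
    spec = PhantomSpec.mini(
        seed=2,
        bone_boxes=(((-40.0, -4.0), (-34.0, -26.0), (-40.0, 40.0)),),
    )
    return generate_phantom(spec)
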