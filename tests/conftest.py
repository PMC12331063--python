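import numpy as np
import pytest

from dualskel import (
    BODY13,
    ExerciseSpec,
    RigSpec,
    SkeletonSequence,
    StreamMetadata,
    generate_motion,
)


@pytest.fixture(scope="session")
def flexion_truth():
    """Exact arm-flexion world trajectory (300 frames, 13 joints)."""
    return generate_motion(ExerciseSpec(kind="arm_flexion"), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, n_frames=20, catalog=BODY13, present_prob=1.0, view="front"):
    """Random valid sequence helper shared across test modules."""
    J = len(catalog)
    pos = rng.normal(0.0, 1.0, (n_frames, J, 3))
    present = rng.random((n_frames, J)) < present_prob
    # keep at least one joint present per frame so frames are not degenerate
    present[:, 0] = True
    return SkeletonSequence(view, 30.0, catalog, pos, present,
                            metadata=StreamMetadata(source="test"))


@pytest.fixture()
def make_random_sequence(rng):
    def _make(**kw):
        return random_sequence(rng, **kw)

    return _make
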