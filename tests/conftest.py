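import numpy as np
import pytest

from motionseq.synthetic import GeneratorConfig, generate_cohort

MINIMAL_BVH = """HIERARCHY
ROOT Hips
{
  OFFSET 0.0 0.0 0.0
  CHANNELS 6 Xposition Yposition Zposition Zrotation Yrotation Xrotation
  JOINT Spine
  {
    OFFSET 0.0 10.0 0.0
    CHANNELS 3 Zrotation Yrotation Xrotation
    End Site
    {
      OFFSET 0.0 5.0 0.0
    }
  }
}
MOTION
Frames: 3
Frame Time: 0.033333
0.0 90.0 0.0 10.0 20.0 30.0 5.0 -5.0 15.0
1.0 91.0 0.5 11.0 21.0 31.0 6.0 -6.0 16.0
2.0 92.0 1.0 12.0 22.0 32.0 7.0 -7.0 17.0
"""


@pytest.fixture
def minimal_bvh(tmp_path):
    path = tmp_path / "minimal.bvh"
    path.write_text(MINIMAL_BVH)
    return path


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast cohort: 6 students/class at 15 Hz."""
    return GeneratorConfig(seed=7, frame_rate=15.0, n_students=6)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def study_cohort():
    """Cohort at the study's sample sizes (95 students + 3 teacher reps
    per class = 98 x 8 motions); 30 Hz keeps the run desk-scale."""
    return generate_cohort(GeneratorConfig(seed=1, frame_rate=30.0, n_students=95))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
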