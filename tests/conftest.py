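import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_eyetrack_csv(tmp_path):
    """4-row TSV with one blank pupil cell."""
    path = tmp_path / "eyes.tsv"
    path.write_text(
        "time\tpupil_left\tpupil_right\tgaze_x\tgaze_y\n"
        "0.000\t3.1\t3.2\t960\t540\n"
        "0.010\t\t3.2\t961\t541\n"
        "0.020\t3.0\t3.1\t962\t542\n"
        "0.030\t3.1\t3.0\t963\t543\n"
    )
    return path


def make_png_dir(tmp_path, n=10, size=(32, 32), name="frames"):
    import imageio.v3 as iio

    d = tmp_path / name
    d.mkdir()
    rng = np.random.default_rng(0)
    for i in range(n):
        img = rng.integers(0, 256, (*size, 3), dtype=np.uint8)
        iio.imwrite(d / f"frame_{i:04d}.png", img)
    return d
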