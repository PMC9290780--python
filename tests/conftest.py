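import numpy as np
import pytest

from srasnet import iam, synthetic


@pytest.fixture(scope="session")
def templates():
    return synthetic.default_templates()


@pytest.fixture(scope="session")
def small_templates():
    """Quarter-scale templates so rendered crops stay a few dozen px."""
    return synthetic.default_templates(0.3)


@pytest.fixture(scope="session")
def sample_images(small_templates):
    """One rendered crop per class, fixed seeds."""
    return {cid: synthetic.generate_chromosome_image(t, 100 + cid)
            for cid, t in small_templates.items()}


@pytest.fixture(scope="session")
def toy_arrays(small_templates):
    """Separable 3-class toy: long / medium / short chromosome classes,
    standardised to a 32 px canvas."""
    cfg = iam.IamConfig(canvas_size=32)

    def build(n_per, seed0):
        xs, ys = [], []
        for ci, cls in enumerate([1, 12, 21]):
            for k in range(n_per):
                img = synthetic.generate_chromosome_image(
                    small_templates[cls], seed0 + cls * 1000 + k)
                xs.append(iam.iam_process(img, cfg))
                ys.append(ci)
        return np.stack(xs), np.array(ys)

    return build(20, 0) + build(8, 77_777)


@pytest.fixture(scope="session")
def sr_pairs(small_templates):
    """50 train + 20 held-out (LR, HR) patch pairs at scale 2."""
    rng = np.random.default_rng(0)

    def make(n, seed0):
        pairs, i = [], seed0
        while len(pairs) < n:
            hr = synthetic.generate_chromosome_image(
                small_templates[int(rng.integers(1, 23))], i)
            i += 1
            if hr.shape[0] < 40 or hr.shape[1] < 20:
                continue
            lr = synthetic.degrade_to_lr(hr, 2, rng_seed=i)
            pairs.append((lr[:20, :10], hr[:40, :20]))
        return pairs

    return make(50, 1_000), make(20, 9_000)
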