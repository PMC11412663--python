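import numpy as np
import pytest

from ifquant.segmentation import LabelMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disk_mask(shape, disks):
    """Paint labeled disks: disks = [(cy, cx, r), ...] labeled 1..N in order.

    Later disks overwrite earlier ones where they overlap.
    """
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    labels = np.zeros(shape, dtype=np.int32)
    for i, (cy, cx, r) in enumerate(disks, start=1):
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = i
    return labels


def random_disk_masks(rng, shape=(64, 64), max_objects=6, r_range=(3, 8)):
    """A (reference, predicted) LabelMask pair of random disks."""
    out = []
    for _ in range(2):
        n = int(rng.integers(1, max_objects + 1))
        disks = [
            (int(rng.integers(0, shape[0])), int(rng.integers(0, shape[1])),
             int(rng.integers(*r_range)))
            for _ in range(n)
        ]
        out.append(LabelMask.from_arbitrary(disk_mask(shape, disks)))
    return out[0], out[1]
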