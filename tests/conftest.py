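import numpy as np
import pytest

from axopipe import Channel, SamplingInfo, TraceMatrix

FS = 15.49


@pytest.fixture(scope="session")
def sampling_1k():
    return SamplingInfo(FS, n_frames=1000, n_rois=1)


def make_traces(values, frame_rate_hz=FS, channel=Channel.ACTIVITY, roi_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_rois, n_frames = values.shape
    return TraceMatrix(
        values=values,
        channel=channel,
        roi_ids=roi_ids or [str(i) for i in range(n_rois)],
        sampling=SamplingInfo(frame_rate_hz, n_frames, n_rois),
    )
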