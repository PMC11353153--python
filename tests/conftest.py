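import numpy as np
import pytest

import fluopipe as fp


@pytest.fixture(scope="session")
def small_movie():
    """A compact two-channel frame-scan session with ground truth.

    6 cells, 96x96 px, 10 s at 34 Hz, two of them coupled to a 3 Hz
    network source. Session-scoped and treated as read-only by tests.
    """
    return fp.make_movie(n_cells=6, shape=(96, 96), duration_s=10.0, fs=34.0,
                         coupled=(0, 1), network_freq=3.0, seed=11)


def build_state(session, truth, with_ephys=True):
    """Run the full pipeline on a synthetic session, returning SessionState."""
    ref_g = fp.make_reference(session, method="average", channel="green")
    ref_r = fp.make_reference(session, method="average", channel="red")
    rs = fp.extract_rois(fp.threshold_reference(ref_g), min_area=30)
    fp.classify_cells(session, rs, ref_g, ref_r, fp.ClassificationParams(min_area=50))
    ts = fp.compute_F(session, rs)
    ts = fp.compute_dff(ts, session, rs, background="auto")
    ts = fp.compute_dgr(ts, session)
    ephys = None
    if with_ephys:
        raw = fp.make_ephys(truth, fs_native=1250.0)
        ephys = fp.load_ephys(raw, session, marker="imaging")
    return fp.SessionState(session=session, rois=rs, traces=ts, ephys=ephys)


@pytest.fixture(scope="session")
def analyzed_state(small_movie):
    session, truth = small_movie
    return build_state(session, truth)


@pytest.fixture()
def flat_session():
    """A constant-intensity 2-channel session (value 7)."""
    stack = np.full((4, 16, 16, 2), 7.0)
    return fp.ImagingSession(stack=stack, sampling_interval=0.5)


def disk_mask(shape, centre, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius ** 2
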