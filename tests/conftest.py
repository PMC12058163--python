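import pytest

from cardioqt.ecg import delineate_record, detect_r_peaks, highpass_baseline
from cardioqt.simulate import ECGSpec, gen_ecg


@pytest.fixture(scope="session")
def mouse_ecg():
    """A default mouse ECG with ground truth, filtered and delineated once."""
    spec = ECGSpec()
    record, truth = gen_ecg(spec)
    filtered = highpass_baseline(record, 0.5)
    peaks = detect_r_peaks(filtered)
    beats = delineate_record(filtered, peaks)
    return spec, record, truth, filtered, beats
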