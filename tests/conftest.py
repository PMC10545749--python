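import pytest

from dentition.candidate_model import Box, ImageFrame, ToothCandidate


@pytest.fixture
def frame640() -> ImageFrame:
    return ImageFrame(640, 640)


def make_candidate(tooth_number: int, cx: float, cy: float = 300.0,
                   w: float = 20.0, h: float = 44.0, mu: float = 0.9,
                   **kwargs) -> ToothCandidate:
    return ToothCandidate(Box(cx, cy, w, h), tooth_number, mu, **kwargs)
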