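import math

import numpy as np
import pytest

from plaqrupt.annotation import ArcSpan, FrameAnnotation, Pullback, ThresholdConfig


@pytest.fixture
def thresholds():
    return ThresholdConfig()


def make_frame(i, z=None, area=3.0, **kwargs):
    return FrameAnnotation(
        frame_index=i, z_mm=(0.4 * i if z is None else z), lumen_area_mm2=area, **kwargs
    )


def make_pullback(areas, group="PR-NV", spacing=0.4, frame_kwargs=None):
    """Pullback with given per-frame lumen areas; frame_kwargs maps index->dict."""
    frame_kwargs = frame_kwargs or {}
    frames = [
        make_frame(i, z=spacing * i, area=a, **frame_kwargs.get(i, {}))
        for i, a in enumerate(areas)
    ]
    return Pullback(frames=frames, frame_spacing_mm=spacing, group=group)


@pytest.fixture
def burden_pullback():
    """10 frames with plaque burdens [30,35,45,50,45,35,30,20,10,5] %, no lipid."""
    burdens = [30, 35, 45, 50, 45, 35, 30, 20, 10, 5]
    frames = [
        make_frame(i, area=3.0, eem_area_mm2=3.0 / (1 - b / 100.0))
        for i, b in enumerate(burdens)
    ]
    return Pullback(frames=frames)


@pytest.fixture
def lipid_frame():
    return make_frame(
        0,
        area=3.0,
        arcs=[ArcSpan(10.0, 130.0, "lipid")],
        cap_thickness_um=[100.0, 200.0, 300.0],
    )
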