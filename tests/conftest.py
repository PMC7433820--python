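"""Shared fixtures: small simulated frames, phantoms and extracted ROIs.

Everything is generated programmatically at test time with fixed seeds; the
geometry is scaled down from clinical frames (16 mm x 12.8 mm media, 50%
window overlap instead of 92%) to keep the suite fast while leaving the
physics untouched.
"""

from __future__ import annotations

import numpy as np
import pytest

from qusrad.rf_core import ROIContour, rasterize_contour
from qusrad.spectral_qus import WindowSpec, extract_roi_features
from qusrad.synthetic_rf import (
    PulseModel,
    make_medium,
    simulate_reference_phantom,
    simulate_rf_frame,
)

EXTENT_AX_MM = 16.0
EXTENT_LAT_MM = 12.8
AXIAL_ORIGIN_M = 0.010
LATERAL_PITCH_M = 2e-4
NOISE_DB = 40.0
PHANTOM_ATT = 0.5
TEST_WINDOW = WindowSpec(2.0, 2.0, 0.5)  # scaled-down overlap for speed


@pytest.fixture(scope="session")
def pulse_model():
    return PulseModel()


@pytest.fixture(scope="session")
def phantoms(pulse_model):
    """Two reference-phantom realizations matching the test frame geometry."""
    return [
        simulate_reference_phantom(
            pulse_model,
            EXTENT_AX_MM - 1.5,
            EXTENT_LAT_MM,
            attenuation=PHANTOM_ATT,
            seed=s,
            lateral_pitch=LATERAL_PITCH_M,
            n_lines=int(EXTENT_LAT_MM / (LATERAL_PITCH_M * 1e3)),
            axial_origin=AXIAL_ORIGIN_M,
            noise_db=NOISE_DB,
        )
        for s in (911, 912)
    ]


def rect_contour(frame_id="frame0"):
    """Rectangular tumor ROI well inside the simulated frame."""
    a0 = AXIAL_ORIGIN_M * 1e3 + 1.6
    a1 = AXIAL_ORIGIN_M * 1e3 + EXTENT_AX_MM - 1.6
    return ROIContour(
        np.array([[a0, 1.6], [a0, EXTENT_LAT_MM - 1.6],
                  [a1, EXTENT_LAT_MM - 1.6], [a1, 1.6]]),
        frame_id=frame_id,
    )


def simulate_test_frame(medium, pm, seed, frame_id="frame0"):
    return simulate_rf_frame(
        medium,
        pm,
        lateral_pitch=LATERAL_PITCH_M,
        noise_db=NOISE_DB,
        seed=seed,
        axial_origin=AXIAL_ORIGIN_M,
        frame_id=frame_id,
    )


def make_test_medium(seed=0, **kwargs):
    kwargs.setdefault("diameter_um", 80.0)
    kwargs.setdefault("attenuation", 0.7)
    return make_medium(EXTENT_AX_MM, EXTENT_LAT_MM, seed=seed, **kwargs)


def extract_test_roi(medium, pm, phantoms, seed, window_spec=TEST_WINDOW):
    frame = simulate_test_frame(medium, pm, seed)
    mask = rasterize_contour(rect_contour(), frame)
    return extract_roi_features(frame, mask, phantoms, window_spec=window_spec)


@pytest.fixture(scope="session")
def diffuse_roi(pulse_model, phantoms):
    """Extracted spectral features for one homogeneous diffuse medium."""
    med = make_test_medium(seed=42, diameter_um=100.0, concentration=2.0)
    return extract_test_roi(med, pulse_model, phantoms, seed=43)


@pytest.fixture(scope="session")
def lattice_roi(pulse_model, phantoms):
    """Extracted features for a 1 mm regularly spaced scatterer lattice."""
    med = make_test_medium(seed=7, diameter_um=60.0, spacing_mode=1.0)
    return extract_test_roi(med, pulse_model, phantoms, seed=8)
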