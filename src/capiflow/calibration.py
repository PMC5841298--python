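"""Shared Doppler-frequency ↔ RBC-velocity calibration.

The mean Doppler frequency (MF) estimated from the eigen-filtered M-scan
signal is linearly proportional to the mean red-blood-cell speed in a
single-file capillary passage.  The proportionality constant is a system
calibration (phantom-derived on real hardware); here a single constant is
shared by the simulator and the estimator so the mapping round-trips
exactly in recovery experiments.

With the default 20 kHz A-line rate (50 µs repeat interval) the Nyquist
frequency is 10 kHz; the default slope of 1e-3 (mm/s)/Hz therefore maps
the Nyquist limit to 10 mm/s, leaving physiological capillary speeds
(~0.3–3 mm/s) far from aliasing.
"""

#: Velocity per unit Doppler frequency, (mm/s)/Hz.
DEFAULT_CALIBRATION_SLOPE: float = 1e-3


def velocity_to_frequency(velocity_mm_s, slope: float = DEFAULT_CALIBRATION_SLOPE):
    """Map RBC speed (mm/s) to Doppler mean frequency (Hz)."""
    return velocity_mm_s / slope


def frequency_to_velocity(frequency_hz, slope: float = DEFAULT_CALIBRATION_SLOPE):
    """Map Doppler mean frequency (Hz) to RBC speed (mm/s)."""
    return frequency_hz * slope
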