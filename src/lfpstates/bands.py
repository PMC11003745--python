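"""Canonical frequency-band definitions used across the pipeline.

Two theta/delta conventions coexist on purpose: the staging features use
4.5-12 Hz (theta) / 0.7-4 Hz (delta), while all between-group spectral
comparisons use the narrower 4.5-11 Hz theta and 1-4 Hz delta.
"""

# band name -> (low_hz, high_hz), edges inclusive
FREQ_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.5, 11.0),
    "low_gamma": (30.0, 55.0),
    "high_gamma": (65.0, 100.0),
    "staging_theta": (4.5, 12.0),
    "staging_delta": (0.7, 4.0),
    "emg": (100.0, 200.0),
}

#: range over which relative power is normalized to sum to 1
REL_POWER_RANGE: tuple[float, float] = (0.5, 55.0)

#: state-map power ratios: (numerator band, denominator band)
RATIO1_BANDS = ((4.5, 9.0), (4.5, 50.0))
RATIO2_BANDS = ((2.0, 20.0), (2.0, 50.0))

#: sleep-wake state labels in canonical order
STATES = ("ACT", "QWK", "NREM", "REM")


def band_edges(name: str) -> tuple[float, float]:
    try:
        return FREQ_BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known: {sorted(FREQ_BANDS)}"
        ) from None
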