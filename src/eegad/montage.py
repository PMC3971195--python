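"""Standard 10-20 montage definitions and the band scheme.

The package works with the classic 20-electrode resting-EEG layout (legacy
T3/T4/T5/T6 names are canonical; modern T7/T8/P7/P8 are accepted as synonyms
on input) plus eight virtual interhemispheric bipolar signals computed as
left-minus-right differences of symmetric electrode pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical scalp labels, in canonical order.
SCALP_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

#: Interhemispheric pairs (left, right), left-minus-right convention.
BIPOLAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"), ("T3", "T4"),
    ("C3", "C4"), ("T5", "T6"), ("P3", "P4"), ("O1", "O2"),
)

#: Midline electrodes (no interhemispheric partner).
MIDLINE_LABELS: tuple[str, ...] = ("Fz", "Cz", "Pz", "Oz")

#: Modern-name synonyms mapped onto the legacy canonical names.
LABEL_SYNONYMS: dict[str, str] = {
    "T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6",
}

_CANON_BY_LOWER = {lbl.lower(): lbl for lbl in SCALP_LABELS}
_SYN_BY_LOWER = {k.lower(): v for k, v in LABEL_SYNONYMS.items()}


def bipolar_label(left: str, right: str) -> str:
    return f"{left}-{right}"


BIPOLAR_LABELS: tuple[str, ...] = tuple(bipolar_label(l, r) for l, r in BIPOLAR_PAIRS)


def canonical_label(name: str) -> str:
    """Resolve a channel name (case-insensitive, synonym-aware) to its
    canonical 10-20 label.

    Raises
    ------
    ValueError
        If the name is not a recognized scalp label.
    """
    key = name.strip().lower()
    if key in _CANON_BY_LOWER:
        return _CANON_BY_LOWER[key]
    if key in _SYN_BY_LOWER:
        return _SYN_BY_LOWER[key]
    raise ValueError(f"unknown 10-20 channel label: {name!r}")


BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")
MODULATION_BAND_NAMES: tuple[str, ...] = tuple(f"m-{b}" for b in BAND_NAMES)

#: Valid (frequency band, modulation band) combinations.  The envelope of a
#: band-limited signal cannot oscillate faster than the band is wide, so only
#: modulation bands slower than the carrier band are meaningful.
VALID_MODULATION_PAIRS: tuple[tuple[str, str], ...] = (
    ("delta", "m-delta"),
    ("theta", "m-delta"), ("theta", "m-theta"),
    ("alpha", "m-delta"), ("alpha", "m-theta"),
    ("beta", "m-delta"), ("beta", "m-theta"), ("beta", "m-alpha"), ("beta", "m-beta"),
    ("gamma", "m-delta"), ("gamma", "m-theta"), ("gamma", "m-alpha"),
    ("gamma", "m-beta"), ("gamma", "m-gamma"),
)


@dataclass(frozen=True)
class BandScheme:
    """Five named frequency bands and five matching modulation bands (Hz).

    The gamma upper edge defaults to 90 Hz: at the 200 Hz sampling rate of the
    target recordings the nominal "30-100+" range exceeds Nyquist, and the
    power-line filter removes content near 60 Hz anyway.  Relative powers are
    normalized over the union of the five bands, so they sum to one by
    construction.
    """

    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "delta": (0.1, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 12.0),
        "beta": (12.0, 30.0),
        "gamma": (30.0, 90.0),
    })
    modulation_bands: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "m-delta": (0.1, 4.0),
        "m-theta": (4.0, 8.0),
        "m-alpha": (8.0, 12.0),
        "m-beta": (12.0, 30.0),
        "m-gamma": (30.0, 90.0),
    })

    def __post_init__(self) -> None:
        prev_high = None
        for name in BAND_NAMES:
            lo, hi = self.bands[name]
            if not lo < hi:
                raise ValueError(f"band {name}: edges must increase, got ({lo}, {hi})")
            if prev_high is not None and lo != prev_high:
                raise ValueError(f"bands must be contiguous; {name} starts at {lo}, "
                                 f"previous band ends at {prev_high}")
            prev_high = hi
        for name in MODULATION_BAND_NAMES:
            lo, hi = self.modulation_bands[name]
            if not lo < hi:
                raise ValueError(f"modulation band {name}: edges must increase")

    @property
    def fullband(self) -> tuple[float, float]:
        """Union of the five bands, used as the normalization denominator."""
        return (self.bands["delta"][0], self.bands["gamma"][1])

    def capped(self, fs: float) -> "BandScheme":
        """Return a scheme whose gamma upper edge does not exceed 0.45*fs."""
        cap = 0.45 * fs
        bands = dict(self.bands)
        lo, hi = bands["gamma"]
        if hi > cap:
            if lo >= cap:
                raise ValueError(f"sampling rate {fs} Hz too low for the gamma band")
            bands["gamma"] = (lo, cap)
        mbands = dict(self.modulation_bands)
        mlo, mhi = mbands["m-gamma"]
        if mhi > cap:
            mbands["m-gamma"] = (mlo, cap)
        return BandScheme(bands=bands, modulation_bands=mbands)


DEFAULT_BANDS = BandScheme()
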