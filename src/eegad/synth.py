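"""Synthetic resting-EEG cohort generator with artifact injection.

Generates labeled multi-channel recordings whose group structure emulates the
electrophysiological signatures of Alzheimer's disease: "slowing" of the EEG
(elevated delta/theta relative power, reduced alpha/beta), reduced
interhemispheric coherence with disease severity, and band-envelope modulation
dynamics.  Ocular, muscular, power-line and amplifier-saturation artifacts are
injected additively, and the clean ground-truth signal is retained so every
downstream stage (artifact removal, feature extraction, classification) can be
validated against a known truth.

The clean-signal model is a sum of per-band filtered Gaussian noise processes,
each amplitude-modulated by low-pass noise envelopes.  Interhemispheric
electrode pairs share a common per-band source mixed so that the expected
magnitude-squared coherence equals the profile's coupling target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .montage import (BAND_NAMES, BIPOLAR_PAIRS, DEFAULT_BANDS,
                      MIDLINE_LABELS, SCALP_LABELS, VALID_MODULATION_PAIRS,
                      BandScheme, canonical_label)
from .recording import Recording

__all__ = [
    "GroupProfile", "ArtifactSpec", "SimSubject",
    "default_profiles", "default_artifacts",
    "simulate_subject", "inject_artifact", "make_cohort", "write_cohort",
]

GROUP_LABELS = ("N", "AD1", "AD2")

#: Healthy-control relative band powers (alpha-dominant, eyes-closed resting).
_N_BAND_POWERS = {"delta": 0.22, "theta": 0.20, "alpha": 0.33,
                  "beta": 0.20, "gamma": 0.05}
#: Per-unit-effect additive shift: slowing moves power from alpha/beta
#: into delta/theta.
_AD_SHIFT = {"delta": 0.06, "theta": 0.03, "alpha": -0.06,
             "beta": -0.03, "gamma": 0.0}
_N_COUPLING = 0.60
#: Per-unit-effect drop in interhemispheric coupling.
_AD_COUPLING_DROP = 0.12


def _default_modulation_profile() -> dict[tuple[str, str], float]:
    """Envelope-energy weights over the valid (band, m-band) pairs.

    Resting EEG envelopes are dominated by slow dynamics, so weights decay
    with the modulation band's rank within each carrier band.
    """
    prof: dict[tuple[str, str], float] = {}
    for band in BAND_NAMES:
        mbs = [mb for b, mb in VALID_MODULATION_PAIRS if b == band]
        weights = np.array([0.5 ** i for i in range(len(mbs))])
        weights /= weights.sum()
        for mb, w in zip(mbs, weights):
            prof[(band, mb)] = float(w)
    return prof


@dataclass(frozen=True)
class GroupProfile:
    """Spectral/coherence/modulation targets for one diagnostic group.

    `effect_scale` is a nonnegative multiplier on the healthy-to-AD contrast:
    0 reproduces the control profile exactly, larger values deepen the
    slowing and coherence loss.
    """

    group_label: str
    band_power_targets: dict[str, float]
    interhemispheric_coupling: dict[str, float]
    modulation_profile: dict[tuple[str, str], float] = field(
        default_factory=_default_modulation_profile)
    effect_scale: float = 0.0

    def __post_init__(self) -> None:
        bp = self.band_power_targets
        if set(bp) != set(BAND_NAMES):
            raise ValueError("band_power_targets must name the five bands")
        if any(not 0 <= v <= 1 for v in bp.values()):
            raise ValueError("band power targets must lie in [0, 1]")
        if abs(sum(bp.values()) - 1.0) > 1e-6:
            raise ValueError("band power targets must sum to 1")
        if any(not 0 <= c <= 1
               for c in self.interhemispheric_coupling.values()):
            raise ValueError("coupling targets must lie in [0, 1]")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be nonnegative")


def make_profile(group_label: str, effect_scale: float) -> GroupProfile:
    """Build a group profile by scaling the healthy-to-AD contrast."""
    bp = {b: _N_BAND_POWERS[b] + effect_scale * _AD_SHIFT[b]
          for b in BAND_NAMES}
    bp = {b: max(v, 0.01) for b, v in bp.items()}
    total = sum(bp.values())
    bp = {b: v / total for b, v in bp.items()}
    c = float(np.clip(_N_COUPLING - effect_scale * _AD_COUPLING_DROP,
                      0.05, 1.0))
    return GroupProfile(group_label=group_label, band_power_targets=bp,
                        interhemispheric_coupling={b: c for b in BAND_NAMES},
                        effect_scale=effect_scale)


def default_profiles(effect_scale: float = 1.0) -> dict[str, GroupProfile]:
    """Default N / AD1 / AD2 profiles.

    AD1 sits at `effect_scale` units of contrast from the controls and AD2 at
    twice that, mirroring mild versus moderate-to-severe disease.
    """
    return {
        "N": make_profile("N", 0.0),
        "AD1": make_profile("AD1", effect_scale),
        "AD2": make_profile("AD2", 2.0 * effect_scale),
    }


# ---------------------------------------------------------------------------
# Artifacts

_BLINK_TOPOGRAPHY = {"Fp1": 1.0, "Fp2": 1.0, "F7": 0.7, "F8": 0.7,
                     "F3": 0.35, "F4": 0.35, "Fz": 0.3}
_MUSCLE_TOPOGRAPHY = {"T3": 1.0, "T4": 1.0, "T5": 0.6, "T6": 0.6,
                      "F7": 0.4, "F8": 0.4}
_SATURATION_TOPOGRAPHY = {"Fp1": 1.0, "Fp2": 1.0, "F7": 1.0, "F8": 1.0}

ARTIFACT_KINDS = ("blink", "muscle", "line_noise", "saturation")


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact process to superimpose on a clean recording.

    `rate` is events per minute for event-like kinds (blink, muscle,
    saturation); line noise is continuous and ignores it.  `topography` maps
    10-20 labels to nonnegative per-channel gains; unlisted channels get 0.
    `duration` is the per-event length in seconds (a (lo, hi) tuple draws the
    length uniformly per event).
    """

    kind: str
    rate: float = 10.0
    amplitude: float = 100.0
    topography: dict[str, float] | None = None
    duration: float | tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("artifact amplitude must be nonnegative")
        if self.topography is not None:
            for lbl, w in self.topography.items():
                canonical_label(lbl)
                if w < 0:
                    raise ValueError("topography weights must be nonnegative")

    def resolved_topography(self) -> dict[str, float]:
        if self.topography is not None:
            return {canonical_label(k): v for k, v in self.topography.items()}
        return {
            "blink": dict(_BLINK_TOPOGRAPHY),
            "muscle": dict(_MUSCLE_TOPOGRAPHY),
            "line_noise": {lbl: 1.0 for lbl in SCALP_LABELS},
            "saturation": dict(_SATURATION_TOPOGRAPHY),
        }[self.kind]

    def duration_range(self) -> tuple[float, float]:
        if self.duration is None:
            return {"blink": (0.2, 0.5), "muscle": (0.3, 2.0),
                    "line_noise": (0.0, 0.0), "saturation": (0.3, 0.8)}[self.kind]
        if isinstance(self.duration, (int, float)):
            return (float(self.duration), float(self.duration))
        lo, hi = self.duration
        return (float(lo), float(hi))


def default_artifacts(blink_rate: float = 3.0, muscle_rate: float = 3.0,
                      line_amplitude: float = 5.0,
                      saturation_rate: float = 0.3) -> list[ArtifactSpec]:
    """Conventional artifact mix for an eyes-closed resting recording.

    Eyes-closed rest keeps blinks sparse (a few per minute); muscle bursts
    are similarly occasional, the 60 Hz component is continuous and modest,
    and a rare amplifier-saturation event exceeds the +/-100 uV rejection
    threshold.
    """
    return [
        ArtifactSpec("blink", rate=blink_rate, amplitude=150.0),
        ArtifactSpec("muscle", rate=muscle_rate, amplitude=30.0),
        ArtifactSpec("line_noise", amplitude=line_amplitude),
        ArtifactSpec("saturation", rate=saturation_rate, amplitude=150.0),
    ]


@dataclass
class SimSubject:
    """A simulated subject: ground-truth clean, artifact-only and mixed
    recordings (mixed = clean + artifact sample-wise), plus bookkeeping."""

    clean: Recording
    artifact: Recording
    mixed: Recording
    group_label: str
    seed: int
    subject_id: str = ""


# ---------------------------------------------------------------------------
# Signal construction

def _bandpass_sos(lo: float, hi: float, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2
    hi = min(hi, 0.99 * nyq)
    return signal.butter(order, [lo / nyq, hi / nyq], btype="band",
                         output="sos")


def _band_noise(rng: np.random.Generator, n: int, lo: float, hi: float,
                fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz.

    The filter's settling transients are several cycles of the low cutoff, so
    extra samples are generated and trimmed to keep the retained stretch
    stationary.
    """
    pad = min(int(round(4.0 * fs / lo)), 4 * n)
    x = rng.standard_normal(n + 2 * pad)
    sos = _bandpass_sos(lo, hi, fs)
    y = signal.sosfiltfilt(sos, x)
    y = y[pad:pad + n]
    sd = y.std()
    return y / sd if sd > 0 else y


def _enveloped_source(rng: np.random.Generator, n: int, band: str,
                      scheme: BandScheme,
                      mod_weights: dict[str, float], fs: float,
                      depth: float = 0.5) -> np.ndarray:
    """One unit-variance band source: band-limited carrier times a positive
    envelope whose fluctuation energy follows `mod_weights`."""
    lo, hi = scheme.bands[band]
    pad = min(int(round(4.0 * fs / lo)), n)
    m = n + 2 * pad
    carrier = _band_noise(rng, m, lo, hi, fs)
    total = sum(mod_weights.values())
    env = np.ones(m)
    if total > 0 and depth > 0:
        for mb, w in mod_weights.items():
            if w <= 0:
                continue
            mlo, mhi = scheme.modulation_bands[mb]
            mhi = min(mhi, hi)           # envelope cannot outrun the band
            if mlo >= mhi:
                continue
            env += depth * np.sqrt(w / total) * _band_noise(rng, m, mlo, mhi, fs)
    env = np.clip(env, 0.05, None)
    x = carrier * env
    # modulation spreads energy past the band edges; re-confine so measured
    # relative band powers track the profile targets, then trim the filter's
    # settling region
    x = signal.sosfiltfilt(_bandpass_sos(lo, hi, fs), x)[pad:pad + n]
    return x / x.std()


def simulate_subject(profile: GroupProfile, duration: float = 120.0,
                     fs: float = 200.0,
                     artifacts: list[ArtifactSpec] | None = None,
                     seed: int = 0, rms_uv: float = 15.0,
                     scheme: BandScheme | None = None) -> SimSubject:
    """Simulate one subject's 20-channel resting EEG.

    The clean signal sums five band-limited, envelope-modulated noise
    processes per channel, scaled so expected relative band powers match the
    profile's targets.  Each interhemispheric pair's band component mixes a
    shared and an independent source so the expected magnitude-squared
    coherence equals the profile's coupling target.  Artifacts are generated
    separately and added; `mixed = clean + artifact` holds exactly.

    Requires ``duration >= 40`` s (five 8-s epochs) and ``fs >= 100`` Hz.
    Identical arguments produce bit-identical output.
    """
    if duration < 40:
        raise ValueError("duration must be at least 40 s (five 8-s epochs)")
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    scheme = (scheme or DEFAULT_BANDS).capped(fs)
    artifacts = artifacts or []

    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    data = np.zeros((len(SCALP_LABELS), n))
    ch_index = {lbl: i for i, lbl in enumerate(SCALP_LABELS)}

    for band in BAND_NAMES:
        p = profile.band_power_targets[band]
        if p <= 0:
            continue
        amp = np.sqrt(p)
        c = profile.interhemispheric_coupling.get(band, 0.0)
        a = np.sqrt(c)                       # mixing weight: expected MSC = a^2 = c
        w_sh, w_ind = np.sqrt(a), np.sqrt(1.0 - a)
        mod_w = {mb: profile.modulation_profile.get((band, mb), 0.0)
                 for b, mb in VALID_MODULATION_PAIRS if b == band}

        def src() -> np.ndarray:
            return _enveloped_source(rng, n, band, scheme, mod_w, fs)

        for left, right in BIPOLAR_PAIRS:
            shared = src()
            data[ch_index[left]] += amp * (w_sh * shared + w_ind * src())
            data[ch_index[right]] += amp * (w_sh * shared + w_ind * src())
        for lbl in MIDLINE_LABELS:
            data[ch_index[lbl]] += amp * src()

    data *= rms_uv / max(data.std(), 1e-12)
    clean = Recording(data=data, fs=fs, labels=SCALP_LABELS)

    art_data = np.zeros_like(data)
    art_seeds = np.random.SeedSequence(seed).spawn(len(artifacts) + 1)[1:]
    for spec, ss in zip(artifacts, art_seeds):
        art_data += _artifact_data(clean, spec,
                                   np.random.default_rng(ss))
    artifact_rec = Recording(data=art_data, fs=fs, labels=SCALP_LABELS)
    mixed = Recording(data=data + art_data, fs=fs, labels=SCALP_LABELS)
    return SimSubject(clean=clean, artifact=artifact_rec, mixed=mixed,
                      group_label=profile.group_label, seed=seed)


def _artifact_data(rec: Recording, spec: ArtifactSpec,
                   rng: np.random.Generator) -> np.ndarray:
    n, fs = rec.n_samples, rec.fs
    out = np.zeros((rec.n_channels, n))
    topo = spec.resolved_topography()
    gains = np.array([topo.get(lbl, 0.0) for lbl in rec.labels])

    if spec.kind == "line_noise":
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        out[:] = np.outer(gains, spec.amplitude * np.sin(2 * np.pi * 60.0 * t
                                                         + phase))
        return out

    minutes = n / fs / 60.0
    n_events = rng.poisson(spec.rate * minutes)
    lo, hi = spec.duration_range()
    for _ in range(n_events):
        dur = rng.uniform(lo, hi) if hi > lo else lo
        width = max(int(round(dur * fs)), 2)
        if width >= n:
            start = 0
            width = n
        else:
            start = rng.integers(0, n - width)
        seg = slice(start, start + width)
        # events vary: eye closures and muscle contractions differ in
        # strength and in how they project onto the scalp from one event to
        # the next
        amp = spec.amplitude * rng.uniform(0.7, 1.3)
        ev_gains = gains * np.clip(1.0 + 0.15 * rng.standard_normal(
            gains.size), 0.0, None)
        if spec.kind == "blink":
            u = np.linspace(0, 1, width)
            bump = np.sin(np.pi * u) ** 2          # smooth unipolar deflection
            out[:, seg] += np.outer(ev_gains, amp * bump)
        elif spec.kind == "muscle":
            burst = _band_noise(rng, max(width, 64), 20.0,
                                min(90.0, 0.45 * fs), fs)[:width]
            burst *= signal.windows.hann(width)
            out[:, seg] += np.outer(ev_gains, amp * burst)
        elif spec.kind == "saturation":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            out[:, seg] += np.outer(gains, sign * spec.amplitude
                                    * np.ones(width))
    return out


def inject_artifact(rec: Recording, spec: ArtifactSpec,
                    seed: int = 0) -> Recording:
    """Generate the artifact-only Recording for one spec (add it to a clean
    recording to corrupt it)."""
    rng = np.random.default_rng(seed)
    return Recording(data=_artifact_data(rec, spec, rng), fs=rec.fs,
                     labels=rec.labels, reference=rec.reference)


# ---------------------------------------------------------------------------
# Cohorts

def make_cohort(n_per_group: int | dict[str, int],
                profiles: dict[str, GroupProfile] | None = None,
                artifacts: list[ArtifactSpec] | None = None,
                duration: float = 120.0, fs: float = 200.0,
                master_seed: int = 0,
                effect_scale: float = 1.0) -> list[SimSubject]:
    """Simulate a labeled cohort with per-subject derived seeds.

    `n_per_group` may be a single count (balanced groups) or a mapping such
    as ``{"N": 24, "AD1": 20, "AD2": 15}``.  The master seed deterministically
    derives one sub-seed per subject, so cohorts are reproducible and
    subjects are statistically independent.
    """
    if profiles is None:
        profiles = default_profiles(effect_scale)
    if isinstance(n_per_group, int):
        if n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")
        counts = {g: n_per_group for g in GROUP_LABELS}
    else:
        counts = dict(n_per_group)
    subjects: list[SimSubject] = []
    total = sum(counts.get(g, 0) for g in GROUP_LABELS)
    seeds = np.random.SeedSequence(master_seed).generate_state(total)
    i = 0
    for group in GROUP_LABELS:
        for k in range(counts.get(group, 0)):
            sub_seed = int(seeds[i] % (2 ** 31))
            i += 1
            subj = simulate_subject(profiles[group], duration=duration, fs=fs,
                                    artifacts=artifacts, seed=sub_seed)
            subj.subject_id = f"{group}{k + 1:02d}"
            subjects.append(subj)
    return subjects


def write_cohort(subjects: list[SimSubject], outdir,
                 format: str = "edf") -> Path:
    """Persist a cohort to disk; returns the path of the JSON manifest."""
    from .preprocess import write_recording

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "edf" if format == "edf" else "tsv"
    manifest = []
    for subj in subjects:
        entry = {"subject_id": subj.subject_id, "group": subj.group_label,
                 "seed": subj.seed, "fs": subj.clean.fs, "files": {}}
        for role in ("clean", "artifact", "mixed"):
            path = outdir / f"{subj.subject_id}_{role}.{ext}"
            write_recording(getattr(subj, role), path, format=format)
            entry["files"][role] = path.name
        manifest.append(entry)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath
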