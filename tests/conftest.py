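"""Shared fixtures: small synthetic subjects generated once per session."""

import warnings

import numpy as np
import pytest

from eegad import (ArtifactSpec, default_artifacts, make_profile,
                   simulate_subject)

warnings.filterwarnings("ignore", message=".*did not converge.*")
warnings.filterwarnings("ignore", message=".*reducing folds.*")


@pytest.fixture(scope="session")
def control_profile():
    return make_profile("N", 0.0)


@pytest.fixture(scope="session")
def clean_subject(control_profile):
    """Artifact-free 120-s control subject."""
    return simulate_subject(control_profile, duration=120.0, fs=200.0,
                            seed=42)


@pytest.fixture(scope="session")
def blink_subject(control_profile):
    """Subject with frequent large blinks plus muscle and line noise."""
    arts = [ArtifactSpec("blink", rate=8.0, amplitude=150.0),
            ArtifactSpec("muscle", rate=4.0, amplitude=30.0),
            ArtifactSpec("line_noise", amplitude=5.0)]
    return simulate_subject(control_profile, duration=120.0, fs=200.0,
                            artifacts=arts, seed=7)


@pytest.fixture(scope="session")
def messy_subject(control_profile):
    """Subject with the default artifact mix, including saturation."""
    return simulate_subject(control_profile, duration=120.0, fs=200.0,
                            artifacts=default_artifacts(saturation_rate=1.0),
                            seed=11)


def frontal_blink_rmse(subject, cleaned_data):
    """RMS error vs ground truth on frontal channels inside blink windows."""
    blink = subject.artifact.channel("Fp1")
    mask = np.abs(blink) > 15.0
    fr = [subject.mixed.labels.index(l) for l in ("Fp1", "Fp2", "F7", "F8")]
    diff = cleaned_data[fr][:, mask] - subject.clean.data[fr][:, mask]
    return float(np.sqrt(np.mean(diff ** 2)))
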