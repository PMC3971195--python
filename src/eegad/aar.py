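"""Automated artifact removal: SAR, BSS (SOBI + CCA) and wICA, plus cascades.

Three families of automated artifact removal are provided:

* **SAR** (statistical artifact rejection) screens whole epochs by amplitude,
  kurtosis and improbability thresholds; it never modifies a surviving epoch.
* **BSS** decomposes the multichannel signal with second-order blind
  identification (SOBI) and removes ocular components selected by a fractal
  dimension criterion, then removes muscular components with a canonical
  correlation analysis (CCA) of the signal against its one-sample delay.
* **wICA** runs ICA, wavelet-thresholds each artifactual independent
  component (removing large coefficients while retaining the sub-threshold
  neural background), and projects back.

The SAR-BSS and SAR-wICA cascades apply epoch screening first and the spatial
method on the concatenated survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import linalg, signal, stats
from sklearn.decomposition import FastICA

from .recording import EpochArray

__all__ = [
    "SARCriteria", "BSSParams", "WICAParams", "AARReport",
    "sar_screen", "sobi", "fractal_dimension",
    "remove_eog_sobi", "remove_emg_cca", "wica", "run_aar", "AAR_METHODS",
]


@dataclass(frozen=True)
class SARCriteria:
    """Epoch-rejection thresholds: absolute amplitude in microvolts, and
    kurtosis / log-probability deviations in across-epoch SD units."""

    amplitude_limit: float = 100.0
    kurtosis_sd: float = 5.0
    improbability_sd: float = 5.0

    def __post_init__(self) -> None:
        if min(self.amplitude_limit, self.kurtosis_sd,
               self.improbability_sd) <= 0:
            raise ValueError("all SAR thresholds must be positive")


@dataclass(frozen=True)
class BSSParams:
    """Parameters of the SOBI/CCA stage.

    `eigenratio` bounds the eigenvalue spread retained by whitening;
    `removal_range` caps how many ocular components SOBI may zero;
    a CCA component is muscular when its mean power above `femg` Hz exceeds
    1/`emg_psd_ratio` of its mean power below.
    """

    eigenratio: float = 1e6
    removal_range: tuple[int, int] = (2, 4)
    emg_psd_ratio: float = 10.0
    femg: float = 15.0
    n_lags: int = 50

    def __post_init__(self) -> None:
        if self.removal_range[0] > self.removal_range[1]:
            raise ValueError("removal_range min must not exceed max")
        if self.eigenratio <= 1:
            raise ValueError("eigenratio must exceed 1")


@dataclass(frozen=True)
class WICAParams:
    """wICA parameters: `tolerance` scales the universal wavelet threshold,
    `ic_threshold` (robust-SD units) flags artifactual components."""

    tolerance: float = 1.25
    ic_threshold: float = 4.0
    wavelet_family: str = "db8"
    decomposition_levels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0 or self.ic_threshold <= 0:
            raise ValueError("tolerance and ic_threshold must be positive")


@dataclass
class AARReport:
    """Per-method record of what was rejected or removed."""

    method: str
    rejected_epoch_indices: list[int] = field(default_factory=list)
    removed_components: dict[str, int] = field(default_factory=dict)
    variance_removed: float = 0.0
    stages: list["AARReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "rejected_epoch_indices": list(map(int, self.rejected_epoch_indices)),
            "removed_components": {k: int(v) for k, v
                                   in self.removed_components.items()},
            "variance_removed": float(self.variance_removed),
            "stages": [s.to_dict() for s in self.stages],
        }


def _variance_removed(x: np.ndarray, xclean: np.ndarray) -> float:
    tot = float(np.var(x))
    if tot <= 0:
        return 0.0
    return float(np.clip(1.0 - np.var(xclean) / tot, 0.0, 1.0))


# ---------------------------------------------------------------------------
# SAR

def sar_screen(epochs: EpochArray,
               criteria: SARCriteria = SARCriteria()) -> tuple[EpochArray,
                                                               AARReport]:
    """Reject epochs whose statistics mark them as artifact-laden.

    An epoch is rejected when any channel exceeds the amplitude limit, when
    any channel's kurtosis deviates from that channel's across-epoch mean by
    more than `kurtosis_sd` across-epoch SDs, or when the epoch's summed
    channel log-probability (under per-channel Gaussian fits across epochs)
    deviates by more than `improbability_sd` SDs.  Surviving epochs are
    returned bit-identical; SAR is pure selection.
    """
    if epochs.n_epochs < 2:
        raise ValueError("SAR needs at least 2 epochs to estimate "
                         "across-epoch statistics")
    data = epochs.data                                   # (e, c, t)

    amp_reject = np.abs(data).max(axis=(1, 2)) > criteria.amplitude_limit

    kurt = stats.kurtosis(data, axis=2)                  # (e, c)
    kmean, ksd = kurt.mean(axis=0), kurt.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        kz = np.abs(kurt - kmean) / ksd
    kz[:, ksd == 0] = 0.0                                # degenerate: no reject
    kurt_reject = (kz > criteria.kurtosis_sd).any(axis=1)

    mu = data.mean(axis=(0, 2))                          # per-channel fit
    sd = data.std(axis=(0, 2))
    sd[sd == 0] = 1.0
    z = (data - mu[None, :, None]) / sd[None, :, None]
    logp = -0.5 * (z ** 2).sum(axis=2).sum(axis=1)       # summed log-prob/epoch
    lsd = logp.std()
    if lsd == 0:
        prob_reject = np.zeros(epochs.n_epochs, dtype=bool)
    else:
        prob_reject = np.abs(logp - logp.mean()) / lsd > criteria.improbability_sd

    reject = amp_reject | kurt_reject | prob_reject
    survivors = epochs.select(~reject)
    report = AARReport(method="SAR",
                       rejected_epoch_indices=list(np.flatnonzero(reject)),
                       removed_components={},
                       variance_removed=float(reject.mean()))
    return survivors, report


# ---------------------------------------------------------------------------
# SOBI

def _joint_diagonalize(mats: np.ndarray, tol: float = 1e-8,
                       max_sweeps: int = 100) -> np.ndarray:
    """Jacobi-style joint approximate diagonalization of symmetric matrices.

    Returns the orthogonal matrix V minimizing the off-diagonal energy of
    V.T M V over the stack (Cardoso-Souloumiac rotations).
    """
    k, n, _ = mats.shape
    V = np.eye(n)
    M = mats.copy()
    for _ in range(max_sweeps):
        changed = False
        for p in range(n - 1):
            for q in range(p + 1, n):
                g1 = M[:, p, p] - M[:, q, q]
                g2 = M[:, p, q] + M[:, q, p]
                ton = g1 @ g1 - g2 @ g2
                toff = 2.0 * (g1 @ g2)
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) > tol:
                    changed = True
                    rot_p = c * M[:, :, p] + s * M[:, :, q]
                    rot_q = -s * M[:, :, p] + c * M[:, :, q]
                    M[:, :, p], M[:, :, q] = rot_p, rot_q
                    rot_p = c * M[:, p, :] + s * M[:, q, :]
                    rot_q = -s * M[:, p, :] + c * M[:, q, :]
                    M[:, p, :], M[:, q, :] = rot_p, rot_q
                    vp = c * V[:, p] + s * V[:, q]
                    vq = -s * V[:, p] + c * V[:, q]
                    V[:, p], V[:, q] = vp, vq
        if not changed:
            break
    return V


def sobi(X: np.ndarray, n_lags: int = 50,
         eigenratio: float = 1e6) -> tuple[np.ndarray, np.ndarray]:
    """Second-order blind identification.

    Whitens the (demeaned) data, then jointly diagonalizes the symmetrized
    lagged covariance matrices at lags 1..n_lags.  Returns ``(mixing,
    sources)`` with ``mixing @ sources`` reconstructing the demeaned data up
    to whitening-rank truncation.  Eigenvalues smaller than the largest
    divided by `eigenratio` are truncated (rank guard).
    """
    X = np.asarray(X, dtype=np.float64)
    n_ch, n_s = X.shape
    if n_s < 10 * n_ch:
        raise ValueError("SOBI needs many more samples than channels")
    Xc = X - X.mean(axis=1, keepdims=True)
    C0 = (Xc @ Xc.T) / n_s
    evals, evecs = linalg.eigh(C0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(evals[0] / eigenratio, 0.0)
    keep &= evals > 1e-12 * evals[0]
    evals, evecs = evals[keep], evecs[:, keep]
    W = evecs / np.sqrt(evals)                     # whitener columns
    Z = W.T @ Xc                                   # whitened data

    lagged = np.empty((n_lags, Z.shape[0], Z.shape[0]))
    for i, lag in enumerate(range(1, n_lags + 1)):
        C = (Z[:, lag:] @ Z[:, :-lag].T) / (n_s - lag)
        lagged[i] = 0.5 * (C + C.T)
    V = _joint_diagonalize(lagged)
    sources = V.T @ Z
    mixing = (evecs * np.sqrt(evals)) @ V          # unwhiten
    return mixing, sources


def fractal_dimension(x: np.ndarray) -> float:
    """Katz-type waveform fractal dimension in [1, 2].

    Uses the curve length L = sum|dy|, the maximal excursion from the first
    sample d = max|y - y0|, and FD = log(n) / (log(n) + log(d / L)).  A
    straight line gives exactly 1; the measure depends only on the shape
    (d/L), so it is invariant to amplitude scaling.  Constant input returns 1.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 10:
        raise ValueError("fractal dimension needs at least 10 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    dy = np.diff(x)
    L = float(np.abs(dy).sum())
    d = float(np.abs(x - x[0]).max())
    if L == 0 or d == 0:
        return 1.0
    n = x.size - 1
    denom = np.log10(n) + np.log10(d / L)
    if denom <= 0:
        return 2.0
    return float(np.clip(np.log10(n) / denom, 1.0, 2.0))


def _windowed_fd(x: np.ndarray, fs: float) -> float:
    """Average Katz fractal dimension over 1-s windows."""
    w = max(int(round(fs)), 10)
    n_win = max(x.size // w, 1)
    vals = [fractal_dimension(x[i * w:(i + 1) * w])
            for i in range(n_win) if x[i * w:(i + 1) * w].size >= 10]
    return float(np.mean(vals)) if vals else 1.0


def remove_eog_sobi(X: np.ndarray, params: BSSParams = BSSParams(),
                    fs: float = 200.0) -> tuple[np.ndarray, AARReport]:
    """Remove ocular components from a channels-x-samples array via SOBI.

    SOBI components are ranked by windowed fractal dimension; ocular
    activity is smooth and low-complexity, so the components with the lowest
    fractal dimension are zeroed.  The number removed is the count of clear
    low-complexity outliers (one across-component SD below the mean), clamped
    to `removal_range`.
    """
    mean = X.mean(axis=1, keepdims=True)
    mixing, sources = sobi(X - mean, n_lags=params.n_lags,
                           eigenratio=params.eigenratio)
    fd = np.array([_windowed_fd(s, fs) for s in sources])
    # fd saturates near 2 on artifact-free components, so rank by fd with a
    # harm-based tie-break: clear low-complexity outliers go first, then the
    # near-ties whose removal costs the least on any single channel
    # (minimizing damage when the mandated minimum exceeds the number of
    # true ocular components)
    ch_var = np.maximum((X - mean).var(axis=1), 1e-30)
    src_var = sources.var(axis=1)
    share = (mixing ** 2) * src_var[None, :] / ch_var[:, None]
    lo, hi = params.removal_range
    n_out = int((fd < fd.mean() - fd.std()).sum())
    k = int(np.clip(n_out, lo, min(hi, len(fd) - 1)))
    fd_r = np.round(fd, 2)
    removed: list[int] = []
    cum = np.zeros(share.shape[0])
    for level in np.unique(fd_r):                # smoothest group first
        group = [i for i in np.flatnonzero(fd_r == level)
                 if i not in removed]
        while group and len(removed) < k:
            # among equally smooth candidates take the one whose removal
            # hurts the worst-hit channel least
            costs = [np.max(cum + share[:, i]) for i in group]
            best = group[int(np.argmin(costs))]
            removed.append(best)
            cum += share[:, best]
            group.remove(best)
        if len(removed) >= k:
            break
    removed = np.array(removed)
    kept = sources.copy()
    kept[removed] = 0.0
    Xclean = mixing @ kept + mean
    # rank truncation may have dropped a subspace; add back the residual
    Xclean += (X - mean) - mixing @ sources
    report = AARReport(method="BSS-SOBI",
                       removed_components={"sobi_eog": k},
                       variance_removed=_variance_removed(X, Xclean))
    return Xclean, report


# ---------------------------------------------------------------------------
# CCA

def _cca_delay(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CCA of X against its one-sample delay.

    Returns (demixing W, mixing A, canonical correlations rho) with sources
    S = W @ X ordered by non-increasing rho (rho approximates each source's
    lag-1 autocorrelation).  Computed in a whitened, rank-truncated basis for
    numerical safety on rank-deficient input.
    """
    n_ch, n_s = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    C0 = (Xc @ Xc.T) / n_s
    evals, evecs = linalg.eigh(C0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > 1e-10 * max(evals[0], 1e-30)
    evals, evecs = evals[keep], evecs[:, keep]
    Wh = evecs / np.sqrt(evals)
    Z = Wh.T @ Xc
    C1 = (Z[:, 1:] @ Z[:, :-1].T) / (n_s - 1)
    C1 = 0.5 * (C1 + C1.T)
    rho, U = linalg.eigh(C1)
    order = np.argsort(rho)[::-1]
    rho, U = rho[order], U[:, order]
    W = U.T @ Wh.T                                # demixing
    A = (evecs * np.sqrt(evals)) @ U              # mixing
    return W, A, rho


def remove_emg_cca(X: np.ndarray, params: BSSParams = BSSParams(),
                   fs: float = 200.0) -> tuple[np.ndarray, AARReport]:
    """Remove muscular components via CCA against the delayed signal.

    Muscle activity is broadband and noise-like, so its components sit in the
    low-autocorrelation tail; a component is flagged when it lies in the
    lowest-autocorrelation quartile AND its mean spectral power above `femg`
    Hz exceeds 1/`emg_psd_ratio` of its mean power below `femg`.
    """
    if params.femg >= fs / 2:
        raise ValueError("femg must be below Nyquist")
    mean = X.mean(axis=1, keepdims=True)
    W, A, rho = _cca_delay(X - mean)
    S = W @ (X - mean)
    n_comp = S.shape[0]
    q = max(int(np.ceil(n_comp / 4)), 1)
    low_auto = np.zeros(n_comp, dtype=bool)
    low_auto[np.argsort(rho)[:q]] = True

    nper = min(int(2 * fs), S.shape[1])
    f, psd = signal.welch(S, fs=fs, nperseg=nper, axis=1)
    hi_band, lo_band = f >= params.femg, f < params.femg
    hi_pow = psd[:, hi_band].mean(axis=1)
    lo_pow = psd[:, lo_band].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        emg_like = hi_pow > lo_pow / params.emg_psd_ratio
    flagged = low_auto & emg_like

    Xclean = X.copy()
    if flagged.any():
        Xclean = Xclean - A[:, flagged] @ S[flagged]
    report = AARReport(method="BSS-CCA",
                       removed_components={"cca_emg": int(flagged.sum())},
                       variance_removed=_variance_removed(X, Xclean))
    return Xclean, report


def remove_bss(X: np.ndarray, params: BSSParams = BSSParams(),
               fs: float = 200.0) -> tuple[np.ndarray, AARReport]:
    """Full BSS stage: SOBI ocular removal followed by CCA muscular removal."""
    X1, rep1 = remove_eog_sobi(X, params, fs=fs)
    X2, rep2 = remove_emg_cca(X1, params, fs=fs)
    report = AARReport(method="BSS",
                       removed_components={**rep1.removed_components,
                                           **rep2.removed_components},
                       variance_removed=_variance_removed(X, X2),
                       stages=[rep1, rep2])
    return X2, report


# ---------------------------------------------------------------------------
# wICA

def _moving_or(mask: np.ndarray, halfwidth: int) -> np.ndarray:
    """Binary dilation of a boolean mask by `halfwidth` samples each side."""
    c = np.zeros(mask.size + 1)
    np.cumsum(mask, out=c[1:])
    lo = np.clip(np.arange(mask.size) - halfwidth, 0, mask.size)
    hi = np.clip(np.arange(mask.size) + halfwidth + 1, 0, mask.size)
    return (c[hi] - c[lo]) > 0


def _moving_mean(x: np.ndarray, halfwidth: int) -> np.ndarray:
    c = np.zeros(x.size + 1)
    np.cumsum(x, out=c[1:])
    lo = np.clip(np.arange(x.size) - halfwidth, 0, x.size)
    hi = np.clip(np.arange(x.size) + halfwidth + 1, 0, x.size)
    return (c[hi] - c[lo]) / np.maximum(hi - lo, 1)


def _wavelet_correct(s: np.ndarray, params: WICAParams) -> np.ndarray:
    """Zero wavelet coefficients above tolerance x universal threshold.

    Each level is thresholded against its own robust scale (universal
    threshold sigma_j*sqrt(2 ln n_j), sigma_j = median|w_j|/0.6745): wavelet
    coefficient magnitudes of ongoing background activity vary strongly
    across scales, and a single fine-level estimate would either spare
    artifacts or gut narrowband background.  Coefficients above threshold
    carry the artifact and are removed; the sub-threshold remainder is the
    recovered neural background.
    """
    n = s.size
    wavelet = pywt.Wavelet(params.wavelet_family)
    level = min(params.decomposition_levels, pywt.swt_max_level(n))
    if level < 1:
        return s.copy()

    # time support of transient events, from the smoothed rectified
    # amplitude: stationary background has a flat envelope, so a 2.5x
    # elevation over its median marks an event with edges included
    env = _moving_mean(np.abs(s), 25)
    support = env > 2.5 * np.median(env)
    if support.any():
        support = _moving_or(support, 50)

    # stationary (translation-invariant) transform: decimated thresholding
    # leaves pseudo-Gibbs tails around removed excursions
    block = 2 ** level
    m = int(np.ceil(n / block)) * block
    sp = np.pad(s, (0, m - n), mode="symmetric") if m > n else s
    supp0 = np.pad(support, (0, m - n)) if m > n else support
    coeffs = [list(pair) for pair in
              pywt.swt(sp, wavelet, level=level, norm=True)]

    has_support = bool(supp0.any())
    for j, pair in enumerate(coeffs):
        lev = level - j                 # coeffs[0] is the coarsest level
        if has_support:
            # a coefficient at this level feels signal over half the filter
            # span to each side; widen the support accordingly so an event's
            # energy cannot hide in "distant" coarse coefficients
            span = (wavelet.dec_len - 1) * 2 ** (lev - 1)
            supp = _moving_or(supp0, span)
            outside = ~supp
        for k, c in enumerate(pair):
            if k == 0 and j > 0:
                continue                # only the top approximation matters
            base = c[outside] if has_support and outside.sum() > 100 else c
            sigma = np.median(np.abs(base)) / 0.6745
            thr = params.tolerance * sigma * np.sqrt(2.0 * np.log(max(n, 2)))
            mask = np.abs(c) > thr
            # details at `lev` span roughly [ny/2^lev, ny/2^(lev-1)]; slow
            # scales inside an event's support are removed wholesale, tails
            # included -- transient artifacts live there
            slow = (k == 0) or lev >= 4
            if has_support and slow:
                mask |= supp
            c[mask] = 0.0
    rec = pywt.iswt([tuple(pair) for pair in coeffs], wavelet, norm=True)
    return rec[:n]


def wica(X: np.ndarray,
         params: WICAParams = WICAParams()) -> tuple[np.ndarray, AARReport]:
    """Wavelet-enhanced ICA artifact removal.

    (1) ICA decomposition; (2) flag components whose maximal amplitude
    exceeds `ic_threshold` robust SDs (median/MAD); (3) wavelet-threshold the
    flagged components, removing super-threshold coefficients and keeping the
    sub-threshold neural background; (4) inverse transform; (5) project back
    through the mixing matrix.
    """
    n_ch, n_s = X.shape
    if n_s < 10 * n_ch:
        raise ValueError("wICA needs many more samples than channels")
    last_err: Exception | None = None
    for attempt in range(3):
        ica = FastICA(whiten="unit-variance", max_iter=500, tol=1e-3,
                      random_state=params.seed + attempt)
        try:
            import warnings
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message=".*did not converge.*")
                S = ica.fit_transform(X.T).T          # (comp, samples)
            break
        except Exception as err:                      # pragma: no cover
            last_err = err
    else:                                             # pragma: no cover
        raise RuntimeError(f"ICA failed after retries: {last_err}")

    flagged = []
    S_clean = S.copy()
    for i, s in enumerate(S):
        mad = np.median(np.abs(s - np.median(s)))
        robust_sd = 1.4826 * mad if mad > 0 else s.std()
        if robust_sd == 0:
            continue
        if np.abs(s).max() / robust_sd > params.ic_threshold:
            flagged.append(i)
            S_clean[i] = _wavelet_correct(s, params)

    Xclean = (S_clean.T @ ica.mixing_.T + ica.mean_).T
    report = AARReport(method="wICA",
                       removed_components={"wica_ics": len(flagged)},
                       variance_removed=_variance_removed(X, Xclean))
    return Xclean, report


# ---------------------------------------------------------------------------
# Method dispatch

AAR_METHODS = ("none", "SAR", "BSS", "wICA", "SAR-BSS", "SAR-wICA")


def _canon_method(method: str) -> str:
    key = method.strip().lower()
    table = {m.lower(): m for m in AAR_METHODS}
    if key not in table:
        raise ValueError(f"unknown AAR method {method!r}; "
                         f"choose from {AAR_METHODS}")
    return table[key]


def run_aar(epochs: EpochArray, method: str,
            sar: SARCriteria = SARCriteria(),
            bss: BSSParams = BSSParams(),
            wica_params: WICAParams = WICAParams()) -> tuple[EpochArray,
                                                             AARReport]:
    """Apply one AAR method (or cascade) to an epoch stack.

    Cascades run SAR screening first and the spatial method on the
    concatenation of surviving epochs; ``"none"`` is the identity.
    """
    method = _canon_method(method)
    if method == "none":
        return epochs, AARReport(method="none")

    stages: list[AARReport] = []
    current = epochs
    if method in ("SAR", "SAR-BSS", "SAR-wICA"):
        current, sar_report = sar_screen(current, sar)
        stages.append(sar_report)
        if method == "SAR":
            return current, sar_report

    spatial = method.split("-")[-1] if "-" in method else method
    rec = current.concatenate()
    if spatial == "BSS":
        cleaned, rep = remove_bss(rec.data, bss, fs=rec.fs)
    else:
        cleaned, rep = wica(rec.data, wica_params)
    stages.append(rep)

    n_e = current.n_epochs
    spe = int(round(current.fs * current.epoch_length))
    data = cleaned[:, :n_e * spe].reshape(rec.n_channels, n_e, spe)
    out = EpochArray(data=data.transpose(1, 0, 2).copy(), fs=current.fs,
                     labels=current.labels, epoch_length=current.epoch_length)
    if len(stages) == 1:
        return out, stages[0]
    report = AARReport(
        method=method,
        rejected_epoch_indices=stages[0].rejected_epoch_indices,
        removed_components=stages[-1].removed_components,
        variance_removed=stages[-1].variance_removed,
        stages=stages)
    return out, report
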