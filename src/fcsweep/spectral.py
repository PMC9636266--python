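"""Epoch-averaged spectral synchronization measures.

Implements the five pairwise synchronization estimators used throughout the
pipeline — wPLI, imaginary coherency, coherence, corrected imaginary PLV and
pairwise phase consistency — from Hann-windowed per-epoch FFT cross-spectra,
band-averaged into one symmetric connectivity matrix per subject and measure.

Definitions (S_xy the per-epoch cross-spectrum, E[] the epoch mean):

    wPLI       |E[Im S_xy]| / E[|Im S_xy|]                        (0 if denom 0)
    ImCoh      Im( E[S_xy] / sqrt(E[S_xx] E[S_yy]) )
    coherence  |E[S_xy]| / sqrt(E[S_xx] E[S_yy])
    ciPLV      Im(PLV) / sqrt(1 - Re(PLV)^2),  PLV = E[S_xy / |S_xy|]
               (0 if |Re(PLV)| = 1)
    PPC        (|sum_e z_e|^2 - n) / (n (n - 1)),  z_e = S_xy / |S_xy|
               == mean pairwise cosine of per-epoch phase differences

wPLI, ImCoh and ciPLV vanish for zero-lag (volume-conduction-like) coupling;
coherence does not.  PPC is the unbiased analogue of squared PLV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import hann

from .synthcohort import Recording

__all__ = [
    "CrossSpectra",
    "ConnectivityMatrix",
    "compute_cross_spectra",
    "wpli",
    "imcoh",
    "coherence",
    "ciplv",
    "ppc",
    "band_connectivity",
    "MEASURES",
    "save_connectivity",
    "load_connectivity",
]

ALPHA_BAND = (8.0, 13.0)


@dataclass
class CrossSpectra:
    """Per-epoch cross-spectral terms restricted to a frequency band.

    ``sxy`` has shape (n_epochs, N, N, n_freqs) with S_yx = conj(S_xy) and a
    real nonnegative diagonal.
    """

    sxy: np.ndarray
    freqs: np.ndarray
    sfreq: float
    node_labels: list[str]

    @property
    def n_epochs(self) -> int:
        return self.sxy.shape[0]

    @property
    def n_channels(self) -> int:
        return self.sxy.shape[1]

    def auto(self) -> np.ndarray:
        """Epoch-mean auto-spectra, shape (N, n_freqs), real."""
        idx = np.arange(self.n_channels)
        return self.sxy[:, idx, idx, :].real.mean(axis=0)


def compute_cross_spectra(
    rec: Recording,
    band: tuple[float, float] = ALPHA_BAND,
    epoch_length: int | None = None,
) -> CrossSpectra:
    """Hann-windowed per-epoch FFT cross-spectra on in-band bins.

    Epochs are fixed-length and non-overlapping; a trailing partial epoch is
    discarded.  Frequency resolution is ``sfreq / epoch_length``; bins whose
    center lies in ``[band[0], band[1]]`` (inclusive) are retained.
    """
    if epoch_length is None:
        epoch_length = rec.epoch_length
    if epoch_length > rec.n_samples:
        raise ValueError("epoch_length exceeds the recording length")
    lo, hi = band
    if not (0 <= lo < hi <= rec.sfreq / 2):
        raise ValueError(f"band {band} outside (0, Nyquist)")
    n_epochs = rec.n_samples // epoch_length
    if n_epochs < 2:
        raise ValueError(
            f"only {n_epochs} complete epoch(s); epoch-averaged estimators "
            "need at least 2"
        )
    x = rec.data[:, : n_epochs * epoch_length].reshape(
        rec.n_channels, n_epochs, epoch_length
    )
    win = hann(epoch_length, sym=False)
    spec = rfft(x * win, axis=-1)  # (N, n_epochs, n_bins_all)
    freqs = rfftfreq(epoch_length, 1.0 / rec.sfreq)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(
            f"no FFT bin falls inside {band} Hz at resolution "
            f"{rec.sfreq / epoch_length:g} Hz"
        )
    spec = spec[:, :, mask].transpose(1, 0, 2)  # (n_epochs, N, n_bins)
    sxy = spec[:, :, None, :] * np.conj(spec[:, None, :, :])
    labels = [f"ch{i:02d}" for i in range(rec.n_channels)]
    return CrossSpectra(sxy=sxy, freqs=freqs[mask], sfreq=rec.sfreq,
                        node_labels=labels)


def _check_epochs(cs: CrossSpectra) -> None:
    if cs.n_epochs < 2:
        raise ValueError("need at least 2 epochs")


def wpli(cs: CrossSpectra) -> np.ndarray:
    """Weighted phase lag index per pair and bin, in [0, 1].

    A vanishing denominator (no imaginary cross-spectral mass, i.e. zero-lag
    coupling) defines the value as 0.  The guard is scale-aware: imaginary
    parts below machine precision relative to the cross-spectral magnitude
    are floating-point residue of an exactly real cross-spectrum, not signal.
    """
    _check_epochs(cs)
    im = cs.sxy.imag
    num = np.abs(im.mean(axis=0))
    den = np.abs(im).mean(axis=0)
    scale = np.abs(cs.sxy).mean(axis=0)
    out = np.zeros_like(num)
    good = den > np.finfo(float).eps * scale
    np.divide(num, den, out=out, where=good)
    return out


def _mean_auto(cs: CrossSpectra) -> np.ndarray:
    auto = cs.auto()
    bad = np.nonzero(~(auto > 0).all(axis=1))[0]
    if bad.size:
        names = ", ".join(cs.node_labels[i] for i in bad)
        raise ValueError(f"zero in-band power for channel(s): {names}")
    return auto


def _coherency(cs: CrossSpectra) -> np.ndarray:
    auto = _mean_auto(cs)
    mean_sxy = cs.sxy.mean(axis=0)
    norm = np.sqrt(auto[:, None, :] * auto[None, :, :])
    return mean_sxy / norm


def imcoh(cs: CrossSpectra) -> np.ndarray:
    """Imaginary part of coherency, in [-1, 1]."""
    _check_epochs(cs)
    return _coherency(cs).imag


def coherence(cs: CrossSpectra) -> np.ndarray:
    """Magnitude coherence, in [0, 1]."""
    _check_epochs(cs)
    return np.abs(_coherency(cs))


def _unit_phases(cs: CrossSpectra) -> np.ndarray:
    mag = np.abs(cs.sxy)
    z = np.zeros_like(cs.sxy)
    np.divide(cs.sxy, mag, out=z, where=mag > 0)
    return z


def ciplv(cs: CrossSpectra) -> np.ndarray:
    """Corrected imaginary PLV: Im(PLV)/sqrt(1 - Re(PLV)^2), guarded."""
    _check_epochs(cs)
    plv = _unit_phases(cs).mean(axis=0)
    re2 = np.clip(plv.real**2, 0.0, 1.0)
    den = np.sqrt(1.0 - re2)
    out = np.zeros(plv.shape)
    np.divide(plv.imag, den, out=out, where=den > 1e-12)
    return out


def ppc(cs: CrossSpectra) -> np.ndarray:
    """Pairwise phase consistency (unbiased), in [-1, 1]."""
    _check_epochs(cs)
    z = _unit_phases(cs)
    n = cs.n_epochs
    s = z.sum(axis=0)
    return (np.abs(s) ** 2 - n) / (n * (n - 1))


MEASURES: dict[str, Callable[[CrossSpectra], np.ndarray]] = {
    "wpli": wpli,
    "imcoh": imcoh,
    "coherence": coherence,
    "ciplv": ciplv,
    "ppc": ppc,
}

# how each signed measure is rectified into a nonnegative edge strength
_DEFAULT_RECTIFY = {
    "wpli": "none",
    "coherence": "none",
    "imcoh": "abs",
    "ciplv": "abs",
    "ppc": "clip",
}


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative N x N edge-weight matrix, zero diagonal."""

    subject_id: str
    measure: str
    band: tuple[float, float]
    node_labels: list[str]
    weights: np.ndarray
    group: str = ""
    rectify: str = "default"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite values")
        if not np.allclose(w, w.T, atol=1e-9):
            raise ValueError("weights must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def upper_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]


def band_connectivity(
    rec: Recording,
    measure: str,
    band: tuple[float, float] = ALPHA_BAND,
    epoch_length: int | None = None,
    rectify: str = "default",
) -> ConnectivityMatrix:
    """One band-averaged connectivity matrix for one subject and measure.

    Per-bin values are averaged over in-band bins, then rectified into a
    nonnegative strength: ``"default"`` applies abs to ImCoh/ciPLV and clips
    PPC at zero (wPLI and coherence are already nonnegative); ``"abs"``,
    ``"clip"`` and ``"raw"`` force that mode.  ``"raw"`` keeps signs and is
    not suitable for quantile thresholding; the signed antisymmetric measures
    are mirrored from the upper triangle in that case.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}")
    if rectify not in ("default", "abs", "clip", "raw"):
        raise ValueError(f"unknown rectify mode {rectify!r}")
    cs = compute_cross_spectra(rec, band=band, epoch_length=epoch_length)
    vals = MEASURES[measure](cs).mean(axis=-1)
    mode = _DEFAULT_RECTIFY[measure] if rectify == "default" else rectify
    if mode == "abs":
        vals = np.abs(vals)
    elif mode == "clip":
        vals = np.clip(vals, 0.0, None)
    if mode == "raw" or mode == "none":
        # antisymmetric measures: keep the upper-triangle sign convention
        vals = np.triu(vals, k=1)
        vals = vals + vals.T
    np.fill_diagonal(vals, 0.0)
    return ConnectivityMatrix(
        subject_id=rec.subject_id,
        measure=measure,
        band=band,
        node_labels=cs.node_labels,
        weights=vals,
        group=rec.group,
        rectify=rectify,
    )


# ---------------------------------------------------------------------------
# delimited-matrix writer / reader: header row of node labels, square body

def save_connectivity(m: ConnectivityMatrix, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{m.subject_id}_{m.measure}.csv"
    with open(path, "w") as fh:
        fh.write(",".join(m.node_labels) + "\n")
        np.savetxt(fh, m.weights, delimiter=",", fmt="%.12g")
    return path


def load_connectivity(
    path: str | Path,
    measure: str | None = None,
    subject_id: str | None = None,
    band: tuple[float, float] = ALPHA_BAND,
    group: str = "",
) -> ConnectivityMatrix:
    path = Path(path)
    if subject_id is None or measure is None:
        stem_parts = path.stem.rsplit("_", 1)
        if subject_id is None:
            subject_id = stem_parts[0]
        if measure is None and len(stem_parts) == 2:
            measure = stem_parts[1]
    with open(path) as fh:
        labels = [s.strip() for s in fh.readline().split(",")]
        body = np.loadtxt(fh, delimiter=",", ndmin=2)
    if body.shape[0] != body.shape[1] or body.shape[0] != len(labels):
        raise ValueError(f"{path.name}: matrix is not square with matching labels")
    if not np.all(np.isfinite(body)):
        bad = np.argwhere(~np.isfinite(body))[0]
        raise ValueError(
            f"{path.name}: non-finite value at cell ({bad[0]}, {bad[1]})"
        )
    if not np.allclose(body, body.T, atol=1e-9):
        raise ValueError(f"{path.name}: asymmetry beyond tolerance 1e-9")
    return ConnectivityMatrix(
        subject_id=subject_id,
        measure=measure or "unknown",
        band=band,
        node_labels=labels,
        weights=body,
        group=group,
    )
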