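"""Maximal-overlap discrete wavelet transform (MODWT) and band bookkeeping.

The MODWT is the undecimated variant of the DWT: every decomposition level
keeps the full signal length, so per-level coefficient series can be
correlated across regions without realignment. Level *j* isolates the dyadic
frequency band (Nyquist/2^j, Nyquist/2^(j-1)]; at the HCP-style repetition
time of 0.72 s, level 4 covers 0.043–0.087 Hz, the canonical resting-state
band.

Implementation is the standard pyramid algorithm with circular (periodic)
boundary treatment. Filters are the Daubechies least-asymmetric LA(8) pair
(PyWavelets' ``sym4``, whose decomposition scaling filter equals the published
LA(8) coefficients), rescaled by 2^(-1/2) per level as the MODWT requires; the
wavelet filter is derived from the scaling filter through the quadrature
mirror relation h_l = (-1)^l g_{L-1-l}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "WaveletBand",
    "WaveletDecomposition",
    "nyquist_frequency",
    "band_for_level",
    "modwt",
    "imodwt",
    "modwt_filters",
    "boundary_width",
    "regress_confounds",
]

#: Accepted aliases for the Daubechies least-asymmetric length-8 filter.
_FILTER_ALIASES = {"la8": "sym4", "la(8)": "sym4", "sym4": "sym4"}


def nyquist_frequency(tr_seconds: float) -> float:
    """Highest resolvable frequency (Hz) for sampling interval ``tr_seconds``."""
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    return 1.0 / (2.0 * tr_seconds)


@dataclass(frozen=True)
class WaveletBand:
    """Dyadic frequency band covered by one MODWT level."""

    level: int
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if not (0 < self.f_low < self.f_high):
            raise ValueError("require 0 < f_low < f_high")

    def contains(self, freq_hz: float) -> bool:
        return self.f_low <= freq_hz <= self.f_high


def band_for_level(tr_seconds: float, level: int) -> WaveletBand:
    """Band (Nyquist/2^level, Nyquist/2^(level-1)] for a MODWT level."""
    if level < 1:
        raise ValueError("level must be >= 1")
    nyq = nyquist_frequency(tr_seconds)
    return WaveletBand(level=level, f_low=nyq / 2.0**level, f_high=nyq / 2.0 ** (level - 1))


def modwt_filters(filter_name: str = "la8") -> tuple[np.ndarray, np.ndarray]:
    """Return the (scaling g, wavelet h) MODWT filters, rescaled by 1/sqrt(2).

    g sums to 1 (= sqrt(2)/sqrt(2)); h sums to 0; together they satisfy the
    MODWT orthonormality conditions that give perfect reconstruction.
    """
    try:
        wavelet = pywt.Wavelet(_FILTER_ALIASES[filter_name.lower()])
    except KeyError:
        raise ValueError(f"unsupported filter {filter_name!r}; use 'la8'") from None
    g = np.asarray(wavelet.dec_lo, dtype=float)
    h = ((-1.0) ** np.arange(g.size)) * g[::-1]
    return g / np.sqrt(2.0), h / np.sqrt(2.0)


def boundary_width(level: int, filter_length: int = 8) -> int:
    """Number of boundary-affected coefficients at a level: L_j - 1.

    L_j = (2^j - 1)(L - 1) + 1 is the equivalent filter width at level j;
    the first L_j - 1 circularly-filtered coefficients mix both signal ends.
    """
    return (2**level - 1) * (filter_length - 1)


@dataclass
class WaveletDecomposition:
    """MODWT pyramid output: per-level detail series plus the final smooth.

    All coefficient arrays share the input's (T, R) shape — the maximal
    overlap property. ``details[j-1]`` holds level-j wavelet coefficients.
    """

    details: list[np.ndarray]
    smooth: np.ndarray
    levels: int
    filter_name: str
    tr_seconds: float

    def band(self, level: int) -> WaveletBand:
        return band_for_level(self.tr_seconds, level)

    def coefficients(self, level: int, drop_boundary: bool = False) -> np.ndarray:
        """Level-``level`` detail coefficients, optionally minus the first
        L_j - 1 boundary-affected rows."""
        if not 1 <= level <= self.levels:
            raise ValueError(f"level must be in 1..{self.levels}")
        w = self.details[level - 1]
        if drop_boundary:
            g, _ = modwt_filters(self.filter_name)
            cut = min(boundary_width(level, g.size), w.shape[0] - 1)
            w = w[cut:]
        return w

    def mra(self) -> tuple[list[np.ndarray], np.ndarray]:
        """Multiresolution analysis: per-level detail components D_j and the
        smooth component S_J, each obtained by inverting a pyramid with all
        other levels zeroed. By linearity of the inverse transform,
        sum_j D_j + S_J reproduces the input exactly."""
        zeros = [np.zeros_like(w) for w in self.details]
        components = []
        for j in range(1, self.levels + 1):
            dets = list(zeros)
            dets[j - 1] = self.details[j - 1]
            components.append(
                imodwt(
                    WaveletDecomposition(
                        dets, np.zeros_like(self.smooth), self.levels, self.filter_name, self.tr_seconds
                    )
                )
            )
        smooth_component = imodwt(
            WaveletDecomposition(zeros, self.smooth, self.levels, self.filter_name, self.tr_seconds)
        )
        return components, smooth_component


def _circular_filter(values: np.ndarray, filt: np.ndarray, step: int) -> np.ndarray:
    out = np.zeros_like(values)
    for lag, coeff in enumerate(filt):
        out += coeff * np.roll(values, step * lag, axis=0)
    return out


def modwt(
    signal_matrix: np.ndarray,
    levels: int = 6,
    filter_name: str = "la8",
    tr_seconds: float = 0.72,
) -> WaveletDecomposition:
    """Decompose a (T,) or (T, R) signal matrix on ``levels`` MODWT levels.

    Requires T >= 2^levels so that the widest equivalent filter still fits the
    circularized signal meaningfully.
    """
    x = np.asarray(signal_matrix, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("signal_matrix must be 1-D or 2-D (time on axis 0)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    n_time = x.shape[0]
    max_level = int(np.floor(np.log2(n_time))) if n_time > 1 else 0
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if n_time < 2**levels:
        raise ValueError(
            f"T={n_time} is too short for {levels} levels; maximum feasible level is {max_level}"
        )
    g, h = modwt_filters(filter_name)
    approx = x
    details: list[np.ndarray] = []
    for j in range(1, levels + 1):
        step = 2 ** (j - 1)
        details.append(_circular_filter(approx, h, step))
        approx = _circular_filter(approx, g, step)
    if squeeze:
        details = [d[:, 0] for d in details]
        approx = approx[:, 0]
    return WaveletDecomposition(
        details=details, smooth=approx, levels=levels, filter_name=filter_name, tr_seconds=tr_seconds
    )


def imodwt(decomposition: WaveletDecomposition) -> np.ndarray:
    """Invert :func:`modwt` (exact, up to floating-point roundoff)."""
    g, h = modwt_filters(decomposition.filter_name)
    smooth = np.asarray(decomposition.smooth, dtype=float)
    squeeze = smooth.ndim == 1
    approx = smooth[:, None] if squeeze else smooth
    shape = approx.shape
    for j in range(decomposition.levels, 0, -1):
        detail = np.asarray(decomposition.details[j - 1], dtype=float)
        if squeeze:
            detail = detail[:, None]
        if detail.shape != shape:
            raise ValueError(f"level-{j} detail shape {detail.shape} != smooth shape {shape}")
        step = 2 ** (j - 1)
        nxt = np.zeros_like(approx)
        for lag in range(g.size):
            nxt += g[lag] * np.roll(approx, -step * lag, axis=0)
            nxt += h[lag] * np.roll(detail, -step * lag, axis=0)
        approx = nxt
    return approx[:, 0] if squeeze else approx


def regress_confounds(signal_matrix: np.ndarray, confound_table) -> np.ndarray:
    """Residualize each region's series against [intercept | confounds] by OLS.

    ``confound_table`` may be a pandas DataFrame (column names used in the
    rank-deficiency diagnostic) or a plain (T, C) array. Raises if the design
    matrix is rank-deficient after adding the intercept, listing the columns
    implicated.
    """
    x = np.asarray(signal_matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    try:
        names = list(confound_table.columns)
        conf = confound_table.to_numpy(dtype=float)
    except AttributeError:
        conf = np.asarray(confound_table, dtype=float)
        if conf.ndim == 1:
            conf = conf[:, None]
        names = [f"confound_{i}" for i in range(conf.shape[1])]
    if conf.shape[0] != x.shape[0]:
        raise ValueError("signal and confounds must have the same number of timepoints")
    design = np.column_stack((np.ones(x.shape[0]), conf))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # QR with pivoting would name the exact culprit; a cheap diagnostic
        # (near-zero R diagonal) suffices for an error message.
        _, r_diag = np.linalg.qr(design)[0], np.abs(np.diag(np.linalg.qr(design)[1]))
        tol = r_diag.max() * max(design.shape) * np.finfo(float).eps
        bad = [(["intercept"] + names)[i] for i in np.nonzero(r_diag <= tol)[0]]
        raise ValueError(f"confound design is rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta
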