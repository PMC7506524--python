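"""Region-wise amplitude of low-frequency fluctuation (ALFF).

Starting from per-subject atlas-region BOLD time series (90 regions in AAL
order), the stages are: motion screening (exclude if translation > 3 mm or
rotation > 3 degrees on any axis), nuisance regression (intercept, linear
trend and user-supplied nuisance signals removed by least squares), spectral
ALFF (mean square-root power over 0.01-0.08 Hz, periodogram convention such
that a pure in-band sinusoid of amplitude A at an exact Fourier frequency
contributes A at its bin), and per-subject normalization by the mean ALFF
across the 90 regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_REGIONS = 90
DEFAULT_BAND = (0.01, 0.08)

#: AAL-90 index (1-based) of the left amygdala, the region in which the
#: planted polygenic effect of the synthetic cohorts lives.
LEFT_AMYGDALA = 41


@dataclass
class RegionSeries:
    """One subject's atlas-region BOLD matrix (timepoints x 90, AAL order)."""

    subject_id: str
    tr: float                      # sampling interval, seconds
    data: np.ndarray               # (n_timepoints, 90)
    n_discarded_initial: int = 0   # initial volumes already removed

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.data.ndim != 2 or self.data.shape[1] != N_REGIONS:
            raise ValueError(f"series must have {N_REGIONS} region columns")
        if self.data.shape[0] < 64:
            raise ValueError("series must have at least 64 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains missing values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @classmethod
    def read_csv(cls, path, subject_id: str, tr: float,
                 discard_initial: int = 0) -> "RegionSeries":
        """Read a timepoints x 90 CSV; ``discard_initial`` leading volumes
        are dropped (raw scans conventionally discard the first ten)."""
        data = pd.read_csv(path).to_numpy(dtype=float)
        if discard_initial:
            data = data[discard_initial:]
        return cls(subject_id=subject_id, tr=tr, data=data,
                   n_discarded_initial=discard_initial)


@dataclass
class MotionSummary:
    """Maximum per-axis head motion for one subject."""

    subject_id: str
    max_translation_mm: np.ndarray  # 3 axes
    max_rotation_deg: np.ndarray    # 3 axes

    def __post_init__(self) -> None:
        self.max_translation_mm = np.asarray(self.max_translation_mm, dtype=float)
        self.max_rotation_deg = np.asarray(self.max_rotation_deg, dtype=float)
        if np.any(self.max_translation_mm < 0) or np.any(self.max_rotation_deg < 0):
            raise ValueError("motion summaries must be non-negative")


@dataclass
class ALFFVector:
    """Raw and normalized 90-region ALFF for one subject."""

    subject_id: str
    raw: np.ndarray
    normalized: np.ndarray | None = None
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (N_REGIONS,):
            raise ValueError(f"ALFF vector must have {N_REGIONS} entries")
        if np.any(self.raw < 0):
            raise ValueError("raw ALFF must be non-negative")


def motion_screen(motion: MotionSummary, translation_mm: float = 3.0,
                  rotation_deg: float = 3.0) -> bool:
    """Keep a subject iff every translation <= 3 mm and rotation <= 3 deg
    (exclusion uses the strict '> 3' reading of the cutoffs)."""
    return bool(np.all(motion.max_translation_mm <= translation_mm)
                and np.all(motion.max_rotation_deg <= rotation_deg))


def nuisance_regress(series: RegionSeries,
                     nuisance: np.ndarray | None = None) -> RegionSeries:
    """Residualize every region on [intercept, linear trend, nuisance].

    With no nuisance signals this reduces to detrending + demeaning.  The
    output is mean-zero per region.  A rank-deficient design is rejected
    with the offending column indices.
    """
    n = series.n_timepoints
    cols = [np.ones(n), np.arange(n, dtype=float)]
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.ndim == 1:
            nuisance = nuisance[:, None]
        if nuisance.shape[0] != n:
            raise ValueError("nuisance rows must equal the number of timepoints")
        cols.extend(nuisance.T)
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify dependent columns by incremental rank
        bad = []
        r = 0
        for j in range(design.shape[1]):
            rj = np.linalg.matrix_rank(design[:, :j + 1])
            if rj == r:
                bad.append(j)
            r = rj
        raise ValueError(f"rank-deficient nuisance design; collinear columns {bad}")
    beta, *_ = np.linalg.lstsq(design, series.data, rcond=None)
    residuals = series.data - design @ beta
    return RegionSeries(subject_id=series.subject_id, tr=series.tr,
                        data=residuals,
                        n_discarded_initial=series.n_discarded_initial)


def band_bins(n: int, tr: float, band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """Indices k of Fourier frequencies k/(n*tr) inside the closed band."""
    freqs = np.fft.rfftfreq(n, d=tr)
    # tolerance absorbs float error at the exact band endpoints
    eps = 1e-12
    mask = (freqs >= band[0] - eps) & (freqs <= band[1] + eps)
    mask[0] = False  # DC never counts
    return np.flatnonzero(mask)


def compute_alff(series: RegionSeries,
                 band: tuple[float, float] = DEFAULT_BAND) -> ALFFVector:
    """Raw ALFF per region: mean square-root spectral power in the band.

    The periodogram amplitude at bin k is 2|X_k|/N, so a pure sinusoid of
    amplitude A sampled at an exact Fourier frequency yields sqrt(power)=A
    at its bin and ALFF = A / n_band_bins.
    """
    nyquist = 1.0 / (2.0 * series.tr)
    if band[1] > nyquist:
        raise ValueError(f"band upper edge {band[1]} Hz above Nyquist {nyquist} Hz")
    bins = band_bins(series.n_timepoints, series.tr, band)
    if bins.size == 0:
        raise ValueError("no Fourier frequencies fall inside the band")
    x = series.data - series.data.mean(axis=0, keepdims=True)
    spectrum = np.fft.rfft(x, axis=0)
    amplitude = 2.0 * np.abs(spectrum) / series.n_timepoints
    raw = amplitude[bins].mean(axis=0)
    return ALFFVector(subject_id=series.subject_id, raw=raw, band=band)


def normalize_alff(alff: ALFFVector) -> ALFFVector:
    """Divide by the subject's mean ALFF over the 90 regions (the region-wise
    stand-in for within-brain normalization); the normalized vector averages
    to exactly 1."""
    mean = float(alff.raw.mean())
    if mean <= 0:
        raise ValueError("cannot normalize an all-zero ALFF vector")
    return ALFFVector(subject_id=alff.subject_id, raw=alff.raw,
                      normalized=alff.raw / mean, band=alff.band)


def alff_pipeline(series: RegionSeries, nuisance: np.ndarray | None = None,
                  band: tuple[float, float] = DEFAULT_BAND) -> ALFFVector:
    """nuisance_regress -> compute_alff -> normalize_alff for one subject."""
    cleaned = nuisance_regress(series, nuisance)
    return normalize_alff(compute_alff(cleaned, band))


def alff_matrix(vectors: list[ALFFVector], normalized: bool = True) -> pd.DataFrame:
    """Stack per-subject ALFF vectors into a subjects x 90 table (AAL
    region indices 1..90 as column names)."""
    rows = {}
    for v in vectors:
        vals = v.normalized if normalized else v.raw
        if vals is None:
            raise ValueError(f"subject {v.subject_id} lacks normalized ALFF")
        rows[v.subject_id] = vals
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[str(i) for i in range(1, N_REGIONS + 1)])
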