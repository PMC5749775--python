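"""Nuclear genome sizing from flow-cytometry histograms.

The 2C DNA amount of a sample is estimated by the internal-standard
peak-ratio method: nuclei of the sample and of a reference line of known
genome size are stained together (propidium iodide), and

    2C_sample = 2C_standard * channel_sample / channel_standard,

where the channels are the fitted means of the two G0/G1 fluorescence peaks.
Peak means, widths and CVs (100*sd/mean) come from Gaussian fits; replicate
runs are averaged into the final nuclear estimate.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import PeakNotFoundError, ValidationError

#: Fits with a CV above this (percent) are flagged, not rejected.
CV_FLAG_THRESHOLD_PCT = 5.0


@dataclass
class FCMHistogram:
    """A one-parameter fluorescence histogram (channel, count)."""

    channels: np.ndarray
    counts: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.channels.ndim != 1 or self.channels.shape != self.counts.shape:
            raise ValidationError("channels and counts must be matching 1-D arrays")
        if np.any(np.diff(self.channels) <= 0):
            raise ValidationError("channels must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["channel", "count"])
            for c, n in zip(self.channels, self.counts):
                w.writerow([int(c), int(n)])

    @classmethod
    def from_csv(cls, path, **metadata) -> "FCMHistogram":
        """Read a two-column (channel,count) CSV; header row optional."""
        path = Path(path)
        channels, counts = [], []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row:
                    continue
                try:
                    c, n = float(row[0]), float(row[1])
                except ValueError:
                    continue  # header or comment line
                channels.append(int(c))
                counts.append(int(round(n)))
        return cls(np.array(channels), np.array(counts), dict(metadata))


@dataclass
class PeakFit:
    """One fitted G0/G1 peak."""

    mean_channel: float
    sd_channel: float
    cv: float  # percent, 100*sd/mean
    height: float
    window: tuple[float, float]
    flags: tuple[str, ...] = ()


@dataclass
class NuclearDNAEstimate:
    """Replicate-averaged nuclear 2C DNA amount."""

    replicate_2C: tuple[float, ...]
    r: int
    mean_2C: float
    sd: float


def _gauss(x, a, mu, sd):
    return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def find_g1_peaks(
    hist: FCMHistogram,
    n_expected: int = 2,
    min_height: float | None = None,
    smooth_sigma: float = 1.0,
    min_separation: int = 5,
    max_iter: int = 25,
) -> list[PeakFit]:
    """Locate and fit the G0/G1 peaks of a histogram.

    Candidate local maxima above ``min_height`` are refined by Gaussian fits
    on windows of +-2.5 fitted sigma.  Because neighbouring G0/G1 peaks can
    overlap in their tails, the refinement is a backfitting loop: each peak
    is re-fitted against the counts minus the current estimates of the other
    peaks, until the means converge.  Peaks are returned sorted by mean
    channel; fits with CV above 5% carry a ``high-cv`` flag and peaks whose
    fit windows overlap carry ``overlapping-window``.

    Raises ``PeakNotFoundError`` if fewer than ``n_expected`` candidates
    exist above the threshold.
    """
    x = hist.channels.astype(float)
    y = hist.counts.astype(float)
    if min_height is None:
        min_height = max(10.0, 1e-3 * y.sum())
    smooth = gaussian_filter1d(y, smooth_sigma, mode="nearest")
    cand, props = find_peaks(smooth, height=min_height, prominence=0.5 * min_height)
    if len(cand) < n_expected:
        raise PeakNotFoundError(
            f"peaks not found: expected {n_expected}, found {len(cand)} candidate(s) "
            f"above height {min_height:.1f}",
            candidates=[(int(x[i]), float(smooth[i])) for i in cand],
        )
    # keep the n_expected tallest candidates at least min_separation apart,
    # ordered by channel
    order = np.argsort(props["peak_heights"])[::-1]
    chosen: list[int] = []
    for k in order:
        if all(abs(cand[k] - cand[c]) >= min_separation for c in chosen):
            chosen.append(k)
        if len(chosen) == n_expected:
            break
    if len(chosen) < n_expected:
        raise PeakNotFoundError(
            f"peaks not found: only {len(chosen)} candidate(s) separated by "
            f">= {min_separation} channels",
            candidates=[(int(x[cand[c]]), float(smooth[cand[c]])) for c in chosen],
        )
    cand = np.sort(cand[chosen])

    # initial estimates: half-width at half max of the smoothed curve
    params = []  # [a, mu, sd]
    for i in cand:
        half = smooth[i] / 2.0
        lo = i
        while lo > 0 and smooth[lo] > half:
            lo -= 1
        hi = i
        while hi < len(x) - 1 and smooth[hi] > half:
            hi += 1
        hwhm = max((x[hi] - x[lo]) / 2.0, 1.0)
        params.append([float(y[i]), float(x[i]), hwhm / math.sqrt(2.0 * math.log(2.0))])

    windows = [(0.0, 0.0)] * len(params)
    for _ in range(max_iter):
        moved = 0.0
        for k, (a, mu, sd) in enumerate(params):
            others = sum(
                _gauss(x, *params[j]) for j in range(len(params)) if j != k
            )
            resid = y - (others if np.ndim(others) else 0.0)
            lo, hi = mu - 2.5 * sd, mu + 2.5 * sd
            sel = (x >= lo) & (x <= hi)
            if sel.sum() < 4:
                sel = slice(max(0, int(mu) - 3), int(mu) + 4)
            try:
                popt, _ = curve_fit(
                    _gauss,
                    x[sel],
                    resid[sel],
                    p0=[a, mu, sd],
                    bounds=([0.0, x.min(), 1e-3], [np.inf, x.max(), np.ptp(x) + 1.0]),
                    maxfev=2000,
                )
            except RuntimeError:
                popt = [a, mu, sd]
            moved = max(moved, abs(popt[1] - mu))
            params[k] = list(popt)
            windows[k] = (lo, hi)
        if moved < 0.01:
            break

    # joint fit of all components on the union of windows removes the
    # residual bias that windowed fits keep when G0/G1 peaks overlap
    if len(params) > 1:
        sel = np.zeros(len(x), dtype=bool)
        for lo, hi in windows:
            sel |= (x >= lo) & (x <= hi)

        def _mixture(xv, *flat):
            out = np.zeros_like(xv, dtype=float)
            for k in range(len(params)):
                out += _gauss(xv, *flat[3 * k : 3 * k + 3])
            return out

        p0 = [v for p in params for v in p]
        lower = [0.0, x.min(), 1e-3] * len(params)
        upper = [np.inf, x.max(), np.ptp(x) + 1.0] * len(params)
        try:
            popt, _ = curve_fit(
                _mixture, x[sel], y[sel], p0=p0, bounds=(lower, upper), maxfev=5000
            )
            params = [list(popt[3 * k : 3 * k + 3]) for k in range(len(params))]
        except RuntimeError:
            pass

    fits = []
    for (a, mu, sd), win in zip(params, windows):
        flags = []
        cv = 100.0 * sd / mu if mu > 0 else math.inf
        if cv > CV_FLAG_THRESHOLD_PCT:
            flags.append("high-cv")
        for (a2, mu2, sd2), win2 in zip(params, windows):
            if mu2 != mu and win[0] < win2[1] and win2[0] < win[1]:
                flags.append("overlapping-window")
                break
        fits.append(PeakFit(float(mu), float(sd), float(cv), float(a), win, tuple(flags)))
    fits.sort(key=lambda p: p.mean_channel)
    return fits


def estimate_2C_from_peaks(
    standard_peak_channel: float,
    sample_peak_channel: float,
    standard_2C: float,
) -> float:
    """Peak-ratio 2C estimate: standard_2C * sample_channel / standard_channel."""
    if standard_peak_channel <= 0 or sample_peak_channel <= 0:
        raise ValidationError("peak channels must be positive")
    if standard_2C <= 0:
        raise ValidationError("standard 2C must be positive")
    return standard_2C * sample_peak_channel / standard_peak_channel


def estimate_2C_from_histogram(
    hist: FCMHistogram, standard_2C: float, standard_peak: str = "lower"
) -> tuple[float, list[PeakFit]]:
    """Fit two G0/G1 peaks and apply the peak-ratio estimator.

    ``standard_peak`` selects which fitted peak is the internal standard:
    ``"lower"`` (smaller mean channel, the usual case when the sample genome
    is larger) or ``"upper"``.
    """
    peaks = find_g1_peaks(hist, n_expected=2)
    std, samp = (peaks[0], peaks[1]) if standard_peak == "lower" else (peaks[1], peaks[0])
    return estimate_2C_from_peaks(std.mean_channel, samp.mean_channel, standard_2C), peaks


def mean_over_replicates(values) -> NuclearDNAEstimate:
    """Average replicate 2C measurements; sd is 0 for a single replicate."""
    vals = tuple(float(v) for v in values)
    if not vals:
        raise ValidationError("at least one replicate is required")
    r = len(vals)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if r > 1 else 0.0
    return NuclearDNAEstimate(vals, r, mean, sd)
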