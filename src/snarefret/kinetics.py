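"""Dwell-time extraction, short/long partitioning, and exponential
rate fitting.

Dwell times come from the idealized (Viterbi) state path, restricted to
the interior of each trace: the first dwell (unknown entry time) and
the last dwell (unknown exit — possibly photobleach) are discarded, so
every retained dwell has both edges observed.  Dwell histograms are
built on linear and logarithmic timescales; the log-timescale histogram
typically shows two modes (short- and long-lived dwells) and the local
minimum between them partitions the populations.  The long-lived
high-FRET dwell distribution is fitted by a single exponential
``A exp(-k t)`` for times beyond the partition threshold, giving the
disassembly rate k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .config import AnalysisConfig, StateBoundaries
from .hmm import HmmFit


@dataclass
class DwellRecord:
    """One contiguous visit to a FRET state (section II only)."""

    molecule_id: str
    field_id: str
    state_label: str
    duration: float            # s; integer multiple of the frame interval
    in_section_ii: bool = True
    censored: bool = False


@dataclass
class Histogram:
    edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n(self) -> float:
        return float(self.counts.sum())


@dataclass
class DwellPartition:
    """Short/long-lived populations of one state's dwell distribution."""

    state_label: str
    threshold: float
    short_population: float
    long_population: float
    sd_short: float
    sd_long: float
    n_dwells: int
    threshold_from_default: bool = False


@dataclass
class RateFit:
    """First-order exponential rate fitted to long-lived dwells."""

    state_label: str
    fit_domain_start: float
    rate: float                # s^-1
    rate_sd: float
    method: str                # "lsq_histogram" | "truncated_mle"
    n_dwells: int

    @property
    def mean_dwell(self) -> float:
        return 1.0 / self.rate


def extract_dwells(path: np.ndarray, fit: HmmFit, boundaries: StateBoundaries,
                   frame_rate: float, molecule_id: str = "",
                   field_id: str = "") -> list[DwellRecord]:
    """Section-II dwells of one idealized trace.

    ``path`` is the Viterbi path over the analyzable (pre-bleach)
    frames.  State labels come from the boundary partition applied to the
    fitted state means — not the raw state index — so a fit whose two
    states both land above the high-FRET boundary yields no low dwells.
    The first and last runs are dropped (entry/exit unknown); molecules
    without transitions therefore contribute zero dwells.
    """
    path = np.asarray(path, dtype=int)
    if path.size == 0:
        return []
    labels = [boundaries.label(m) for m in fit.means]
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [path.size]])
    records: list[DwellRecord] = []
    for a, b in list(zip(starts, stops))[1:-1]:   # drop first & last dwell
        records.append(DwellRecord(
            molecule_id, field_id, labels[path[a]],
            duration=(b - a) / frame_rate))
    return records


def dwell_histograms(durations: Sequence[float],
                     linear_bin_width: float = 1.0,
                     log_bin_width: float = 0.25,
                     ) -> tuple[Histogram, Histogram]:
    """Linear and log10-timescale dwell histograms (raw counts).

    Linear bins start at 0 with the given width; log bins are uniform in
    log10 seconds with the given width, aligned to multiples of the
    width.  Counts are conserved in both.
    """
    d = np.asarray(list(durations), dtype=float)
    if d.size == 0:
        warnings.warn("dwell_histograms: no dwells")
        return (Histogram(np.array([0.0, linear_bin_width]), np.zeros(1)),
                Histogram(np.array([-1.0, -1.0 + log_bin_width]), np.zeros(1)))
    upper = float(d.max())
    n_lin = max(int(np.ceil(upper / linear_bin_width)), 1)
    lin_edges = np.arange(n_lin + 1) * linear_bin_width
    lin_counts, _ = np.histogram(d, bins=lin_edges)

    logs = np.log10(d)
    lo = np.floor(logs.min() / log_bin_width) * log_bin_width
    hi = np.ceil(logs.max() / log_bin_width) * log_bin_width
    if hi <= lo:
        hi = lo + log_bin_width
    n_log = int(round((hi - lo) / log_bin_width))
    log_edges = lo + np.arange(n_log + 1) * log_bin_width
    log_counts, _ = np.histogram(logs, bins=log_edges)
    return Histogram(lin_edges, lin_counts.astype(float)), \
        Histogram(log_edges, log_counts.astype(float))


def find_partition_threshold(log_hist: Histogram, default_threshold: float,
                             smooth_width: int = 3) -> tuple[float, bool]:
    """Short/long partition threshold from the log-timescale histogram.

    The histogram is smoothed by a moving average, the two largest modes
    located, and the interior minimum between them returned (in seconds).
    If the smoothed histogram has no interior minimum between two modes
    (unimodal data), the supplied default is returned with a flag.
    The result is invariant to rescaling the counts.
    """
    counts = np.asarray(log_hist.counts, dtype=float)
    if counts.size < 3 or counts.sum() == 0:
        return default_threshold, True
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        smoothed = np.convolve(counts, kernel, mode="same")
    else:
        smoothed = counts
    # local maxima (plateau-tolerant at edges)
    maxima = [i for i in range(len(smoothed))
              if (i == 0 or smoothed[i] > smoothed[i - 1])
              and (i == len(smoothed) - 1 or smoothed[i] >= smoothed[i + 1])
              and smoothed[i] > 0]
    if len(maxima) < 2:
        return default_threshold, True
    top_two = sorted(sorted(maxima, key=lambda i: smoothed[i])[-2:])
    lo, hi = top_two
    if hi - lo < 2:
        return default_threshold, True
    interior = np.arange(lo + 1, hi)
    i_min = interior[np.argmin(smoothed[interior])]
    centers = log_hist.centers
    return float(10.0 ** centers[i_min]), False


def partition_populations(dwells: Sequence[DwellRecord], threshold: float,
                          state_label: str | None = None,
                          threshold_from_default: bool = False) -> DwellPartition:
    """Short/long-lived dwell populations, mean ± SD across fields.

    A dwell is short-lived when strictly below the threshold and
    long-lived at or above it.  The headline fractions pool all dwells;
    the SDs are sample SDs of the per-field fractions (0, with a note,
    when only one field is present).
    """
    dwells = list(dwells)
    if state_label is not None:
        dwells = [d for d in dwells if d.state_label == state_label]
    n = len(dwells)
    if n == 0:
        raise ValueError("partition_populations requires at least one dwell")
    durations = np.array([d.duration for d in dwells])
    short = float(np.mean(durations < threshold))

    by_field: dict[str, list[float]] = {}
    for d in dwells:
        by_field.setdefault(d.field_id, []).append(d.duration)
    fracs = np.array([np.mean(np.asarray(v) < threshold)
                      for v in by_field.values()])
    if fracs.size > 1:
        sd = float(np.std(fracs, ddof=1))
    else:
        warnings.warn("single field: SD of populations reported as 0")
        sd = 0.0
    label = state_label if state_label is not None else "all"
    return DwellPartition(label, threshold, short, 1.0 - short, sd, sd, n,
                          threshold_from_default)


def _exp_model(t: np.ndarray, a: float, k: float) -> np.ndarray:
    return a * np.exp(-k * t)


def fit_exponential_rate(durations: Sequence[float], fit_domain_start: float,
                         method: str = "lsq_histogram",
                         bin_width: float = 1.0, min_dwells: int = 20,
                         state_label: str = "high") -> RateFit:
    """Single-exponential rate of the long-lived dwell population.

    ``lsq_histogram`` (default, mirroring the assay's procedure):
    unweighted least squares of ``A exp(-k t)`` to the linear-histogram
    bin counts whose centers lie at or beyond ``fit_domain_start``.

    ``truncated_mle``: closed-form maximum likelihood for the
    left-truncated exponential — the mean dwell is the sample mean of
    dwells ≥ cutoff minus the cutoff; statistically efficient and the
    recommended cross-check.

    Raises ``ValueError`` when fewer than ``min_dwells`` dwells lie
    beyond the cutoff.
    """
    d = np.asarray(list(durations), dtype=float)
    tail = d[d >= fit_domain_start]
    if tail.size < min_dwells:
        raise ValueError(
            f"only {tail.size} dwells beyond {fit_domain_start} s "
            f"(minimum {min_dwells})")
    if method == "truncated_mle":
        mean = float(np.mean(tail)) - fit_domain_start
        rate = 1.0 / mean
        rate_sd = rate / np.sqrt(tail.size)
        return RateFit(state_label, fit_domain_start, rate, rate_sd,
                       method, int(tail.size))
    if method != "lsq_histogram":
        raise ValueError(f"unknown method {method!r}")

    hist, _ = dwell_histograms(d, linear_bin_width=bin_width)
    centers = hist.centers
    sel = centers >= fit_domain_start
    t_fit = centers[sel]
    y_fit = hist.counts[sel]
    k0 = 1.0 / max(float(np.mean(tail)) - fit_domain_start, bin_width)
    a0 = max(float(y_fit.max()), 1.0)
    popt, pcov = curve_fit(_exp_model, t_fit, y_fit, p0=(a0, k0), maxfev=20000)
    rate = float(popt[1])
    rate_sd = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    return RateFit(state_label, fit_domain_start, rate, rate_sd,
                   method, int(tail.size))
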