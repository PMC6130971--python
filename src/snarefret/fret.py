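"""Leakage correction, FRET computation, photobleach-aware trace
classification, and point-wise FRET histograms.

The FRET efficiency is the uncorrected proximity ratio
``E = I_A / (I_A + I_D)`` computed from leakage-corrected channel
intensities.  Leakage removal is a full 2x2 linear unmixing of
``observed = M @ true`` with ``M = [[1-l_DA, l_AD], [l_DA, 1-l_AD]]``;
sequential subtraction of the two leakage terms differs at order
``l_DA * l_AD`` and is not invertible, so it is not offered.

Trace sectioning follows the dwell-time bookkeeping of the assay: the
first dwell of a trace (section I) has an unknown entry time and the
final dwell (section III) an unknown exit time — the terminal down-step
can be acceptor photobleaching rather than a conformational transition —
so only interior dwells (section II) carry usable kinetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit

from .config import AnalysisConfig, LeakageMatrix, StateBoundaries
from .traceio import IntensityTrace


def correct_leakage(raw_donor: np.ndarray, raw_acceptor: np.ndarray,
                    lm: LeakageMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Invert the 2x2 channel-mixing model frame-wise.

    Solves ``observed = M @ true`` exactly; raises ``ValueError`` when
    ``l_DA + l_AD = 1`` makes M singular.
    """
    raw_donor = np.asarray(raw_donor, dtype=float)
    raw_acceptor = np.asarray(raw_acceptor, dtype=float)
    det = 1.0 - lm.l_da - lm.l_ad
    if abs(det) < 1e-12:
        raise ValueError("leakage matrix is singular (l_DA + l_AD = 1)")
    # analytic inverse of [[1-l_da, l_ad], [l_da, 1-l_ad]]
    donor = ((1.0 - lm.l_ad) * raw_donor - lm.l_ad * raw_acceptor) / det
    acceptor = (-lm.l_da * raw_donor + (1.0 - lm.l_da) * raw_acceptor) / det
    return donor, acceptor


def apply_leakage(donor: np.ndarray, acceptor: np.ndarray,
                  lm: LeakageMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Forward channel mixing (the simulator's view); inverse of
    :func:`correct_leakage`."""
    m = lm.matrix()
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    return m[0, 0] * donor + m[0, 1] * acceptor, m[1, 0] * donor + m[1, 1] * acceptor


def compute_fret(donor: np.ndarray, acceptor: np.ndarray,
                 total_floor: float = 0.0) -> np.ndarray:
    """Per-frame proximity ratio ``E = A / (A + D)``.

    Frames whose summed intensity falls at or below ``total_floor`` are
    invalid and returned as NaN rather than divided.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    total = donor + acceptor
    e = np.full(donor.shape, np.nan)
    ok = total > total_floor
    e[ok] = acceptor[ok] / total[ok]
    return e


@dataclass
class FretTrace:
    """Leakage-corrected, sectioned, classified FRET trace.

    ``section_bounds = (i_end, iii_start)`` delimits sections as frame
    index intervals within the analyzable (pre-bleach) region:
    section I = ``[0, i_end)``, section II = ``[i_end, iii_start)``,
    section III = ``[iii_start, bleach_frame)``.  ``bleach_frame`` is the
    first frame excluded from analysis (None if the trace survives to the
    end).
    """

    molecule_id: str
    field_id: str
    frame_rate: float
    efficiency: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    classification: str = "excluded"   # with_transitions | without_transitions | excluded
    exclusion_reason: str | None = None
    bleach_frame: int | None = None
    section_bounds: tuple[int, int] = (0, 0)

    @property
    def n_frames(self) -> int:
        return int(self.efficiency.size)

    @property
    def analysis_end(self) -> int:
        return self.n_frames if self.bleach_frame is None else self.bleach_frame

    @property
    def section_ii_slice(self) -> slice:
        return slice(self.section_bounds[0], self.section_bounds[1])

    def analyzable_efficiency(self) -> np.ndarray:
        """Pre-bleach E with invalid frames as NaN."""
        return self.efficiency[: self.analysis_end]


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous same-value runs as (start, stop, value)."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [labels.size]])
    return [(int(a), int(b), int(labels[a])) for a, b in zip(starts, stops)]


def _detect_donor_bleach(total: np.ndarray, recovery_frac: float,
                         floor_frac: float, smooth: int = 5) -> int | None:
    """First frame after which the summed intensity never recovers.

    The total is boxcar-smoothed (width ``smooth``) so single-frame noise
    excursions cannot mask a bleach step.  The pre-bleach level is the
    median of smoothed frames above ``floor_frac`` of the maximum; bleach
    is the first frame whose suffix maximum stays below
    ``recovery_frac`` of that level.
    """
    if total.size == 0:
        return None
    if smooth > 1 and total.size >= smooth:
        kernel = np.ones(smooth) / smooth
        sm = np.convolve(total, kernel, mode="same")
    else:
        sm = total
    ref_mask = sm > floor_frac * float(np.max(sm))
    level = float(np.median(sm[ref_mask])) if ref_mask.any() else float(np.max(sm))
    if level <= 0:
        return 0
    suffix_max = np.maximum.accumulate(sm[::-1])[::-1]
    below = suffix_max < recovery_frac * level
    if not below.any():
        return None
    return int(np.argmax(below))


def classify_trace(trace: IntensityTrace, cfg: AnalysisConfig,
                   reference_total: float | None = None) -> FretTrace:
    """Correct, bleach-detect, section, and classify one raw trace.

    Steps: (1) 2x2 leakage unmixing; (2) per-frame E with low-total
    frames marked invalid; (3) donor bleach = change-point after which
    total intensity never recovers; (4) threshold idealization (median
    filtered) against the high-state boundary; a terminal low run is
    treated as candidate acceptor photobleach (a down-step that never
    returns to high FRET is indistinguishable from bleach) and trimmed;
    (5) classification:

    * ``excluded`` — no colocalized acceptor signal (no high-FRET dwell),
      multi-complex intensity (> ``multi_complex_factor`` x the
      single-molecule level), or fewer analyzable frames than
      ``min_frames``;
    * ``without_transitions`` — E stays above the high boundary for the
      whole pre-bleach trace;
    * ``with_transitions`` — at least one accepted transition (a low
      excursion that returns to high FRET).
    """
    donor, acceptor = correct_leakage(trace.donor, trace.acceptor, cfg.leakage)
    total = donor + acceptor
    db = _detect_donor_bleach(total, cfg.bleach_recovery_frac, cfg.total_floor_frac)
    if db is not None:
        # the frames spanning the bleach step carry partial intensity
        # (camera integration + detection smoothing); drop them too
        db = max(db - 2, 0)
    pre_end = trace.n_frames if db is None else db

    level = float(np.median(total[:pre_end])) if pre_end > 0 else 0.0
    floor = max(cfg.intensity_floor, cfg.total_floor_frac * max(level, 0.0))
    eff = compute_fret(donor, acceptor, total_floor=floor)

    ft = FretTrace(trace.molecule_id, trace.field_id, trace.frame_rate,
                   eff, donor, acceptor, bleach_frame=db)

    e_pre = eff[:pre_end]
    valid = np.isfinite(e_pre)
    if valid.sum() < cfg.min_frames:
        ft.classification = "excluded"
        ft.exclusion_reason = "too_short"
        return ft

    # intensity checks against the field-level single-molecule intensity:
    # too bright = multiple complexes in one spot; too dim = no credible
    # single-molecule signal (e.g. near-immediate bleach leaving noise)
    if reference_total is not None:
        if level > cfg.multi_complex_factor * reference_total:
            ft.classification = "excluded"
            ft.exclusion_reason = "multi_complex"
            return ft
        if level < cfg.low_signal_frac * reference_total:
            ft.classification = "excluded"
            ft.exclusion_reason = "no_signal"
            return ft

    # threshold idealization against the top boundary, robust to 1-frame noise
    e_filled = np.where(valid, e_pre, 0.0)
    if cfg.median_filter_width > 1:
        e_filled = median_filter(e_filled, size=cfg.median_filter_width,
                                 mode="nearest")
    high_cut = cfg.boundaries.cutpoints[-1]
    is_high = (e_filled > high_cut).astype(int)
    runs = _runs(is_high)

    if not any(v == 1 for *_, v in runs):
        ft.classification = "excluded"
        ft.exclusion_reason = "no_acceptor"
        return ft

    # terminal low run: candidate acceptor bleach — trim it from analysis
    if runs and runs[-1][2] == 0:
        ab_frame = runs[-1][0]
        ft.bleach_frame = ab_frame if db is None else min(db, ab_frame)
        runs = runs[:-1]

    end = ft.analysis_end
    if end < cfg.min_frames:
        ft.classification = "excluded"
        ft.exclusion_reason = "too_short"
        return ft

    if len(runs) <= 1:
        ft.classification = "without_transitions"
        ft.section_bounds = (end, end)   # everything is section I/III; no interior
        return ft

    ft.classification = "with_transitions"
    # section I = first run, section III = last run, II = the interior
    ft.section_bounds = (runs[0][1], runs[-1][0])
    return ft


def classify_field(traces: Sequence[IntensityTrace], cfg: AnalysisConfig) -> list[FretTrace]:
    """Classify all traces of one field, using the field's median
    single-molecule intensity as the multi-complex reference."""
    if not traces:
        return []
    totals = []
    for t in traces:
        d, a = correct_leakage(t.donor, t.acceptor, cfg.leakage)
        tot = d + a
        db = _detect_donor_bleach(tot, cfg.bleach_recovery_frac, cfg.total_floor_frac)
        pre = tot if db is None else tot[:db]
        if pre.size:
            totals.append(float(np.median(pre)))
    reference = float(np.median(totals)) if totals else None
    return [classify_trace(t, cfg, reference_total=reference) for t in traces]


def fraction_without_transitions(
        fields: Mapping[str, Sequence[FretTrace]]) -> tuple[float, float, dict[str, float]]:
    """Per-field fraction of molecules without transitions, mean ± SD.

    The denominator counts every donor-visible molecule in the field
    (including excluded ones); the numerator counts only
    ``without_transitions``.  Fields with zero molecules are skipped with
    a warning.  SD is the sample SD across fields (0 for a single field).
    """
    per_field: dict[str, float] = {}
    for fid, traces in fields.items():
        total = len(traces)
        if total == 0:
            warnings.warn(f"field {fid}: no molecules, skipped")
            continue
        n_without = sum(1 for t in traces if t.classification == "without_transitions")
        per_field[fid] = n_without / total
    if not per_field:
        return float("nan"), float("nan"), per_field
    vals = np.array(list(per_field.values()))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd, per_field


def pointwise_histogram(ftraces: Sequence[FretTrace], which: str = "with_transitions_only",
                        bins: int | np.ndarray = 50,
                        range_: tuple[float, float] = (-0.2, 1.2),
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Point-wise FRET histogram (unit area) pooled over molecules.

    ``which='with_transitions_only'`` pools section II frames of
    molecules with transitions (the population histogram of the
    transitioning complexes); ``which='all'`` pools all analyzable frames
    of every non-excluded molecule.
    """
    pool = []
    for ft in ftraces:
        if ft.classification == "excluded":
            continue
        if which == "with_transitions_only":
            if ft.classification != "with_transitions":
                continue
            e = ft.efficiency[ft.section_ii_slice]
        elif which == "all":
            e = ft.analyzable_efficiency()
        else:
            raise ValueError(f"unknown selection {which!r}")
        pool.append(e[np.isfinite(e)])
    if not pool or sum(p.size for p in pool) == 0:
        warnings.warn("pointwise_histogram: empty selection")
        edges = (bins if isinstance(bins, np.ndarray)
                 else np.linspace(*range_, int(bins) + 1))
        return 0.5 * (edges[:-1] + edges[1:]), np.zeros(len(edges) - 1)
    data = np.concatenate(pool)
    density, edges = np.histogram(data, bins=bins, range=range_, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


@dataclass
class MixtureFit:
    """Sum-of-Gaussians fit to a binned FRET density, components sorted
    by mean."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    goodness: float          # residual sum of squares
    converged: bool = True
    message: str = ""

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, m, s in zip(self.weights, self.means, self.sigmas):
            out += w * np.exp(-0.5 * ((x - m) / s) ** 2)
        return out


def _gaussian_sum(x: np.ndarray, *params: float) -> np.ndarray:
    n = len(params) // 3
    out = np.zeros_like(x)
    for i in range(n):
        w, m, s = params[3 * i: 3 * i + 3]
        out += w * np.exp(-0.5 * ((x - m) / s) ** 2)
    return out


def fit_gaussian_mixture(centers: np.ndarray, density: np.ndarray,
                         n_components: int, init_means: Sequence[float],
                         init_sigma: float = 0.08) -> MixtureFit:
    """Nonlinear least-squares fit of a sum of Gaussians to a binned
    density (the point-wise FRET histogram).

    Non-convergence is returned as a flagged fit with diagnostics, never
    raised.  Component means are constrained to [-0.2, 1.2] and the
    result is sorted by mean.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    if len(init_means) != n_components:
        raise ValueError("init_means length must equal n_components")
    centers = np.asarray(centers, dtype=float)
    density = np.asarray(density, dtype=float)
    if not np.any(density > 0):
        return MixtureFit(n_components, np.zeros(n_components),
                          np.asarray(init_means, dtype=float),
                          np.full(n_components, init_sigma),
                          goodness=float("nan"), converged=False,
                          message="empty histogram")
    p0, lo, hi = [], [], []
    peak = float(np.max(density))
    for m in init_means:
        p0 += [peak / n_components, float(m), init_sigma]
        lo += [0.0, -0.2, 1e-4]
        hi += [np.inf, 1.2, 1.0]
    try:
        popt, _ = curve_fit(_gaussian_sum, centers, density, p0=p0,
                            bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return MixtureFit(n_components, np.zeros(n_components),
                          np.asarray(init_means, dtype=float),
                          np.full(n_components, init_sigma),
                          goodness=float("nan"), converged=False,
                          message=str(exc))
    params = np.asarray(popt).reshape(n_components, 3)
    order = np.argsort(params[:, 1])
    params = params[order]
    resid = density - _gaussian_sum(centers, *popt)
    return MixtureFit(n_components, params[:, 0], params[:, 1], params[:, 2],
                      goodness=float(np.sum(resid ** 2)))
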