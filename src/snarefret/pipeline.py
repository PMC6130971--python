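"""End-to-end analysis: raw traces → classification → HMM idealization
→ dwell kinetics.

This is the one entry point the CLI and the integration tests share.
Per-molecule HMM failures are logged and skipped, never abort a run;
every molecule ends in exactly one terminal category, and the stage
counts (total → colocalized → with/without transitions → fitted →
dwells) are reported so molecule conservation can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .fret import FretTrace, classify_field, fraction_without_transitions, \
    pointwise_histogram
from .hmm import HmmFit, InsufficientDataError, fit_hmm
from .kinetics import DwellPartition, DwellRecord, RateFit, dwell_histograms, \
    extract_dwells, fit_exponential_rate, partition_populations
from .traceio import TraceSet

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Everything one analysis run produces, in memory."""

    fret_traces: list[FretTrace]
    fits: dict[str, HmmFit]                  # molecule_id -> fit
    dwells: list[DwellRecord]
    partitions: dict[str, DwellPartition]    # state label -> partition
    rates: dict[str, RateFit]                # state label -> rate fit
    fraction_without: tuple[float, float]    # mean, SD across fields
    stage_counts: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def classification_table(self) -> pd.DataFrame:
        rows = []
        for ft in self.fret_traces:
            rows.append({
                "molecule_id": ft.molecule_id,
                "field_id": ft.field_id,
                "classification": ft.classification,
                "exclusion_reason": ft.exclusion_reason or "",
                "bleach_frame": -1 if ft.bleach_frame is None else ft.bleach_frame,
                "section_i_end": ft.section_bounds[0],
                "section_iii_start": ft.section_bounds[1],
            })
        return pd.DataFrame(rows)

    def dwell_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "molecule_id": d.molecule_id,
            "field_id": d.field_id,
            "state_label": d.state_label,
            "duration_s": d.duration,
            "in_section_ii": d.in_section_ii,
            "censored": d.censored,
        } for d in self.dwells])

    def fit_table(self) -> pd.DataFrame:
        rows = []
        for mid, f in self.fits.items():
            row = {"molecule_id": mid, "log_likelihood": f.log_likelihood,
                   "converged": f.converged, "n_iterations": f.n_iterations}
            for k in range(f.n_states):
                row[f"mean_{k}"] = f.means[k]
                row[f"sigma_{k}"] = f.sigmas[k]
                row[f"p_stay_{k}"] = f.trans[k, k]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for label, part in self.partitions.items():
            rate = self.rates.get(label)
            rows.append({
                "state_label": label,
                "n_dwells": part.n_dwells,
                "partition_threshold_s": part.threshold,
                "short_population": part.short_population,
                "long_population": part.long_population,
                "population_sd": part.sd_short,
                "rate_per_s": rate.rate if rate else float("nan"),
                "mean_dwell_s": rate.mean_dwell if rate else float("nan"),
                "rate_method": rate.method if rate else "",
            })
        return pd.DataFrame(rows)


def analyze(ts: TraceSet, cfg: AnalysisConfig) -> AnalysisResult:
    """Run the full analysis on a trace set.

    Classification happens per field (the multi-complex reference
    intensity is a field-level median); HMM fits and dwell extraction
    run per molecule on the transitioning traces; dwells pool across
    molecules per state label for the partition and rate summaries.
    """
    warn_log: list[str] = []
    ftraces: list[FretTrace] = []
    for fid, traces in sorted(ts.by_field().items()):
        ftraces.extend(classify_field(traces, cfg))

    by_field = {fid: [ft for ft in ftraces if ft.field_id == fid]
                for fid in sorted({ft.field_id for ft in ftraces})}
    frac_mean, frac_sd, _ = (fraction_without_transitions(by_field)
                             if by_field else (float("nan"), float("nan"), {}))

    with_trans = [ft for ft in ftraces if ft.classification == "with_transitions"]
    fits: dict[str, HmmFit] = {}
    dwells: list[DwellRecord] = []
    frame_rate = ts.frame_rate or 10.0
    for ft in with_trans:
        e = ft.analyzable_efficiency()
        try:
            fit = fit_hmm(e, cfg.hmm.n_states, cfg.hmm.init_means,
                          tol=cfg.hmm.tol, max_iter=cfg.hmm.max_iter,
                          sigma_floor=cfg.hmm.sigma_floor,
                          min_frames=cfg.hmm.min_frames)
        except InsufficientDataError as exc:
            msg = f"{ft.molecule_id}: HMM refused ({exc})"
            logger.warning(msg)
            warn_log.append(msg)
            continue
        fits[ft.molecule_id] = fit
        dwells.extend(extract_dwells(fit.viterbi_path, fit, cfg.boundaries,
                                     frame_rate, ft.molecule_id, ft.field_id))

    partitions: dict[str, DwellPartition] = {}
    rates: dict[str, RateFit] = {}
    for label in cfg.boundaries.labels:
        label_dwells = [d for d in dwells if d.state_label == label]
        if not label_dwells:
            continue
        threshold = cfg.default_partition(label)
        partitions[label] = partition_populations(label_dwells, threshold,
                                                  state_label=label,
                                                  threshold_from_default=True)
        try:
            rates[label] = fit_exponential_rate(
                [d.duration for d in label_dwells],
                cfg.fit_domain_start_s if label == "high" else cfg.partition_low_s,
                bin_width=cfg.linear_bin_width_s,
                min_dwells=cfg.min_fit_dwells, state_label=label)
        except ValueError as exc:
            msg = f"state {label}: rate fit refused ({exc})"
            logger.warning(msg)
            warn_log.append(msg)

    stage_counts = {
        "total": len(ftraces),
        "excluded": sum(ft.classification == "excluded" for ft in ftraces),
        "without_transitions": sum(ft.classification == "without_transitions"
                                   for ft in ftraces),
        "with_transitions": len(with_trans),
        "fitted": len(fits),
        "dwells": len(dwells),
    }
    assert (stage_counts["excluded"] + stage_counts["without_transitions"]
            + stage_counts["with_transitions"]) == stage_counts["total"]

    return AnalysisResult(ftraces, fits, dwells, partitions, rates,
                          (frac_mean, frac_sd), stage_counts, warn_log)
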