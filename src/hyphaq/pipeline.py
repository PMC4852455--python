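"""End-to-end per-hypha quantification and cohort table assembly.

Glue over :mod:`hyphaq.kinetics` and :mod:`hyphaq.rings`: run the growth
fit, rise detection and ring-interval detection on every hypha of a cohort
and collect the Table-style parameter summaries per strain.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import kinetics, rings
from .cohort_stats import CohortSummary, summarize_cohort
from .trace_io import Channel, Cohort, HyphaTrace

__all__ = ["quantify_hypha", "quantify_cohort", "cohort_tables"]

#: Cohort-table parameters in publication order.
TABLE_PARAMETERS = [
    "extension_time_min",
    "final_length_um",
    "rate_um_per_h",
    "ftsz_rise_offset_min",
    "ring_appear_offset_min",
    "ring_lifetime_min",
    "maturation_min",
    "total_sporulation_min",
    "total_differentiation_min",
]


def quantify_hypha(trace: HyphaTrace, t_spore_sep: float | None = None,
                   rel_threshold: float = 0.10, window: int = 4,
                   persistence: int = 2, min_rings: int = 3,
                   min_prominence_rel: float = 0.5,
                   min_separation_um: float = 0.5,
                   min_plateau_frames: int = 3) -> dict:
    """Full single-hypha quantification → flat record.

    Growth fit, FtsZ rise detection (if the channel is present), ring
    interval, and the derived event offsets.  ``t_spore_sep`` is the
    observed spore-separation time (no channel marks it; pass the truth
    value for synthetic data or the curated observation for real data).
    """
    fit = kinetics.fit_growth(trace, min_plateau_frames=min_plateau_frames)
    rise = None
    has_ftsz = any(Channel.FTSZ in fr.profiles for fr in trace.frames)
    if has_ftsz:
        series = kinetics.mean_intensity_series(trace, Channel.FTSZ)
        rise = kinetics.detect_rise(series, rel_threshold=rel_threshold,
                                    window=window, persistence=persistence,
                                    channel=Channel.FTSZ)
    interval = (None, None)
    if has_ftsz:
        interval = rings.ring_interval(
            trace, Channel.FTSZ, min_rings=min_rings, persistence=persistence,
            min_prominence_rel=min_prominence_rel,
            min_separation_um=min_separation_um)
    timing = kinetics.event_offsets(trace, fit, rise, interval, t_spore_sep)
    return dict(
        hypha_id=trace.hypha_id,
        strain=trace.strain,
        rate_um_per_h=fit.rate_um_per_h,
        cessation_time_min=fit.cessation_time_min,
        extension_time_min=fit.extension_time_min,
        final_length_um=fit.final_length_um,
        fit_sse=fit.sse,
        ftsz_rise_offset_min=timing.ftsz_rise_offset_min,
        ring_appear_offset_min=timing.ring_appear_offset_min,
        ring_lifetime_min=timing.ring_lifetime_min,
        maturation_min=timing.maturation_min,
        total_sporulation_min=timing.total_sporulation_min,
        total_differentiation_min=timing.total_differentiation_min,
    )


def quantify_cohort(cohort: Cohort,
                    spore_sep_times: Mapping[str, float] | None = None,
                    **kwargs) -> pd.DataFrame:
    """Quantify every hypha of a cohort; one row per hypha.

    ``spore_sep_times`` maps hypha_id → observed spore-separation time.
    """
    spore_sep_times = spore_sep_times or {}
    rows = []
    for strain in cohort:
        for trace in cohort[strain]:
            rows.append(quantify_hypha(
                trace, t_spore_sep=spore_sep_times.get(trace.hypha_id),
                **kwargs))
    return pd.DataFrame(rows)


def cohort_tables(results: pd.DataFrame,
                  parameters: list[str] | None = None
                  ) -> dict[str, CohortSummary]:
    """Per-parameter strain summaries (the Table-style report).

    Rows with missing values for a parameter are dropped from that
    parameter's summary only.
    """
    parameters = parameters or [p for p in TABLE_PARAMETERS
                                if p in results.columns]
    out = {}
    for p in parameters:
        values = {}
        for strain, g in results.groupby("strain", sort=False):
            xs = g[p].dropna().to_numpy(dtype=float)
            if xs.size:
                values[strain] = xs
        if values:
            out[p] = summarize_cohort(values, p)
    return out


def tables_to_frame(tables: dict[str, CohortSummary], digits: int = 1
                    ) -> pd.DataFrame:
    """Render summaries as a parameter × strain table of
    ``mean±sd (median)`` strings."""
    return pd.DataFrame({p: s.formatted(digits) for p, s in tables.items()}).T
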