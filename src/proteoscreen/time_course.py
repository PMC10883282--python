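"""Drug-treatment time-course analysis of TMT reporter matrices.

A multiplexed time course assigns each time point to a TMT reporter channel
(a channel map such as {1: 0 min, 3: 5 min, ..., 11: 1440 min}; channel 2 is
by convention a second time-zero "bridge" sample shared between batches).
Processing:

  1. median normalisation — every channel scaled multiplicatively so all
     channel medians equal the grand median;
  2. collapsing — methionine-oxidation tokens are stripped from modified
     sequences and rows that become identical are summed channel-wise
     (phospho tokens are kept: they define the analyte);
  3. ratios to time zero, feature-wise;
  4. linear interpolation over the minute grid for internal gaps, and
     ranking by the absolute maximal log2 response;
  5. regulation calls: a feature is regulated when its ratio passes the
     fold cutoff (strictly <1/fold or >fold) at any post-treatment point.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("proteoscreen")

TIME_GRID_MIN = (0, 5, 10, 15, 30, 90, 180, 360, 720, 1440)

#: default channel -> minutes map; channel 2 is the cross-batch bridge (t0 bis)
DEFAULT_CHANNEL_MAP = {1: 0, 3: 5, 4: 10, 5: 15, 6: 30, 7: 90, 8: 180,
                       9: 360, 10: 720, 11: 1440}

_OXIDATION_TOKEN = re.compile(r"\(ox\)", flags=re.IGNORECASE)


@dataclass
class TimeCourseMatrix:
    ratios: pd.DataFrame  # features x time points (minutes), ratio to t0
    arm: str = "treated"  # or "vehicle"
    dropped_features: list[str] = field(default_factory=list)

    @property
    def times(self) -> list[int]:
        return [int(t) for t in self.ratios.columns]


def normalize_channels(reporter: pd.DataFrame) -> pd.DataFrame:
    """Scale each channel so channel medians equal the grand median."""
    n_obs = reporter.notna().sum(axis=0)
    if (n_obs == 0).any():
        empty = list(reporter.columns[n_obs == 0])
        raise ValueError(f"channels with no observed values: {empty}")
    medians = reporter.median(axis=0, skipna=True)
    grand = float(np.nanmedian(reporter.to_numpy()))
    return reporter.mul(grand / medians, axis=1)


def strip_oxidation(modified_sequence: str) -> str:
    return _OXIDATION_TOKEN.sub("", modified_sequence)


def collapse_modified_sequences(reporter: pd.DataFrame) -> pd.DataFrame:
    """Strip oxidation tokens and sum rows with identical sequences.

    The index holds modified-sequence strings; all other modification tokens
    (notably phospho) are preserved. Within a duplicate group missing cells
    count as 0 when at least one duplicate was observed.
    """
    stripped = reporter.index.map(strip_oxidation)
    grouped = reporter.groupby(stripped, sort=False).sum(min_count=1)
    return grouped


def ratios_vs_t0(
    matrix: pd.DataFrame,
    t0_column,
    channel_map: dict | None = None,
    arm: str = "treated",
) -> TimeCourseMatrix:
    """Divide every channel by the time-zero channel, feature-wise.

    Features missing (or zero in) the t0 channel cannot be expressed as
    ratios; they are dropped and reported. Columns are renamed to minutes
    via ``channel_map`` when given.
    """
    t0 = matrix[t0_column]
    bad = t0.isna() | (t0 <= 0)
    if bad.any():
        logger.warning("dropping %d features without usable t0", int(bad.sum()))
    kept = matrix.loc[~bad]
    ratios = kept.div(kept[t0_column], axis=0)
    if channel_map is not None:
        ratios = ratios[[c for c in ratios.columns if c in channel_map]]
        ratios = ratios.rename(columns=channel_map)
    ratios = ratios.sort_index(axis=1)
    return TimeCourseMatrix(
        ratios=ratios, arm=arm, dropped_features=list(matrix.index[bad])
    )


def interpolate_and_rank(tc: TimeCourseMatrix) -> pd.DataFrame:
    """Fill internal gaps linearly in time and rank by |max log2 response|.

    Interpolation is linear on the minute axis and never extrapolates past
    the first/last observed point. Returns a table sorted descending by
    ``max_abs_log2``, with the interpolated ratio columns appended.
    """
    times = np.array(tc.times, dtype=float)
    interp = tc.ratios.copy()
    interp.columns = times
    interp = interp.interpolate(axis=1, method="index", limit_area="inside")
    log2 = np.log2(interp.where(interp > 0))
    resp = log2.drop(columns=times[0]) if times[0] == 0 else log2
    max_abs = resp.abs().max(axis=1, skipna=True).fillna(0.0)
    # time point of the extreme response, for direction calls downstream
    peak_t = resp.abs().fillna(-1.0).idxmax(axis=1)
    out = pd.DataFrame(
        {
            "max_abs_log2": max_abs,
            "peak_time_min": peak_t,
            "peak_log2": [
                resp.loc[f, t] if t in resp.columns else np.nan
                for f, t in zip(resp.index, peak_t)
            ],
        }
    )
    out = pd.concat([out, interp], axis=1)
    return out.sort_values("max_abs_log2", ascending=False, kind="mergesort")


def call_regulated(tc: TimeCourseMatrix, fold: float = 2.0) -> pd.DataFrame:
    """Regulated features: ratio strictly <1/fold or >fold at any t > 0.

    Direction is the sign of the log2 ratio at the maximal-|response| time
    point. Returns a table restricted to regulated features.
    """
    if fold <= 1:
        raise ValueError("fold cutoff must exceed 1")
    post = tc.ratios[[t for t in tc.ratios.columns if t > 0]]
    hit = (post < 1.0 / fold) | (post > fold)
    post = post.loc[hit.any(axis=1)]
    log2 = np.log2(post.where(post > 0))
    peak = log2.abs().idxmax(axis=1)
    direction = pd.Series(
        [
            "up" if log2.loc[f, t] > 0 else "down"
            for f, t in zip(log2.index, peak)
        ],
        index=log2.index,
        dtype=object,
    )
    return pd.DataFrame(
        {
            "direction": direction,
            "peak_time_min": peak,
            "max_abs_log2": log2.abs().max(axis=1),
        }
    )
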