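"""Cell-cycle phase proportions from bulk proteomes.

Bulk proteomes of asynchronously cycling populations carry a footprint of
the population's phase composition: "periodic" proteins oscillate over the
cycle and fall into five clusters with phase-specific expression (the usual
reading is 1: G1, 2: S, 3: G2, 4: early M, 5: M, carried as annotation
metadata, not computed here). Per cell line:

  1. map identified proteins to the periodic-protein clusters;
  2. sum the (linear) intensities of each cluster's members;
  3. min-max rescale each cluster's sums across cell lines (removes the
     bias of clusters that simply contain more proteins);
  4. normalise the five rescaled values of each line to sum to 1.

The resulting proportions are then screened against drug response: Pearson
correlation of each cluster proportion with each drug's AUC across lines,
restricted to drugs that actually do something (minimum AUC below a cutoff),
flagging strong negative correlations as phase-specific sensitivity and
strong positive ones as resistance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import DrugResponseMatrix
from .preprocessing import LINEAR, AbundanceMatrix

logger = logging.getLogger("proteoscreen")

CLUSTER_PHASES = {1: "G1", 2: "S", 3: "G2", 4: "early M", 5: "M"}


@dataclass
class CellCycleProportions:
    proportions: pd.DataFrame  # cell lines x 5 clusters, rows sum to 1
    summed: pd.DataFrame  # intermediate: cluster intensity sums
    rescaled: pd.DataFrame  # intermediate: min-max rescaled values
    undefined_lines: list[str] = field(default_factory=list)


def cluster_proportions(
    proteome: AbundanceMatrix, periodic_clusters: dict[int, set[str]]
) -> CellCycleProportions:
    """Estimate per-line phase proportions from periodic-protein clusters."""
    if proteome.scale_tag != LINEAR:
        raise ValueError("cluster_proportions expects linear-scale intensities")
    vals = proteome.values
    sums = {}
    for label in sorted(periodic_clusters):
        members = [p for p in periodic_clusters[label] if p in vals.index]
        if not members:
            raise ValueError(f"cluster {label} has no mapped proteins")
        sums[label] = vals.loc[members].sum(axis=0, skipna=True)
    summed = pd.DataFrame(sums)  # lines x clusters

    span = summed.max(axis=0) - summed.min(axis=0)
    rescaled = (summed - summed.min(axis=0)) / span.where(span > 0)
    rescaled = rescaled.fillna(0.5)  # constant cluster across lines: uninformative

    totals = rescaled.sum(axis=1)
    undefined = list(rescaled.index[totals == 0])
    if undefined:
        logger.warning("proportions undefined for lines %s", undefined)
    props = rescaled.div(totals.where(totals > 0), axis=0)
    return CellCycleProportions(
        proportions=props, summed=summed, rescaled=rescaled,
        undefined_lines=undefined,
    )


def correlate_with_response(
    proportions: CellCycleProportions,
    response: DrugResponseMatrix,
    min_auc: float = 0.8,
    flag_threshold: float = -0.5,
) -> pd.DataFrame:
    """Correlate cluster proportions with drug AUC across cell lines.

    Drugs whose minimum AUC is >= ``min_auc`` (hardly any effect anywhere)
    are excluded. Returns one row per (drug, cluster) with the Pearson r,
    the number of lines used, and flags: ``sensitivity`` where
    r < ``flag_threshold`` (more cells in that phase, stronger response)
    and ``resistance`` where r > -``flag_threshold``.
    """
    props = proportions.proportions
    shared = [l for l in props.index if l in response.auc.columns]
    rows = []
    for drug in response.drugs:
        auc = response.auc.loc[drug, shared]
        if auc.min(skipna=True) >= min_auc:
            continue
        for cluster in props.columns:
            pair = pd.concat([props.loc[shared, cluster], auc], axis=1).dropna()
            if len(pair) < 3:
                continue
            if pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                continue  # constant input: correlation undefined
            r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append(
                {
                    "drug": drug,
                    "cluster": cluster,
                    "phase": CLUSTER_PHASES.get(cluster, str(cluster)),
                    "r": float(r),
                    "p": float(p),
                    "n": len(pair),
                    "sensitivity": bool(r < flag_threshold),
                    "resistance": bool(r > -flag_threshold),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["drug", "cluster", "phase", "r", "p", "n",
                 "sensitivity", "resistance"],
    )
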