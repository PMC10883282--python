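"""Kinase activity landscapes from baseline (phospho)proteomes.

Kinase activity per cell line is scored by combining up to four evidence
layers, each row-standardised (z-score across cell lines):

  a) kinase protein abundance (log10 full-proteome intensity);
  b) kinase phosphorylation — linear intensities of the kinase's own
     p-sites summed per line, then log10, then z-scored;
  c) activation-loop phosphorylation — as (b) restricted to annotated
     activation-loop sites;
  d) substrate phosphorylation — as (b) over the kinase's annotated
     substrate sites.

Layer (a) is a hard requirement: without protein-level quantification no
score is produced. On top of that, at least one phospho layer (b, c or d)
must be present; kinases with abundance evidence only are flagged in the
output rather than scored. The combined score is the plain sum of the
available z-layers, so each layer contributes on a comparable scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AnnotationSet
from .preprocessing import LINEAR, LOG10, AbundanceMatrix

logger = logging.getLogger("proteoscreen")

LAYERS = ("a", "b", "c", "d")


@dataclass
class ActivityLandscape:
    scores: pd.DataFrame  # kinases x cell lines; NaN where not scorable
    layers: dict[str, pd.DataFrame]  # per-layer z matrices (NaN = unavailable)
    layer_mask: pd.DataFrame  # kinases x cell lines, strings like "abd"
    abundance_only: pd.DataFrame  # True where only layer a was available

    @property
    def kinases(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.scores.columns)


def zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores over non-missing entries (sample SD, n-1).

    Rows with fewer than two observed values become all-missing (SD is
    undefined); constant rows get z = 0 so layer availability is preserved.
    """
    mean = df.mean(axis=1, skipna=True)
    sd = df.std(axis=1, ddof=1, skipna=True)
    n_obs = df.notna().sum(axis=1)
    z = df.sub(mean, axis=0).div(sd.where(sd > 0), axis=0)
    z[sd == 0] = df[sd == 0].notna().astype(float) * 0.0
    z = z.where(df.notna())
    z.loc[n_obs < 2] = np.nan
    return z


def _sum_sites_per_kinase(
    phospho: AbundanceMatrix, site_map: dict[str, set[str]]
) -> pd.DataFrame:
    """Sum linear site intensities per kinase per line, then log10.

    Inside a sum, a missing site counts as 0 as long as at least one of the
    kinase's sites is observed in that line (evidence is additive on the
    linear scale); lines where all sites are missing stay missing.
    """
    if phospho.scale_tag != LINEAR:
        raise ValueError("phospho layer sums expect linear-scale intensities")
    vals = phospho.values
    rows = {}
    for kinase, sites in site_map.items():
        present = [s for s in sites if s in vals.index]
        if not present:
            continue
        block = vals.loc[present]
        total = block.sum(axis=0, skipna=True)
        any_obs = block.notna().any(axis=0)
        rows[kinase] = total.where(any_obs)
    if not rows:
        return pd.DataFrame(columns=vals.columns)
    summed = pd.DataFrame(rows).T
    return np.log10(summed.where(summed > 0))


def _own_site_map(phospho: AbundanceMatrix, kinases: set[str]) -> dict[str, set[str]]:
    """Sites belonging to each kinase by the GENE_RESPOS id convention."""
    out: dict[str, set[str]] = {}
    for site_id in phospho.values.index:
        gene = str(site_id).rsplit("_", 1)[0]
        if gene in kinases:
            out.setdefault(gene, set()).add(site_id)
    return out


def layer_a_kinase_abundance(
    proteome: AbundanceMatrix, annotations: AnnotationSet
) -> pd.DataFrame:
    """Layer (a): z-scored log10 kinase abundance from the full proteome."""
    if proteome.scale_tag != LOG10:
        raise ValueError("layer a expects a log10 proteome")
    kin = [k for k in proteome.values.index if k in annotations.kinase_ids]
    return zscore_rows(proteome.values.loc[kin])


def layer_b_kinase_phospho(
    phospho: AbundanceMatrix, annotations: AnnotationSet
) -> pd.DataFrame:
    """Layer (b): z-scored log10 sum of the kinase's own p-site intensities."""
    site_map = _own_site_map(phospho, annotations.kinase_ids)
    return zscore_rows(_sum_sites_per_kinase(phospho, site_map))


def layer_c_activation_loop(
    phospho: AbundanceMatrix, annotations: AnnotationSet
) -> pd.DataFrame:
    """Layer (c): as (b), restricted to annotated activation-loop sites."""
    return zscore_rows(
        _sum_sites_per_kinase(phospho, annotations.activation_loop_sites)
    )


def layer_d_substrates(
    phospho: AbundanceMatrix, annotations: AnnotationSet
) -> pd.DataFrame:
    """Layer (d): z-scored log10 sum of annotated substrate-site intensities."""
    return zscore_rows(_sum_sites_per_kinase(phospho, annotations.substrate_sites))


def combine(
    a: pd.DataFrame, b: pd.DataFrame, c: pd.DataFrame, d: pd.DataFrame
) -> ActivityLandscape:
    """Sum available z-layers into the activity landscape.

    Score is present only where layer (a) is present and at least one of
    (b, c, d) is; abundance-only cells are flagged, not scored.
    """
    kinases = a.index
    lines = a.columns
    layers = {
        "a": a,
        "b": b.reindex(index=kinases, columns=lines),
        "c": c.reindex(index=kinases, columns=lines),
        "d": d.reindex(index=kinases, columns=lines),
    }
    score = pd.DataFrame(0.0, index=kinases, columns=lines)
    mask = pd.DataFrame("", index=kinases, columns=lines)
    for name, z in layers.items():
        score = score + z.fillna(0.0)
        mask = mask.where(z.isna(), mask + name)
    has_a = layers["a"].notna()
    has_phospho = layers["b"].notna() | layers["c"].notna() | layers["d"].notna()
    valid = has_a & has_phospho
    return ActivityLandscape(
        scores=score.where(valid),
        layers=layers,
        layer_mask=mask,
        abundance_only=has_a & ~has_phospho,
    )


def compute_landscape(
    proteome: AbundanceMatrix,
    phospho: AbundanceMatrix,
    annotations: AnnotationSet,
) -> ActivityLandscape:
    """Full pipeline: the four layers plus their combination."""
    return combine(
        layer_a_kinase_abundance(proteome, annotations),
        layer_b_kinase_phospho(phospho, annotations),
        layer_c_activation_loop(phospho, annotations),
        layer_d_substrates(phospho, annotations),
    )


def rank_kinases(
    landscape: ActivityLandscape,
    cell_line: str,
    annotations: AnnotationSet | None = None,
    druggable_only: bool = False,
) -> list[str]:
    """Kinases of one cell line in descending activity-score order.

    Ties break lexicographically on the kinase id. With ``druggable_only``
    the ranking is restricted to annotated druggable kinases.
    """
    if cell_line not in landscape.scores.columns:
        raise KeyError(f"unknown cell line {cell_line!r}")
    col = landscape.scores[cell_line].dropna()
    if druggable_only:
        if annotations is None:
            raise ValueError("druggable_only requires annotations")
        col = col[col.index.isin(annotations.druggable_kinases)]
    if col.empty:
        logger.warning("no scorable kinases for cell line %s", cell_line)
        return []
    order = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in order]
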