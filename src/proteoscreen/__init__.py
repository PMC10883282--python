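"""proteoscreen: integrate cell-line (phospho)proteomes with drug screens.

The package covers the computational stages of a panel study: reading
search-engine output tables and screen plates (:mod:`~proteoscreen.io_formats`),
post-processing intensity matrices (:mod:`~proteoscreen.preprocessing`),
dose-response fitting and standardised AUC (:mod:`~proteoscreen.dose_response`),
four-layer kinase activity landscapes (:mod:`~proteoscreen.activity_score`),
cell-cycle phase proportions (:mod:`~proteoscreen.cell_cycle`), sparse
multiblock PLS drug/marker co-selection (:mod:`~proteoscreen.smbplsr`),
bootstrapped elastic-net marker discovery (:mod:`~proteoscreen.elastic_net`),
treatment time courses (:mod:`~proteoscreen.time_course`) and a synthetic
study generator with planted ground truth (:mod:`~proteoscreen.synthetic_data`).
"""

from . import (
    activity_score,
    cell_cycle,
    dose_response,
    elastic_net,
    io_formats,
    preprocessing,
    smbplsr,
    synthetic_data,
    time_course,
)
from .preprocessing import (
    AbundanceMatrix,
    filter_decoys_contaminants,
    impute_half_min_rowwise,
    median_center,
)

__version__ = "0.1.0"

__all__ = [
    "AbundanceMatrix",
    "activity_score",
    "cell_cycle",
    "dose_response",
    "elastic_net",
    "filter_decoys_contaminants",
    "impute_half_min_rowwise",
    "io_formats",
    "median_center",
    "preprocessing",
    "smbplsr",
    "standard_postprocess",
    "synthetic_data",
    "time_course",
]


def standard_postprocess(matrix, flags=None):
    """Filter decoys/contaminants, log10-transform, median-centre, impute.

    The standard post-processing chain applied to both the proteome and the
    phosphoproteome before any downstream analysis. Returns the imputed
    log10 matrix and the imputation report.
    """
    if flags is not None:
        matrix = filter_decoys_contaminants(matrix, flags)
    centred = median_center(matrix.to_log10())
    return impute_half_min_rowwise(centred)
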