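"""Loading-time preprocessing: low-expression filter, sample alignment, log scaling.

The low-expression filter mirrors the common RNA-seq practice of dropping
transcripts detected (count > 0) in fewer than a fixed number of samples —
by default 22, roughly 20% of a ~113-sample cohort. Genes and miRNAs are
expected to be filtered separately before being concatenated for network
analysis.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .data import CountMatrix, ExpressionMatrix, GEBVMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_SAMPLES = 22

__all__ = [
    "filter_low_expression",
    "min_samples_from_fraction",
    "align_samples",
    "log_scale",
    "DEFAULT_MIN_SAMPLES",
]


def filter_low_expression(counts: CountMatrix, min_samples: int = DEFAULT_MIN_SAMPLES) -> list:
    """Return ids of features expressed (count > 0) in at least `min_samples` samples.

    Order of the input features is preserved. A feature with all-zero counts
    is always removed (for any ``min_samples >= 1``).
    """
    if counts.n_features == 0 or counts.n_samples == 0:
        raise ValueError("cannot filter an empty count matrix")
    if min_samples <= 0:
        raise ValueError(f"min_samples must be positive, got {min_samples}")
    if min_samples > counts.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {counts.n_samples} available samples"
        )
    nonzero = (counts.data.to_numpy() > 0).sum(axis=1)
    keep = nonzero >= min_samples
    retained = [fid for fid, k in zip(counts.feature_ids, keep) if k]
    logger.info(
        "low-expression filter: kept %d/%d features (min_samples=%d)",
        len(retained), counts.n_features, min_samples,
    )
    return retained


def min_samples_from_fraction(n_samples: int, fraction: float = 0.20) -> int:
    """Alternative parameterization of the filter: a fraction of the cohort.

    Rounded up so the resulting cut is at least as strict as the fraction.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return max(1, math.ceil(fraction * n_samples))


def align_samples(expr: ExpressionMatrix, gebv: GEBVMatrix):
    """Restrict both matrices to their common samples, in the expression order.

    Returns a ``(ExpressionMatrix, GEBVMatrix)`` pair with identical
    ``sample_ids`` sequences. Raises if the two sample sets are disjoint.
    """
    common = [s for s in expr.sample_ids if s in set(gebv.sample_ids)]
    if not common:
        raise ValueError(
            "no samples in common between expression "
            f"({expr.n_samples} samples) and GEBV ({gebv.n_samples} samples) matrices"
        )
    expr_out = type(expr)(expr.data[common], expr.feature_role)
    gebv_out = GEBVMatrix(gebv.data.loc[common])
    return expr_out, gebv_out


def log_scale(counts: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(count + pseudocount) convenience transform.

    A plain monotone scaling used so synthetic count data can flow through
    the network stages; real data should arrive already normalized by a
    proper variance-stabilizing method.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = np.log2(counts.data.to_numpy(dtype=float) + pseudocount)
    import pandas as pd

    df = pd.DataFrame(values, index=counts.data.index, columns=counts.data.columns)
    return ExpressionMatrix(df, counts.feature_role)
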