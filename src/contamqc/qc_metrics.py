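"""Repeatability and reproducibility metrics between batches and runs.

Intraclass correlation (ICC) quantifies how well per-taxon summaries agree
between batches treated as "raters" of the same taxa: the absolute-agreement
two-way random single-measurement form ICC(2,1) penalises systematic
between-batch shifts, while the consistency two-way fixed form ICC(3,1)
tolerates them.  Both come from the two-way ANOVA mean squares.

``batch_pairing`` builds the per-taxon (batch 1, batch 2) summary pairs that
feed the ICCs and scatter exports; ``correlation_structure`` computes the
within-group Spearman correlation matrix among sufficiently abundant taxa —
reagent contaminants co-vary strongly within a batch whereas genuine taxa
do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable, SampleRecord, metadata_by_id, prevalence, relative_abundance

logger = logging.getLogger(__name__)

VARIANTS = ("agreement_2way_random_single", "consistency_2way_fixed_single")
_SHORT = {"agreement": VARIANTS[0], "consistency": VARIANTS[1]}


@dataclass
class IccResult:
    """Intraclass correlation with its ANOVA components."""

    value: float
    variant: str
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int


def icc(x: np.ndarray | pd.DataFrame, variant: str = "agreement_2way_random_single") -> IccResult:
    """Single-measurement ICC from a complete subjects x raters matrix.

    With two-way ANOVA mean squares MSR (subjects), MSC (raters), MSE and
    k raters over n subjects:

        agreement (2,1):   (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        consistency (3,1): (MSR - MSE) / (MSR + (k-1) MSE)

    A fully degenerate matrix (every entry identical) returns 1 by
    convention, with a log message.
    """
    variant = _SHORT.get(variant, variant)
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS} or {list(_SHORT)}")
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be a 2-D subjects x raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - gm) ** 2)
    ssc = n * np.sum((col_means - gm) ** 2)
    sst = np.sum((x - gm) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse, 0.0) / ((n - 1) * (k - 1))
    if msr == 0.0 and mse == 0.0:
        logger.info("icc: degenerate constant matrix; returning 1 by convention")
        value = 1.0
    elif variant == "agreement_2way_random_single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        value = (msr - mse) / denom if denom != 0 else 1.0
    else:
        denom = msr + (k - 1) * mse
        value = (msr - mse) / denom if denom != 0 else 1.0
    return IccResult(float(value), variant, float(msr), float(msc), float(mse), n, k)


def batch_pairing(
    table: FeatureTable,
    metadata: Iterable[SampleRecord],
    statistic: str = "mean_relative_abundance",
    sample_types: Sequence[str] = ("biological",),
    log_transform: bool = False,
    pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Per-taxon (batch 1, batch 2) summary pairs over the full taxon set.

    ``statistic`` is ``prevalence`` or ``mean_relative_abundance``; taxa
    absent from a batch enter as zeros rather than being dropped.  Columns
    are named after the two batch labels.  ``log_transform`` applies
    log10(x + pseudocount) to the paired values.
    """
    if statistic not in ("prevalence", "mean_relative_abundance"):
        raise ValueError(f"unknown statistic {statistic!r}")
    by_id = metadata_by_id(metadata)
    keep = [
        s for s in table.sample_ids
        if s in by_id and by_id[s].sample_type in sample_types
    ]
    batches = sorted({by_id[s].batch for s in keep})
    if len(batches) != 2:
        raise ValueError(f"expected exactly 2 batches, found {batches}")
    cols = {}
    for b in batches:
        members = [s for s in keep if by_id[s].batch == b]
        if not members:
            raise ValueError(f"batch {b!r} is empty")
        if statistic == "prevalence":
            cols[b] = prevalence(table, members)
        else:
            rel = relative_abundance(table.subset_samples(members))
            cols[b] = rel.mean(axis=1).reindex(table.taxon_ids).fillna(0.0)
    out = pd.DataFrame(cols)
    if log_transform:
        out = np.log10(out + pseudocount)
    return out


def correlation_structure(
    table: FeatureTable,
    sample_subset: Sequence[str],
    taxa_subset: Sequence[str] | None = None,
    min_mean_abundance: float = 0.001,
) -> pd.DataFrame:
    """Spearman correlation matrix among abundant taxa over a sample group.

    Restricted to taxa whose mean relative abundance over the subset is at
    least ``min_mean_abundance`` (default 0.1%).  Constant taxa yield NaN
    correlations (undefined ranks); the diagonal is 1.
    """
    if len(sample_subset) < 3:
        raise ValueError("need >= 3 samples for a correlation structure")
    sub = table.subset_samples(list(sample_subset))
    rel = relative_abundance(sub)
    mean_ab = rel.mean(axis=1)
    taxa = [t for t in rel.index if mean_ab[t] >= min_mean_abundance]
    if taxa_subset is not None:
        wanted = set(taxa_subset)
        taxa = [t for t in taxa if t in wanted]
    if len(taxa) < 2:
        return pd.DataFrame(np.ones((len(taxa), len(taxa))), index=taxa, columns=taxa)
    mat = rel.loc[taxa].to_numpy().T  # samples x taxa
    with np.errstate(invalid="ignore"):
        rho = stats.spearmanr(mat).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    constant = mat.std(axis=0) == 0
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=taxa, columns=taxa)
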