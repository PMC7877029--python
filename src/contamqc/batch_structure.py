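"""Second-tier contaminant identification from cross-batch prevalence structure.

Reagent contamination is consistent within a batch (same kit lots) but varies
between batches, while genuine community members should be detected at
comparable rates everywhere.  A taxon is therefore suspect when its
prevalence in one group of samples falls far below what its prevalence in
the other group predicts, after allowing for sampling error in both.

For a prevalence P observed over N samples the standard error of prevalence
is taken as

    SEP = sqrt(P * (1 - P)) / N

(the conventional sqrt(P(1-P)/N) is available behind ``conventional=True``),
and the minimum acceptable prevalence in the *other* group is

    T = (P - (SEP_a + SEP_b)) * k

with a stringency factor k in [0, 1], default 0.067.  A taxon with
p_other < T (strict) is called a contaminant of the higher-prevalence group.
Comparisons run pairwise between sequencing runs within a batch and between
batches; calls are unioned with provenance.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, SampleRecord, metadata_by_id, prevalence

logger = logging.getLogger(__name__)

DEFAULT_K = 0.067


def sep(p: float | np.ndarray, n: int, conventional: bool = False) -> float | np.ndarray:
    """Standard error of prevalence for proportion ``p`` over ``n`` samples.

    Default form is sqrt(p*(1-p)) / n; ``conventional=True`` gives the
    binomial-proportion form sqrt(p*(1-p)/n).  Zero at p in {0, 1}.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("prevalence must be in [0, 1]")
    if n < 1:
        raise ValueError("group size must be >= 1")
    if conventional:
        out = np.sqrt(p * (1.0 - p) / n)
    else:
        out = np.sqrt(p * (1.0 - p)) / n
    return float(out) if out.ndim == 0 else out


def acceptance_threshold(
    p: float | np.ndarray,
    sep_a: float | np.ndarray,
    sep_b: float | np.ndarray,
    k: float = DEFAULT_K,
) -> float | np.ndarray:
    """Minimum acceptable cross-group prevalence T = (p - (sep_a + sep_b)) * k.

    May be negative (then nothing can be flagged, since verdicts require the
    other group's prevalence to fall strictly below T).
    """
    if not 0 <= k <= 1:
        raise ValueError("k must be in [0, 1]")
    t = (np.asarray(p, dtype=float) - (np.asarray(sep_a) + np.asarray(sep_b))) * k
    return float(t) if t.ndim == 0 else t


def compare_groups(
    table: FeatureTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    k: float = DEFAULT_K,
    detection_threshold: int = 1,
    conventional_sep: bool = False,
    label: str = "a-vs-b",
) -> pd.DataFrame:
    """Pairwise prevalence-structure comparison of two disjoint sample groups.

    For every taxon detected in at least one group, computes prevalences,
    their standard errors and the two acceptance thresholds, and assigns a
    verdict: ``contaminant_of_a`` when p_b < T_a, ``contaminant_of_b`` when
    p_a < T_b (both strict), else ``clean``.  The two conditions are mutually
    exclusive for k <= 1.

    Returns a DataFrame indexed by taxon with columns p_a, p_b, n_a, n_b,
    sep_a, sep_b, t_a, t_b, verdict, k, comparison.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)[:5]}")
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    p_a = prevalence(table, group_a, detection_threshold).to_numpy()
    p_b = prevalence(table, group_b, detection_threshold).to_numpy()
    n_a, n_b = len(group_a), len(group_b)
    s_a = sep(p_a, n_a, conventional_sep)
    s_b = sep(p_b, n_b, conventional_sep)
    t_a = acceptance_threshold(p_a, s_a, s_b, k)
    t_b = acceptance_threshold(p_b, s_a, s_b, k)
    flag_a = p_b < t_a  # taxon rides high in a, too rare in b
    flag_b = p_a < t_b
    assert not np.any(flag_a & flag_b), "verdicts cannot conflict for k <= 1"
    verdict = np.where(flag_a, "contaminant_of_a", np.where(flag_b, "contaminant_of_b", "clean"))
    out = pd.DataFrame(
        {
            "p_a": p_a, "p_b": p_b,
            "n_a": n_a, "n_b": n_b,
            "sep_a": s_a, "sep_b": s_b,
            "t_a": t_a, "t_b": t_b,
            "verdict": verdict,
            "k": k,
            "comparison": label,
        },
        index=pd.Index(table.taxon_ids, name="taxon_id"),
    )
    return out[(out["p_a"] > 0) | (out["p_b"] > 0)]


def flagged_ids(comparison: pd.DataFrame) -> list[str]:
    """Taxa flagged in either direction of a compare_groups result."""
    return list(comparison.index[comparison["verdict"] != "clean"])


def _biological_samples(
    table: FeatureTable, metadata: Iterable[SampleRecord]
) -> dict[str, SampleRecord]:
    """Biological samples only: technical and replicate controls are excluded
    from prevalence computations (too few to estimate prevalence, and mock /
    negative profiles are not community samples)."""
    by_id = metadata_by_id(metadata)
    return {
        s: by_id[s]
        for s in table.sample_ids
        if s in by_id and by_id[s].sample_type == "biological"
    }


def compare_batches(
    table: FeatureTable,
    metadata: Iterable[SampleRecord],
    k: float = DEFAULT_K,
    detection_threshold: int = 1,
    conventional_sep: bool = False,
) -> pd.DataFrame:
    """Between-batch comparison over biological samples.

    Requires exactly two batches among biological samples; group a is the
    lexically first batch label.
    """
    bio = _biological_samples(table, metadata)
    batches = sorted({r.batch for r in bio.values()})
    if len(batches) != 2:
        raise ValueError(f"expected exactly 2 batches, found {batches}")
    a = [s for s, r in bio.items() if r.batch == batches[0]]
    b = [s for s, r in bio.items() if r.batch == batches[1]]
    return compare_groups(
        table, a, b, k, detection_threshold, conventional_sep,
        label=f"batch:{batches[0]}-vs-{batches[1]}",
    )


def pairwise_within_batch(
    table: FeatureTable,
    metadata: Iterable[SampleRecord],
    batch: str,
    k: float = DEFAULT_K,
    detection_threshold: int = 1,
    conventional_sep: bool = False,
) -> tuple[set[str], pd.DataFrame]:
    """Between-run comparisons within one batch; union of flagged taxa.

    Runs compare_groups on every unordered pair of sequencing runs in the
    batch and unions the flags, keeping per-pair provenance rows.  A single
    run yields an empty result with a warning.
    """
    bio = _biological_samples(table, metadata)
    in_batch = {s: r for s, r in bio.items() if r.batch == batch}
    if not in_batch:
        raise ValueError(f"no biological samples in batch {batch!r}")
    runs = sorted({r.run for r in in_batch.values()})
    if len(runs) < 2:
        logger.warning("batch %r has a single run; no between-run comparison", batch)
        return set(), pd.DataFrame()
    flagged: set[str] = set()
    parts = []
    for ra, rb in itertools.combinations(runs, 2):
        ga = [s for s, r in in_batch.items() if r.run == ra]
        gb = [s for s, r in in_batch.items() if r.run == rb]
        cmp = compare_groups(
            table, ga, gb, k, detection_threshold, conventional_sep,
            label=f"run:{batch}:{ra}-vs-{rb}",
        )
        flagged |= set(flagged_ids(cmp))
        parts.append(cmp[cmp["verdict"] != "clean"])
    prov = pd.concat(parts) if parts else pd.DataFrame()
    return flagged, prov


def combine_calls(call_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Union taxon-id sets from several analyses with provenance.

    ``call_sets`` maps an analysis label to the taxa it flagged.  Returns a
    DataFrame indexed by taxon with columns ``analyses`` (comma-joined
    labels) and ``n_analyses``.
    """
    prov: dict[str, list[str]] = {}
    for analysis_label, ids in call_sets.items():
        for t in ids:
            prov.setdefault(t, []).append(analysis_label)
    rows = [
        {"taxon_id": t, "analyses": ",".join(labels), "n_analyses": len(labels)}
        for t, labels in sorted(prov.items())
    ]
    return pd.DataFrame(rows, columns=["taxon_id", "analyses", "n_analyses"]).set_index("taxon_id")
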