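"""First-tier contaminant identification from negative controls and DNA yield.

Reagent contaminants ("kitome") contribute a roughly fixed amount of DNA per
reaction, so in a low-biomass sample their *relative* frequency falls as the
sample's own DNA concentration rises, and they dominate template-free
negative controls.  Two per-taxon scores capture these signatures:

* ``frequency_score`` — an F-type comparison, in log10-log10 space, of a
  fixed-slope -1 model (relative frequency inversely proportional to DNA
  concentration: contaminant-like) against a constant-frequency model
  (concentration-independent: non-contaminant-like).  Small scores are
  contaminant-like.
* ``prevalence_score`` — a one-sided Fisher exact (hypergeometric tail)
  p-value for the taxon being over-represented in negative controls.

``is_contaminant`` combines the scores per taxon under the classification
rules (frequency / prevalence / either / both / combined) with a single
threshold, 0.5 by default.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable, SampleRecord, relative_abundance

logger = logging.getLogger(__name__)

METHODS = ("frequency", "prevalence", "either", "both", "combined")

#: minimum usable (freq > 0, DNA known) samples for the frequency fit
MIN_FREQUENCY_POINTS = 5


def frequency_score(freqs: np.ndarray, dna: np.ndarray) -> float:
    """Score the inverse relation between relative frequency and DNA conc.

    Fits two one-parameter models to (log10 d, log10 f) over usable samples
    (f > 0, d > 0):  contaminant, log f = -log d + a;  non-contaminant,
    log f = b.  With residual sums of squares S_c and S_n over m points the
    score is the upper tail of F(m-1, m-1) at S_n / S_c: 1 when frequency is
    concentration-independent, 0 when frequency tracks 1/d exactly.

    Returns NaN (logged) with fewer than ``MIN_FREQUENCY_POINTS`` usable
    samples, or in the degenerate case where both models fit perfectly.
    """
    freqs = np.asarray(freqs, dtype=float)
    dna = np.asarray(dna, dtype=float)
    if freqs.shape != dna.shape:
        raise ValueError("freqs and dna must be aligned")
    usable = (freqs > 0) & (dna > 0) & np.isfinite(freqs) & np.isfinite(dna)
    m = int(usable.sum())
    if m < MIN_FREQUENCY_POINTS:
        logger.debug("frequency_score: only %d usable samples (< %d)", m, MIN_FREQUENCY_POINTS)
        return float("nan")
    lf = np.log10(freqs[usable])
    ld = np.log10(dna[usable])
    # contaminant model: residuals of (lf + ld) about its mean (slope fixed -1)
    u = lf + ld
    s_c = float(np.sum((u - u.mean()) ** 2))
    # non-contaminant model: residuals of lf about its mean (slope 0)
    s_n = float(np.sum((lf - lf.mean()) ** 2))
    if s_c == 0.0 and s_n == 0.0:
        logger.debug("frequency_score: degenerate fit (constant f and constant f*d)")
        return float("nan")
    if s_c == 0.0:
        return 0.0
    return float(stats.f.sf(s_n / s_c, m - 1, m - 1))


def prevalence_score(
    present_in_samples: int,
    n_samples: int,
    present_in_negatives: int,
    n_negatives: int,
) -> float:
    """One-sided hypergeometric tail for enrichment in negative controls.

    Probability, under random allocation of the taxon's presences across all
    units, of at least the observed number of presences among negatives.
    Small when the taxon is disproportionately present in negative controls.
    """
    if not (0 <= present_in_negatives <= n_negatives):
        raise ValueError("present_in_negatives outside [0, n_negatives]")
    if not (0 <= present_in_samples <= n_samples):
        raise ValueError("present_in_samples outside [0, n_samples]")
    k_total = present_in_samples + present_in_negatives
    if k_total == 0:
        raise ValueError("taxon present nowhere")
    m_total = n_samples + n_negatives
    return float(stats.hypergeom.sf(present_in_negatives - 1, m_total, k_total, n_negatives))


def _fisher_combined(scores: list[float]) -> float:
    """Fisher's combination of p-like scores (chi-square, 2 df per score)."""
    clipped = [min(max(s, 1e-300), 1.0) for s in scores]
    stat = -2.0 * sum(np.log(s) for s in clipped)
    return float(stats.chi2.sf(stat, 2 * len(clipped)))


def is_contaminant(
    table: FeatureTable,
    metadata: Iterable[SampleRecord],
    method: str = "either",
    threshold: float = 0.5,
    detection_threshold: int = 1,
) -> pd.DataFrame:
    """Per-taxon contaminant classification against a score threshold.

    Frequency scores are fitted on biological samples with known DNA
    concentration; prevalence scores contrast biological samples with pooled
    negative controls from all batches.  The verdict rule per ``method``:
    ``frequency`` / ``prevalence`` use that score alone; ``either`` flags
    when the smaller defined score is below threshold, ``both`` when the
    larger is; ``combined`` applies Fisher's combination of the defined
    scores.  Taxa with no defined score are left unscored (verdict NA).

    Returns a DataFrame indexed by taxon with columns freq_score,
    prev_score, score (the value the rule compared), verdict, method.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    records = list(metadata)
    by_id = {r.sample_id: r for r in records}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")

    bio = [s for s in table.sample_ids if by_id[s].sample_type == "biological"]
    neg = [s for s in table.sample_ids if by_id[s].sample_type == "negative_control"]
    bio_dna = [
        s for s in bio
        if by_id[s].dna_concentration is not None and by_id[s].dna_concentration > 0
    ]

    use_freq = method in ("frequency", "either", "both", "combined")
    use_prev = method in ("prevalence", "either", "both", "combined")
    if method == "frequency" and len(bio_dna) < MIN_FREQUENCY_POINTS:
        raise ValueError(
            "frequency method requires >= "
            f"{MIN_FREQUENCY_POINTS} biological samples with dna_concentration"
        )
    if method == "prevalence" and not neg:
        raise ValueError("prevalence method requires negative-control samples")
    if len(bio_dna) < MIN_FREQUENCY_POINTS:
        use_freq = False
    if not neg:
        use_prev = False
    if not use_freq and not use_prev:
        raise ValueError(
            "neither DNA concentrations nor negative controls available; "
            "no score can be computed"
        )

    freq_scores = pd.Series(np.nan, index=table.taxon_ids)
    if use_freq:
        rel = relative_abundance(table.subset_samples(bio_dna))
        dna = np.array([by_id[s].dna_concentration for s in rel.columns])
        for t in table.taxon_ids:
            freq_scores[t] = frequency_score(rel.loc[t].to_numpy(), dna)

    prev_scores = pd.Series(np.nan, index=table.taxon_ids)
    if use_prev:
        bio_counts = table.subset_samples(bio).counts >= detection_threshold
        neg_counts = table.subset_samples(neg).counts >= detection_threshold
        pb = bio_counts.sum(axis=1)
        pn = neg_counts.sum(axis=1)
        for i, t in enumerate(table.taxon_ids):
            if pb[i] + pn[i] > 0:
                prev_scores[t] = prevalence_score(int(pb[i]), len(bio), int(pn[i]), len(neg))

    rows = []
    for t in table.taxon_ids:
        fs, ps = float(freq_scores[t]), float(prev_scores[t])
        defined = [s for s in (fs, ps) if not np.isnan(s)]
        if not defined:
            score, verdict = float("nan"), pd.NA
        else:
            if method == "frequency":
                score = fs
            elif method == "prevalence":
                score = ps
            elif method == "either":
                score = min(defined)
            elif method == "both":
                score = max(defined)
            else:  # combined
                score = _fisher_combined(defined) if len(defined) > 1 else defined[0]
            verdict = bool(score < threshold) if not np.isnan(score) else pd.NA
        rows.append(
            {"taxon_id": t, "freq_score": fs, "prev_score": ps,
             "score": score, "verdict": verdict, "method": method}
        )
    out = pd.DataFrame(rows).set_index("taxon_id")
    n_unscored = int(out["verdict"].isna().sum())
    if n_unscored:
        logger.info("is_contaminant: %d taxa unscored (no usable data)", n_unscored)
    return out


def contaminant_ids(calls: pd.DataFrame) -> list[str]:
    """Taxon ids with a True verdict."""
    return list(calls.index[calls["verdict"] == True])  # noqa: E712 (NA-safe)


def unscored_ids(calls: pd.DataFrame) -> list[str]:
    return list(calls.index[calls["verdict"].isna()])


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index_label="taxon_id")
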