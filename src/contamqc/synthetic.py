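"""Synthetic two-batch low-biomass studies with ground-truth labels.

The generator emulates the statistical structure that the two-tier
contaminant framework relies on:

* one shared "true" community across both batches (expected composition
  drawn once from a normalized log-normal; per-sample compositions from a
  Dirichlet centered on it);
* a disjoint reagent-contaminant profile per batch, consistent within the
  batch: each contaminant taxon carries a fixed pseudo-load added to the
  sample's expected DNA mixture, so its *relative* frequency falls as the
  sample's own DNA concentration rises;
* template-free negative controls containing contaminants only;
* a known-proportion 8-taxon mock community;
* biological controls — the same latent sample sequenced in both batches;
* sequencing depths drawn negative-binomially, counts multinomially.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_table import (
    RANKS,
    FeatureTable,
    SampleRecord,
    TaxonAnnotation,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    write_feature_table,
    write_metadata,
    write_taxonomy,
)

TRUE_LABEL = "true_taxon"


def _contaminant_label(batch_index: int) -> str:
    return f"contaminant_batch{batch_index + 1}"


@dataclass
class SimulationConfig:
    """Study-design and distributional knobs of the simulator.

    Defaults describe a two-batch milk-microbiota-like study: 200
    biological samples per batch over 2 sequencing runs each, 300 genuine
    taxa, 40 reagent contaminants per batch with per-reaction loads drawn
    once per batch, DNA concentrations log-normal around 1 (arbitrary
    units), depths around 20k reads, 12 negative controls and 8 mock
    samples per batch, and 9 replicate biological controls.
    """

    samples_per_batch: tuple[int, int] = (200, 200)
    runs_per_batch: tuple[int, int] = (2, 2)
    n_true_taxa: int = 300
    n_contaminants_per_batch: tuple[int, int] = (40, 40)
    true_abundance_lognormal_sigma: float = 2.0
    dirichlet_concentration: float = 50.0
    dna_lognormal: tuple[float, float] = (0.0, 0.7)
    contaminant_load_range: tuple[float, float] = (0.005, 0.03)
    depth_negbinom: tuple[float, float] = (20000.0, 10.0)  # (mean, dispersion size)
    n_negative_controls_per_batch: tuple[int, int] = (12, 12)
    n_biological_controls: int = 9
    n_mock_per_batch: tuple[int, int] = (8, 8)
    mock_proportions: tuple[float, ...] = (0.125,) * 8
    run_contaminants_per_run: int = 0  # extra contaminants confined to one run
    seed: int = 0

    def validate(self) -> None:
        if self.n_true_taxa < 1:
            raise ValueError("n_true_taxa must be >= 1")
        for pair_name in ("samples_per_batch", "runs_per_batch"):
            if any(v < 1 for v in getattr(self, pair_name)):
                raise ValueError(f"{pair_name} entries must be >= 1")
        if any(v < 0 for v in self.n_contaminants_per_batch):
            raise ValueError("n_contaminants_per_batch entries must be >= 0")
        if any(v < 0 for v in self.n_negative_controls_per_batch):
            raise ValueError("n_negative_controls_per_batch entries must be >= 0")
        if self.n_biological_controls < 0:
            raise ValueError("n_biological_controls must be >= 0")
        props = np.asarray(self.mock_proportions, dtype=float)
        if len(props) != 8 or (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("mock_proportions must be 8 non-negative fractions summing to 1")
        lo, hi = self.contaminant_load_range
        if not (0 < lo <= hi):
            raise ValueError("contaminant_load_range must be a positive interval")


@dataclass
class SimTruth:
    """Ground truth: per-taxon label, latent DNA and latent compositions."""

    labels: pd.Series                 # taxon -> label (3-way partition)
    dna: pd.Series                    # sample -> latent DNA concentration
    true_composition: pd.DataFrame    # true taxa x biological(+control) samples
    mock_taxa: list[str] = field(default_factory=list)
    run_of_contaminant: pd.Series | None = None  # run-confined contaminants

    def taxa_with_label(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def contaminants(self) -> list[str]:
        return list(self.labels.index[self.labels != TRUE_LABEL])


@dataclass
class SimulatedStudy:
    table: FeatureTable
    metadata: list[SampleRecord]
    annotations: list[TaxonAnnotation]
    truth: SimTruth
    config: SimulationConfig


_PHYLA = ("Firmicutes", "Proteobacteria", "Actinobacteria", "Bacteroidetes")


def _lineage_for(taxon: str, i: int) -> TaxonAnnotation:
    phylum = _PHYLA[i % len(_PHYLA)]
    return TaxonAnnotation(
        taxon,
        ("Bacteria", phylum, f"Class_{i % 11}", f"Order_{i % 17}",
         f"Family_{i % 29}", f"Genus_{i}", "unassigned"),
    )


def _draw_depth(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    d = rng.negative_binomial(size_param, p, size=n)
    return np.maximum(d, 1)


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a complete two-batch study bundle with ground truth."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_true = config.n_true_taxa
    true_taxa = [f"ASV_T{i:04d}" for i in range(n_true)]
    contam_taxa: list[list[str]] = []
    run_contam: dict[str, dict] = {}  # taxon -> {"batch": b, "run": run label}
    for b in range(2):
        base = [f"ASV_C{b + 1}_{i:03d}" for i in range(config.n_contaminants_per_batch[b])]
        if config.run_contaminants_per_run > 0:
            for r in range(config.runs_per_batch[b]):
                for i in range(config.run_contaminants_per_run):
                    t = f"ASV_R{b + 1}_{r + 1}_{i:03d}"
                    base.append(t)
                    run_contam[t] = {"batch": b, "run": f"run{b + 1}.{r + 1}"}
        contam_taxa.append(base)
    mock_taxa = [f"ASV_M{i}" for i in range(8)]
    all_taxa = true_taxa + contam_taxa[0] + contam_taxa[1] + mock_taxa
    tx_index = {t: i for i, t in enumerate(all_taxa)}

    # shared true community
    theta = rng.lognormal(0.0, config.true_abundance_lognormal_sigma, n_true)
    theta /= theta.sum()

    # per-batch contaminant pseudo-loads, drawn once (within-batch consistency)
    lo, hi = config.contaminant_load_range
    loads = [rng.uniform(lo, hi, len(contam_taxa[b])) for b in range(2)]

    mu_d, sigma_d = config.dna_lognormal
    depth_mean, depth_size = config.depth_negbinom
    mock_props = np.asarray(config.mock_proportions, dtype=float)

    counts_cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    records: list[SampleRecord] = []
    dna_latent: dict[str, float] = {}
    comps: dict[str, np.ndarray] = {}

    def add_sample(sid, batch_idx, run, stype, mixture, dna, comp=None):
        mixture = np.asarray(mixture, dtype=float)
        if mixture.sum() == 0:
            # template-free control in a contaminant-free design: nothing amplifies
            counts_cols.append(np.zeros(len(all_taxa), dtype=np.int64))
        else:
            mixture = mixture / mixture.sum()
            depth = _draw_depth(rng, depth_mean, depth_size, 1)[0]
            counts_cols.append(rng.multinomial(depth, mixture))
        sample_ids.append(sid)
        records.append(SampleRecord(sid, f"batch{batch_idx + 1}", run, stype, dna))
        dna_latent[sid] = dna
        if comp is not None:
            comps[sid] = comp

    def full_mixture(batch_idx, true_comp, dna):
        mix = np.zeros(len(all_taxa))
        mix[: n_true] = dna * true_comp
        offset = n_true + (len(contam_taxa[0]) if batch_idx == 1 else 0)
        mix[offset: offset + len(contam_taxa[batch_idx])] = loads[batch_idx]
        return mix

    alpha = config.dirichlet_concentration * theta

    # biological samples
    for b in range(2):
        runs = [f"run{b + 1}.{r + 1}" for r in range(config.runs_per_batch[b])]
        for i in range(config.samples_per_batch[b]):
            run = runs[i % len(runs)]
            comp = rng.dirichlet(alpha)
            dna = rng.lognormal(mu_d, sigma_d)
            mix = full_mixture(b, comp, dna)
            if config.run_contaminants_per_run > 0:
                # zero out run contaminants not belonging to this run
                for t, info in run_contam.items():
                    if info["batch"] == b and info["run"] != run:
                        mix[tx_index[t]] = 0.0
            add_sample(f"B{b + 1}S{i + 1:03d}", b, run, "biological", mix, dna, comp)

    # biological controls: one latent sample sequenced in both batches
    for j in range(config.n_biological_controls):
        comp = rng.dirichlet(alpha)
        for b in range(2):
            run = f"run{b + 1}.1"
            dna = rng.lognormal(mu_d, sigma_d)
            mix = full_mixture(b, comp, dna)
            if config.run_contaminants_per_run > 0:
                for t, info in run_contam.items():
                    if info["batch"] == b and info["run"] != run:
                        mix[tx_index[t]] = 0.0
            add_sample(f"BC{j + 1:02d}_b{b + 1}", b, run, "biological_control", mix, dna, comp)

    # negative controls: contaminant profile only, tiny DNA yield
    for b in range(2):
        for j in range(config.n_negative_controls_per_batch[b]):
            dna = rng.lognormal(mu_d - 4.0, 0.3)
            mix = np.zeros(len(all_taxa))
            offset = n_true + (len(contam_taxa[0]) if b == 1 else 0)
            if len(contam_taxa[b]):
                mix[offset: offset + len(contam_taxa[b])] = loads[b]
            if config.run_contaminants_per_run > 0:
                for t, info in run_contam.items():
                    if info["batch"] == b and info["run"] != f"run{b + 1}.1":
                        mix[tx_index[t]] = 0.0
            add_sample(f"NC{b + 1}_{j + 1:02d}", b, f"run{b + 1}.1", "negative_control", mix, dna)

    # mock community: high biomass, known proportions, no overlay
    for b in range(2):
        for j in range(config.n_mock_per_batch[b]):
            dna = rng.lognormal(mu_d + 2.0, 0.2)
            mix = np.zeros(len(all_taxa))
            mix[n_true + len(contam_taxa[0]) + len(contam_taxa[1]):] = mock_props
            add_sample(f"MOCK{b + 1}_{j + 1:02d}", b, f"run{b + 1}.1", "mock", mix, dna)

    counts = np.column_stack(counts_cols) if counts_cols else np.zeros((len(all_taxa), 0), int)
    table = FeatureTable(all_taxa, sample_ids, counts)

    labels = pd.Series(TRUE_LABEL, index=pd.Index(all_taxa, name="taxon_id"), name="label")
    for b in range(2):
        labels[contam_taxa[b]] = _contaminant_label(b)
    run_series = pd.Series(
        {t: info["run"] for t, info in run_contam.items()}, dtype=object, name="run"
    )
    truth = SimTruth(
        labels=labels,
        dna=pd.Series(dna_latent, name="dna"),
        true_composition=pd.DataFrame(comps, index=true_taxa),
        mock_taxa=mock_taxa,
        run_of_contaminant=run_series if len(run_series) else None,
    )
    annotations = [_lineage_for(t, i) for i, t in enumerate(all_taxa)]
    return SimulatedStudy(table, records, annotations, truth, config)


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(study: SimulatedStudy, directory: str | Path) -> list[Path]:
    """Write counts.tsv, metadata.tsv, taxonomy.tsv and truth.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "metadata": directory / "metadata.tsv",
        "taxonomy": directory / "taxonomy.tsv",
        "truth": directory / "truth.tsv",
    }
    write_feature_table(study.table, paths["counts"])
    write_metadata(study.metadata, paths["metadata"])
    write_taxonomy(study.annotations, paths["taxonomy"])
    truth_df = study.truth.labels.to_frame()
    truth_df["run"] = (
        study.truth.run_of_contaminant.reindex(truth_df.index).fillna("")
        if study.truth.run_of_contaminant is not None
        else ""
    )
    truth_df.to_csv(paths["truth"], sep="\t")
    return list(paths.values())


def read_fixture(directory: str | Path):
    """Read back a fixture directory: (table, metadata, annotations, truth labels)."""
    directory = Path(directory)
    table = read_feature_table(directory / "counts.tsv")
    metadata = read_metadata(directory / "metadata.tsv")
    annotations = read_taxonomy(directory / "taxonomy.tsv")
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", index_col=0)
    return table, metadata, annotations, truth


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
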