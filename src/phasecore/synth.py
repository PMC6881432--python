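"""Synthetic studies emulating a multi-design phase-polyphenism experiment.

Three expression datasets are generated with the statistical structure the
downstream analysis assumes:

* a **development** design: 6 developmental stages x 2 phases (12 samples),
* a **tissue** design: 8 tissues/organs x 2 phases (16 samples),
* a **time-course** design: 2 tissues x 2 transition directions
  (CS = crowding of solitary animals, IG = isolation of gregarious animals)
  x 6 time points (24 samples), with the phase effect attenuated to zero at
  the final time point so the two directions converge there.

A configurable fraction of genes is planted with a phase-biased expression
shift that is deliberately smaller than the between-level confounder shift:
ordinary PCA then separates samples by stage/tissue/time, not by phase,
which is exactly the failure mode confounder-adjusted PCA corrects.

A planted TF->target network, synthetic gene sequences with a controllable
CpG dinucleotide depletion, per-gene methylation tables, and arena-behavior
records round out the study so every downstream stage is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, write_expression_tsv, write_metadata_tsv

DEV_STAGES = ["egg", "instar12", "instar3", "instar4", "instar5", "adult"]
TISSUES8 = ["brain", "ganglia", "antenna", "wing", "pronotum",
            "fatbody", "hemolymph", "antenna_adult"]
TC_TISSUES = ["brain", "ganglia"]
TC_TREATMENTS = ["CS", "IG"]  # CS -> becoming gregarious, IG -> becoming solitary
TC_TIMEPOINTS = [0, 4, 8, 16, 32, 64]
#: Multiplier on the planted phase effect per time point; the transition
#: courses converge (multiplier 0) at the final time point.
TC_PHASE_SCHEDULE = {0: 1.0, 4: 1.0, 8: 0.8, 16: 0.6, 32: 0.4, 64: 0.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; the seed fully determines the output."""

    n_genes: int = 2000
    core_fraction: float = 0.10
    phase_effect: float = 1.0       # log2 between-phase shift of planted genes
    confounder_effect: float = 5.0  # width of the uniform log2 between-level shift
    noise_sd: float = 0.5           # log2 residual s.d.
    dispersion: float = 0.05        # negative-binomial dispersion of counts
    n_tfs: int = 50
    targets_per_tf: int = 20
    tf_effect: float = 1.0          # coupling of targets to TF signal
    mean_depth: float = 150.0       # sequencing depth, millions of reads
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_tfs <= 0:
            raise ValueError("n_tfs must be positive")
        if not 0.0 < self.core_fraction < 1.0:
            raise ValueError("core_fraction must be in (0, 1)")
        for name in ("phase_effect", "confounder_effect", "noise_sd",
                     "dispersion", "tf_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.targets_per_tf < 0:
            raise ValueError("targets_per_tf must be >= 0")
        if self.n_tfs + self.targets_per_tf > self.n_genes:
            raise ValueError("network does not fit into n_genes genes")


@dataclass
class SyntheticStudy:
    """A generated study plus the latent truth needed by tests."""

    config: SimulationConfig
    datasets: dict[str, ExpressionDataset]
    latent: dict[str, pd.DataFrame]      # log2 latent signal, genes x samples
    truth_core: pd.Series                # gene_id -> +1 (G-biased) / -1 (S-biased)
    truth_edges: pd.DataFrame            # columns tf, target, sign
    tf_ids: list[str]
    gene_lengths: pd.Series
    sequences: dict[str, str] = field(default_factory=dict)
    methylation: pd.DataFrame | None = None
    behavior: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> pd.Index:
        return next(iter(self.datasets.values())).gene_ids


def _design_tables(n_genes: int) -> dict[str, pd.DataFrame]:
    """Sample metadata for the three study designs."""
    rows = []
    for stage in DEV_STAGES:
        for phase in ("G", "S"):
            rows.append((f"dev_{stage}_{phase}", phase, stage, "development",
                         np.nan, ""))
    dev = rows
    rows = []
    for tissue in TISSUES8:
        for phase in ("G", "S"):
            rows.append((f"tis_{tissue}_{phase}", phase, tissue, "tissue",
                         np.nan, ""))
    tis = rows
    rows = []
    for tissue in TC_TISSUES:
        for treat in TC_TREATMENTS:
            for tp in TC_TIMEPOINTS:
                phase = "G" if treat == "CS" else "S"
                rows.append((f"tc_{tissue}_{treat}_{tp}h", phase,
                             f"{tissue}_{tp}h", "timecourse", tp, treat))
    tc = rows
    cols = ["sample_id", "phase", "confounder_level", "dataset",
            "timepoint", "treatment"]
    out = {}
    for name, rows in (("development", dev), ("tissue", tis), ("timecourse", tc)):
        df = pd.DataFrame(rows, columns=cols).set_index("sample_id")
        out[name] = df
    return out


def _counts_from_latent(latent: np.ndarray, lengths: np.ndarray,
                        dispersion: float, mean_depth: float,
                        rng: np.random.Generator) -> np.ndarray:
    depth = mean_depth * rng.uniform(0.7, 1.3, size=latent.shape[1])
    mu = np.exp2(latent) * (lengths[:, None] / 1000.0) * depth[None, :]
    if dispersion == 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_studies(config: SimulationConfig) -> SyntheticStudy:
    """Generate the three expression datasets plus sequences, methylation
    and behavior under one latent model.

    The log2 latent signal of gene ``g`` in sample ``s`` is

    ``baseline_g + confounder_effect * z[g, level(s)]
    + sign_g * (phase_effect / 2) * phase_dir(s) * schedule(s)   (core genes)
    + tf_effect * sign_edge * driver_tf(s)                       (TF targets)
    + Normal(0, noise_sd)``

    where ``z`` is a standard-normal draw per gene and confounder level,
    ``phase_dir`` is +1 for gregarious and -1 for solitary samples, and a
    target's ``driver`` is its TF's own confounder-plus-phase signal.  Counts
    are negative-binomial draws around the exponentiated signal scaled by
    gene length and a per-sample sequencing depth.
    """
    rng = np.random.default_rng(config.seed)
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene_id")

    n_core = round(config.core_fraction * config.n_genes)
    core_genes = rng.choice(config.n_genes, size=n_core, replace=False)
    core_sign = rng.choice([1, -1], size=n_core)
    truth_core = pd.Series(core_sign, index=genes[core_genes], name="sign")

    # TFs are drawn outside the planted core so that the core genes' direct
    # phase shift is not compounded by inherited TF signal.
    non_core = np.setdiff1d(np.arange(config.n_genes), core_genes)
    tf_idx = rng.choice(non_core, size=config.n_tfs, replace=False)
    tf_ids = list(genes[tf_idx])
    non_tf = np.setdiff1d(np.arange(config.n_genes), tf_idx)
    edges = []
    for t in tf_idx:
        targets = rng.choice(non_tf, size=config.targets_per_tf, replace=False)
        signs = rng.choice([1, -1], size=config.targets_per_tf)
        for tgt, sgn in zip(targets, signs):
            edges.append((genes[t], genes[tgt], int(sgn)))
    truth_edges = pd.DataFrame(edges, columns=["tf", "target", "sign"])

    baseline = rng.normal(4.0, 1.5, size=config.n_genes)
    lengths = pd.Series(
        np.exp(rng.uniform(np.log(500), np.log(10_000), size=config.n_genes)),
        index=genes, name="length").round().astype(int)

    core_vec = np.zeros(config.n_genes)
    core_vec[core_genes] = core_sign

    metas = _design_tables(config.n_genes)
    datasets: dict[str, ExpressionDataset] = {}
    latents: dict[str, pd.DataFrame] = {}
    for name, meta in metas.items():
        # the dominant confounder: developmental stage, tissue, or (for the
        # time course) tissue plus a milder shared time drift that affects
        # both transition directions alike
        if name == "timecourse":
            tissues = pd.Index(pd.Series(meta.index).str.split("_").str[1].unique())
            tkey = pd.Series(meta.index).str.split("_").str[1].to_numpy()
            z = rng.uniform(-0.5, 0.5, size=(config.n_genes, len(tissues)))
            conf = config.confounder_effect * z[:, tissues.get_indexer(tkey)]
            tps = pd.Index(sorted(meta["timepoint"].unique()))
            drift = rng.normal(size=(config.n_genes, len(tps)))
            conf = conf + 0.5 * config.noise_sd * drift[
                :, tps.get_indexer(meta["timepoint"])]
            sched = meta["timepoint"].map(TC_PHASE_SCHEDULE).to_numpy(float)
        else:
            levels = pd.Index(meta["confounder_level"].unique())
            z = rng.uniform(-0.5, 0.5, size=(config.n_genes, len(levels)))
            conf = config.confounder_effect * z[:, levels.get_indexer(
                meta["confounder_level"])]
            sched = np.ones(len(meta))
        phase_dir = np.where(meta["phase"] == "G", 1.0, -1.0)
        phase = (core_vec[:, None] * (config.phase_effect / 2.0)
                 * (phase_dir * sched)[None, :])
        signal = baseline[:, None] + conf + phase

        # targets inherit their TF's confounder + phase signal
        if len(truth_edges):
            tf_pos = genes.get_indexer(truth_edges["tf"])
            tgt_pos = genes.get_indexer(truth_edges["target"])
            driver = conf[tf_pos, :] + phase[tf_pos, :]
            contrib = config.tf_effect * truth_edges["sign"].to_numpy()[:, None] * driver
            np.add.at(signal, tgt_pos, contrib)

        if config.noise_sd > 0:
            signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)

        latent = pd.DataFrame(signal, index=genes, columns=meta.index)
        counts = _counts_from_latent(signal, lengths.to_numpy(float),
                                     config.dispersion, config.mean_depth, rng)
        values = pd.DataFrame(counts, index=genes, columns=meta.index)
        datasets[name] = ExpressionDataset(values, meta, kind="counts",
                                           gene_lengths=lengths)
        latents[name] = latent

    sequences = simulate_sequences(config.n_genes, length=2000, gc_content=0.4,
                                   cpg_depletion=1.0,
                                   rng=rng, gene_ids=genes)
    methylation = _simulate_methylation(genes, rng)
    behavior = simulate_behavior(30, rng=rng)

    return SyntheticStudy(config=config, datasets=datasets, latent=latents,
                          truth_core=truth_core, truth_edges=truth_edges,
                          tf_ids=tf_ids, gene_lengths=lengths,
                          sequences=sequences, methylation=methylation,
                          behavior=behavior)


def simulate_sequences(n_genes: int, length: int, gc_content: float = 0.4,
                       cpg_depletion: float = 1.0, seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       gene_ids=None) -> dict[str, str]:
    """First-order Markov nucleotide sequences with a tunable CpG rate.

    Bases are drawn with the stationary composition implied by
    ``gc_content`` (C and G each at gc/2).  The C->G transition probability
    is set to ``d * pG * (1 - pC) / (1 - d * pC)`` with ``d =
    cpg_depletion``, and the displaced mass is moved to the A/T transitions,
    which keeps the C column of the chain intact; the expected CpG
    observed/expected ratio of long sequences is then ``d`` itself.
    """
    if length < 2:
        raise ValueError("sequence length must be >= 2 (CpG o/e undefined)")
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be in (0, 1)")
    if cpg_depletion <= 0:
        raise ValueError("cpg_depletion must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    p_c = p_g = gc_content / 2.0
    p_a = p_t = (1.0 - gc_content) / 2.0
    base = np.array([p_a, p_c, p_g, p_t])  # A, C, G, T
    d = cpg_depletion
    delta = d * p_g * (1.0 - p_c) / (1.0 - d * p_c)
    spill = p_g - delta
    row_c = np.array([p_a + spill * p_a / (p_a + p_t), p_c, delta,
                      p_t + spill * p_t / (p_a + p_t)])
    if (row_c < 0).any():
        raise ValueError("cpg_depletion too large for this gc_content")

    cum_base = np.cumsum(base)
    cum_c = np.cumsum(row_c)
    u = rng.random((n_genes, length))
    states = np.empty((n_genes, length), dtype=np.int8)
    states[:, 0] = np.searchsorted(cum_base, u[:, 0])
    for j in range(1, length):
        from_c = states[:, j - 1] == 1
        nxt = np.searchsorted(cum_base, u[:, j])
        if from_c.any():
            nxt[from_c] = np.searchsorted(cum_c, u[from_c, j])
        states[:, j] = nxt

    alphabet = np.array(list("ACGT"))
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    return {gid: "".join(alphabet[row]) for gid, row in zip(gene_ids, states)}


def _simulate_methylation(genes: pd.Index, rng: np.random.Generator,
                          mean_sites: float = 30.0) -> pd.DataFrame:
    """Per-gene CG-site methylation levels around a gene-level mean."""
    rows = []
    n_sites = rng.poisson(mean_sites, size=len(genes))
    gene_mean = rng.beta(2.0, 2.0, size=len(genes))
    for gid, k, m in zip(genes, n_sites, gene_mean):
        betas = np.clip(m + rng.normal(0.0, 0.15, size=k), 0.0, 1.0)
        for pos, b in enumerate(betas):
            rows.append((gid, pos * 50, b))
    return pd.DataFrame(rows, columns=["gene_id", "site_pos", "beta"])


def simulate_behavior(n_per_phase: int, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Arena-tracking records for gregarious and solitary animals.

    Gregarious animals spend more time near the stimulus group, move farther
    (total distance moved, TDM) and longer (total duration of movement,
    TDMV); solitary animals avoid the stimulus and move little.  Trial
    length is 300 s.
    """
    if n_per_phase < 0:
        raise ValueError("n_per_phase must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_per_phase):
        ds = rng.uniform(120, 200)
        do = rng.uniform(5, 50)
        rows.append((f"G{i:03d}", "G", ds, do,
                     abs(rng.normal(150, 40)), abs(rng.normal(90, 30))))
    for i in range(n_per_phase):
        ds = rng.uniform(5, 50)
        do = rng.uniform(120, 200)
        rows.append((f"S{i:03d}", "S", ds, do,
                     abs(rng.normal(25, 15)), abs(rng.normal(15, 10))))
    return pd.DataFrame(rows, columns=["animal_id", "phase", "dur_stimulus",
                                       "dur_opposite", "tdm", "tdmv"])


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write the study as plain-text files (TSV / FASTA)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, ds in study.datasets.items():
        write_expression_tsv(ds.values, outdir / f"{name}_counts.tsv")
        write_metadata_tsv(ds.meta, outdir / f"{name}_meta.tsv")
    study.gene_lengths.to_frame().to_csv(outdir / "gene_lengths.tsv", sep="\t",
                                         index_label="gene_id")
    study.truth_core.to_frame().to_csv(outdir / "truth_core.tsv", sep="\t",
                                       index_label="gene_id")
    study.truth_edges.to_csv(outdir / "truth_edges.tsv", sep="\t", index=False)
    pd.Series(study.tf_ids, name="tf_id").to_csv(outdir / "tfs.tsv", sep="\t",
                                                 index=False)
    if study.methylation is not None:
        study.methylation.to_csv(outdir / "methylation.tsv", sep="\t", index=False)
    if study.behavior is not None:
        study.behavior.to_csv(outdir / "behavior.tsv", sep="\t", index=False)
    if study.sequences:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO
        records = [SeqRecord(Seq(s), id=g, description="")
                   for g, s in study.sequences.items()]
        SeqIO.write(records, outdir / "sequences.fasta", "fasta")
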