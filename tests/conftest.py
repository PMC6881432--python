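import numpy as np
import pandas as pd
import pytest

from phasecore import SimulationConfig, simulate_studies


@pytest.fixture(scope="session")
def small_study():
    """A small three-design study for fast structural tests."""
    cfg = SimulationConfig(n_genes=300, core_fraction=0.1, n_tfs=10,
                           targets_per_tf=5, seed=11)
    return simulate_studies(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The study at the default conditions (2,000 genes, 10% planted core,
    phase effect 1, confounder effect 5, noise 0.5), fixed seed."""
    return simulate_studies(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_dev_dataset(n_genes=30, marker_genes=None, phase_delta=1.0,
                     base=6.0, seed=0, noise_sd=0.0):
    """Hand-built development-style RPKM dataset (6 stages x 2 phases).

    ``marker_genes`` get a deterministic +/- ``phase_delta`` log2 phase
    shift; other genes get stage-dependent values only.  No sampling noise,
    so phase separation on the marker genes is exact.
    """
    from phasecore.datasets import ExpressionDataset

    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    marker_genes = set(marker_genes or [])
    rows, meta_rows = [], []
    samples = []
    for stage in range(6):
        for phase in ("G", "S"):
            sid = f"s{stage}_{phase}"
            samples.append(sid)
            meta_rows.append((sid, phase, f"stage{stage}", "development"))
    values = np.zeros((n_genes, len(samples)))
    stage_effect = rng.uniform(-2, 2, size=(n_genes, 6))
    for j, sid in enumerate(samples):
        stage = int(sid[1])
        phase = sid.split("_")[1]
        for i, g in enumerate(genes):
            v = base + stage_effect[i, stage]
            if g in marker_genes:
                v += (phase_delta / 2) if phase == "G" else -(phase_delta / 2)
            if noise_sd:
                v += rng.normal(0.0, noise_sd)
            values[i, j] = v
    rpkm = pd.DataFrame(np.exp2(values), index=pd.Index(genes, name="gene_id"),
                        columns=samples)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "phase",
                                            "confounder_level", "dataset"]
                        ).set_index("sample_id")
    return ExpressionDataset(rpkm, meta, kind="rpkm")
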