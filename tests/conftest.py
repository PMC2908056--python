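import numpy as np
import pandas as pd
import pytest

from pathscore import (
    GenotypeMatrix,
    SimulationScenario,
    map_snps_to_genes,
    simulate_dataset,
)


def make_genotypes(dosage, chrom="1", positions=None, subject_ids=None, snp_ids=None):
    """Build a GenotypeMatrix from a plain array (rows = subjects)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    subject_ids = subject_ids or [f"S{i}" for i in range(n)]
    snp_ids = snp_ids or [f"snp{j}" for j in range(m)]
    positions = positions if positions is not None else (np.arange(m) + 1) * 1000
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=int),
            "ref": "A",
            "alt": "G",
        },
        index=snp_ids,
    )
    return GenotypeMatrix(subject_ids, snp_ids, dosage, meta)


@pytest.fixture
def make_gm():
    return make_genotypes


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated study reused by read-only tests: 40 genes, 10
    pathways, a distributed signal and a hero gene, 150 cases/controls."""
    sc = SimulationScenario(
        n_cases=150,
        n_controls=150,
        n_genes=40,
        n_pathways=10,
        causal_spec=[(f"G{i:04d}", 0, 1.6) for i in range(5)],
        hero_gene="G0030",
        seed=20,
    )
    g, ph, genes, pathways, truth = simulate_dataset(sc)
    snp_map = map_snps_to_genes(g, genes)
    return {
        "scenario": sc,
        "g": g,
        "ph": ph,
        "genes": genes,
        "pathways": pathways,
        "truth": truth,
        "map": snp_map,
    }
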