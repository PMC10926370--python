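import numpy as np
import pandas as pd
import pytest

from helihybrid import SimConfig, VariantTable, simulate_dataset


def make_table(dosage, depth=None, qual=None, chroms=None, pos=None,
               samples=None):
    """Hand-build a VariantTable from a (samples x sites) dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, j = dosage.shape
    if depth is None:
        depth = np.full((n, j), 30)
    if qual is None:
        qual = np.full(j, 60.0)
    if chroms is None:
        chroms = [f"chr{2 + i % 3}" for i in range(j)]
    if pos is None:
        pos = []
        seen = {}
        for c in chroms:
            seen[c] = seen.get(c, 0) + 100
            pos.append(seen[c])
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    sites = pd.DataFrame({
        "chrom": chroms, "pos": pos,
        "ref": ["A"] * j, "alt": ["T"] * j, "qual": qual,
    })
    return VariantTable(sites=sites, samples=samples, dosage=dosage,
                        depth=np.asarray(depth))


@pytest.fixture(scope="session")
def reference_cohort():
    """20+20 pure panels plus two F1s at 30x, moderate divergence."""
    cfg = SimConfig(n_sites=2000, fst=0.3, n_pure_armigera=20, n_pure_zea=20,
                    hybrid_spec=[{"kind": "F1", "count": 2}],
                    mean_depth=30.0, seed=20260927)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Same design but the analysis table holds the *true* genotypes
    (no caller noise): useful for exact enumeration oracles."""
    cfg = SimConfig(n_sites=1500, fst=0.3, n_pure_armigera=20, n_pure_zea=20,
                    hybrid_spec=[{"kind": "F1", "count": 2}],
                    fixed_diff_fraction=0.1, mean_depth=30.0, seed=915)
    ds = simulate_dataset(cfg)
    table = VariantTable(sites=ds.table.sites, samples=ds.table.samples,
                         dosage=ds.truth.genotype_true.astype(float),
                         depth=ds.table.depth)
    return table, ds
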