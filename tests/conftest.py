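import numpy as np
import pandas as pd
import pytest

from epicqtl import synthetic_data as sim
from epicqtl.pipeline import RunConfig, run_epicqtl


def make_observations(cells: dict, chrom="II", pos=1000) -> pd.DataFrame:
    """Build per-replicate smoothed observations from {(bg, sel): [(oak, wine), ...]}."""
    rows = []
    for (bg, sel), reps in cells.items():
        for r, (oak, wine) in enumerate(reps, start=1):
            rows.append(dict(chrom=chrom, pos=pos, selection=sel, background=bg,
                             replicate=r, oak_smooth=float(oak), wine_smooth=float(wine)))
    return pd.DataFrame(rows)


def analyze(table, fixed_chrom, n_perm=100, seed=0, alpha=0.05):
    """Full in-memory analysis of a simulated variant table."""
    cfg = RunConfig(fixed_chrom=fixed_chrom, n_perm=n_perm, alpha=alpha,
                    exclude=(), seed=seed)
    return run_epicqtl(cfg, variant_table=table, write=False)


@pytest.fixture(scope="session")
def magnitude_run():
    """One simulated magnitude-epistasis experiment, fully analyzed."""
    config, model = sim.magnitude_scenario(seed=7)
    table, truth, genome = sim.generate_experiment(config, model)
    return analyze(table, model.fixed_chrom, seed=7), truth, genome


@pytest.fixture(scope="session")
def small_variant_table():
    """A compact two-chromosome experiment for I/O and smoothing tests."""
    config = sim.SimConfig(n_chrom=3, chrom_bp=12_000, n_segregants=800, seed=11)
    model = sim.QTLModel(fixed_chrom="I")
    table, _, _ = sim.generate_experiment(config, model)
    return table
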