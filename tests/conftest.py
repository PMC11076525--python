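import numpy as np
import pandas as pd
import pytest

from splicescreen import counting, simulate, stats
from splicescreen.library import ReporterAnnotation, design_library


@pytest.fixture(scope="session")
def small_annotation():
    """110-nt reporter with the canonical feature layout, fixed sequence."""
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=110)])
    return ReporterAnnotation(
        sequence=seq,
        features=(
            ("exon6", 0, 10),
            ("intron6", 10, 40),
            ("exon7", 40, 60),
            ("intron7", 60, 100),
            ("exon8", 100, 110),
        ),
    )


@pytest.fixture(scope="session")
def small_library(small_annotation):
    return design_library(small_annotation, lengths=(22, 25), step=1, n_controls=8, seed=7)


@pytest.fixture(scope="session")
def demo_library():
    return simulate.demo_library(seed=0)


@pytest.fixture(scope="session")
def demo_truth(demo_library):
    return simulate.default_demo_truth(demo_library.annotation)


def make_random_counts(seed, n_guides=50, replicate_id="R1", reporter="DUAL_IN"):
    """Random count table with a spread of depths so all filter branches fire."""
    rng = np.random.default_rng(seed)
    ids = [f"g{i:03d}" for i in range(n_guides)]
    lam = rng.choice([0.5, 3.0, 30.0, 300.0], size=n_guides)
    data = {
        "n_u": rng.poisson(lam),
        "n_t": rng.poisson(lam * rng.uniform(0.2, 3.0, n_guides)),
        "n_b": rng.poisson(lam * rng.uniform(0.2, 3.0, n_guides)),
    }
    df = pd.DataFrame(data, index=pd.Index(ids, name="guide_id"), dtype=np.int64)
    totals, unassigned = {}, {}
    for b, s in counting.BIN_SUFFIX.items():
        assigned = int(df[f"n_{s}"].sum())
        extra = int(rng.integers(0, 50))
        totals[b] = assigned + extra
        unassigned[b] = extra
    return counting.BinCountTable(replicate_id, reporter, df, totals, unassigned)


@pytest.fixture()
def random_counts():
    return make_random_counts(seed=11)


@pytest.fixture(scope="session")
def small_screen(demo_library, demo_truth):
    """One simulated demo screen (4 replicates) plus its analysis results."""
    config = simulate.SimConfig(seed=123)
    tables = simulate.simulate_screen(demo_library, demo_truth, config)
    results = stats.analyze_screen(tables)
    return {"config": config, "tables": tables, "results": results}
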