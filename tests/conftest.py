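import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from erparrange import (
    DepthSpec, FragmentationSpec, GenomeSpec, RunConfig, arrange_contigs,
    evaluate_arrangement, simulate_dataset,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def run_simulated(
    seed: int,
    length: int = 300_000,
    copy_ratio: float = 2.0,
    depth: float = 100.0,
    noise: str = "poisson",
    n_contigs: int = 12,
    min_len: int = 6000,
    shape: str = "exponential",
    cut_ter: bool = False,
    null_reps: int = 0,
    config: RunConfig | None = None,
):
    """Simulate one dataset, arrange it, and evaluate against the truth."""
    gspec = GenomeSpec(length=length, copy_ratio=copy_ratio, seed=seed * 7 + 1,
                       shape=shape)
    fspec = FragmentationSpec(
        n_contigs=n_contigs, min_len=min_len, seed=seed * 7 + 3,
        cut_sites=(gspec.ter,) if cut_ter else (),
    )
    dspec = DepthSpec(depth_at_ter=depth, noise=noise, seed=seed * 7 + 2)
    ds = simulate_dataset(gspec, dspec, fspec)
    out = arrange_contigs(ds.contigs, ds.depths, config or RunConfig())
    result = evaluate_arrangement(
        out.arrangement, ds.contigs, ds.genome, truth=ds.truth,
        null_reps=null_reps, seed=seed * 7 + 4,
    )
    return ds, out, result


@pytest.fixture
def simrun():
    return run_simulated


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
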