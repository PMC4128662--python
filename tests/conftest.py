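import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_analysis_matrix(calls, pos=None, chrom="chr1", chrom_len=None, ref=None, alts=None):
    """Build an AnalysisMatrix directly from a complete (n, S) call array."""
    from haplopop.qc import AnalysisMatrix

    calls = np.asarray(calls, dtype=np.int16)
    n, S = calls.shape
    if pos is None:
        pos = np.arange(S, dtype=np.int64) * 10 + 5
    pos = np.asarray(pos, dtype=np.int64)
    if chrom_len is None:
        chrom_len = int(pos[-1]) + 10 if S else 100
    if ref is None:
        ref = np.array(["A"] * S, dtype=object)
    if alts is None:
        alts = [("T", "C", "G")[: max(1, int(calls[:, s].max()))] for s in range(S)]
    return AnalysisMatrix(
        samples=[f"s{i:02d}" for i in range(n)],
        chrom=np.array([chrom] * S, dtype=object),
        pos=pos,
        ref=ref,
        alts=alts,
        calls=calls,
        callable={chrom: np.array([[0, chrom_len]], dtype=np.int64)},
    )


@pytest.fixture
def small_matrix():
    """4 samples, 5 SNPs over a 100-bp callable chromosome."""
    calls = np.array(
        [
            [0, 0, 1, 0, 1],
            [0, 1, 1, 0, 1],
            [1, 0, 0, 0, 1],
            [1, 1, 0, 1, 0],
        ]
    )
    return make_analysis_matrix(calls, pos=np.array([5, 20, 40, 60, 80]), chrom_len=100)


@pytest.fixture(scope="session")
def neutral_sim():
    """One neutral coalescent data set reused across tests (n=32, 200 kb)."""
    from haplopop.simulate import SimulationConfig, simulate_population, to_analysis_matrix

    cfg = SimulationConfig(chrom_lengths={"chr1": 200_000}, seed=42)
    reference, matrix, truth = simulate_population(cfg)
    amatrix = to_analysis_matrix(matrix, cfg.chrom_lengths)
    return cfg, reference, matrix, amatrix, truth
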