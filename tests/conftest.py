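import numpy as np
import pytest

from chimehmm.airr_io import ReferenceMSA, ThreadedQuery, thread_queries
from chimehmm.simulate import airr_records_from_frame


@pytest.fixture
def tiny_msa() -> ReferenceMSA:
    """Two 12-column references differing at 6 columns, one with a gap."""
    return ReferenceMSA.from_records(
        [
            ("VA1-1*01", "ACGTACGTACGT"),
            ("VA1-2*01", "ACGTTGCATC-T"),
        ]
    )


def thread_sim(airr_frame, msa):
    """Thread a simulated AIRR frame back onto its MSA."""
    _, threaded, _ = thread_queries(airr_records_from_frame(airr_frame), msa)
    return threaded


def random_instance(rng, with_gaps=True, n_max=5, k_max=3, l_max=50):
    """A random small model instance for oracle cross-checks."""
    from chimehmm.hmm import ModelConfig, StateSpace

    N = int(rng.integers(1, n_max + 1))
    K = int(rng.integers(1, k_max + 1))
    L = int(rng.integers(5, l_max + 1))
    rows = []
    for r in range(N):
        chars = rng.choice(list("ACGT"), size=L)
        if with_gaps:
            chars[rng.random(L) < 0.05] = "-"
        rows.append((f"g{r % 3 + 1}-{r + 1}*01", "".join(chars)))
    msa = ReferenceMSA.from_records(rows)
    rates = np.sort(rng.random(K) * 0.3)
    if K == 1:
        rates[0] = max(rates[0], 1e-3)  # avoid the stated m==0/K==1 degeneracy
    rates = rates + np.arange(K) * 1e-9  # strictly increasing
    psi = float(10 ** rng.uniform(-6, -1))
    mu = 0.0 if K == 1 else float(10 ** rng.uniform(-6, -1))
    cfg = ModelConfig(psi=psi, mu=mu, rates=tuple(rates))
    obs = rng.choice(list("ACGT"), size=L)
    obs[rng.random(L) < 0.08] = "-"
    obs[rng.random(L) < 0.05] = "N"
    q = ThreadedQuery("q", "".join(obs), msa.names[0])
    return q, msa, StateSpace(N=N, K=K), cfg
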