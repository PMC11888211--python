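"""The chimera HMM: state space, emission/transition laws, Forward and Viterbi.

For N germline references and K discretized mutation-rate classes the model
has 2NK states: NK "non-chimeric" states U (no template switch so far) and NK
"chimeric" states C (switched at least once).  Cross-reference transitions are
only allowed *into* C, so any path ending in U never switched and any path
ending in C switched at least once; the Forward mass of terminal C states,
normalized by the total evidence, is the posterior probability that the query
is a PCR chimera.

Because transitions depend only on (self / same-reference / cross-reference
into C), the Forward, Backward and Viterbi inductions reduce from O(L(NK)^2)
to O(LNK) using three per-column aggregates: the global sum, the per-reference
per-class sum, and the per-reference sum over both classes.  A dense quadratic
log-space implementation is kept as an independent oracle for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .airr_io import ReferenceMSA, ThreadedQuery, encode

logger = logging.getLogger(__name__)


class NumericalDegeneracyError(ArithmeticError):
    """All-zero Forward column: every state assigns probability 0 to a symbol."""


def db_rate_grid(k: int = 15, lo: float = 0.0, hi: float = 0.25) -> tuple[float, ...]:
    """The discretized mutation-rate grid: k equally spaced values on [lo, hi]."""
    if k == 1:
        return (lo,)
    return tuple(np.linspace(lo, hi, k))


@dataclass(frozen=True)
class ModelConfig:
    """HMM parameters.

    psi is the per-column probability of switching to a different reference
    (the chimeric transition), mu the per-column probability of switching to a
    different mutation-rate class of the same reference.  ``rates`` is the
    ordered grid M1..MK; with K == 1 the rate-class machinery is vacuous and mu
    must be 0.
    """

    psi: float = 1e-4
    mu: float = 1e-3
    rates: tuple[float, ...] = field(default_factory=lambda: db_rate_grid())
    method: str = "DB"
    threshold: float = 0.95
    viterbi: bool = False

    def __post_init__(self):
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        if self.psi < 0 or self.mu < 0 or self.psi + self.mu >= 1:
            raise ValueError("require psi >= 0, mu >= 0, psi + mu < 1")
        if len(self.rates) < 1:
            raise ValueError("need at least one mutation-rate class")
        if any(not (0 <= r < 1) for r in self.rates):
            raise ValueError("mutation rates must lie in [0, 1)")
        if any(b <= a for a, b in zip(self.rates, self.rates[1:])):
            raise ValueError("mutation rates must be strictly increasing")
        if len(self.rates) == 1 and self.mu != 0:
            raise ValueError("mu must be 0 when there is a single rate class")
        if self.method not in ("DB", "BW"):
            raise ValueError("method must be 'DB' or 'BW'")
        if not (0 <= self.threshold <= 1):
            raise ValueError("threshold must be a probability")

    @property
    def K(self) -> int:
        return len(self.rates)


@dataclass(frozen=True)
class StateSpace:
    """Indexing of the 2NK states.

    Flat state index = class * N * K + r * K + k, with class 0 = U
    (non-chimeric), class 1 = C (chimeric); r and k zero-based.
    """

    N: int
    K: int

    @property
    def n_states(self) -> int:
        return 2 * self.N * self.K

    def index(self, chimeric: int, r: int, k: int) -> int:
        return chimeric * self.N * self.K + r * self.K + k

    def unpack(self, i: int) -> tuple[int, int, int]:
        nk = self.N * self.K
        return i // nk, (i % nk) // self.K, i % self.K

    def is_chimeric(self, i: int) -> bool:
        return i >= self.N * self.K

    def R(self, i: int) -> np.ndarray:
        """States sharing i's reference AND chimeric class (size K)."""
        c, r, _ = self.unpack(i)
        base = c * self.N * self.K + r * self.K
        return np.arange(base, base + self.K)

    def R_star(self, i: int) -> np.ndarray:
        """All states of i's reference, either class (size 2K)."""
        _, r, _ = self.unpack(i)
        nk = self.N * self.K
        return np.concatenate(
            [np.arange(r * self.K, (r + 1) * self.K), nk + np.arange(r * self.K, (r + 1) * self.K)]
        )

    def psi_star(self, j: int, psi: float) -> float:
        """The switch-in rate: 0 for non-chimeric states, psi for chimeric."""
        return psi if self.is_chimeric(j) else 0.0


def build_state_space(msa: ReferenceMSA, config: ModelConfig) -> StateSpace:
    return StateSpace(N=msa.N, K=config.K)


def emission_prob(state_nt: str, obs: str, m: float) -> float:
    """P(observed symbol | state): 1-m on match, m/3 on mismatch, 1 on -/N.

    A reference gap opposite a query base is scored as a mismatch (m/3); the
    emission law is otherwise defined only for reference nucleotides.
    """
    if obs not in "ACGT-N" or len(obs) != 1:
        raise ValueError(f"invalid observation symbol {obs!r}")
    if state_nt not in "ACGT-N" or len(state_nt) != 1:
        raise ValueError(f"invalid reference symbol {state_nt!r}")
    if not (0 <= m < 1):
        raise ValueError("mutation rate must lie in [0, 1)")
    if obs in "-N":
        return 1.0
    if obs == state_nt:
        return 1.0 - m
    return m / 3.0


def _effective(psi: float, mu: float, N: int, K: int) -> tuple[float, float]:
    """psi/mu with the degenerate branches (N==1, K==1) switched off."""
    return (psi if N > 1 else 0.0), (mu if K > 1 else 0.0)


def transition_prob(i: int, j: int, space: StateSpace, config: ModelConfig) -> float:
    """a_ij under the structured transition law (rows sum to 1)."""
    N, K = space.N, space.K
    psi, mu = _effective(config.psi, config.mu, N, K)
    ci, ri, _ = space.unpack(i)
    cj, rj, _ = space.unpack(j)
    if i == j:
        return 1.0 - psi - mu
    if ri == rj and ci == cj:  # same reference, same class: rate-class switch
        return mu / (K - 1) if K > 1 else 0.0
    if ri != rj and cj == 1:  # cross-reference, only into C
        return psi / ((N - 1) * K) if N > 1 else 0.0
    return 0.0


@dataclass
class ForwardResult:
    """Forward pass summary.

    ``scale_factors[t]`` is the per-column normalizer c_t; the unscaled
    alpha column t equals the scaled one times prod(scale_factors[: t + 1]).
    """

    log_evidence: float
    log_chimeric_mass: float
    posterior: float
    scale_factors: np.ndarray


@dataclass
class ViterbiResult:
    """Most likely path, as (reference_name, rate_class, start, end) segments.

    ``breakpoints`` lists the 1-based columns at which the path's reference
    changes (the first column of each new parent).
    """

    segments: list[tuple[str, int, int, int]]
    breakpoints: list[int]
    log_path_prob: float
    path: np.ndarray


class OpCounter:
    """Counts array elements touched per Forward column (complexity probe)."""

    def __init__(self):
        self.elements = 0

    def add(self, n: int) -> None:
        self.elements += int(n)


def _expand_rates(rates, N: int) -> np.ndarray:
    """Accept a shared grid (K,) or per-reference rates (N, K); return (N, K)."""
    arr = np.asarray(rates, dtype=float)
    if arr.ndim == 1:
        arr = np.broadcast_to(arr, (N, arr.shape[0]))
    if arr.shape[0] != N:
        raise ValueError("rates first dimension must match the reference count")
    return np.ascontiguousarray(arr)


def _emissions(obs_col: np.ndarray, ref_col: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Emission probabilities for one column: (B, N, K).

    obs_col: (B,) uint8 codes; ref_col: (N,) uint8 codes; rates: (N, K).
    Gap/N observations emit 1 from every state; a reference gap or N opposite
    a query base never matches, so it scores m/3.
    """
    match = obs_col[:, None] == ref_col[None, :]
    e = np.where(match[:, :, None], 1.0 - rates[None, :, :], rates[None, :, :] / 3.0)
    e[obs_col >= 4] = 1.0
    return e


def forward_batch(
    obs_codes: np.ndarray,
    ref_codes: np.ndarray,
    rates,
    psi: float,
    mu: float,
    keep_lattice: bool = False,
    counter: OpCounter | None = None,
):
    """Vectorized linear-time Forward over a batch of queries.

    obs_codes: (B, L) uint8; ref_codes: (N, L) uint8; rates: (K,) or (N, K).

    Returns a dict with ``log_evidence`` (B,), ``posterior`` (B,),
    ``scale`` (B, L) per-column normalizers, and, when ``keep_lattice``,
    ``alpha`` (B, L, 2, N, K) scaled so each column sums to 1 per query.
    """
    obs_codes = np.atleast_2d(np.asarray(obs_codes, dtype=np.uint8))
    B, L = obs_codes.shape
    N, Lr = ref_codes.shape
    if L != Lr:
        raise ValueError("query length does not match MSA column count")
    rates = _expand_rates(rates, N)
    K = rates.shape[1]
    psi_e, mu_e = _effective(psi, mu, N, K)
    stay = 1.0 - psi_e - mu_e
    mu_c = mu_e / (K - 1) if K > 1 else 0.0
    psi_c = psi_e / ((N - 1) * K) if N > 1 else 0.0

    scale = np.empty((B, L))
    alpha_lat = np.empty((B, L, 2, N, K)) if keep_lattice else None

    # alpha_1(i) = pi_i * b_i1: uniform over the NK non-chimeric states
    alpha = np.zeros((B, 2, N, K))
    alpha[:, 0] = _emissions(obs_codes[:, 0], ref_codes[:, 0], rates) / (N * K)
    c = alpha.sum(axis=(1, 2, 3))
    if np.any(c <= 0):
        raise NumericalDegeneracyError("all states assign probability 0 at column 1")
    alpha /= c[:, None, None, None]
    scale[:, 0] = c
    if keep_lattice:
        alpha_lat[:, 0] = alpha

    for t in range(1, L):
        e = _emissions(obs_codes[:, t], ref_codes[:, t], rates)
        tot = alpha.sum(axis=(1, 2, 3))  # (B,)
        s_cr = alpha.sum(axis=3)  # (B, 2, N): same-class same-reference sums
        new = alpha * stay
        if mu_c:
            new += (s_cr[:, :, :, None] - alpha) * mu_c
        if psi_c:
            s_r = s_cr.sum(axis=1)  # (B, N): both-class same-reference sums
            new[:, 1] += ((tot[:, None] - s_r) * psi_c)[:, :, None]
        new *= e[:, None, :, :]
        c = new.sum(axis=(1, 2, 3))
        if np.any(c <= 0):
            raise NumericalDegeneracyError(
                f"all states assign probability 0 at column {t + 1}"
            )
        alpha = new / c[:, None, None, None]
        scale[:, t] = c
        if keep_lattice:
            alpha_lat[:, t] = alpha
        if counter is not None:
            counter.add(alpha.size * 4 + e.size)

    log_evidence = np.log(scale).sum(axis=1)
    chim = alpha[:, 1].sum(axis=(1, 2))
    with np.errstate(divide="ignore"):
        log_chim = log_evidence + np.log(chim)
    out = {
        "log_evidence": log_evidence,
        "posterior": chim,
        "log_chimeric_mass": log_chim,
        "scale": scale,
    }
    if keep_lattice:
        out["alpha"] = alpha_lat
    return out


def forward_linear(
    q: ThreadedQuery,
    msa: ReferenceMSA,
    space: StateSpace,
    config: ModelConfig,
    rates=None,
) -> ForwardResult:
    """Linear-time Forward pass for one query; O(L N K) total work.

    ``rates`` may override the config grid with per-reference rates (N, K),
    as used by the Baum-Welch variant.
    """
    if len(q.obs) != msa.L:
        raise ValueError("threaded query length does not match MSA")
    r = forward_batch(
        encode(q.obs)[None, :],
        msa.codes,
        config.rates if rates is None else rates,
        config.psi,
        config.mu,
    )
    return ForwardResult(
        log_evidence=float(r["log_evidence"][0]),
        log_chimeric_mass=float(r["log_chimeric_mass"][0]),
        posterior=float(r["posterior"][0]),
        scale_factors=r["scale"][0],
    )


def forward_many(
    queries: Sequence[ThreadedQuery],
    msa: ReferenceMSA,
    config: ModelConfig,
    rates=None,
    chunk: int = 1024,
) -> np.ndarray:
    """Posterior chimera probabilities for many queries (chunked batches)."""
    obs = np.vstack([encode(q.obs) for q in queries])
    post = np.empty(len(queries))
    use_rates = config.rates if rates is None else rates
    for lo in range(0, len(queries), chunk):
        hi = min(lo + chunk, len(queries))
        r = forward_batch(obs[lo:hi], msa.codes, use_rates, config.psi, config.mu)
        post[lo:hi] = r["posterior"]
    return post


def chimera_call(result: ForwardResult, config: ModelConfig) -> bool:
    """A query is called chimeric iff posterior >= threshold."""
    return result.posterior >= config.threshold


# ---------------------------------------------------------------------------
# dense quadratic oracle (log space) — test-time cross-check, O(L (NK)^2)
# ---------------------------------------------------------------------------


def dense_log_transitions(space: StateSpace, config: ModelConfig) -> np.ndarray:
    S = space.n_states
    A = np.empty((S, S))
    for i in range(S):
        for j in range(S):
            A[i, j] = transition_prob(i, j, space, config)
    with np.errstate(divide="ignore"):
        return np.log(A)


def _dense_log_emissions(
    obs_codes: np.ndarray, msa: ReferenceMSA, space: StateSpace, rates: np.ndarray
) -> np.ndarray:
    """(L, S) log emission matrix for one query."""
    L = obs_codes.shape[0]
    S = space.n_states
    out = np.empty((L, S))
    ref = msa.codes
    for t in range(L):
        col = _emissions(obs_codes[t : t + 1], ref[:, t], rates)[0]  # (N, K)
        out[t] = np.concatenate([col.ravel(), col.ravel()])
    with np.errstate(divide="ignore"):
        return np.log(out)


def forward_quadratic_oracle(
    q: ThreadedQuery,
    msa: ReferenceMSA,
    space: StateSpace,
    config: ModelConfig,
    rates=None,
) -> ForwardResult:
    """Dense Rabiner Forward in log space; identical contract to forward_linear."""
    obs = encode(q.obs)
    rmat = _expand_rates(config.rates if rates is None else rates, msa.N)
    logA = dense_log_transitions(space, config)
    logB = _dense_log_emissions(obs, msa, space, rmat)
    S = space.n_states
    nk = S // 2
    with np.errstate(divide="ignore"):
        logpi = np.concatenate([np.full(nk, -np.log(nk)), np.full(nk, -np.inf)])
    la = logpi + logB[0]
    col_ll = [logsumexp(la)]
    for t in range(1, len(obs)):
        la = logsumexp(la[:, None] + logA, axis=0) + logB[t]
        col_ll.append(logsumexp(la))
    log_evidence = float(col_ll[-1])
    log_chim = float(logsumexp(la[nk:]))
    scale = np.exp(np.diff(np.asarray([0.0] + col_ll)))
    return ForwardResult(
        log_evidence=log_evidence,
        log_chimeric_mass=log_chim,
        posterior=float(np.exp(log_chim - log_evidence)),
        scale_factors=scale,
    )


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------


def _top2_lastaxis(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(max, argmax, runner-up, its arg) along the last axis, first-occurrence ties."""
    a1 = v.argmax(axis=-1)
    m1 = np.take_along_axis(v, a1[..., None], axis=-1)[..., 0]
    masked = v.copy()
    np.put_along_axis(masked, a1[..., None], -np.inf, axis=-1)
    a2 = masked.argmax(axis=-1)
    m2 = np.take_along_axis(masked, a2[..., None], axis=-1)[..., 0]
    return m1, a1, m2, a2


def _take_better(best, bidx, cand, cidx):
    """Keep the higher-scoring candidate; on ties the lower predecessor index."""
    switch = (cand > best) | ((cand == best) & (cidx < bidx))
    return np.where(switch, cand, best), np.where(switch, cidx, bidx)


def _segments_from_path(path: np.ndarray, space: StateSpace, names: Sequence[str]):
    segments: list[tuple[str, int, int, int]] = []
    breakpoints: list[int] = []
    prev_rk = None
    for t, s in enumerate(path):
        _, r, k = space.unpack(int(s))
        if prev_rk is not None and (r, k) == prev_rk:
            name, kk, start, _ = segments[-1]
            segments[-1] = (name, kk, start, t + 1)
        else:
            if prev_rk is not None and r != prev_rk[0]:
                breakpoints.append(t + 1)
            segments.append((names[r], k, t + 1, t + 1))
        prev_rk = (r, k)
    return segments, breakpoints


def viterbi_linear(
    q: ThreadedQuery,
    msa: ReferenceMSA,
    space: StateSpace,
    config: ModelConfig,
    rates=None,
) -> ViterbiResult:
    """Max-product analogue of the linear Forward recursion.

    Per column the best predecessor of each state is one of: itself; the best
    other rate class of its reference/class (mu move); or, for chimeric
    states, the best state of any other reference (psi move).  The last is
    found from per-reference maxima plus the global top two, so per-column
    work stays O(NK).  Ties go to the lowest predecessor index.
    """
    obs = encode(q.obs)
    N, K = space.N, space.K
    nk = N * K
    rmat = _expand_rates(config.rates if rates is None else rates, N)
    psi_e, mu_e = _effective(config.psi, config.mu, N, K)
    with np.errstate(divide="ignore"):
        l_stay = np.log(1.0 - psi_e - mu_e)
        l_mu = np.log(mu_e / (K - 1)) if K > 1 else -np.inf
        l_psi = np.log(psi_e / ((N - 1) * K)) if N > 1 else -np.inf

    L = len(obs)
    ptr = np.empty((L, 2 * nk), dtype=np.int64)
    idx_flat = np.arange(2 * nk)
    k_of = (idx_flat % K).reshape(2, N, K)

    with np.errstate(divide="ignore"):
        e0 = np.log(_emissions(obs[:1], msa.codes[:, 0], rmat)[0])  # (N, K)
    v = np.full((2, N, K), -np.inf)
    v[0] = -np.log(nk) + e0
    ptr[0] = -1

    for t in range(1, L):
        with np.errstate(divide="ignore"):
            le = np.log(_emissions(obs[t : t + 1], msa.codes[:, t], rmat)[0])
        best = v + l_stay
        bidx = idx_flat.reshape(2, N, K).copy()

        if K > 1:
            m1, a1, m2, a2 = _top2_lastaxis(v)  # over k, per (class, r)
            alt = np.where(k_of == a1[..., None], m2[..., None], m1[..., None])
            alt_k = np.where(k_of == a1[..., None], a2[..., None], a1[..., None])
            base = (idx_flat.reshape(2, N, K) // K) * K
            best, bidx = _take_better(best, bidx, alt + l_mu, base + alt_k)

        if N > 1:
            # per-reference max over both classes and all rate classes,
            # flattened in state-index order so first-occurrence = lowest index
            per_ref = v.transpose(1, 0, 2).reshape(N, 2 * K)
            a = per_ref.argmax(axis=1)
            m = per_ref[np.arange(N), a]
            flat_arg = (a // K) * nk + np.arange(N) * K + (a % K)
            order = sorted(range(N), key=lambda r: (-m[r], flat_arg[r]))
            r1 = order[0]
            r2 = order[1] if N > 1 else r1
            use = np.where(np.arange(N) == r1, r2, r1)  # best ref != own ref
            cand = m[use] + l_psi  # (N,)
            cidx = flat_arg[use]
            best_c, bidx_c = _take_better(
                best[1], bidx[1], cand[:, None] * np.ones((1, K)), np.broadcast_to(cidx[:, None], (N, K))
            )
            best = np.stack([best[0], best_c])
            bidx = np.stack([bidx[0], bidx_c])

        v = best + le[None, :, :]
        ptr[t] = bidx.ravel()
        if not np.any(np.isfinite(v)):
            raise NumericalDegeneracyError(f"no viable path at column {t + 1}")

    flat = v.ravel()
    end = int(flat.argmax())
    log_path = float(flat[end])
    path = np.empty(L, dtype=np.int64)
    path[-1] = end
    for t in range(L - 1, 0, -1):
        path[t - 1] = ptr[t, path[t]]
    segments, breakpoints = _segments_from_path(path, space, msa.names)
    return ViterbiResult(
        segments=segments, breakpoints=breakpoints, log_path_prob=log_path, path=path
    )


def viterbi_quadratic_oracle(
    q: ThreadedQuery,
    msa: ReferenceMSA,
    space: StateSpace,
    config: ModelConfig,
    rates=None,
) -> ViterbiResult:
    """Dense log-space Viterbi; argmax ties resolve to the lowest index."""
    obs = encode(q.obs)
    rmat = _expand_rates(config.rates if rates is None else rates, msa.N)
    logA = dense_log_transitions(space, config)
    logB = _dense_log_emissions(obs, msa, space, rmat)
    S = space.n_states
    nk = S // 2
    with np.errstate(divide="ignore"):
        logpi = np.concatenate([np.full(nk, -np.log(nk)), np.full(nk, -np.inf)])
    v = logpi + logB[0]
    L = len(obs)
    ptr = np.empty((L, S), dtype=np.int64)
    ptr[0] = -1
    for t in range(1, L):
        scores = v[:, None] + logA
        ptr[t] = scores.argmax(axis=0)
        v = scores[ptr[t], np.arange(S)] + logB[t]
    end = int(v.argmax())
    path = np.empty(L, dtype=np.int64)
    path[-1] = end
    for t in range(L - 1, 0, -1):
        path[t - 1] = ptr[t, path[t]]
    segments, breakpoints = _segments_from_path(path, space, msa.names)
    return ViterbiResult(
        segments=segments,
        breakpoints=breakpoints,
        log_path_prob=float(v[end]),
        path=path,
    )
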