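"""The "BW" model variant: two states per germline, rates fitted by Baum-Welch.

Instead of a shared grid of discretized mutation-rate classes, each reference
carries a single continuous mutation rate, re-estimated by expectation-
maximization from the posterior state occupancies (Baum-Welch).  K == 1, so
the rate-class switching rate mu is vacuous and held at 0; the chimeric
switching rate psi is a user prior and is never re-estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .airr_io import ReferenceMSA, ThreadedQuery, encode
from .hmm import (
    ForwardResult,
    ModelConfig,
    StateSpace,
    _effective,
    _emissions,
    _expand_rates,
    forward_batch,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BWConfig:
    """EM settings: initial rate, iteration cap, convergence tolerance, clamps."""

    init_rate: float = 0.05
    max_iter: int = 10
    tol: float = 1e-3
    rate_floor: float = 1e-6
    rate_ceiling: float = 0.3

    def __post_init__(self):
        if not (0 < self.init_rate < 1):
            raise ValueError("init_rate must lie in (0, 1)")
        if not (self.rate_floor < self.rate_ceiling):
            raise ValueError("rate_floor must be below rate_ceiling")


@dataclass
class SufficientStats:
    """Expected per-reference mismatch and informative-emission counts.

    Accumulated from gamma occupancies over columns where the observation is a
    plain base (A/C/G/T); gap/N columns are emission-neutral and contribute
    nothing.  U and C states of a reference are pooled.
    """

    mismatches: np.ndarray
    emissions: np.ndarray

    @classmethod
    def zeros(cls, n_refs: int) -> "SufficientStats":
        return cls(np.zeros(n_refs), np.zeros(n_refs))

    def __iadd__(self, other: "SufficientStats") -> "SufficientStats":
        self.mismatches += other.mismatches
        self.emissions += other.emissions
        return self


def backward_batch(
    obs_codes: np.ndarray,
    ref_codes: np.ndarray,
    rates,
    psi: float,
    mu: float,
    scale: np.ndarray,
) -> np.ndarray:
    """Linear-time scaled Backward pass: (B, L, 2, N, K).

    ``scale`` are the Forward per-column normalizers; with this scaling
    sum_i alpha_hat_t(i) * beta_hat_t(i) == 1 for every column t.
    """
    obs_codes = np.atleast_2d(np.asarray(obs_codes, dtype=np.uint8))
    B, L = obs_codes.shape
    N = ref_codes.shape[0]
    rates = _expand_rates(rates, N)
    K = rates.shape[1]
    psi_e, mu_e = _effective(psi, mu, N, K)
    stay = 1.0 - psi_e - mu_e
    mu_c = mu_e / (K - 1) if K > 1 else 0.0
    psi_c = psi_e / ((N - 1) * K) if N > 1 else 0.0

    beta = np.empty((B, L, 2, N, K))
    beta[:, L - 1] = 1.0
    for t in range(L - 2, -1, -1):
        e = _emissions(obs_codes[:, t + 1], ref_codes[:, t + 1], rates)  # (B,N,K)
        w = beta[:, t + 1] * e[:, None, :, :]  # (B,2,N,K)
        b = w * stay
        if mu_c:
            b += (w.sum(axis=3, keepdims=True) - w) * mu_c
        if psi_c:
            # outgoing psi mass goes into C states of every other reference
            w_c_ref = w[:, 1].sum(axis=2)  # (B, N)
            w_c_tot = w_c_ref.sum(axis=1)  # (B,)
            b += ((w_c_tot[:, None] - w_c_ref) * psi_c)[:, None, :, None]
        beta[:, t] = b / scale[:, t + 1][:, None, None, None]
    return beta


def backward_linear(
    q: ThreadedQuery,
    msa: ReferenceMSA,
    space: StateSpace,
    config: ModelConfig,
    rates=None,
    forward=None,
) -> np.ndarray:
    """Scaled Backward values for one query, shape (L, 2NK).

    Uses the Forward pass's scale factors (recomputed if not supplied) so the
    forward-backward product is constant over columns.
    """
    obs = encode(q.obs)[None, :]
    use_rates = config.rates if rates is None else rates
    if forward is None:
        fwd = forward_batch(obs, msa.codes, use_rates, config.psi, config.mu)
        scale = fwd["scale"]
    else:
        scale = np.atleast_2d(forward.scale_factors)
    beta = backward_batch(obs, msa.codes, use_rates, config.psi, config.mu, scale)
    L = msa.L
    return beta[0].reshape(L, -1)


def _stats_from_lattices(
    obs_codes: np.ndarray,
    ref_codes: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
) -> SufficientStats:
    """Accumulate expected mismatch/emission counts from gamma = alpha * beta."""
    gamma = alpha * beta  # (B, L, 2, N, K); columns sum to 1 per query
    g_ref = gamma.sum(axis=(2, 4))  # (B, L, N)
    informative = obs_codes < 4  # (B, L)
    mismatch = (obs_codes[:, :, None] != ref_codes[None, :, :].swapaxes(1, 2)) & informative[:, :, None]
    inf_mass = g_ref * informative[:, :, None]
    return SufficientStats(
        mismatches=(g_ref * mismatch).sum(axis=(0, 1)),
        emissions=inf_mass.sum(axis=(0, 1)),
    )


def accumulate_stats(
    q: ThreadedQuery,
    forward,
    backward: np.ndarray,
    msa: ReferenceMSA,
    space: StateSpace,
) -> SufficientStats:
    """Per-query expected counts from one forward/backward pair.

    ``forward`` must carry the scaled alpha lattice (as produced by
    :func:`chimehmm.hmm.forward_batch` with ``keep_lattice=True``) or be a
    dict with an ``alpha`` entry; ``backward`` is the matching (L, 2NK) or
    (L, 2, N, K) scaled beta array.
    """
    obs = encode(q.obs)[None, :]
    if isinstance(forward, dict):
        alpha = forward["alpha"]
    else:
        alpha = np.asarray(forward)[None, ...]
    L = msa.L
    alpha = alpha.reshape(1, L, 2, space.N, space.K)
    beta = np.asarray(backward).reshape(1, L, 2, space.N, space.K)
    return _stats_from_lattices(obs, msa.codes, alpha, beta)


def reestimate_rates(
    stats: SufficientStats,
    prev_rates: np.ndarray | None = None,
    rate_floor: float = 1e-6,
    rate_ceiling: float = 0.3,
) -> np.ndarray:
    """M-step: rate_r = mismatches_r / emissions_r, clamped to the bounds.

    References with no informative emission mass keep their previous rate.
    """
    if np.any(stats.mismatches < 0) or np.any(stats.mismatches > stats.emissions + 1e-9):
        raise ValueError("inconsistent sufficient statistics")
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = stats.mismatches / stats.emissions
    rates = np.clip(raw, rate_floor, rate_ceiling)
    empty = stats.emissions == 0
    if np.any(empty):
        if prev_rates is None:
            raise ValueError("references with no emissions but no previous rates given")
        rates[empty] = np.asarray(prev_rates)[empty]
    return rates


@dataclass
class BWFit:
    """Result of the EM fit: per-reference rates and per-query posteriors."""

    rates: np.ndarray
    results: list[ForwardResult]
    log_likelihoods: list[float]
    n_iter: int

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([r.posterior for r in self.results])


def fit_bw(
    queries: Sequence[ThreadedQuery],
    msa: ReferenceMSA,
    bw_config: BWConfig | None = None,
    model_config: ModelConfig | None = None,
    chunk: int = 512,
) -> BWFit:
    """Fit per-reference mutation rates by EM and score every query.

    The E-step pools expected mismatch/emission counts over the whole dataset
    (both U and C states of each reference); the M-step is the clamped ratio
    estimator.  Total log-likelihood is non-decreasing across iterations; the
    loop stops when the improvement drops below ``tol`` or at ``max_iter``.
    Final posteriors are computed under the fitted rates.
    """
    if not queries:
        raise ValueError("fit_bw requires at least one query")
    bw = bw_config or BWConfig()
    cfg = model_config or ModelConfig(mu=0.0, rates=(bw.init_rate,), method="BW")
    if cfg.K != 1:
        raise ValueError("the BW variant has exactly one rate class per reference")
    N = msa.N
    obs = np.vstack([encode(q.obs) for q in queries])
    rates = np.full((N, 1), bw.init_rate)
    lls: list[float] = []
    n_iter = 0
    for it in range(bw.max_iter):
        stats = SufficientStats.zeros(N)
        total_ll = 0.0
        for lo in range(0, len(queries), chunk):
            hi = min(lo + chunk, len(queries))
            fwd = forward_batch(
                obs[lo:hi], msa.codes, rates, cfg.psi, cfg.mu, keep_lattice=True
            )
            beta = backward_batch(
                obs[lo:hi], msa.codes, rates, cfg.psi, cfg.mu, fwd["scale"]
            )
            stats += _stats_from_lattices(obs[lo:hi], msa.codes, fwd["alpha"], beta)
            total_ll += float(fwd["log_evidence"].sum())
        lls.append(total_ll)
        n_iter = it + 1
        rates = reestimate_rates(
            stats, rates, rate_floor=bw.rate_floor, rate_ceiling=bw.rate_ceiling
        ).reshape(N, 1)
        if it > 0 and lls[-1] - lls[-2] < bw.tol:
            break
    # final posteriors under the fitted rates
    results: list[ForwardResult] = []
    for lo in range(0, len(queries), chunk):
        hi = min(lo + chunk, len(queries))
        r = forward_batch(obs[lo:hi], msa.codes, rates, cfg.psi, cfg.mu)
        for b in range(hi - lo):
            results.append(
                ForwardResult(
                    log_evidence=float(r["log_evidence"][b]),
                    log_chimeric_mass=float(r["log_chimeric_mass"][b]),
                    posterior=float(r["posterior"][b]),
                    scale_factors=r["scale"][b],
                )
            )
    logger.info(
        "BW fit: %d iterations, final log-likelihood %.3f", n_iter, lls[-1]
    )
    return BWFit(rates=rates.ravel(), results=results, log_likelihoods=lls, n_iter=n_iter)
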