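"""Hierarchical ABC over co-distributed taxon pairs (msBayes-style).

The hierarchical model: the number of distinct divergence events Ψ is uniform
on {1..Y}; Ψ event times are i.i.d. uniform on (0, upper_tau]; each taxon pair
is assigned uniformly at random to an event, redrawing until every event has
at least one pair. Per-pair nuisance parameters (θ, migration, ancestral size)
come from independent uniform priors. Each prior draw is pushed through the
two-deme coalescent to a vector of six summary statistics per pair; simple
rejection against the observed vector (columns standardized by the reference
table's moments, Euclidean distance, fixed acceptance fraction) yields the
posterior over Ψ, the mean divergence time E(τ), and the dispersion index
Ω = Var(τ)/E(τ), whose posterior mass near zero measures support for
simultaneous divergence (summarized by a Bayes factor on Ω ≤ ε vs Ω > ε).
"""

from __future__ import annotations

import dataclasses
import functools
import logging
import math

import numpy as np
import pandas as pd

from .coalescent_sim import simulate_summaries_batch
from .errors import ConfigError, InputError

logger = logging.getLogger("beringia")


@dataclasses.dataclass
class HabcConfig:
    """Hyperprior bounds and rejection settings.

    ``upper_rec`` is fixed at 0: the mitochondrial locus does not recombine, so
    one genealogy underlies each pair. ``theta_upper`` of None is resolved at
    run time to twice the largest observed pooled Watterson's θ across pairs.
    ``upper_size`` bounds descendant deme sizes as fractions of the reference
    population (the one whose θ is ``theta_upper``): the analysis is run on
    taxon pairs pre-screened as differentiated, i.e. whose mitochondrial
    lineages have largely sorted within the bounded divergence-time window, so
    the prior concentrates on demes small enough to sort on that time scale.
    ``upper_anc`` is relative to the pair's current (mean descendant) size.
    """

    upper_tau: float = 0.2
    upper_mig: float = 10.0
    upper_rec: float = 0.0
    upper_anc: float = 0.5
    upper_size: float = 0.25
    theta_upper: float | None = None
    psi_max: int | None = None  # None -> number of pairs
    n_reps: int = 100_000
    tolerance: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.tolerance <= 1.0):
            raise ConfigError(f"tolerance must lie in (0, 1], got {self.tolerance}")
        if self.upper_tau <= 0:
            raise ConfigError("upper_tau must be positive")
        if self.upper_rec != 0.0:
            raise ConfigError("recombination is hard-wired to 0 for mtDNA")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be positive")
        if self.psi_max is not None and self.psi_max < 1:
            raise ConfigError("psi_max must be >= 1")


@dataclasses.dataclass
class HyperDraw:
    """One sampled hierarchical parameter set.

    Times are in units of 4·N_ref generations where N_ref is the population
    whose per-site θ equals ``theta_upper``; per-pair descendant deme sizes
    are uniform on (0, upper_size] as fractions of N_ref, and the ancestral
    size is uniform on (0, upper_anc] RELATIVE to the pair's mean descendant
    size (``anc`` stores the absolute ratio handed to the simulator).
    """

    psi: int
    class_times: np.ndarray  # psi distinct event times
    assignment: np.ndarray  # pair index -> class index
    tau_by_pair: np.ndarray
    size_a: np.ndarray  # descendant deme sizes relative to N_ref
    size_b: np.ndarray
    mig: np.ndarray
    anc: np.ndarray


@dataclasses.dataclass
class ReferenceTable:
    """Prior-predictive table: hyperparameters plus simulated statistics."""

    psi: np.ndarray  # (n_reps,)
    e_tau: np.ndarray
    omega: np.ndarray
    stats: np.ndarray  # (n_reps, 6 * Y)
    n_pairs: int
    config: HabcConfig

    def __len__(self) -> int:
        return len(self.psi)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"stat_{i}": self.stats[:, i] for i in range(self.stats.shape[1])}
        return pd.DataFrame({"psi": self.psi, "e_tau": self.e_tau, "omega": self.omega, **cols})


@dataclasses.dataclass
class Posterior:
    """Rejection-sampling posterior over the hyperparameters."""

    psi: np.ndarray  # accepted Ψ draws
    e_tau: np.ndarray
    omega: np.ndarray
    distances: np.ndarray
    accepted_idx: np.ndarray
    n_pairs: int

    @property
    def psi_probs(self) -> np.ndarray:
        """P(Ψ = k) for k = 1..Y from accepted-draw frequencies."""
        counts = np.bincount(self.psi, minlength=self.n_pairs + 1)[1:]
        return counts / counts.sum()

    @property
    def psi_mode(self) -> int:
        return int(np.argmax(self.psi_probs)) + 1

    def prob_omega_above(self, epsilon: float = 0.01) -> float:
        return float((self.omega > epsilon).mean())

    def summary(self) -> dict:
        return {
            "n_accepted": int(len(self.psi)),
            "psi_mode": self.psi_mode,
            "psi_probs": self.psi_probs.tolist(),
            "e_tau_mean": float(self.e_tau.mean()),
            "e_tau_quantiles": np.quantile(self.e_tau, [0.025, 0.5, 0.975]).tolist(),
            "omega_mean": float(self.omega.mean()),
            "omega_median": float(np.median(self.omega)),
            "omega_quantiles": np.quantile(self.omega, [0.025, 0.5, 0.975]).tolist(),
            "p_omega_gt_0.01": self.prob_omega_above(0.01),
        }


def dispersion_index(taus) -> float:
    """Ω = Var(τ)/E(τ) with population variance; 0 for an all-zero vector."""
    taus = np.asarray(taus, dtype=float)
    if taus.size == 0:
        raise InputError("dispersion index of an empty vector is undefined")
    if taus.max() == taus.min():  # exact zero for shared times (Ψ = 1)
        return 0.0
    mean = taus.mean()
    if mean == 0.0:
        return 0.0
    return float(taus.var() / mean)


# ---------------------------------------------------------------------------
# hyperprior sampling
#
# The pair→event assignment is uniform over assignments conditioned on every
# event class being nonempty, i.e. uniform over surjections. Naive redrawing
# has acceptance probability psi!·S(Y,psi)/psi^Y, which collapses for psi ≈ Y
# (≈6e-8 at Y = 19), so the same distribution is sampled exactly: a uniform
# set partition of the Y pairs into psi blocks via the Stirling recursion
# S(n,k) = k·S(n−1,k) + S(n−1,k−1), then a random bijection of blocks to
# event classes.


@functools.lru_cache(maxsize=None)
def _stirling2(n: int, k: int) -> int:
    if k == 0:
        return 1 if n == 0 else 0
    if k > n:
        return 0
    if k == n:
        return 1
    return k * _stirling2(n - 1, k) + _stirling2(n - 1, k - 1)


def _random_surjection(n_items: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random surjection {0..n_items−1} → {0..k−1}."""
    leaders = np.zeros(n_items, dtype=bool)
    kk = k
    for i in range(n_items, 0, -1):
        if kk == 0:
            break
        if kk == i:
            leaders[:i] = True
            kk = 0
            break
        p_new = _stirling2(i - 1, kk - 1) / _stirling2(i, kk)
        if rng.random() < p_new:
            leaders[i - 1] = True
            kk -= 1
    assignment = np.empty(n_items, dtype=np.int64)
    n_blocks = 0
    for i in range(n_items):
        if leaders[i]:
            assignment[i] = n_blocks
            n_blocks += 1
        else:
            assignment[i] = int(rng.integers(n_blocks))
    return rng.permutation(k)[assignment]


def _resolve_psi_max(config: HabcConfig, n_pairs: int) -> int:
    psi_max = config.psi_max if config.psi_max is not None else n_pairs
    if psi_max > n_pairs:
        raise ConfigError("psi_max cannot exceed the number of pairs")
    return psi_max


def draw_hyper_batch(
    config: HabcConfig, n_pairs: int, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Batch hyperprior draws: n joint (Ψ, τ, nuisance) samples.

    Returns arrays: psi (n,), tau/size_a/size_b/mig/anc (n, n_pairs), e_tau,
    omega. Pair→class assignments are uniform conditioned on all Ψ classes
    nonempty. Time is in 4·N_ref units with θ_ref = theta_upper; descendant
    deme sizes are U(0, upper_size] fractions of N_ref and ancestral sizes
    U(0, upper_anc] relative to the pair's mean descendant size.
    """
    if config.theta_upper is None or config.theta_upper <= 0:
        raise ConfigError("theta_upper must be resolved to a positive value")
    psi_max = _resolve_psi_max(config, n_pairs)
    psi = rng.integers(1, psi_max + 1, size=n)
    class_times = rng.uniform(0.0, config.upper_tau, size=(n, psi_max))
    assignment = np.empty((n, n_pairs), dtype=np.int64)
    for row in range(n):
        assignment[row] = _random_surjection(n_pairs, int(psi[row]), rng)
    tau = np.take_along_axis(class_times, assignment, axis=1)
    size_a = rng.uniform(0.0, config.upper_size, size=(n, n_pairs))
    size_b = rng.uniform(0.0, config.upper_size, size=(n, n_pairs))
    mig = rng.uniform(0.0, config.upper_mig, size=(n, n_pairs))
    # ancestral size bound is RELATIVE to the pair's current (mean descendant)
    # size; the absolute ratio passed to the simulator is u · (x_a + x_b)/2
    anc_rel = rng.uniform(0.0, config.upper_anc, size=(n, n_pairs))
    anc = anc_rel * 0.5 * (size_a + size_b)
    # guard against literal zero sizes (measure-zero but fatal to rates)
    tiny = 1e-9
    size_a = np.maximum(size_a, tiny)
    size_b = np.maximum(size_b, tiny)
    anc = np.maximum(anc, tiny)
    e_tau = tau.mean(axis=1)
    omega = np.where(e_tau > 0, tau.var(axis=1) / np.where(e_tau > 0, e_tau, 1.0), 0.0)
    return {
        "psi": psi,
        "tau": tau,
        "size_a": size_a,
        "size_b": size_b,
        "mig": mig,
        "anc": anc,
        "e_tau": e_tau,
        "omega": omega,
    }


def draw_hyper(
    config: HabcConfig, n_pairs: int, rng: np.random.Generator
) -> HyperDraw:
    """One hierarchical prior draw (see draw_hyper_batch for the scheme)."""
    psi_max = _resolve_psi_max(config, n_pairs)
    psi = int(rng.integers(1, psi_max + 1))
    class_times = rng.uniform(0.0, config.upper_tau, size=psi)
    assignment = _random_surjection(n_pairs, psi, rng)
    if config.theta_upper is None or config.theta_upper <= 0:
        raise ConfigError("theta_upper must be resolved to a positive value")
    size_a = rng.uniform(0.0, config.upper_size, size=n_pairs)
    size_b = rng.uniform(0.0, config.upper_size, size=n_pairs)
    return HyperDraw(
        psi=psi,
        class_times=class_times,
        assignment=assignment,
        tau_by_pair=class_times[assignment],
        size_a=size_a,
        size_b=size_b,
        mig=rng.uniform(0.0, config.upper_mig, size=n_pairs),
        anc=rng.uniform(0.0, config.upper_anc, size=n_pairs) * 0.5 * (size_a + size_b),
    )


def prior_omega_samples(
    config: HabcConfig, n_pairs: int, n: int = 100_000, seed: int | None = None
) -> np.ndarray:
    """Fresh hyperprior Ω samples (for Bayes-factor prior odds).

    Only the (Ψ, τ, assignment) layer matters for Ω, so no simulation is run.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    cfg = dataclasses.replace(config, theta_upper=config.theta_upper or 1.0)
    draws = draw_hyper_batch(cfg, n_pairs, n, rng)
    return draws["omega"]


# ---------------------------------------------------------------------------
# reference table


def build_reference_table(
    layout: list[tuple[int, int, int]],
    config: HabcConfig,
    chunk_size: int = 20_000,
) -> ReferenceTable:
    """Simulate the prior-predictive reference table for one study layout.

    ``layout`` is the observed study's per-pair (n_a, n_b, locus_length).
    Work proceeds in chunks (progress logged, seeds derived per chunk from
    config.seed) so paper-scale runs can be checkpointed by the caller.
    """
    if config.theta_upper is None or config.theta_upper <= 0:
        raise ConfigError("theta_upper must be set (e.g. 2x max observed pooled θ_W)")
    n_pairs = len(layout)
    if n_pairs < 1:
        raise ConfigError("layout must contain at least one pair")
    rng = np.random.default_rng(config.seed)
    psi_parts, etau_parts, omega_parts, stat_parts = [], [], [], []
    done = 0
    while done < config.n_reps:
        m = min(chunk_size, config.n_reps - done)
        draws = draw_hyper_batch(config, n_pairs, m, rng)
        chunk_seed = int(rng.integers(0, 2**31 - 1))
        stats = simulate_summaries_batch(
            layout,
            draws["tau"],
            draws["mig"],
            np.full_like(draws["tau"], config.theta_upper),
            draws["anc"],
            size_a=draws["size_a"],
            size_b=draws["size_b"],
            seed=chunk_seed,
        )
        psi_parts.append(draws["psi"])
        etau_parts.append(draws["e_tau"])
        omega_parts.append(draws["omega"])
        stat_parts.append(stats)
        done += m
        logger.info("reference table: %d / %d replicates", done, config.n_reps)
    return ReferenceTable(
        psi=np.concatenate(psi_parts),
        e_tau=np.concatenate(etau_parts),
        omega=np.concatenate(omega_parts),
        stats=np.vstack(stat_parts),
        n_pairs=n_pairs,
        config=config,
    )


# ---------------------------------------------------------------------------
# rejection


def _sort_pair_blocks(stats: np.ndarray, n_pairs: int, key_stat: int = 2) -> np.ndarray:
    """Reorder each row's per-pair statistic blocks by descending key statistic.

    Taxon pairs are exchangeable under the hierarchical prior, so observed and
    simulated vectors are aligned by their divergence order statistics
    (default key: π_between) before distances are computed — otherwise a draw
    whose deep-divergence pair sits at a different index than the observed
    deep pair is penalized as badly as a genuinely mismatched draw.
    """
    n = stats.shape[0]
    blocks = stats.reshape(n, n_pairs, 6)
    order = np.argsort(-blocks[:, :, key_stat], axis=1, kind="stable")
    return np.take_along_axis(blocks, order[:, :, None], axis=1).reshape(n, -1)


def rejection_sample(
    observed: np.ndarray,
    table: ReferenceTable,
    tolerance: float | None = None,
    sort_pairs: bool = True,
) -> Posterior:
    """Simple rejection: accept the ⌈tolerance·n⌉ reference rows closest to
    the observed vector in standardized Euclidean distance.

    Columns are standardized by the reference table's mean/SD; zero-variance
    columns are dropped from the distance with a warning; ties are broken by
    row index (stable sort). With ``sort_pairs`` (default) the per-pair
    statistic blocks of both the table and the observed vector are aligned by
    descending π_between before the distance is taken (see _sort_pair_blocks).
    """
    observed = np.asarray(observed, dtype=float).ravel()
    if observed.size != table.stats.shape[1]:
        raise InputError(
            f"observed vector has {observed.size} entries, table has "
            f"{table.stats.shape[1]} statistic columns"
        )
    tol = table.config.tolerance if tolerance is None else tolerance
    if not (0.0 < tol <= 1.0):
        raise InputError(f"tolerance must lie in (0, 1], got {tol}")
    stats = table.stats
    if sort_pairs:
        stats = _sort_pair_blocks(stats, table.n_pairs)
        observed = _sort_pair_blocks(observed.reshape(1, -1), table.n_pairs).ravel()
    mean = stats.mean(axis=0)
    sd = stats.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "%d zero-variance statistic column(s) dropped from rejection distance",
            int((~keep).sum()),
        )
    z_table = (stats[:, keep] - mean[keep]) / sd[keep]
    z_obs = (observed[keep] - mean[keep]) / sd[keep]
    dist = np.sqrt(((z_table - z_obs) ** 2).sum(axis=1))
    n_accept = max(1, math.ceil(tol * len(table)))
    order = np.argsort(dist, kind="stable")[:n_accept]
    return Posterior(
        psi=table.psi[order].astype(int),
        e_tau=table.e_tau[order],
        omega=table.omega[order],
        distances=dist[order],
        accepted_idx=order,
        n_pairs=table.n_pairs,
    )


def bayes_factor_omega(
    posterior: Posterior, prior_omega: np.ndarray, epsilon: float = 0.01
) -> float:
    """Bayes factor for simultaneous divergence: (Ω ≤ ε) vs (Ω > ε).

    BF = posterior odds / prior odds. Returns 0.0 when the posterior puts no
    mass at Ω ≤ ε and math.inf when it puts no mass above ε (with finite prior
    odds). Raises when the prior sample is entirely on one side.
    """
    prior_omega = np.asarray(prior_omega, dtype=float)
    if prior_omega.size == 0 or posterior.omega.size == 0:
        raise InputError("need nonempty posterior and prior Ω samples")
    prior_le = float((prior_omega <= epsilon).mean())
    if prior_le in (0.0, 1.0):
        raise InputError(
            "prior Ω mass is entirely on one side of epsilon; "
            "enlarge the prior sample"
        )
    post_le = float((posterior.omega <= epsilon).mean())
    prior_odds = prior_le / (1.0 - prior_le)
    if post_le == 0.0:
        return 0.0
    if post_le == 1.0:
        return math.inf
    return (post_le / (1.0 - post_le)) / prior_odds
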