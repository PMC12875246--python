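"""Two-deme isolation-with-migration coalescent with a finite/infinite-sites
mutation layer.

Time and rate scaling (pinned once, used everywhere τ and θ appear):

* time is measured in units of 4·N_ref generations of the reference deme;
* a pair of lineages in a deme of relative size x coalesces at rate 1/x;
* each lineage migrates to the other deme at rate mig/2 (symmetric);
* mutations fall at rate θ/2 per site per lineage per unit time.

Under this convention two singleton samples with mig = 0 have
E[per-site between-deme divergence] = θ·(τ + anc_ratio): the pair cannot
coalesce before the split at τ and then coalesces at rate 1/anc_ratio.

Two execution paths produce the same process: a readable per-replicate path
(`simulate_genealogy` → `drop_mutations` → `pair_summary_vector`) that builds
genealogies and alignments, and a numba batch kernel
(`simulate_summaries_batch`) that accumulates the six summary statistics
branch-wise under infinite sites without materializing alignments — the form
the hierarchical ABC reference table needs millions of times.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from numba import njit

from .errors import ConfigError, InputError
from .io_manifest import DemeAlignment
from .popgen_stats import (
    _pi_or_zero,
    mean_pairwise_p,
    sfs_stats,
)

SUMMARY_STAT_NAMES = (
    "pi_a",
    "pi_b",
    "pi_between",
    "d_a_net",
    "theta_w_pooled",
    "tajima_d_pooled",
)

_CODE_TO_BASE = np.array(list("ACGT"))


@dataclasses.dataclass
class PairDemography:
    """Demographic parameters of one taxon pair.

    ``theta`` is the per-site scaled mutation rate 4·N_ref·μ of the reference
    deme; ``tau`` the split time in units of 4·N_ref generations; ``mig`` the
    symmetric scaled migration rate; size ratios are relative to the reference
    deme (ratio 1).
    """

    n_a: int
    n_b: int
    theta: float
    tau: float
    mig: float = 0.0
    size_ratio_a: float = 1.0
    size_ratio_b: float = 1.0
    anc_ratio: float = 1.0
    locus_length: int = 1041

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise InputError("sample sizes must be >= 1")
        if self.theta <= 0:
            raise InputError(f"theta must be positive, got {self.theta}")
        if self.tau < 0 or self.mig < 0:
            raise InputError("tau and mig must be >= 0")
        if min(self.size_ratio_a, self.size_ratio_b, self.anc_ratio) <= 0:
            raise InputError("size ratios must be positive")
        if self.locus_length < 1:
            raise InputError("locus_length must be >= 1")


@dataclasses.dataclass
class Genealogy:
    """Coalescent tree: leaves 0..n−1 (deme A first), internal nodes appended.

    ``parent[i]`` is −1 for the root; ``time`` is in 4·N_ref units.
    """

    parent: np.ndarray
    time: np.ndarray
    n_a: int
    n_b: int

    @property
    def n_leaves(self) -> int:
        return self.n_a + self.n_b

    @property
    def height(self) -> float:
        return float(self.time[-1])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        idx = np.arange(len(self.parent) - 1)
        return self.time[self.parent[idx]] - self.time[idx]

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_sets(self) -> np.ndarray:
        """(n_nodes, n_leaves) boolean matrix of leaf descendants."""
        n_nodes = len(self.parent)
        n = self.n_leaves
        desc = np.zeros((n_nodes, n), dtype=bool)
        desc[np.arange(n), np.arange(n)] = True
        # internal nodes are created in increasing time order, so children
        # always precede parents in index order
        for i in range(n_nodes - 1):
            desc[self.parent[i]] |= desc[i]
        return desc


@dataclasses.dataclass
class SimulatedPair:
    """A simulated two-deme alignment plus its genealogy."""

    deme_a: DemeAlignment
    deme_b: DemeAlignment
    tree: Genealogy
    n_mutations: int


def simulate_genealogy(
    demog: PairDemography, seed: int | np.random.Generator = 0
) -> Genealogy:
    """Structured coalescent of a two-deme split with symmetric migration.

    Lineages coalesce within demes and migrate until time ``tau``, when all
    surviving lineages merge into the ancestral deme of relative size
    ``anc_ratio``; the process continues to the MRCA.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = demog.n_a + demog.n_b
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    active = list(range(n))
    deme = [0] * demog.n_a + [1] * demog.n_b
    sizes = (demog.size_ratio_a, demog.size_ratio_b)
    next_node = n
    t = 0.0
    merged = demog.tau <= 0.0

    def _coalesce(members: list[int]) -> None:
        nonlocal next_node
        i, j = rng.choice(len(members), size=2, replace=False)
        a, b = members[i], members[j]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        pos_a, pos_b = active.index(a), active.index(b)
        deme_new = deme[pos_a]
        for pos in sorted((pos_a, pos_b), reverse=True):
            active.pop(pos)
            deme.pop(pos)
        active.append(next_node)
        deme.append(deme_new)
        next_node += 1

    while len(active) > 1:
        if not merged:
            k = [deme.count(0), deme.count(1)]
            coal = [k[d] * (k[d] - 1) / 2.0 / sizes[d] for d in (0, 1)]
            mig_rate = len(active) * demog.mig / 2.0
            total = coal[0] + coal[1] + mig_rate
            if total <= 0.0:
                t = demog.tau
                merged = True
                continue
            dt = rng.exponential(1.0 / total)
            if t + dt >= demog.tau:
                t = demog.tau
                merged = True
                continue
            t += dt
            u = rng.uniform(0.0, total)
            if u < coal[0] + coal[1]:
                d = 0 if u < coal[0] else 1
                members = [a for a, dm in zip(active, deme) if dm == d]
                _coalesce(members)
            else:
                pos = int(rng.integers(len(active)))
                deme[pos] = 1 - deme[pos]
        else:
            k = len(active)
            rate = k * (k - 1) / 2.0 / demog.anc_ratio
            t += rng.exponential(1.0 / rate)
            _coalesce(list(active))
    return Genealogy(parent=parent, time=time, n_a=demog.n_a, n_b=demog.n_b)


def drop_mutations(
    tree: Genealogy,
    theta: float,
    locus_length: int,
    model: str = "infinite_sites",
    seed: int | np.random.Generator = 0,
) -> SimulatedPair:
    """Place mutations on a genealogy and build the two-deme alignment.

    Mutations fall as a Poisson process at rate θ/2 per site per lineage per
    unit time. ``infinite_sites`` gives every event a fresh column;
    ``finite_sites_jc`` draws columns with replacement and applies a uniform
    non-identical substitution in time order (oldest first), i.e. Jukes–Cantor.
    The root sequence is uniform random.
    """
    if model not in ("infinite_sites", "finite_sites_jc"):
        raise ConfigError(f"unknown mutation model {model!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = tree.n_leaves
    lengths = tree.branch_lengths()
    tbl = float(lengths.sum())
    n_mut = int(rng.poisson(0.5 * theta * locus_length * tbl)) if tbl > 0 else 0
    aln = np.tile(rng.integers(0, 4, size=locus_length, dtype=np.uint8), (n, 1))
    if n_mut > 0:
        branch = rng.choice(len(lengths), size=n_mut, p=lengths / tbl)
        desc = tree.leaf_sets()
        if model == "infinite_sites":
            if n_mut > locus_length:
                raise InputError(
                    f"{n_mut} mutations exceed locus length {locus_length} "
                    "under infinite sites; lower theta or use finite_sites_jc"
                )
            cols = rng.choice(locus_length, size=n_mut, replace=False)
            for b, col in zip(branch, cols):
                anc = aln[0, col]
                derived = (anc + rng.integers(1, 4)) % 4
                aln[desc[b], col] = derived
        else:
            cols = rng.integers(0, locus_length, size=n_mut)
            # event time uniform along its branch; apply oldest first so
            # repeat hits at a column layer correctly along each lineage
            t_event = tree.time[branch] + rng.uniform(size=n_mut) * lengths[branch]
            order = np.argsort(-t_event, kind="stable")
            for idx in order:
                b, col = branch[idx], cols[idx]
                leaves = desc[b]
                current = aln[np.flatnonzero(leaves)[0], col]
                aln[leaves, col] = (current + rng.integers(1, 4)) % 4
    residues = ["".join(_CODE_TO_BASE[row]) for row in aln]
    deme_a = DemeAlignment(
        "A", [(f"a{i}", residues[i]) for i in range(tree.n_a)]
    )
    deme_b = DemeAlignment(
        "B", [(f"b{i}", residues[tree.n_a + i]) for i in range(tree.n_b)]
    )
    return SimulatedPair(deme_a=deme_a, deme_b=deme_b, tree=tree, n_mutations=n_mut)


def summary_vector_from_matrices(mat_a: np.ndarray, mat_b: np.ndarray) -> np.ndarray:
    """Six summary statistics of a two-deme alignment, SUMMARY_STAT_NAMES order.

    (π_a, π_b, π_between, D_A, pooled Watterson's θ, pooled Tajima's D);
    Tajima's D on monomorphic data is imputed as 0 to keep the vector
    dimension fixed for rejection distances.
    """
    pi_a = _pi_or_zero(mat_a, "A")
    pi_b = _pi_or_zero(mat_b, "B")
    pi_between, _ = mean_pairwise_p(mat_a, mat_b)
    d_a = pi_between - 0.5 * (pi_a + pi_b)
    pooled = np.concatenate([mat_a, mat_b])
    theta_w, tajima = sfs_stats(pooled)
    return np.array(
        [pi_a, pi_b, pi_between, d_a, theta_w, 0.0 if tajima is None else tajima]
    )


def pair_summary_vector(sim: SimulatedPair) -> np.ndarray:
    """Summary statistics of a simulated pair (see summary_vector_from_matrices)."""
    return summary_vector_from_matrices(sim.deme_a.matrix(), sim.deme_b.matrix())


def simulate_pair(demog: PairDemography, seed: int | np.random.Generator = 0,
                  model: str = "infinite_sites") -> SimulatedPair:
    """Genealogy plus mutations in one call (shared rng stream)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = simulate_genealogy(demog, rng)
    return drop_mutations(tree, demog.theta, demog.locus_length, model=model, seed=rng)


# ---------------------------------------------------------------------------
# batch kernel (numba): branch-wise summary statistics under infinite sites
#
# Every mutation on a branch whose descendant set contains d_a leaves of deme A
# and d_b of deme B contributes, per mutation,
#   d_a·(n_a−d_a)              mismatches to the within-A pair sum,
#   d_b·(n_b−d_b)              to the within-B pair sum,
#   d_a·(n_b−d_b)+d_b·(n_a−d_a) to the between sum, and
#   d·(n−d)                    to the pooled sum (d = d_a+d_b),
# so the six statistics follow from per-branch Poisson mutation counts and the
# (d_a, d_b) bookkeeping carried along the coalescent — no alignment needed.


@njit(cache=True)
def _sim_stats_batch(n_a_arr, n_b_arr, len_arr, tau, mig, theta, anc, sra, srb, seed, out):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    n_reps, n_pairs = tau.shape
    for r in range(n_reps):
        for y in range(n_pairs):
            n_a = n_a_arr[y]
            n_b = n_b_arr[y]
            L = len_arr[y]
            n = n_a + n_b
            tau_v = tau[r, y]
            mig_v = mig[r, y]
            theta_v = theta[r, y]
            anc_v = anc[r, y]
            size_a = sra[r, y]
            size_b = srb[r, y]

            deme = np.empty(n, dtype=np.int64)
            da = np.empty(n, dtype=np.int64)
            db = np.empty(n, dtype=np.int64)
            tstart = np.zeros(n)
            for i in range(n_a):
                deme[i] = 0
                da[i] = 1
                db[i] = 0
            for i in range(n_a, n):
                deme[i] = 1
                da[i] = 0
                db[i] = 1
            k = n
            k_a = n_a
            k_b = n_b
            t = 0.0
            merged = tau_v <= 0.0

            s_total = 0
            w_a = 0.0
            w_b = 0.0
            w_bt = 0.0
            w_pool = 0.0

            while k > 1:
                if not merged:
                    ca = 0.5 * k_a * (k_a - 1) / size_a
                    cb = 0.5 * k_b * (k_b - 1) / size_b
                    mr = k * mig_v * 0.5
                    total = ca + cb + mr
                    if total <= 0.0:
                        t = tau_v
                        merged = True
                        continue
                    dt = np.random.exponential(1.0 / total)
                    if t + dt >= tau_v:
                        t = tau_v
                        merged = True
                        continue
                    t += dt
                    u = np.random.random() * total
                    if u < ca + cb:
                        d_ev = 0 if u < ca else 1
                        k_d = k_a if d_ev == 0 else k_b
                        r1 = int(np.random.random() * k_d)
                        r2 = int(np.random.random() * (k_d - 1))
                        if r2 >= r1:
                            r2 += 1
                        i1 = -1
                        i2 = -1
                        c = 0
                        for i in range(k):
                            if deme[i] == d_ev:
                                if c == r1:
                                    i1 = i
                                if c == r2:
                                    i2 = i
                                c += 1
                        # finish both branches, accumulate mutations
                        for idx in (i1, i2):
                            ln = t - tstart[idx]
                            m = np.random.poisson(0.5 * theta_v * L * ln)
                            if m > 0:
                                s_total += m
                                w_a += m * da[idx] * (n_a - da[idx])
                                w_b += m * db[idx] * (n_b - db[idx])
                                w_bt += m * (da[idx] * (n_b - db[idx]) + db[idx] * (n_a - da[idx]))
                                d_tot = da[idx] + db[idx]
                                w_pool += m * d_tot * (n - d_tot)
                        da[i1] += da[i2]
                        db[i1] += db[i2]
                        tstart[i1] = t
                        # swap-remove i2
                        k -= 1
                        deme[i2] = deme[k]
                        da[i2] = da[k]
                        db[i2] = db[k]
                        tstart[i2] = tstart[k]
                        if d_ev == 0:
                            k_a -= 1
                        else:
                            k_b -= 1
                    else:
                        pos = int(np.random.random() * k)
                        if deme[pos] == 0:
                            deme[pos] = 1
                            k_a -= 1
                            k_b += 1
                        else:
                            deme[pos] = 0
                            k_a += 1
                            k_b -= 1
                else:
                    rate = 0.5 * k * (k - 1) / anc_v
                    t += np.random.exponential(1.0 / rate)
                    r1 = int(np.random.random() * k)
                    r2 = int(np.random.random() * (k - 1))
                    if r2 >= r1:
                        r2 += 1
                    for idx in (r1, r2):
                        ln = t - tstart[idx]
                        m = np.random.poisson(0.5 * theta_v * L * ln)
                        if m > 0:
                            s_total += m
                            w_a += m * da[idx] * (n_a - da[idx])
                            w_b += m * db[idx] * (n_b - db[idx])
                            w_bt += m * (da[idx] * (n_b - db[idx]) + db[idx] * (n_a - da[idx]))
                            d_tot = da[idx] + db[idx]
                            w_pool += m * d_tot * (n - d_tot)
                    da[r1] += da[r2]
                    db[r1] += db[r2]
                    tstart[r1] = t
                    k -= 1
                    deme[r2] = deme[k]
                    da[r2] = da[k]
                    db[r2] = db[k]
                    tstart[r2] = tstart[k]

            pi_a = w_a / (0.5 * n_a * (n_a - 1)) / L if n_a > 1 else 0.0
            pi_b = w_b / (0.5 * n_b * (n_b - 1)) / L if n_b > 1 else 0.0
            pi_bt = w_bt / (n_a * n_b) / L
            d_a_net = pi_bt - 0.5 * (pi_a + pi_b)

            a1 = 0.0
            a2 = 0.0
            for i in range(1, n):
                a1 += 1.0 / i
                a2 += 1.0 / (i * i)
            theta_w = s_total / (a1 * L)
            tajima = 0.0
            if s_total > 0:
                b1 = (n + 1) / (3.0 * (n - 1))
                b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
                c1 = b1 - 1.0 / a1
                c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
                e1 = c1 / a1
                e2 = c2 / (a1 * a1 + a2)
                k_hat = w_pool / (0.5 * n * (n - 1))
                var = e1 * s_total + e2 * s_total * (s_total - 1)
                if var > 0.0:  # n = 2 leaves the normalization degenerate
                    tajima = (k_hat - s_total / a1) / math.sqrt(var)

            base = y * 6
            out[r, base] = pi_a
            out[r, base + 1] = pi_b
            out[r, base + 2] = pi_bt
            out[r, base + 3] = d_a_net
            out[r, base + 4] = theta_w
            out[r, base + 5] = tajima


def simulate_summaries_batch(
    layout: list[tuple[int, int, int]],
    tau: np.ndarray,
    mig: np.ndarray,
    theta: np.ndarray,
    anc: np.ndarray,
    size_a: np.ndarray | None = None,
    size_b: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulate (n_reps × n_pairs) replicates, returning (n_reps, 6·n_pairs) stats.

    ``layout`` gives per-pair (n_a, n_b, locus_length); parameter arrays are
    (n_reps, n_pairs). Statistics are exact infinite-sites values computed
    branch-wise (identical in law to pair_summary_vector on infinite-sites
    alignments). Fully deterministic under ``seed``.
    """
    tau = np.ascontiguousarray(tau, dtype=np.float64)
    n_reps, n_pairs = tau.shape
    if len(layout) != n_pairs:
        raise InputError("layout length must match parameter array width")

    def _as(arr):
        return np.ascontiguousarray(np.broadcast_to(arr, tau.shape), dtype=np.float64)

    mig = _as(mig)
    theta = _as(theta)
    anc = _as(anc)
    size_a = _as(size_a if size_a is not None else 1.0)
    size_b = _as(size_b if size_b is not None else 1.0)
    n_a_arr = np.array([la[0] for la in layout], dtype=np.int64)
    n_b_arr = np.array([la[1] for la in layout], dtype=np.int64)
    len_arr = np.array([la[2] for la in layout], dtype=np.int64)
    if (n_a_arr < 1).any() or (n_b_arr < 1).any() or (len_arr < 1).any():
        raise InputError("layout entries must be positive")
    out = np.empty((n_reps, 6 * n_pairs))
    _sim_stats_batch(
        n_a_arr, n_b_arr, len_arr, tau, mig, theta, anc, size_a, size_b,
        int(seed) % (2**32), out,
    )
    return out


def simulate_pair_batch(
    demog: PairDemography, n_reps: int, seed: int = 0
) -> np.ndarray:
    """(n_reps, 6) summary statistics for one fixed demography (batch kernel)."""
    shape = (n_reps, 1)
    return simulate_summaries_batch(
        [(demog.n_a, demog.n_b, demog.locus_length)],
        np.full(shape, demog.tau),
        np.full(shape, demog.mig),
        np.full(shape, demog.theta),
        np.full(shape, demog.anc_ratio),
        np.full(shape, demog.size_ratio_a),
        np.full(shape, demog.size_ratio_b),
        seed=seed,
    )
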