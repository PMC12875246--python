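"""Per-pair population-genetic statistics on two-deme alignments.

Conventions, pinned once and used everywhere:

* All pairwise quantities use **pairwise deletion**: a site is dropped from a
  given sequence pair iff either sequence is missing (N or "-") there; other
  pairs keep the site. This matches MEGA-style distance handling and keeps
  data at high coverage.
* π (nucleotide diversity) is the unbiased mean over distinct sequence pairs
  of per-site mismatch proportions; for haploid sequence panels this equals
  the classical Nei–Li estimator.
* F_ST is the Hudson/Slatkin/Maddison sequence statistic
  ``1 − H_w/H_b`` with ``H_w = (π_a + π_b)/2`` and ``H_b`` the mean between-
  deme pairwise distance. Negative values are legitimate sampling outcomes.
* Net divergence ``D_A = H_b − H_w`` (between-deme mean minus average
  within-deme diversity); it may be negative.
* Permutation p-values are reported as k/n (a flag switches to (k+1)/(n+1)).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import InputError, SaturationError, StatisticError
from .io_manifest import MISSING, DemeAlignment, TaxonPairData

logger = logging.getLogger("beringia")


# ---------------------------------------------------------------------------
# pairwise mismatch kernel


def _pair_counts(mat_x: np.ndarray, mat_y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch and comparable-site counts for all (x, y) sequence pairs.

    Returns (diff, comp) arrays of shape (n_x, n_y) using pairwise deletion.
    """
    ok = (mat_x[:, None, :] != MISSING) & (mat_y[None, :, :] != MISSING)
    ne = mat_x[:, None, :] != mat_y[None, :, :]
    diff = (ne & ok).sum(axis=2)
    comp = ok.sum(axis=2)
    return diff, comp


def mean_pairwise_p(
    mat_x: np.ndarray, mat_y: np.ndarray | None = None
) -> tuple[float, float]:
    """Average per-pair mismatch proportion with pairwise deletion.

    ``mat_x``/``mat_y`` are uint8 code matrices (rows = sequences). With
    ``mat_y`` None the average runs over distinct pairs within ``mat_x``;
    otherwise over all cross pairs. Pairs with no comparable site are excluded
    with a warning. Returns (mean proportion, mean comparable sites over the
    included pairs).
    """
    within = mat_y is None
    if within:
        if mat_x.shape[0] < 2:
            raise StatisticError("within-set mean pairwise p needs >= 2 sequences")
        diff, comp = _pair_counts(mat_x, mat_x)
        iu = np.triu_indices(mat_x.shape[0], k=1)
        diff, comp = diff[iu], comp[iu]
    else:
        diff, comp = _pair_counts(mat_x, mat_y)
        diff, comp = diff.ravel(), comp.ravel()
    usable = comp > 0
    if not usable.all():
        logger.warning(
            "%d sequence pair(s) share no comparable site; excluded", (~usable).sum()
        )
    if not usable.any():
        raise StatisticError("no sequence pair has a comparable site")
    props = diff[usable] / comp[usable]
    return float(props.mean()), float(comp[usable].mean())


# ---------------------------------------------------------------------------
# distances


def jc_distance(p: float, gamma_shape: float | None = None) -> float:
    """Jukes–Cantor distance, optionally gamma-corrected for rate variation.

    d = −(3/4)·ln(1 − 4p/3); with shape a,
    d = (3/4)·a·[(1 − 4p/3)^(−1/a) − 1].
    """
    if not 0.0 <= p:
        raise InputError(f"proportion p must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"p = {p} >= 3/4: Jukes-Cantor correction saturates")
    if gamma_shape is None:
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    if gamma_shape <= 0:
        raise InputError(f"gamma_shape must be positive, got {gamma_shape}")
    a = gamma_shape
    return 0.75 * a * ((1.0 - 4.0 * p / 3.0) ** (-1.0 / a) - 1.0)


def nucleotide_diversity(deme: DemeAlignment | np.ndarray) -> float:
    """π: mean per-site pairwise mismatch proportion within one deme."""
    mat = deme.matrix() if isinstance(deme, DemeAlignment) else deme
    if mat.shape[0] < 2:
        raise StatisticError("nucleotide diversity needs >= 2 sequences")
    pi, _ = mean_pairwise_p(mat)
    return pi


_warned_singleton: set[str] = set()


def _pi_or_zero(mat: np.ndarray, label: str) -> float:
    if mat.shape[0] < 2:
        if label not in _warned_singleton:  # warn once per deme label, not per call
            logger.warning("deme %s has a single sequence; π taken as 0", label)
            _warned_singleton.add(label)
        return 0.0
    return nucleotide_diversity(mat)


def net_divergence(
    pair: TaxonPairData, gamma_shape: float | None = None, corrected: bool = False
) -> tuple[float, float]:
    """(π_between, D_A) for a taxon pair.

    By default raw p-distances are averaged. With ``corrected=True`` the JC
    correction (optionally gamma) is applied to each pairwise proportion
    before averaging, for both the between and within components.
    """
    mat_a, mat_b = pair.deme_a.matrix(), pair.deme_b.matrix()

    def _avg(mx, my):
        if corrected:
            diff, comp = _pair_counts(mx, mx if my is None else my)
            if my is None:
                iu = np.triu_indices(mx.shape[0], k=1)
                diff, comp = diff[iu], comp[iu]
            else:
                diff, comp = diff.ravel(), comp.ravel()
            usable = comp > 0
            if not usable.any():
                raise StatisticError("no comparable sites")
            vals = [jc_distance(d / c, gamma_shape) for d, c in zip(diff[usable], comp[usable])]
            return float(np.mean(vals))
        return mean_pairwise_p(mx, my)[0]

    pi_between = _avg(mat_a, mat_b)
    pi_a = _avg(mat_a, None) if mat_a.shape[0] >= 2 else _pi_or_zero(mat_a, pair.deme_a.label)
    pi_b = _avg(mat_b, None) if mat_b.shape[0] >= 2 else _pi_or_zero(mat_b, pair.deme_b.label)
    d_a = pi_between - 0.5 * (pi_a + pi_b)
    return pi_between, d_a


# ---------------------------------------------------------------------------
# frequency-spectrum statistics


def _tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) of the standard Tajima variance normalization."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def sfs_stats(deme: DemeAlignment | np.ndarray) -> tuple[float, float | None]:
    """(Watterson's θ per site, Tajima's D) for one sequence panel.

    S counts columns with ≥ 2 distinct non-missing bases; the effective length
    is the count of columns with ≥ 2 non-missing sequences. D follows the
    standard normalization, with the mean pairwise difference count taken over
    distinct pairs with pairwise deletion; it is None when S = 0.
    """
    mat = deme.matrix() if isinstance(deme, DemeAlignment) else deme
    n = mat.shape[0]
    if n < 2:
        raise StatisticError("SFS statistics need >= 2 sequences")
    present = mat != MISSING
    n_present = present.sum(axis=0)
    informative = n_present >= 2
    l_eff = int(informative.sum())
    if l_eff == 0:
        raise StatisticError("no column with >= 2 non-missing sequences")
    seg = np.zeros(mat.shape[1], dtype=bool)
    for col in np.flatnonzero(informative):
        bases = mat[present[:, col], col]
        seg[col] = np.unique(bases).size > 1
    s = int(seg.sum())
    a1, e1, e2 = _tajima_constants(n)
    theta_w = s / (a1 * l_eff)
    if s == 0:
        return theta_w, None
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0.0:  # n = 2: the variance normalization vanishes, D undefined
        return theta_w, None
    diff, comp = _pair_counts(mat, mat)
    iu = np.triu_indices(n, k=1)
    k_hat = float(diff[iu].mean())  # mean pairwise difference count
    d = (k_hat - s / a1) / math.sqrt(var)
    return theta_w, d


# ---------------------------------------------------------------------------
# F_ST and its permutation test


def _fst_from_means(pi_a: float, pi_b: float, pi_between: float) -> float | None:
    if pi_between == 0.0:
        return None
    return 1.0 - 0.5 * (pi_a + pi_b) / pi_between


def hudson_fst(pair: TaxonPairData) -> float | None:
    """Hudson-style F_ST = 1 − H_w/H_b; None when H_b = 0 (undefined)."""
    mat_a, mat_b = pair.deme_a.matrix(), pair.deme_b.matrix()
    pi_between, _ = mean_pairwise_p(mat_a, mat_b)
    pi_a = _pi_or_zero(mat_a, pair.deme_a.label)
    pi_b = _pi_or_zero(mat_b, pair.deme_b.label)
    return _fst_from_means(pi_a, pi_b, pi_between)


def _fst_from_distance_matrix(
    diff: np.ndarray, comp: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> float | None:
    """F_ST for one labelling, from precomputed full pairwise matrices."""

    def _mean(rows, cols, within):
        d = diff[np.ix_(rows, cols)]
        c = comp[np.ix_(rows, cols)]
        if within:
            iu = np.triu_indices(len(rows), k=1)
            d, c = d[iu], c[iu]
        else:
            d, c = d.ravel(), c.ravel()
        usable = c > 0
        if not usable.any():
            return None
        return float((d[usable] / c[usable]).mean())

    pi_a = _mean(idx_a, idx_a, True) if len(idx_a) >= 2 else 0.0
    pi_b = _mean(idx_b, idx_b, True) if len(idx_b) >= 2 else 0.0
    pi_between = _mean(idx_a, idx_b, False)
    if pi_a is None or pi_b is None or pi_between is None:
        return None
    return _fst_from_means(pi_a, pi_b, pi_between)


def fst_permutation_test(
    pair: TaxonPairData,
    n_permutations: int = 10_000,
    seed: int = 0,
    plus_one: bool = False,
) -> float | None:
    """One-sided permutation p-value for F_ST > 0.

    Deme labels are permuted over the pooled sequences, preserving deme sizes;
    p = #(permuted F_ST ≥ observed)/n (ties count as exceeding; permutations
    with undefined F_ST count as non-exceeding). ``plus_one`` switches to the
    (k+1)/(n+1) convention. Returns None when the observed F_ST is undefined.
    """
    mat = np.concatenate([pair.deme_a.matrix(), pair.deme_b.matrix()])
    n_a = pair.deme_a.n
    n = mat.shape[0]
    diff, comp = _pair_counts(mat, mat)
    observed = _fst_from_distance_matrix(
        diff, comp, np.arange(n_a), np.arange(n_a, n)
    )
    if observed is None:
        return None
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        f = _fst_from_distance_matrix(diff, comp, perm[:n_a], perm[n_a:])
        if f is not None and f >= observed - 1e-12:
            k += 1
    if plus_one:
        return (k + 1) / (n_permutations + 1)
    return k / n_permutations


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(pvalues, q: float = 0.05) -> list[bool]:
    """Benjamini–Hochberg step-up reject flags at level q."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    if any(not (0.0 <= p <= 1.0) for p in pvalues):
        raise InputError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return [bool(r) for r in reject]


# ---------------------------------------------------------------------------
# the full per-pair statistics row


@dataclasses.dataclass
class PairStats:
    """All per-pair statistics reported by the study."""

    name: str
    n_a: int
    n_b: int
    effective_sites: float
    p_between: float
    d_jc: float
    d_jc_gamma: float | None
    pi_a: float
    pi_b: float
    pi_total: float
    pi_between: float
    d_a_net: float
    theta_w_a: float | None
    theta_w_b: float | None
    tajima_d_a: float | None
    tajima_d_b: float | None
    fst: float | None
    fst_p: float | None


def compute_pair_stats(
    pair: TaxonPairData,
    gamma_shape: float | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PairStats:
    """Compute every reported statistic for one taxon pair."""
    mat_a, mat_b = pair.deme_a.matrix(), pair.deme_b.matrix()
    p_between, eff = mean_pairwise_p(mat_a, mat_b)
    d_jc = jc_distance(p_between)
    d_jc_gamma = jc_distance(p_between, gamma_shape) if gamma_shape else None
    pi_a = _pi_or_zero(mat_a, pair.deme_a.label)
    pi_b = _pi_or_zero(mat_b, pair.deme_b.label)
    pooled = np.concatenate([mat_a, mat_b])
    pi_total = nucleotide_diversity(pooled)
    pi_between, d_a_net = net_divergence(pair)

    def _sfs(mat):
        if mat.shape[0] < 2:
            return None, None
        return sfs_stats(mat)

    theta_a, taj_a = _sfs(mat_a)
    theta_b, taj_b = _sfs(mat_b)
    fst = hudson_fst(pair)
    fst_p = (
        fst_permutation_test(pair, n_permutations=n_permutations, seed=seed)
        if fst is not None
        else None
    )
    return PairStats(
        name=pair.name,
        n_a=pair.deme_a.n,
        n_b=pair.deme_b.n,
        effective_sites=eff,
        p_between=p_between,
        d_jc=d_jc,
        d_jc_gamma=d_jc_gamma,
        pi_a=pi_a,
        pi_b=pi_b,
        pi_total=pi_total,
        pi_between=pi_between,
        d_a_net=d_a_net,
        theta_w_a=theta_a,
        theta_w_b=theta_b,
        tajima_d_a=taj_a,
        tajima_d_b=taj_b,
        fst=fst,
        fst_p=fst_p,
    )
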