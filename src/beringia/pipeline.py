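"""Study orchestration: statistics → dating → subset selection → hABC, plus
the study-level summary operations (group summaries by taxonomic depth,
significance counts, the Sanger-vs-Illumina diversity comparison).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import divergence_dating, habc, popgen_stats
from .coalescent_sim import summary_vector_from_matrices
from .errors import InputError
from .io_manifest import RunConfig, StudyManifest
from .habc import HabcConfig

logger = logging.getLogger("beringia")

GROUP_ORDER = ("all", "species", "subspecies", "population")


def group_summary(values) -> pd.DataFrame:
    """Mean, sample SD (n−1), min, max per taxonomic depth and overall.

    ``values`` is an iterable of (depth, statistic). SD is NaN for singleton
    groups. Full precision is kept; round only when rendering.
    """
    df = pd.DataFrame(list(values), columns=["depth", "value"])
    if df.empty:
        raise InputError("group_summary needs at least one value")
    df["depth"] = df["depth"].str.lower()
    unknown = set(df["depth"]) - set(GROUP_ORDER[1:])
    if unknown:
        raise InputError(f"unknown depth categories: {sorted(unknown)}")
    rows = []
    for cat in GROUP_ORDER:
        sub = df if cat == "all" else df[df["depth"] == cat]
        if sub.empty:
            continue
        vals = sub["value"].to_numpy(dtype=float)
        rows.append(
            {
                "group": cat,
                "n": len(vals),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if len(vals) > 1 else math.nan,
                "min": vals.min(),
                "max": vals.max(),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def count_significant(pvalues, alpha: float = 0.05) -> int:
    """Number of defined p-values strictly below alpha."""
    arr = pd.Series(list(pvalues), dtype=float)
    return int((arr.dropna() < alpha).sum())


def select_differentiated(
    fst_results, clade_flags, alpha: float = 0.05
) -> list[str]:
    """Differentiated subset: pairs with F_ST p < alpha, union the
    clade-flagged pairs, in stable input order.

    ``fst_results`` is an iterable of (name, p) with p possibly None/NaN.
    """
    flags = set(clade_flags)
    out = []
    for name, p in fst_results:
        significant = p is not None and not (isinstance(p, float) and math.isnan(p)) and p < alpha
        if significant or name in flags:
            out.append(name)
    return out


def sequencing_comparison(table5: pd.DataFrame) -> tuple[float, float, float]:
    """(mean Sanger π, mean Illumina π, ratio) over the per-taxon rows.

    Summary rows labelled Overall/Averages are excluded; means are unweighted
    and the ratio is kept at full precision (display rounds to 2 decimals).
    """
    taxa = table5[~table5["taxon"].isin(["Overall", "Averages"])]
    taxa = taxa.dropna(subset=["sanger_pi", "illumina_pi"])
    if taxa.empty:
        raise InputError("no taxon rows with both diversity columns")
    mean_sanger = float(taxa["sanger_pi"].mean())
    mean_illumina = float(taxa["illumina_pi"].mean())
    if mean_illumina == 0.0:
        raise InputError("Illumina mean diversity is zero; ratio undefined")
    return mean_sanger, mean_illumina, mean_sanger / mean_illumina


# ---------------------------------------------------------------------------
# end-to-end run


def pair_stats_frame(
    manifest: StudyManifest, config: RunConfig
) -> pd.DataFrame:
    """Per-pair statistics rows for a whole study (seed-deterministic)."""
    root = np.random.default_rng(config.seed)
    pair_seeds = root.integers(0, 2**31 - 1, size=max(len(manifest), 1))
    rows = []
    for i, pair in enumerate(manifest):
        st = popgen_stats.compute_pair_stats(
            pair,
            gamma_shape=config.gamma_shape,
            n_permutations=config.n_permutations,
            seed=int(pair_seeds[i]),
        )
        row = dataclasses.asdict(st)
        row["depth"] = pair.depth
        row["order"] = pair.order
        row["locus"] = pair.locus
        row["clade_flag"] = pair.clade_flag
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    manifest: StudyManifest,
    config: RunConfig,
    rate_table: pd.DataFrame | None = None,
    habc_config: HabcConfig | None = None,
) -> dict:
    """Full analysis bundle for one study.

    Computes per-pair statistics (with FDR flags), optional divergence dates,
    group summaries of the JC distance by depth, the differentiated subset
    (F_ST significance union clade flags), and — when ``habc_config`` is given
    — the hierarchical ABC posterior for the differentiated subset. Results
    are written under ``config.outdir`` as TSV/JSON; numbers are serialized at
    full precision.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(manifest) == 0:
        raise InputError("empty study manifest")

    stats = pair_stats_frame(manifest, config)
    defined = stats["fst_p"].notna()
    reject = pd.Series(False, index=stats.index)
    if defined.any():
        reject[defined] = popgen_stats.bh_fdr(stats.loc[defined, "fst_p"], q=config.fdr_q)
    stats["fst_fdr_reject"] = reject

    if rate_table is not None:
        stats["date_mya"] = divergence_dating.date_pairs(
            stats["d_jc"] * 100.0, stats["order"], stats["locus"], rate_table
        )
    stats.to_csv(outdir / "pair_stats.tsv", sep="\t", index=False)

    summary = group_summary(zip(stats["depth"], stats["d_jc"] * 100.0))
    summary.to_csv(outdir / "group_summary.tsv", sep="\t")

    flagged = {p.name for p in manifest if p.clade_flag}
    subset = select_differentiated(
        zip(stats["name"], stats["fst_p"]), flagged, alpha=config.alpha
    )
    (outdir / "subset.txt").write_text("".join(f"{s}\n" for s in subset))

    bundle = {
        "pair_stats": stats,
        "group_summary": summary,
        "n_significant": count_significant(stats["fst_p"], alpha=config.alpha),
        "subset": subset,
        "posterior": None,
    }

    if habc_config is not None:
        chosen = [p for p in manifest if p.name in set(subset)] or list(manifest)
        layout = [(p.deme_a.n, p.deme_b.n, p.length) for p in chosen]
        observed = observed_vector(chosen)
        cfg = habc_config
        if cfg.theta_upper is None:
            pooled_theta = _pooled_theta(manifest)
            cfg = dataclasses.replace(cfg, theta_upper=2.0 * pooled_theta)
            logger.info("theta_upper resolved to %.6g", cfg.theta_upper)
        table = habc.build_reference_table(layout, cfg)
        posterior = habc.rejection_sample(observed, table)
        prior_omega = habc.prior_omega_samples(cfg, len(chosen))
        report = posterior.summary()
        report["bayes_factor_omega_le_0.01"] = habc.bayes_factor_omega(
            posterior, prior_omega
        )
        report["subset"] = subset
        with open(outdir / "habc_posterior.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        bundle["posterior"] = posterior
        bundle["habc_report"] = report

    with open(outdir / "run.log", "w") as fh:
        fh.write(f"seed={config.seed}\nn_pairs={len(manifest)}\n")
        fh.write(f"n_significant={bundle['n_significant']}\nsubset={subset}\n")
    return bundle


def observed_vector(pairs) -> np.ndarray:
    """Concatenated observed summary vector across pairs, in manifest order."""
    return np.concatenate(
        [summary_vector_from_matrices(p.deme_a.matrix(), p.deme_b.matrix()) for p in pairs]
    )


def _pooled_theta(manifest: StudyManifest) -> float:
    """Max pooled Watterson's θ across pairs (per site)."""
    best = 0.0
    for pair in manifest:
        pooled = np.concatenate([pair.deme_a.matrix(), pair.deme_b.matrix()])
        theta, _ = popgen_stats.sfs_stats(pooled)
        best = max(best, theta)
    return best if best > 0 else 1e-3
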