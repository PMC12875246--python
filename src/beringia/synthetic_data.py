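"""Synthetic studies with known truth, plus the packaged printed-table fixtures.

``generate_study`` emulates the study design this package analyses: Y taxon
pairs of two-deme mitochondrial alignments (default 5+5 sequences of an
ND2-length 1,041 bp locus), with a known number of divergence events Ψ, a
known per-pair τ vector, and per-pair demography, written (optionally) as
FASTA + manifest + truth JSON. The fixtures are hand-transcribed copies of the
study's printed tables (sampling design/divergences, F_ST significance, the
Sanger-vs-Illumina π comparison, and the haplotype-clade list).
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coalescent_sim import PairDemography, simulate_pair
from .errors import InputError
from .io_manifest import MANIFEST_COLUMNS, StudyManifest, TaxonPairData, write_fasta

FIXTURE_NAMES = ("table1", "table4", "table5", "clade_list")

# default per-pair demography of a generated study, in the hierarchical
# model's own units (θ is the reference mutation scale, deme sizes are
# fractions of the reference): small, well-sorted descendant demes emulate the
# differentiated taxon pairs the hierarchical analysis targets (F_ST ≈ 0.6 at
# τ = 0.05, within-deme π ≈ 0.4%), strict vicariance, and an ancestral deme
# at the middle of its prior range — anc_ratio is RELATIVE to the current
# deme size, as in the hyperprior
DEFAULT_THETA = 0.2
DEFAULT_SIZE_RATIO = 0.02
DEFAULT_MIG = 0.0
DEFAULT_ANC_RATIO = 0.25
DEFAULT_LAYOUT = (5, 5, 1041)


@dataclasses.dataclass
class StudyTruth:
    """Ground truth of a generated study."""

    psi_true: int
    tau_by_pair: list[float]
    demographies: list[PairDemography]
    seed: int

    def to_dict(self) -> dict:
        return {
            "psi_true": self.psi_true,
            "tau_by_pair": self.tau_by_pair,
            "demographies": [dataclasses.asdict(d) for d in self.demographies],
            "seed": self.seed,
        }


def _resolve_taus(
    Y: int, psi_true: int, tau_spec: float | Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair τ vector and class assignment from an explicit vector or a
    spread parameter.

    A scalar s > 0 places the psi_true event times evenly over (0, s]; a
    vector of length psi_true gives the event times; a vector of length Y
    gives per-pair τ directly (its distinct values must number psi_true).
    Pairs are assigned to events cyclically, so every event is used.
    """
    if np.isscalar(tau_spec):
        s = float(tau_spec)
        if s <= 0:
            raise InputError("tau spread must be positive")
        classes = s * (np.arange(1, psi_true + 1) / psi_true)
    else:
        vec = np.asarray(tau_spec, dtype=float)
        if vec.ndim != 1:
            raise InputError("tau_spec vector must be one-dimensional")
        if len(vec) == Y:
            classes_unique = np.unique(vec)
            if len(classes_unique) != psi_true:
                raise InputError(
                    f"per-pair tau vector has {len(classes_unique)} distinct values, "
                    f"psi_true is {psi_true}"
                )
            assignment = np.searchsorted(classes_unique, vec)
            return vec, assignment
        if len(vec) != psi_true:
            raise InputError(
                f"tau_spec must have length psi_true ({psi_true}) or Y ({Y})"
            )
        classes = vec
    assignment = np.arange(Y) % psi_true
    return classes[assignment], assignment


def generate_study(
    Y: int,
    psi_true: int,
    tau_spec: float | Sequence[float],
    layout: Sequence[tuple[int, int, int]] | tuple[int, int, int] = DEFAULT_LAYOUT,
    seed: int = 0,
    theta: float = DEFAULT_THETA,
    size_ratio: float = DEFAULT_SIZE_RATIO,
    mig: float = DEFAULT_MIG,
    anc_ratio: float = DEFAULT_ANC_RATIO,
    model: str = "finite_sites_jc",
    outdir: str | Path | None = None,
) -> tuple[StudyManifest, StudyTruth]:
    """Generate a Y-pair synthetic study with known divergence structure.

    Deterministic under ``seed``; with ``outdir`` set, writes one FASTA per
    deme, a TSV manifest, and a truth JSON (byte-identical across reruns).
    """
    if psi_true < 1 or psi_true > Y:
        raise InputError(f"psi_true must lie in [1, Y]; got {psi_true} with Y={Y}")
    if isinstance(layout, tuple) and len(layout) == 3 and np.isscalar(layout[0]):
        layout = [tuple(layout)] * Y
    layout = [tuple(la) for la in layout]
    if len(layout) != Y:
        raise InputError("layout must give (n_a, n_b, length) for each pair")
    tau_by_pair, _ = _resolve_taus(Y, psi_true, tau_spec)
    root = np.random.default_rng(seed)
    pair_seeds = root.integers(0, 2**31 - 1, size=Y)
    pairs, demographies = [], []
    for i, ((n_a, n_b, length), tau) in enumerate(zip(layout, tau_by_pair)):
        demog = PairDemography(
            n_a=n_a,
            n_b=n_b,
            theta=theta,
            tau=float(tau),
            mig=mig,
            size_ratio_a=size_ratio,
            size_ratio_b=size_ratio,
            anc_ratio=anc_ratio * size_ratio,  # anc_ratio is relative to current size
            locus_length=length,
        )
        sim = simulate_pair(demog, seed=int(pair_seeds[i]), model=model)
        name = f"pair_{i:02d}"
        sim.deme_a.label, sim.deme_b.label = "OW", "NW"
        deme_a = dataclasses.replace(
            sim.deme_a, sequences=[(f"{name}_ow_{j}", s) for j, (_, s) in enumerate(sim.deme_a.sequences)]
        )
        deme_b = dataclasses.replace(
            sim.deme_b, sequences=[(f"{name}_nw_{j}", s) for j, (_, s) in enumerate(sim.deme_b.sequences)]
        )
        pairs.append(
            TaxonPairData(
                name=name,
                deme_a=deme_a,
                deme_b=deme_b,
                depth="population",
                order="Passeriformes",
                locus="ND2",
            )
        )
        demographies.append(demog)
    # depth labels by true-τ terciles: exercises the group-summary path only
    order_idx = np.argsort(tau_by_pair, kind="stable")
    depths = np.empty(Y, dtype=object)
    for rank, idx in enumerate(order_idx):
        frac = rank / Y
        depths[idx] = "population" if frac < 1 / 3 else ("subspecies" if frac < 2 / 3 else "species")
    for pair, depth in zip(pairs, depths):
        pair.depth = str(depth)
    manifest = StudyManifest(pairs=pairs)
    truth = StudyTruth(
        psi_true=psi_true,
        tau_by_pair=[float(t) for t in tau_by_pair],
        demographies=demographies,
        seed=seed,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for pair in pairs:
            fa, fb = f"{pair.name}_ow.fasta", f"{pair.name}_nw.fasta"
            write_fasta(pair.deme_a.sequences, outdir / fa)
            write_fasta(pair.deme_b.sequences, outdir / fb)
            rows.append(
                {
                    "name": pair.name,
                    "depth": pair.depth,
                    "order": pair.order,
                    "locus": pair.locus,
                    "fasta_a": fa,
                    "fasta_b": fb,
                    "clade_flag": pair.clade_flag,
                }
            )
        pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
            outdir / "manifest.tsv", sep="\t", index=False
        )
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    return manifest, truth


# ---------------------------------------------------------------------------
# printed-table fixtures


def load_fixture(name: str):
    """Load a packaged printed-table fixture.

    ``table1``/``table4``/``table5`` return DataFrames typed at printed
    precision; ``clade_list`` returns the 10 haplotype-clade-flagged taxon
    names (matching table4's taxon strings).
    """
    if name not in FIXTURE_NAMES:
        raise InputError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("beringia.fixtures")
    if name == "clade_list":
        text = (ref / "clade_list.txt").read_text()
        return [line.strip() for line in text.splitlines() if line.strip()]
    with resources.as_file(ref / f"{name}.tsv") as path:
        return pd.read_csv(path, sep="\t")
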