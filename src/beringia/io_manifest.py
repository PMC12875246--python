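"""Input/output layer: two-deme FASTA alignments, study manifests, rate tables.

A study consists of taxon pairs, each split into two demes (Old World / New
World sides of the Bering–Chukchi divide). Deme membership is external
metadata carried by the manifest, never inferred from sequence headers.
Sequences are nucleotide alignments over A, C, G, T with N and "-" treated as
missing; other IUPAC ambiguity codes are accepted on input and mapped to N.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, ConfigError, InputError

logger = logging.getLogger("beringia")

DEPTH_CATEGORIES = ("population", "subspecies", "species")

# byte codes used throughout: ACGT -> 0..3, missing (N or -) -> 4
_BASE_CODE = {b: i for i, b in enumerate("ACGT")}
_AMBIGUOUS = set("URYSWKMBDHVN")  # valid IUPAC input, treated as missing
MISSING = 4


def encode_sequence(residues: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (ACGT -> 0..3, missing -> 4).

    Raises InputError on characters outside the IUPAC nucleotide alphabet.
    """
    out = np.empty(len(residues), dtype=np.uint8)
    for i, ch in enumerate(residues.upper()):
        if ch in _BASE_CODE:
            out[i] = _BASE_CODE[ch]
        elif ch == "-" or ch in _AMBIGUOUS:
            out[i] = MISSING
        else:
            raise InputError(f"non-IUPAC character {ch!r} at position {i}")
    return out


@dataclasses.dataclass
class DemeAlignment:
    """One deme's aligned sequences: ids plus residue strings of equal length."""

    label: str
    sequences: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"deme {self.label!r} has no sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"deme {self.label!r} has unequal sequence lengths: {sorted(lengths)}"
            )
        if lengths == {0}:
            raise AlignmentError(f"deme {self.label!r} has zero-length sequences")
        ids = [sid for sid, _ in self.sequences]
        if len(set(ids)) != len(ids):
            raise InputError(f"duplicate sequence ids in deme {self.label!r}")
        self.sequences = [(sid, seq.upper()) for sid, seq in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def n(self) -> int:
        return len(self.sequences)

    def matrix(self) -> np.ndarray:
        """(n, length) uint8 matrix; validates residues on first use."""
        return np.stack([encode_sequence(seq) for _, seq in self.sequences])


@dataclasses.dataclass
class TaxonPairData:
    """A taxon pair: two deme alignments plus study metadata."""

    name: str
    deme_a: DemeAlignment
    deme_b: DemeAlignment
    depth: str = "population"
    order: str = ""
    locus: str = ""
    clade_flag: bool = False

    def __post_init__(self) -> None:
        if self.depth not in DEPTH_CATEGORIES:
            raise InputError(
                f"unknown taxonomic depth {self.depth!r}; expected one of {DEPTH_CATEGORIES}"
            )
        if self.deme_a.length != self.deme_b.length:
            raise AlignmentError(
                f"pair {self.name!r}: deme alignment lengths differ "
                f"({self.deme_a.length} vs {self.deme_b.length})"
            )

    @property
    def length(self) -> int:
        return self.deme_a.length


@dataclasses.dataclass
class StudyManifest:
    """Ordered collection of taxon pairs forming one comparative study."""

    pairs: list[TaxonPairData]

    def __post_init__(self) -> None:
        names = [p.name for p in self.pairs]
        if len(set(names)) != len(names):
            raise InputError("duplicate pair names in manifest")
        seen_ids: set[str] = set()
        for p in self.pairs:
            for deme in (p.deme_a, p.deme_b):
                for sid, _ in deme.sequences:
                    key = sid
                    if key in seen_ids:
                        raise InputError(
                            f"sequence id {sid!r} appears in more than one deme/pair"
                        )
                    seen_ids.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA alignment; returns (id, upper-cased residues) records."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"empty FASTA file: {path}")
    for sid, seq in records:
        encode_sequence(seq)  # validate alphabet early
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write records as single-line FASTA (bit-exact round trip with read_fasta)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")


def read_pair_fasta(
    path_a: str | Path,
    path_b: str | Path,
    name: str = "",
    label_a: str = "OW",
    label_b: str = "NW",
    **meta,
) -> TaxonPairData:
    """Read a taxon pair from two per-deme FASTA files."""
    deme_a = DemeAlignment(label_a, read_fasta(path_a))
    deme_b = DemeAlignment(label_b, read_fasta(path_b))
    return TaxonPairData(
        name=name or Path(path_a).stem, deme_a=deme_a, deme_b=deme_b, **meta
    )


# ---------------------------------------------------------------------------
# Manifest

MANIFEST_COLUMNS = ["name", "depth", "order", "locus", "fasta_a", "fasta_b", "clade_flag"]


def read_manifest(path: str | Path) -> StudyManifest:
    """Read a TSV study manifest and load every referenced FASTA pair.

    Columns: name, depth, order, locus, fasta_a, fasta_b, clade_flag.
    FASTA paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise InputError(f"manifest missing columns: {sorted(missing_cols)}")
    if df.empty:
        logger.warning("manifest %s has no rows; empty study", path)
        return StudyManifest(pairs=[])
    base = path.parent
    pairs = []
    for row in df.itertuples(index=False):
        depth = str(row.depth).strip().lower()
        if depth not in DEPTH_CATEGORIES:
            raise InputError(f"pair {row.name!r}: unknown depth {row.depth!r}")
        flag_raw = str(row.clade_flag).strip().lower()
        if flag_raw in {"true", "1", "yes"}:
            flag = True
        elif flag_raw in {"false", "0", "no"}:
            flag = False
        else:
            raise InputError(f"pair {row.name!r}: bad clade_flag {row.clade_flag!r}")
        try:
            pair = read_pair_fasta(
                base / str(row.fasta_a),
                base / str(row.fasta_b),
                name=str(row.name),
                depth=depth,
                order=str(row.order),
                locus=str(row.locus),
                clade_flag=flag,
            )
        except InputError as exc:
            raise InputError(f"pair {row.name!r}: {exc}") from exc
        pairs.append(pair)
    return StudyManifest(pairs=pairs)


def write_manifest(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a manifest DataFrame (MANIFEST_COLUMNS) as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Rate table

PASSERINE_ORDER = "Passeriformes"


def read_rate_table(path: str | Path) -> "pd.DataFrame":
    """Read a per-(order, locus) divergence-rate table (% pairwise div / Myr).

    Requires a Passeriformes reference row for every locus present (it anchors
    the ordinal rate scaling). Returns a DataFrame indexed by (order, locus).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"rate table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"order": str, "locus": str, "rate": float})
    for col in ("order", "locus", "rate"):
        if col not in df.columns:
            raise InputError(f"rate table missing column {col!r}")
    if (df["rate"] <= 0).any():
        bad = df[df["rate"] <= 0]
        raise InputError(f"nonpositive rates in rate table: {bad.to_dict('records')}")
    if df.duplicated(subset=["order", "locus"]).any():
        raise InputError("duplicate (order, locus) rows in rate table")
    loci = set(df["locus"])
    passerine_loci = set(df.loc[df["order"] == PASSERINE_ORDER, "locus"])
    if loci - passerine_loci:
        raise ConfigError(
            f"rate table lacks {PASSERINE_ORDER} reference for loci: "
            f"{sorted(loci - passerine_loci)}"
        )
    return df.set_index(["order", "locus"]).sort_index()


# ---------------------------------------------------------------------------
# Run configuration


@dataclasses.dataclass
class RunConfig:
    """Seed and analysis knobs for one end-to-end run.

    All randomness downstream flows from ``seed``; identical configs give
    bit-identical result tables.
    """

    seed: int = 0
    gamma_shape: float | None = None  # None -> plain Jukes-Cantor
    n_permutations: int = 10_000
    fdr_q: float = 0.05
    alpha: float = 0.05
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_q < 1.0):
            raise ConfigError(f"fdr_q must lie in (0,1), got {self.fdr_q}")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise InputError(f"gamma_shape must be positive, got {self.gamma_shape}")
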