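"""Readers, writers and shared configuration for the pipeline's file formats.

Formats handled: FASTA (plain or aligned, via Biopython), Newick (via
scikit-bio), and tab-separated tables for binary trait matrices, per-enzyme
restriction-pattern letters, enzyme definitions and square
similarity/distance matrices.  All tabular I/O is strict TSV, UTF-8, Unix
newlines; every reader rejects malformed input with an error naming the
offending record rather than silently coercing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

if TYPE_CHECKING:  # pragma: no cover
    from .rflp import GenotypeTable

__all__ = [
    "IUPAC_CODES",
    "EnzymeDef",
    "PrimerPair",
    "RunConfig",
    "FD1_RD1",
    "DEFAULT_ENZYMES",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_trait_table",
    "write_trait_table",
    "read_pattern_table",
    "read_enzyme_table",
    "write_square_matrix",
    "read_square_matrix",
    "write_newick",
    "read_newick",
    "table3_path",
]

#: IUPAC nucleotide codes mapped to the bases they stand for.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-"
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes allowed)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeDef:
    """A restriction endonuclease: recognition site and cut position.

    ``cut_offset`` is measured from the 5' end of the recognition site;
    e.g. MboI (^GATC) has offset 0 and AluI (AG^CT) has offset 2.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", self.recognition.upper())
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition site shorter than 4 nt")
        bad = set(self.recognition) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"{self.name}: invalid IUPAC code(s) {sorted(bad)} in recognition site"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside recognition site"
            )

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair, both given 5'->3' as conventionally printed."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p:
                raise ValueError(f"{label} primer is empty")
            bad = set(p.upper()) - set(IUPAC_CODES)
            if bad:
                raise ValueError(f"{label} primer has invalid characters {sorted(bad)}")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


#: fD1/rD1, the near-full-length 16S rDNA primer pair (E. coli positions
#: 8-27 and 1524-1540).
FD1_RD1 = PrimerPair("AGAGTTTGATCCTGGCTCAG", "AAGGAGGTGATCCAGCC")


def read_enzyme_table(path: str | Path) -> list[EnzymeDef]:
    """Read an enzyme definition TSV with columns name/recognition/cut_offset."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "recognition", "cut_offset"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"enzyme table missing column(s) {sorted(missing)}")
    return [
        EnzymeDef(r["name"], r["recognition"], int(r["cut_offset"]))
        for _, r in df.iterrows()
    ]


def _data_path(name: str) -> Path:
    return Path(str(files("rhizotax").joinpath("data", name)))


def table3_path() -> Path:
    """Path of the packaged per-enzyme pattern-letter table (41 strains)."""
    return _data_path("table3_patterns.tsv")


#: The seven 4-cutters of the ARDRA panel, with their standard recognition
#: sites (not restated in the study; taken from enzyme catalogues).
DEFAULT_ENZYMES: tuple[EnzymeDef, ...] = tuple(read_enzyme_table(_data_path("enzymes.tsv")))


@dataclass
class RunConfig:
    """Tunable pipeline parameters with the study's defaults."""

    enzymes: tuple[EnzymeDef, ...] = DEFAULT_ENZYMES
    min_band: int = 50                  # smallest gel-visible fragment, bp
    gel_tolerance: float = 0.05         # co-migration tolerance, fraction
    genus_threshold: float = 0.95       # 16S identity cutoff for genus calls
    bootstrap_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gel_tolerance <= 0.2:
            raise ValueError("gel co-migration tolerance must lie in [0, 0.2]")
        if not 0.0 < self.genus_threshold <= 1.0:
            raise ValueError("genus identity threshold must lie in (0, 1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap replicate count must be >= 1")
        if self.min_band < 0:
            raise ValueError("minimum band size must be non-negative")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) pairs.

    Gap characters are preserved, so aligned FASTA round-trips.  Duplicate
    ids and empty records raise.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append((rec.id, seq))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Tabular formats


def read_trait_table(path: str | Path):
    """Read a strains x characters TSV of 0/1/NA into a TraitMatrix."""
    from .phenotype import TraitMatrix

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = np.full(df.shape, np.nan)
    for i, strain in enumerate(df.index):
        for j, char in enumerate(df.columns):
            cell = df.iat[i, j]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue
            cell = str(cell).strip()
            if cell in {"", "NA"}:
                continue
            if cell not in {"0", "1"}:
                raise ValueError(
                    f"non-binary cell {cell!r} at strain {strain!r}, "
                    f"character {char!r} in {path}"
                )
            values[i, j] = int(cell)
    return TraitMatrix(list(df.index), list(df.columns), values)


def write_trait_table(matrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.strains, columns=matrix.characters)
    out = df.map(lambda v: "NA" if math.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t", index_label="strain")


def read_pattern_table(
    path: str | Path, enzymes: Sequence[str] | None = None
) -> "GenotypeTable":
    """Read a per-enzyme pattern-letter TSV into a GenotypeTable.

    The file has a strain-id column, one letter column per enzyme and
    optionally a ``group`` column with the genotype labels as printed.
    When ``enzymes`` is given those columns are required and used in that
    order; otherwise every non-reserved column is treated as an enzyme.
    """
    from .rflp import GenotypeTable

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"pattern table {path} is empty or has no enzyme columns")
    strain_col = df.columns[0]
    if enzymes is None:
        enzyme_cols = [c for c in df.columns[1:] if c != "group"]
    else:
        missing = [e for e in enzymes if e not in df.columns]
        if missing:
            raise ValueError(f"pattern table missing enzyme column(s) {missing}")
        enzyme_cols = list(enzymes)
    strains = [str(s) for s in df[strain_col]]
    letters = []
    for _, row in df.iterrows():
        for e in enzyme_cols:
            if pd.isna(row[e]) or not str(row[e]).strip():
                raise ValueError(
                    f"missing pattern letter for strain {row[strain_col]!r}, "
                    f"enzyme {e!r}"
                )
        letters.append(tuple(str(row[e]).strip() for e in enzyme_cols))
    printed = [str(g) for g in df["group"]] if "group" in df.columns else None
    return GenotypeTable(
        strains=strains, enzymes=enzyme_cols, letters=letters, printed_groups=printed
    )


def write_square_matrix(ids: Sequence[str], values: np.ndarray, path: str | Path) -> None:
    """Write a square similarity/distance matrix as a TSV with id headers."""
    pd.DataFrame(values, index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t", index_label="id", float_format="%.6f"
    )


def read_square_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"matrix in {path} has mismatched row/column ids")
    return list(df.index), df.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree to Newick with branch lengths.

    Internal-node names (e.g. bootstrap supports attached by
    ``bootstrap_support``) are emitted as internal labels.  Unlabeled
    leaves and negative branch lengths raise.
    """
    for tip in tree.tips():
        if not tip.name:
            raise ValueError("tree has an unlabeled leaf")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError("tree has a negative branch length")
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
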