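"""In silico PCR-RFLP (ARDRA) genotyping of 16S rDNA amplicons.

The track mirrors the wet-lab workflow: a near-full-length 16S rDNA
amplicon is extracted between a universal primer pair, digested separately
with a panel of 4-cutters, the fragments are "run" through a simple gel
model (detection limit plus co-migration merging), per-enzyme band patterns
are assigned letters (A, B, ...) by first appearance, and the combined
seven-letter tuple defines a strain's 16S rDNA genotype (labelled with
Roman numerals).  Band presence/absence across strains feeds the Nei-Li
(Dice) band-sharing coefficient, and UPGMA on 1 - similarity yields the
RFLP dendrogram.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .io import IUPAC_CODES, EnzymeDef, PrimerPair, RunConfig, reverse_complement
from .phenotype import (
    DistanceMatrix,
    SimilarityMatrix,
    UndefinedSimilarityError,
    similarity_to_distance,
    upgma,
)

__all__ = [
    "AmpliconError",
    "AmbiguousAmpliconError",
    "Amplicon",
    "DigestProfile",
    "GelPattern",
    "GenotypeTable",
    "GenotypeCounts",
    "BandMatrix",
    "extract_amplicon",
    "find_sites",
    "digest",
    "to_gel",
    "assign_pattern_letters",
    "combine_genotypes",
    "band_matrix",
    "nei_li_similarity",
    "nei_li_matrix",
    "rflp_dendrogram",
    "genotype_amplicons",
    "genotype_sequences",
    "roman",
]


class AmpliconError(ValueError):
    """No amplification product for a template/primer combination."""


class AmbiguousAmpliconError(AmpliconError):
    """Several equally good primer matches imply distinct products."""


@dataclass(frozen=True)
class Amplicon:
    """A PCR product, primer sites included, with template coordinates."""

    strain_id: str
    sequence: str
    start: int
    end: int  # exclusive

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("amplicon sequence is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestProfile:
    """Fragment-length multiset from one enzyme's complete digest."""

    strain_id: str
    enzyme: str
    fragments: tuple[int, ...]  # ascending

    @property
    def total(self) -> int:
        return sum(self.fragments)


@dataclass(frozen=True)
class GelPattern:
    """Gel-visible bands for one strain x enzyme, largest first."""

    strain_id: str
    enzyme: str
    bands: tuple[float, ...]


@dataclass
class GenotypeTable:
    """Per-enzyme pattern letters and combined genotypes, Table-style.

    ``letters`` holds one tuple per strain, in ``enzymes`` order;
    ``genotypes`` (Roman numerals, first-appearance order) is filled by
    :func:`combine_genotypes`; ``printed_groups`` preserves labels read
    from a file, when present.
    """

    strains: list[str]
    enzymes: list[str]
    letters: list[tuple[str, ...]]
    genotypes: list[str] | None = None
    printed_groups: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.letters) != len(self.strains):
            raise ValueError("one letter tuple required per strain")
        for strain, tup in zip(self.strains, self.letters):
            if len(tup) != len(self.enzymes):
                raise ValueError(
                    f"strain {strain!r} has {len(tup)} letters for "
                    f"{len(self.enzymes)} enzymes"
                )


@dataclass(frozen=True)
class GenotypeCounts:
    """Summary statistics of a combined-genotype assignment."""

    n_strains: int
    n_genotypes: int
    n_isolate_genotypes: int
    n_reference_genotypes: int
    n_singleton_isolate_genotypes: int
    n_isolate_genotypes_matching_reference: int


@dataclass
class BandMatrix:
    """Strains x (enzyme, size-bin) band presence/absence."""

    strains: list[str]
    bands: list[tuple[str, float]]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (len(self.strains), len(self.bands)):
            raise ValueError("band matrix shape does not match ids")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("band matrix entries must be 0/1")


# ---------------------------------------------------------------------------
# Amplicon extraction


def _best_matches(template: str, probe: str, max_mismatches: int) -> tuple[int, list[int]]:
    """Positions of the fewest-mismatch occurrences of probe in template."""
    k = len(probe)
    best = max_mismatches + 1
    positions: list[int] = []
    for i in range(len(template) - k + 1):
        mm = sum(1 for a, b in zip(template[i : i + k], probe) if a != b)
        if mm < best:
            best, positions = mm, [i]
        elif mm == best:
            positions.append(i)
    return best, positions


def extract_amplicon(
    template: str,
    primers: PrimerPair,
    max_mismatches: int = 0,
    strain_id: str = "",
) -> Amplicon:
    """Extract the PCR product between a primer pair on a linear template.

    The product runs from the 5' end of the best forward-primer match to
    the 3' end of the best match of the reverse primer's reverse
    complement, primer sites included.  Ties among equally good matches
    that imply distinct products raise :class:`AmbiguousAmpliconError`.
    """
    t = template.upper()
    fwd = primers.forward
    rev_rc = reverse_complement(primers.reverse)
    mm_f, f_pos = _best_matches(t, fwd, max_mismatches)
    if mm_f > max_mismatches or not f_pos:
        raise AmpliconError(
            f"no forward primer match within {max_mismatches} mismatches"
        )
    mm_r, r_pos = _best_matches(t, rev_rc, max_mismatches)
    if mm_r > max_mismatches or not r_pos:
        raise AmpliconError(
            f"no reverse primer match within {max_mismatches} mismatches"
        )
    spans = sorted(
        {(f, r + len(rev_rc)) for f in f_pos for r in r_pos if r + len(rev_rc) > f + len(fwd)}
    )
    if not spans:
        raise AmpliconError("primer matches do not bracket a product")
    if len(spans) > 1:
        raise AmbiguousAmpliconError(
            f"multiple equally good products at coordinates {spans}"
        )
    start, end = spans[0]
    return Amplicon(strain_id=strain_id, sequence=t[start:end], start=start, end=end)


# ---------------------------------------------------------------------------
# Digestion


def _iupac_regex(pattern: str) -> str:
    return "".join(
        b if len(IUPAC_CODES[b]) == 1 else f"[{IUPAC_CODES[b]}]" for b in pattern
    )


def find_sites(sequence: str, enzyme: EnzymeDef, both_strands: bool = True) -> list[int]:
    """Start positions of (possibly overlapping) recognition-site matches.

    All panel defaults are palindromic, so the given strand suffices; for a
    non-palindromic pattern the reverse-complement is also scanned when
    ``both_strands`` is set (positions reported on the given strand).
    """
    seq = sequence.upper()
    hits = [m.start() for m in re.finditer(f"(?=({_iupac_regex(enzyme.recognition)}))", seq)]
    if both_strands and not enzyme.is_palindromic:
        rc = reverse_complement(enzyme.recognition)
        hits += [m.start() for m in re.finditer(f"(?=({_iupac_regex(rc)}))", seq)]
    return sorted(set(hits))


def _cut_positions(seq: str, enzyme: EnzymeDef, both_strands: bool) -> list[int]:
    n, k = len(seq), len(enzyme.recognition)
    cuts = {
        m.start() + enzyme.cut_offset
        for m in re.finditer(f"(?=({_iupac_regex(enzyme.recognition)}))", seq)
    }
    if both_strands and not enzyme.is_palindromic:
        rc = reverse_complement(enzyme.recognition)
        cuts |= {
            m.start() + (k - enzyme.cut_offset)
            for m in re.finditer(f"(?=({_iupac_regex(rc)}))", seq)
        }
    return sorted(c for c in cuts if 0 < c < n)


def digest(
    amplicon: Amplicon | str,
    enzyme: EnzymeDef,
    both_strands: bool = True,
    strain_id: str | None = None,
) -> DigestProfile:
    """Complete digest of an amplicon: fragment lengths between all cuts.

    The sequence must be unambiguous A/C/G/T; IUPAC degeneracy is allowed
    only in the enzyme's recognition pattern.  Fragment lengths always sum
    to the amplicon length.
    """
    if isinstance(amplicon, Amplicon):
        seq = amplicon.sequence
        sid = strain_id if strain_id is not None else amplicon.strain_id
    else:
        seq = amplicon.upper()
        sid = strain_id or ""
    bad = re.search("[^ACGT]", seq)
    if bad:
        raise ValueError(
            f"ambiguous base {seq[bad.start()]!r} at position {bad.start()} "
            f"in sequence for {sid or 'amplicon'}"
        )
    cuts = _cut_positions(seq, enzyme, both_strands)
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))
    return DigestProfile(strain_id=sid, enzyme=enzyme.name, fragments=fragments)


# ---------------------------------------------------------------------------
# Gel model


def _merge_groups(sizes: Iterable[float], tolerance: float) -> list[list[float]]:
    """Left-to-right co-migration merging of distinct sizes, to stability."""
    groups: list[list[float]] = [[s] for s in sorted(set(sizes))]
    merged = True
    while merged:
        merged = False
        i = 0
        while i + 1 < len(groups):
            lo = float(np.mean(groups[i]))
            hi = float(np.mean(groups[i + 1]))
            if hi - lo <= tolerance * hi:
                groups[i : i + 2] = [groups[i] + groups[i + 1]]
                merged = True
            else:
                i += 1
    return groups


def to_gel(profile: DigestProfile, min_size: int = 50, tolerance: float = 0.05) -> GelPattern:
    """Resolve a digest on a gel: detection limit, then co-migration merging.

    Fragments below ``min_size`` are invisible; sizes within ``tolerance``
    (fraction of the larger size) co-migrate and merge into one band at
    their mean; duplicate sizes collapse.  Bands are reported largest
    first.
    """
    if not 0.0 <= tolerance <= 0.2:
        raise ValueError("co-migration tolerance must lie in [0, 0.2]")
    visible = [float(f) for f in profile.fragments if f >= min_size]
    bands = sorted(
        (float(np.mean(g)) for g in _merge_groups(visible, tolerance)), reverse=True
    )
    return GelPattern(profile.strain_id, profile.enzyme, tuple(bands))


# ---------------------------------------------------------------------------
# Pattern typing and genotypes


def _letter(i: int) -> str:
    """A, B, ..., Z, AA, AB, ... (spreadsheet-style)."""
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = chr(ord("A") + r) + out
    return out


_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def roman(n: int) -> str:
    if n < 1:
        raise ValueError("Roman numerals start at 1")
    out = ""
    for value, sym in _ROMAN:
        while n >= value:
            out += sym
            n -= value
    return out


def assign_pattern_letters(patterns: Sequence[GelPattern]) -> list[str]:
    """Letter per strain for one enzyme: identical band lists share a letter.

    Letters are issued A, B, C, ... in order of first appearance in the
    input, reproducing the labelling convention of gel-typing tables.
    """
    enzymes = {p.enzyme for p in patterns}
    if len(enzymes) > 1:
        raise ValueError(f"patterns from multiple enzymes: {sorted(enzymes)}")
    seen: dict[tuple[float, ...], str] = {}
    out = []
    for p in patterns:
        if p.bands not in seen:
            seen[p.bands] = _letter(len(seen))
        out.append(seen[p.bands])
    return out


def combine_genotypes(
    table: GenotypeTable,
    isolates: Sequence[str] | None = None,
    references: Sequence[str] | None = None,
) -> tuple[GenotypeTable, GenotypeCounts]:
    """Combine per-enzyme letters into genotypes and count them.

    Strains share a genotype label (Roman numeral, first-appearance order)
    iff their full letter tuples are identical.  When the strain set is
    split into ``isolates`` and ``references``, the counts additionally
    report distinct genotypes per subset, genotypes carried by exactly one
    isolate, and isolate genotypes identical to some reference genotype.
    """
    for strain, tup in zip(table.strains, table.letters):
        for enzyme, letter in zip(table.enzymes, tup):
            if not letter:
                raise ValueError(f"missing letter for strain {strain!r} x {enzyme!r}")
    labels: dict[tuple[str, ...], str] = {}
    genotypes = []
    for tup in table.letters:
        if tup not in labels:
            labels[tup] = roman(len(labels) + 1)
        genotypes.append(labels[tup])
    labelled = GenotypeTable(
        strains=list(table.strains),
        enzymes=list(table.enzymes),
        letters=list(table.letters),
        genotypes=genotypes,
        printed_groups=table.printed_groups,
    )
    by_strain = dict(zip(table.strains, table.letters))
    if isolates is None and references is None:
        isolates = list(table.strains)
        references = []
    elif isolates is None:
        refset = set(references or [])
        isolates = [s for s in table.strains if s not in refset]
    elif references is None:
        isoset = set(isolates)
        references = [s for s in table.strains if s not in isoset]
    unknown = (set(isolates) | set(references)) - set(table.strains)
    if unknown:
        raise ValueError(f"unknown strain id(s) {sorted(unknown)}")
    iso_tuples = [by_strain[s] for s in isolates]
    ref_tuples = {by_strain[s] for s in references}
    iso_counter = Counter(iso_tuples)
    counts = GenotypeCounts(
        n_strains=len(table.strains),
        n_genotypes=len(labels),
        n_isolate_genotypes=len(set(iso_tuples)),
        n_reference_genotypes=len(ref_tuples),
        n_singleton_isolate_genotypes=sum(1 for c in iso_counter.values() if c == 1),
        n_isolate_genotypes_matching_reference=len(set(iso_tuples) & ref_tuples),
    )
    return labelled, counts


# ---------------------------------------------------------------------------
# Band-sharing similarity


def band_matrix(patterns: Sequence[GelPattern], tolerance: float = 0.05) -> BandMatrix:
    """Presence/absence of (enzyme, size-bin) bands across strains.

    Band sizes of each enzyme are pooled over strains and merged into bins
    with the same co-migration rule used on a single lane, so the same
    true band gets the same column even when per-strain merged means
    differ slightly.
    """
    strains: list[str] = []
    for p in patterns:
        if p.strain_id not in strains:
            strains.append(p.strain_id)
    by_enzyme: dict[str, list[GelPattern]] = defaultdict(list)
    enzyme_order: list[str] = []
    for p in patterns:
        if p.enzyme not in enzyme_order:
            enzyme_order.append(p.enzyme)
        by_enzyme[p.enzyme].append(p)
    columns: list[tuple[str, float]] = []
    presence: dict[tuple[str, float], set[str]] = {}
    for enzyme in enzyme_order:
        pool = [b for p in by_enzyme[enzyme] for b in p.bands]
        groups = _merge_groups(pool, tolerance)
        centers = [float(np.mean(g)) for g in groups]
        members = [set(g) for g in groups]
        for center in sorted(centers, reverse=True):
            columns.append((enzyme, center))
        for p in by_enzyme[enzyme]:
            for b in p.bands:
                center = next(c for c, mem in zip(centers, members) if b in mem)
                presence.setdefault((enzyme, center), set()).add(p.strain_id)
    values = np.array(
        [[1 if s in presence.get(col, set()) else 0 for col in columns] for s in strains]
    )
    return BandMatrix(strains=strains, bands=columns, values=values)


def nei_li_similarity(x, y) -> float:
    """Nei-Li (Dice) band-sharing: 2 n_xy / (n_x + n_y).

    Accepts 0/1 vectors over a common band set, or explicit band sets.
    """
    sx = set(np.flatnonzero(np.asarray(x))) if not isinstance(x, (set, frozenset)) else set(x)
    sy = set(np.flatnonzero(np.asarray(y))) if not isinstance(y, (set, frozenset)) else set(y)
    if not sx and not sy:
        raise UndefinedSimilarityError("both band sets are empty")
    return 2.0 * len(sx & sy) / (len(sx) + len(sy))


def nei_li_matrix(bm: BandMatrix) -> SimilarityMatrix:
    n = len(bm.strains)
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s[i, j] = s[j, i] = nei_li_similarity(bm.values[i], bm.values[j])
            except UndefinedSimilarityError:
                raise UndefinedSimilarityError(
                    f"no bands for strain pair {bm.strains[i]!r}, {bm.strains[j]!r}"
                ) from None
    return SimilarityMatrix(list(bm.strains), s)


def rflp_dendrogram(bm: BandMatrix) -> TreeNode:
    """UPGMA dendrogram on 1 - Nei-Li band-sharing similarity."""
    return upgma(similarity_to_distance(nei_li_matrix(bm)))


# ---------------------------------------------------------------------------
# End-to-end genotyping helpers


def genotype_amplicons(
    amplicons: Sequence[Amplicon], config: RunConfig | None = None
) -> tuple[GenotypeTable, list[GelPattern]]:
    """Digest amplicons with the panel and type the gel patterns."""
    config = config or RunConfig()
    all_patterns: list[GelPattern] = []
    letters_by_enzyme: list[list[str]] = []
    for enzyme in config.enzymes:
        pats = [
            to_gel(digest(a, enzyme), config.min_band, config.gel_tolerance)
            for a in amplicons
        ]
        all_patterns.extend(pats)
        letters_by_enzyme.append(assign_pattern_letters(pats))
    table = GenotypeTable(
        strains=[a.strain_id for a in amplicons],
        enzymes=[e.name for e in config.enzymes],
        letters=[tuple(col[i] for col in letters_by_enzyme) for i in range(len(amplicons))],
    )
    return table, all_patterns


def genotype_sequences(
    templates: Sequence[tuple[str, str]],
    config: RunConfig | None = None,
    primers: PrimerPair | None = None,
    max_mismatches: int = 0,
) -> tuple[GenotypeTable, list[GelPattern]]:
    """Full in silico ARDRA: amplify each template, digest, and type."""
    from .io import FD1_RD1

    primers = primers or FD1_RD1
    amplicons = [
        extract_amplicon(seq, primers, max_mismatches, strain_id=name)
        for name, seq in templates
    ]
    return genotype_amplicons(amplicons, config)
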