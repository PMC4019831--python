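"""Generators of synthetic inputs with known ground truth.

Three generators cover the pipeline's three tracks:

* :func:`simulate_alignment` — gapless 16S-like alignments evolved down a
  two-level (genus/strain) tree under a transition-biased substitution
  process, with controlled within- and between-genus divergence;
* :func:`simulate_traits` — binary trait matrices with planted phena
  (cluster consensus vectors copied with a per-character agreement
  probability);
* :func:`plant_rflp_groups` — families of amplicons carrying
  group-specific point edits that destroy restriction sites of a panel
  enzyme, so the true genotype partition is known by construction.

All generators are pure functions of their spec (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .io import FD1_RD1, DEFAULT_ENZYMES, EnzymeDef, PrimerPair, RunConfig
from .phenotype import TraitMatrix
from .phylogeny import Alignment
from .rflp import Amplicon, digest, find_sites, genotype_amplicons

__all__ = [
    "SimTreeSpec",
    "SimTraitSpec",
    "simulate_alignment",
    "simulate_traits",
    "random_amplicon",
    "destroy_site",
    "plant_rflp_groups",
]

_BASE = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimTreeSpec:
    """Conditions for a two-genus (or k-genus) 16S-like sequence set.

    Divergences are expected substitutions per site on the path between
    two leaves; the defaults mirror a within-genus 1-5% / between-genus
    >=7% regime at the study's 1,239 bp sequence length.
    """

    leaves_per_genus: int = 5
    n_genera: int = 2
    within_divergence: tuple[float, float] = (0.01, 0.05)
    between_divergence: float = 0.10
    kappa: float = 2.0
    length: int = 1239
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.within_divergence
        if not (0.0 < lo <= hi < 0.75):
            raise ValueError("within-genus divergence range must lie in (0, 0.75)")
        if not 0.0 < self.between_divergence < 0.75:
            raise ValueError("between-genus divergence must lie in (0, 0.75)")
        if self.n_genera > 1 and self.between_divergence <= (lo + hi) / 2:
            raise ValueError("between-genus divergence must exceed the mean within")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.length < 100:
            raise ValueError("sequence length must be >= 100")
        if self.leaves_per_genus < 1 or self.n_genera < 1:
            raise ValueError("need at least one genus with one leaf")


@dataclass(frozen=True)
class SimTraitSpec:
    """Conditions for a binary trait matrix with planted phena.

    ``within_agreement`` and ``between_agreement`` are the expected
    simple-matching similarities between two strains of the same cluster
    and of different clusters, respectively (the scale the phenogram is
    cut on).  Pairwise agreement below 0.5 is not achievable by
    independent noisy copies of a consensus, hence the (0.5, 1] bound.
    """

    cluster_sizes: tuple[int, ...] = (14, 14)
    n_characters: int = 86
    within_agreement: float = 0.9
    between_agreement: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.within_agreement <= 1.0:
            raise ValueError("within-cluster agreement must lie in (0.5, 1]")
        if not 0.5 <= self.between_agreement <= self.within_agreement:
            raise ValueError(
                "between-cluster agreement must lie in [0.5, within agreement]"
            )
        if self.n_characters < 1:
            raise ValueError("need at least one character")
        if any(s < 1 for s in self.cluster_sizes) or not self.cluster_sizes:
            raise ValueError("cluster sizes must be positive")


def _mutate(seq: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of length t (expected substitutions/site).

    Each site substitutes independently with probability 1 - exp(-t); a
    substitution is a transition with probability kappa/(kappa+2), else
    one of the two transversions.  Bases are coded 0..3 = A,C,G,T, so a
    transition is XOR 2 and the transversions are XOR 1 and XOR 3.
    """
    out = seq.copy()
    hit = rng.random(seq.size) < 1.0 - np.exp(-t)
    n = int(hit.sum())
    if n:
        kind = rng.choice([2, 1, 3], size=n, p=[kappa / (kappa + 2), 1 / (kappa + 2), 1 / (kappa + 2)])
        out[hit] ^= kind
    return out


def simulate_alignment(spec: SimTreeSpec) -> tuple[TreeNode, Alignment]:
    """Evolve sequences down a genus/strain tree; returns (true tree, alignment).

    The root sequence is uniform over A/C/G/T.  Leaf branch lengths are
    drawn uniformly from half the within-genus divergence range, so the
    expected leaf-to-leaf divergence within a genus spans that range;
    genus branches are sized so the expected between-genus path equals
    ``between_divergence``.  Leaves are named ``G<genus>_<leaf>``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.within_divergence
    genus_branch = (spec.between_divergence - (lo + hi) / 2) / 2 if spec.n_genera > 1 else 0.0
    root_seq = rng.integers(0, 4, size=spec.length, dtype=np.int64)
    root = TreeNode()
    ids: list[str] = []
    rows: list[str] = []
    for g in range(spec.n_genera):
        genus_node = TreeNode(length=genus_branch)
        root.append(genus_node)
        genus_seq = _mutate(root_seq, genus_branch, spec.kappa, rng)
        for i in range(spec.leaves_per_genus):
            name = f"G{g + 1}_{i + 1}"
            bl = float(rng.uniform(lo / 2, hi / 2))
            leaf = TreeNode(name=name, length=bl)
            genus_node.append(leaf)
            leaf_seq = _mutate(genus_seq, bl, spec.kappa, rng)
            ids.append(name)
            rows.append(_BASE[leaf_seq].tobytes().decode())
    return root, Alignment(ids, rows)


def simulate_traits(spec: SimTraitSpec) -> tuple[TraitMatrix, dict[str, int]]:
    """Binary trait matrix with planted phena; returns (matrix, true partition).

    A consensus vector is drawn for the first cluster and every further
    cluster's consensus agrees with it per character with a derived
    probability; each strain then copies its cluster consensus per
    character with probability p (flipping otherwise).  p and the
    consensus agreement are chosen so the EXPECTED pairwise simple
    matching equals ``within_agreement`` within a cluster
    (p^2 + (1-p)^2 = a_w, i.e. p = (1 + sqrt(2 a_w - 1))/2) and
    ``between_agreement`` across clusters.
    """
    rng = np.random.default_rng(spec.seed)
    c = spec.n_characters
    a_w, a_b = spec.within_agreement, spec.between_agreement
    p_copy = (1.0 + np.sqrt(2.0 * a_w - 1.0)) / 2.0
    # cross-cluster per-character match prob = c_agree*a_w + (1-c_agree)*(1-a_w)
    consensus_agree = 1.0 if a_w == a_b else (a_b - (1.0 - a_w)) / (2.0 * a_w - 1.0)
    base = rng.integers(0, 2, size=c)
    strains: list[str] = []
    values: list[np.ndarray] = []
    partition: dict[str, int] = {}
    for k, size in enumerate(spec.cluster_sizes):
        if k == 0:
            consensus = base
        else:
            flip = rng.random(c) >= consensus_agree
            consensus = np.where(flip, 1 - base, base)
        for i in range(size):
            name = f"C{k + 1}_{i + 1}"
            keep = rng.random(c) < p_copy
            row = np.where(keep, consensus, 1 - consensus)
            strains.append(name)
            values.append(row.astype(float))
            partition[name] = k
    matrix = TraitMatrix(strains, [f"char{j + 1}" for j in range(c)], np.array(values))
    return matrix, partition


# ---------------------------------------------------------------------------
# Restriction-site engineering


def random_amplicon(
    length: int = 1500,
    primers: PrimerPair = FD1_RD1,
    seed: int | None = None,
    strain_id: str = "base",
) -> Amplicon:
    """A random amplicon flanked by the primer pair (insert uniform A/C/G/T)."""
    from .io import reverse_complement

    rng = np.random.default_rng(seed)
    insert_len = length - len(primers.forward) - len(primers.reverse)
    if insert_len < 0:
        raise ValueError("amplicon shorter than the two primers")
    insert = _BASE[rng.integers(0, 4, size=insert_len)].tobytes().decode()
    seq = primers.forward + insert + reverse_complement(primers.reverse)
    return Amplicon(strain_id=strain_id, sequence=seq, start=0, end=len(seq))


def _panel_sites(seq: str, panel: tuple[EnzymeDef, ...]) -> dict[str, list[int]]:
    return {e.name: find_sites(seq, e) for e in panel}


def destroy_site(
    sequence: str,
    enzyme: EnzymeDef,
    panel: tuple[EnzymeDef, ...] = DEFAULT_ENZYMES,
    occurrence: int = 0,
    primers: PrimerPair = FD1_RD1,
) -> str:
    """Point-mutate one occurrence of an enzyme's site so it no longer cuts.

    The edit must leave every other panel enzyme's site set unchanged and
    must not touch the primer regions at the sequence ends (edits that
    would collide with a primer site raise).  Tries each position within
    the recognition site and each replacement base deterministically and
    returns the first sequence satisfying all constraints.
    """
    seq = sequence.upper()
    sites = find_sites(seq, enzyme)
    if occurrence >= len(sites):
        raise ValueError(
            f"{enzyme.name} has only {len(sites)} site(s); occurrence "
            f"{occurrence} does not exist"
        )
    pos = sites[occurrence]
    k = len(enzyme.recognition)
    fwd_end = len(primers.forward)
    rev_start = len(seq) - len(primers.reverse)
    if pos < fwd_end or pos + k > rev_start:
        raise ValueError(
            f"{enzyme.name} site at {pos} collides with a primer region"
        )
    before = _panel_sites(seq, panel)
    for offset in range(k):
        for base in "ACGT":
            if seq[pos + offset] == base:
                continue
            cand = seq[: pos + offset] + base + seq[pos + offset + 1 :]
            after = _panel_sites(cand, panel)
            target_ok = after[enzyme.name] == [s for s in before[enzyme.name] if s != pos]
            others_ok = all(
                after[e.name] == before[e.name] for e in panel if e.name != enzyme.name
            )
            if target_ok and others_ok:
                return cand
    raise ValueError(
        f"could not destroy {enzyme.name} site at {pos} without side effects"
    )


def plant_rflp_groups(
    base: Amplicon | str,
    groups: int,
    edits_per_group: int = 1,
    panel: tuple[EnzymeDef, ...] = DEFAULT_ENZYMES,
    seed: int | None = None,
    strains_per_group: int = 3,
    target_enzyme: str | None = None,
    config: RunConfig | None = None,
    primers: PrimerPair = FD1_RD1,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Amplicon family with planted genotype groups; returns (sequences, truth).

    Every group receives ``edits_per_group`` group-specific site
    destructions (group g destroys a distinct subset of the base
    amplicon's panel sites), so groups differ at panel sites while
    within-group sequences are identical.  The construction is verified:
    genotyping the family under ``config`` must yield exactly ``groups``
    combined genotypes, else candidate sites are re-drawn.
    """
    if groups < 1:
        raise ValueError("need at least one group")
    base_amp = base if isinstance(base, Amplicon) else Amplicon("base", str(base), 0, len(str(base)))
    seq0 = base_amp.sequence.upper()
    config = config or RunConfig(enzymes=panel)
    rng = np.random.default_rng(seed)

    # candidate (enzyme, occurrence) edits, interior sites only
    fwd_end = len(primers.forward)
    rev_start = len(seq0) - len(primers.reverse)
    candidates: list[tuple[str, int]] = []
    enzymes = [e for e in panel if target_enzyme is None or e.name == target_enzyme]
    for e in enzymes:
        for occ, pos in enumerate(find_sites(seq0, e)):
            if fwd_end <= pos and pos + len(e.recognition) <= rev_start:
                candidates.append((e.name, occ))
    rng.shuffle(candidates)
    needed = (groups - 1) * edits_per_group if groups > 1 else 0
    by_name = {e.name: e for e in panel}

    def build(chosen: list[tuple[str, int]]) -> list[str]:
        group_seqs = [seq0]
        for g in range(1, groups):
            seq = seq0
            for ename, occ in chosen[(g - 1) * edits_per_group : g * edits_per_group]:
                seq = destroy_site(seq, by_name[ename], panel, occ, primers)
            group_seqs.append(seq)
        return group_seqs

    # greedy with retries: some candidate sets fail (edit side-effects or
    # gel-level collisions), so re-draw until genotyping recovers the groups
    for _ in range(50):
        if len(candidates) < needed:
            raise ValueError(
                f"only {len(candidates)} editable sites for {needed} edits"
            )
        chosen = [candidates[i] for i in rng.choice(len(candidates), size=needed, replace=False)] if needed else []
        try:
            group_seqs = build(chosen)
        except ValueError:
            continue
        amps = [
            Amplicon(f"grp{g + 1}_s{i + 1}", gs, 0, len(gs))
            for g, gs in enumerate(group_seqs)
            for i in range(strains_per_group)
        ]
        table, _ = genotype_amplicons(amps, config)
        if len(set(table.letters)) == groups:
            truth = {a.strain_id: int(a.strain_id[3 : a.strain_id.index("_")]) - 1 for a in amps}
            return [(a.strain_id, a.sequence) for a in amps], truth
    raise RuntimeError("failed to plant distinguishable RFLP groups; try another base")
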