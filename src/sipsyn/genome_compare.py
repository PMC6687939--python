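"""Fragment-based average nucleotide identity and population delineation.

Genomes are chopped into fixed-length fragments (ANIb convention, 1020 bp);
each fragment is placed on the other genome by exact k-mer anchors on both
strands followed by ungapped scoring of the full diagonal, and ANI is the
mean identity of fragments passing identity/coverage filters, symmetrized
over the two directions. Genomes are then clustered on 100 - ANI with Ward's
minimum-variance linkage and flat-cut into sequence-discrete populations
(ANI >= 99) and species (ANI >= 95).

The aligner is deterministic and self-contained; on closely related genomes
its values track the per-site substitution rate (ANI ~ 100*(1 - mu)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

__all__ = [
    "GenomeSequence",
    "ANIMatrix",
    "fragment_genome",
    "best_identity",
    "ani",
    "ani_matrix",
    "ward_cluster",
    "DEFAULT_FRAGMENT_LENGTH",
    "DEFAULT_KMER",
    "SPECIES_ANI_CUT",
    "POPULATION_ANI_CUT",
    "UNDEFINED_ANI_IMPUTE",
]

DEFAULT_FRAGMENT_LENGTH = 1020
DEFAULT_KMER = 16
DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_COVERAGE = 0.7

#: ANI >= 95 % -> same species; >= 99 % -> same sequence-discrete population.
SPECIES_ANI_CUT = 95.0
POPULATION_ANI_CUT = 99.0

#: Pairs with no alignable fragments are imputed to this ANI for clustering.
UNDEFINED_ANI_IMPUTE = 70.0

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

# anchor-search bounds keeping worst-case work small on repetitive sequence
_MAX_POSITIONS_PER_KMER = 8
_MAX_DIAGONALS = 50
_ANCHOR_STRIDE = 4


@dataclass(frozen=True)
class GenomeSequence:
    """A genome as a list of contigs over the alphabet {A, C, G, T, N}."""

    id: str
    contigs: tuple[str, ...]

    def __post_init__(self) -> None:
        contigs = tuple(c.upper() for c in self.contigs)
        if sum(len(c) for c in contigs) == 0:
            raise ValueError(f"{self.id}: genome has zero length")
        bad = set("".join(contigs)) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "contigs", contigs)

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass(frozen=True)
class ANIMatrix:
    """Symmetric ANI (%) and aligned-fraction matrices over a genome set."""

    ids: tuple[str, ...]
    ani: pd.DataFrame
    aligned_fraction: pd.DataFrame


def _revcomp(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT)[::-1].decode()


def fragment_genome(
    genome: GenomeSequence,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    max_n_fraction: float = 0.2,
) -> list[str]:
    """Non-overlapping fragments of ``fragment_length`` from each contig.

    A terminal remainder shorter than half the fragment length is discarded;
    longer remainders are kept as shorter fragments. Fragments with more than
    ``max_n_fraction`` ambiguous bases are dropped.
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    fragments: list[str] = []
    for contig in genome.contigs:
        for start in range(0, len(contig), fragment_length):
            frag = contig[start : start + fragment_length]
            if len(frag) < fragment_length / 2:
                continue
            if frag.count("N") > max_n_fraction * len(frag):
                continue
            fragments.append(frag)
    return fragments


class _ReferenceIndex:
    """Exact k-mer index over a genome's contigs (forward strand)."""

    def __init__(self, genome: GenomeSequence, k: int = DEFAULT_KMER):
        self.k = k
        self.contigs = [np.frombuffer(c.encode(), dtype="S1") for c in genome.contigs]
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ci, contig in enumerate(genome.contigs):
            for pos in range(0, len(contig) - k + 1):
                kmer = contig[pos : pos + k]
                if "N" in kmer:
                    continue
                hits = self.index.setdefault(kmer, [])
                if len(hits) < _MAX_POSITIONS_PER_KMER:
                    hits.append((ci, pos))

    def _score_diagonal(self, frag: np.ndarray, ci: int, offset: int) -> tuple[int, int]:
        """Ungapped comparison of the fragment on one diagonal; (matches, aligned)."""
        contig = self.contigs[ci]
        flen = frag.size
        f_start = max(0, -offset)
        f_end = min(flen, contig.size - offset)
        if f_end <= f_start:
            return 0, 0
        sub_f = frag[f_start:f_end]
        sub_c = contig[f_start + offset : f_end + offset]
        return int((sub_f == sub_c).sum()), f_end - f_start

    def best_placement(self, fragment: str) -> tuple[float, float]:
        """Best (identity %, coverage) over anchored diagonals, both strands."""
        best = (0.0, 0.0, -1)  # identity, coverage, matches
        for seq in (fragment, _revcomp(fragment)):
            frag = np.frombuffer(seq.encode(), dtype="S1")
            votes: dict[tuple[int, int], int] = {}
            for fpos in range(0, len(seq) - self.k + 1, _ANCHOR_STRIDE):
                kmer = seq[fpos : fpos + self.k]
                for ci, rpos in self.index.get(kmer, ()):
                    key = (ci, rpos - fpos)
                    votes[key] = votes.get(key, 0) + 1
            if not votes:
                continue
            diagonals = sorted(votes, key=votes.get, reverse=True)[:_MAX_DIAGONALS]
            for ci, offset in diagonals:
                matches, aligned = self._score_diagonal(frag, ci, offset)
                if aligned == 0:
                    continue
                identity = 100.0 * matches / aligned
                coverage = aligned / frag.size
                if matches > best[2]:
                    best = (identity, coverage, matches)
        return best[0], best[1]


def best_identity(
    fragment: str, reference_genome: GenomeSequence, k: int = DEFAULT_KMER
) -> tuple[float, float]:
    """Best ungapped placement of a fragment on a reference genome.

    Exact k-mer anchors on both strands propose diagonals; the best-scoring
    diagonal's (identity %, coverage fraction) is returned, or (0, 0) when no
    anchor exists.
    """
    return _ReferenceIndex(reference_genome, k).best_placement(fragment)


def _directed_ani(
    query: GenomeSequence,
    ref_index: _ReferenceIndex,
    fragment_length: int,
    min_identity: float,
    min_coverage: float,
) -> tuple[float, float]:
    """(mean identity of passing fragments, aligned fraction of query) or (nan, 0)."""
    identities: list[float] = []
    aligned_bp = 0
    for frag in fragment_genome(query, fragment_length):
        identity, coverage = ref_index.best_placement(frag)
        if identity >= min_identity and coverage >= min_coverage:
            identities.append(identity)
            aligned_bp += int(round(coverage * len(frag)))
    if not identities:
        return float("nan"), 0.0
    return float(np.mean(identities)), aligned_bp / query.length


def ani(
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    k: int = DEFAULT_KMER,
) -> float:
    """Average nucleotide identity (%) between two genomes.

    Mean fragment identity A->B averaged with B->A; fragments must pass the
    identity and coverage filters. Returns NaN (undefined-ANI sentinel) when
    no fragment aligns in either direction.
    """
    a_to_b, _ = _directed_ani(
        genome_a, _ReferenceIndex(genome_b, k), fragment_length, min_identity, min_coverage
    )
    b_to_a, _ = _directed_ani(
        genome_b, _ReferenceIndex(genome_a, k), fragment_length, min_identity, min_coverage
    )
    vals = [v for v in (a_to_b, b_to_a) if np.isfinite(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def ani_matrix(
    genomes: Sequence[GenomeSequence],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    k: int = DEFAULT_KMER,
) -> ANIMatrix:
    """All-vs-all symmetric ANI and aligned-fraction matrices.

    Genomes are processed in id-sorted order so the result is independent of
    input order. The diagonal is 100 % / fully aligned by definition.
    """
    ordered = sorted(genomes, key=lambda g: g.id)
    ids = [g.id for g in ordered]
    if len(set(ids)) != len(ids):
        raise ValueError("genome ids must be unique")
    n = len(ordered)
    ani_mat = np.full((n, n), 100.0)
    af_mat = np.eye(n)
    indexes = [_ReferenceIndex(g, k) for g in ordered]
    for i in range(n):
        for j in range(i + 1, n):
            fwd_id, fwd_af = _directed_ani(
                ordered[i], indexes[j], fragment_length, min_identity, min_coverage
            )
            rev_id, rev_af = _directed_ani(
                ordered[j], indexes[i], fragment_length, min_identity, min_coverage
            )
            vals = [v for v in (fwd_id, rev_id) if np.isfinite(v)]
            ani_mat[i, j] = ani_mat[j, i] = float(np.mean(vals)) if vals else np.nan
            af_mat[i, j] = af_mat[j, i] = (fwd_af + rev_af) / 2.0
    return ANIMatrix(
        ids=tuple(ids),
        ani=pd.DataFrame(ani_mat, index=ids, columns=ids),
        aligned_fraction=pd.DataFrame(af_mat, index=ids, columns=ids),
    )


def ward_cluster(
    matrix: ANIMatrix,
    population_cut: float = 100.0 - POPULATION_ANI_CUT,
    species_cut: float = 100.0 - SPECIES_ANI_CUT,
) -> dict:
    """Ward clustering of genomes on 100 - ANI with threshold cuts.

    Undefined ANI values are imputed to 70 % before clustering. The
    dendrogram is flat-cut at distance ``population_cut`` (default 1, i.e.
    ANI >= 99: sequence-discrete populations) and ``species_cut`` (default 5,
    ANI >= 95: species); both cuts are boundary-inclusive. Returns the
    linkage matrix, a Newick string, and id -> cluster-label maps.
    """
    ids = list(matrix.ids)
    if len(ids) < 2:
        return {
            "linkage": None,
            "newick": f"({ids[0]});" if ids else ";",
            "populations": {i: 1 for i in ids},
            "species": {i: 1 for i in ids},
        }
    ani_vals = matrix.ani.to_numpy(dtype=float).copy()
    ani_vals[~np.isfinite(ani_vals)] = UNDEFINED_ANI_IMPUTE
    dist = 100.0 - ani_vals
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    populations = hierarchy.fcluster(linkage, t=population_cut, criterion="distance")
    species = hierarchy.fcluster(linkage, t=species_cut, criterion="distance")
    tree = TreeNode.from_linkage_matrix(linkage, ids)
    return {
        "linkage": linkage,
        "newick": str(tree).strip(),
        "populations": dict(zip(ids, (int(c) for c in populations))),
        "species": dict(zip(ids, (int(c) for c in species))),
    }
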