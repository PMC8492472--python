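"""Ancestral-region calling, rearrangement accounting and Dollo gene-family loss.

An ancestral region (AR) is a multiple-alignment block longer than 1 kb in
which at least four of the seven genome rows map, through the user-supplied
homoeolog map, to the same ancestral chromosome. AR orientation is the
majority strand among the supporting rows. Translocation and inversion
fractions, retention/loss densities and Dollo-parsimony branch losses follow
from the AR calls and a family presence/absence matrix over the species tree.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy import stats

from .io_formats import AlignmentBlock, BlockRow

logger = logging.getLogger("allokit")

AR_MIN_LENGTH = 1000
AR_MIN_SUPPORT = 4
AR_RESOLUTION = 1000  # report coordinates snapped to 1-kb boundaries


@dataclass
class AncestralRegion:
    ar_id: str
    ancestral_chromosome: str
    orientation: str  # '+' or '-' (majority strand; tie -> '+', flagged)
    rows: list[BlockRow]
    supporting_genomes: frozenset[str]
    length: int
    orientation_tie: bool = False

    def snapped_interval(self, row: BlockRow) -> tuple[int, int]:
        """Row interval snapped outward to 1-kb boundaries for reporting."""
        start = (row.start // AR_RESOLUTION) * AR_RESOLUTION
        end = -(-row.end // AR_RESOLUTION) * AR_RESOLUTION
        return start, end


def call_ancestral_regions(
    blocks: Sequence[AlignmentBlock],
    homoeolog_map: Mapping[str, str],
) -> list[AncestralRegion]:
    """Call ARs from alignment blocks.

    A block becomes an AR iff its length exceeds 1 kb and at least four rows
    map to one ancestral chromosome; that chromosome is the AR's ancestral
    chromosome and the majority strand among agreeing rows its orientation.
    Blocks touching unmapped chromosomes are skipped with a warning. The
    result is independent of block order.
    """
    ars: list[AncestralRegion] = []
    for block in blocks:
        mapped: list[tuple[BlockRow, str]] = []
        skip = False
        for row in block.rows:
            anc = homoeolog_map.get(row.chromosome)
            if anc is None:
                logger.warning(
                    "block %s: chromosome %s not in homoeolog map; block skipped",
                    block.block_id, row.chromosome,
                )
                skip = True
                break
            mapped.append((row, anc))
        if skip or block.length <= AR_MIN_LENGTH:
            continue
        counts = Counter(anc for _, anc in mapped)
        anc_chrom, support = counts.most_common(1)[0]
        if support < AR_MIN_SUPPORT:
            continue
        agreeing = [row for row, anc in mapped if anc == anc_chrom]
        strands = Counter(row.strand for row in agreeing)
        plus, minus = strands.get("+", 0), strands.get("-", 0)
        tie = plus == minus
        orientation = "+" if plus >= minus else "-"
        ars.append(
            AncestralRegion(
                ar_id=block.block_id,
                ancestral_chromosome=anc_chrom,
                orientation=orientation,
                rows=list(block.rows),
                supporting_genomes=frozenset(r.genome_id for r in agreeing),
                length=block.length,
                orientation_tie=tie,
            )
        )
    return ars


# ---------------------------------------------------------------------------
# Rearrangement fractions
# ---------------------------------------------------------------------------


@dataclass
class RearrangementSummary:
    genome_id: str
    n_ars: int  # ARs with a row in this genome
    n_translocated: int
    n_inverted: int
    translocated_fraction: float
    inverted_fraction: float  # computed over non-translocated ARs only
    retained_per_mb: Optional[float] = None
    lost_per_mb: Optional[float] = None


def rearrangement_fractions(
    ars: Sequence[AncestralRegion],
    genome_id: str,
    homoeolog_map: Mapping[str, str],
) -> RearrangementSummary:
    """Translocated and inverted AR fractions for one genome.

    An AR is translocated in a genome when that genome's row maps to an
    ancestral chromosome different from the AR's; among non-translocated
    ARs, it is inverted when the row strand opposes the AR orientation.
    """
    n_total = n_trans = n_inv = n_non_trans = 0
    for ar in ars:
        row = next((r for r in ar.rows if r.genome_id == genome_id), None)
        if row is None:
            continue
        n_total += 1
        if homoeolog_map.get(row.chromosome) != ar.ancestral_chromosome:
            n_trans += 1
        else:
            n_non_trans += 1
            if row.strand != ar.orientation:
                n_inv += 1
    if n_total == 0:
        raise ValueError(f"genome {genome_id!r} absent from all ARs")
    return RearrangementSummary(
        genome_id=genome_id,
        n_ars=n_total,
        n_translocated=n_trans,
        n_inverted=n_inv,
        translocated_fraction=n_trans / n_total,
        inverted_fraction=(n_inv / n_non_trans) if n_non_trans else 0.0,
    )


# ---------------------------------------------------------------------------
# Retention / loss densities
# ---------------------------------------------------------------------------


def retention_loss_per_mb(
    ars: Sequence[AncestralRegion],
    genome_id: str,
    subgenome_size_mb: float,
    universe: Sequence[str],
) -> tuple[float, float, int, int]:
    """Retained and lost AR densities per Mb for one genome.

    ``universe`` lists all ancestral AR loci; an AR locus is retained when
    the genome has a supporting row in the called AR of that id, lost
    otherwise. Returns ``(retained_per_mb, lost_per_mb, n_retained, n_lost)``.
    """
    if subgenome_size_mb <= 0:
        raise ValueError("subgenome size must be positive")
    present = {
        ar.ar_id for ar in ars if genome_id in ar.supporting_genomes
    }
    universe_set = set(universe)
    if not present <= universe_set:
        raise ValueError("universe must contain every called AR for the genome")
    n_ret = len(present)
    n_lost = len(universe_set) - n_ret
    return (
        n_ret / subgenome_size_mb,
        n_lost / subgenome_size_mb,
        n_ret,
        n_lost,
    )


def compare_retention_chi2(
    retained1: int, lost1: int, retained2: int, lost2: int
) -> tuple[float, float]:
    """χ² comparison (1 df, continuity corrected) of two retained/lost tables."""
    table = np.array([[retained1, lost1], [retained2, lost2]])
    if (table.sum(axis=1) == 0).any():
        raise ValueError("empty retention table")
    if np.array_equal(table[0], table[1]):
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# Dollo-parsimony family losses
# ---------------------------------------------------------------------------


@dataclass
class FamilyPresenceMatrix:
    """Presence/absence of gene families over the taxa of a species tree."""

    species_tree_newick: str
    presence: dict[str, frozenset[str]]  # family -> taxa with the family

    def __post_init__(self) -> None:
        for family, taxa in self.presence.items():
            if not taxa:
                raise ValueError(f"family {family} absent from every taxon")


@dataclass
class DolloResult:
    branch_losses: dict[str, int]  # branch (named by its leaf set) -> losses
    retained_per_taxon: dict[str, int]
    origins: dict[str, str]  # family -> branch name of its origin node


def _branch_name(leaves: frozenset[str]) -> str:
    return "+".join(sorted(leaves))


def dollo_branch_losses(matrix: FamilyPresenceMatrix) -> DolloResult:
    """Map family losses onto the species tree by Dollo parsimony.

    Each family originates once, at the most recent common ancestor of the
    taxa containing it; losses are the minimal set of branches below the
    origin whose removal explains every absence (one loss per maximal
    all-absent subtree). Branches are named by the leaf set below them.
    """
    tree = dendropy.Tree.get(
        data=matrix.species_tree_newick,
        schema="newick",
        preserve_underscores=True,
    )
    taxa_in_tree = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    branch_losses: dict[str, int] = defaultdict(int)
    retained: dict[str, int] = {t: 0 for t in taxa_in_tree}
    origins: dict[str, str] = {}

    leafset: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafset[node] = frozenset({node.taxon.label})
        else:
            leafset[node] = frozenset().union(
                *(leafset[c] for c in node.child_nodes())
            )

    for family, present in matrix.presence.items():
        unknown = present - taxa_in_tree
        if unknown:
            raise ValueError(f"family {family}: taxa {sorted(unknown)} not in tree")
        for t in present:
            retained[t] += 1
        # origin: smallest clade containing all present taxa
        origin = tree.seed_node
        changed = True
        while changed:
            changed = False
            for child in origin.child_nodes():
                if present <= leafset[child]:
                    origin = child
                    changed = True
                    break
        origins[family] = _branch_name(leafset[origin])

        def visit(node) -> None:
            for child in node.child_nodes():
                below = leafset[child]
                if below & present:
                    visit(child)
                else:
                    branch_losses[_branch_name(below)] += 1

        visit(origin)

    return DolloResult(
        branch_losses=dict(branch_losses),
        retained_per_taxon=retained,
        origins=origins,
    )
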