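"""Subgenome assignment of allo-tetraploid gene copies from gene-tree topology.

A heptad family carries one gene from each diploid (zebrafish, the outgroup
P. guichenoti and the progenitor-like P. tetrazona) and two genes from each
tetraploid (common carp, goldfish). After rooting on zebrafish, the family is
*canonical* when one clade holds exactly the P. tetrazona gene plus one carp
and one goldfish gene (those tetraploid genes are subB, being phylogenetically
closer to P. tetrazona) and its sister clade holds the remaining carp and
goldfish genes (subA). Chromosomes are assigned to subgenomes by majority
vote of the labelled genes they host, and a gene whose label disagrees with
its host chromosome's subgenome marks a homoeologous exchange (HE).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneTree, GeneLocation, split_leaf_label

logger = logging.getLogger("allokit")

TETRAPLOIDS = ("carp", "goldfish")
EXPECTED_CENSUS = {
    "zebrafish": 1,
    "pguichenoti": 1,
    "ptetrazona": 1,
    "carp": 2,
    "goldfish": 2,
}


class HeptadError(ValueError):
    """Raised when a tree violates the heptad leaf census."""


@dataclass
class HeptadClassification:
    family_id: str
    carp_subB_gene: Optional[str] = None
    carp_subA_gene: Optional[str] = None
    goldfish_subB_gene: Optional[str] = None
    goldfish_subA_gene: Optional[str] = None
    status: str = "complex"  # {canonical, complex}
    min_support_ok: bool = True

    @property
    def labels(self) -> dict[str, str]:
        """gene id -> {subA, subB} for canonical families (empty otherwise)."""
        if self.status != "canonical":
            return {}
        return {
            self.carp_subB_gene: "subB",
            self.goldfish_subB_gene: "subB",
            self.carp_subA_gene: "subA",
            self.goldfish_subA_gene: "subA",
        }


def classify_heptad_topology(
    tree: GeneTree,
    min_support: Optional[int] = None,
    family_id: str = "",
) -> HeptadClassification:
    """Classify a 7-leaf gene tree as canonical (subA/subB resolved) or complex.

    The tree is rooted on the zebrafish leaf; classification is invariant to
    leaf order and internal-node rotation. When ``min_support`` is given, the
    two internal branches defining the subB clade and the subA pair must have
    support at least that value, else ``min_support_ok`` is False.
    """
    leaves = list(tree.tree.leaf_node_iter())
    census = Counter(split_leaf_label(l.taxon.label)[0] for l in leaves)
    if dict(census) != EXPECTED_CENSUS:
        raise HeptadError(
            f"heptad tree needs leaf census {EXPECTED_CENSUS}, got {dict(census)}"
        )

    work = tree.tree.clone(depth=1)
    zeb = next(
        l for l in work.leaf_node_iter()
        if split_leaf_label(l.taxon.label)[0] == "zebrafish"
    )
    work.reroot_at_edge(zeb.edge, update_bipartitions=False)

    def leaf_info(node) -> list[tuple[str, str]]:
        return [
            split_leaf_label(l.taxon.label)
            for l in node.leaf_iter()
        ]

    result = HeptadClassification(family_id=family_id)
    for node in work.preorder_internal_node_iter():
        info = leaf_info(node)
        if len(info) != 3:
            continue
        tags = Counter(t for t, _ in info)
        if tags != Counter({"ptetrazona": 1, "carp": 1, "goldfish": 1}):
            continue
        parent = node.parent_node
        if parent is None:
            continue
        siblings = [c for c in parent.child_nodes() if c is not node]
        if len(siblings) != 1:
            continue
        sib_info = leaf_info(siblings[0])
        sib_tags = Counter(t for t, _ in sib_info)
        if sib_tags != Counter({"carp": 1, "goldfish": 1}):
            continue
        b_genes = {t: g for t, g in info}
        a_genes = {t: g for t, g in sib_info}
        result.carp_subB_gene = b_genes["carp"]
        result.goldfish_subB_gene = b_genes["goldfish"]
        result.carp_subA_gene = a_genes["carp"]
        result.goldfish_subA_gene = a_genes["goldfish"]
        result.status = "canonical"
        if min_support is not None:
            supports = []
            for n in (node, siblings[0]):
                try:
                    supports.append(int(float(n.label)) if n.label else None)
                except (TypeError, ValueError):
                    supports.append(None)
            result.min_support_ok = all(
                s is not None and s >= min_support for s in supports
            )
        break
    return result


# ---------------------------------------------------------------------------
# Chromosome-level subgenome assignment
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeAssignment:
    chromosome: str
    subgenome: str  # {A, B}
    subA_count: int
    subB_count: int
    tie_broken: bool = False


def _chromosome_votes(
    classifications: Sequence[HeptadClassification],
    locations: Mapping[str, GeneLocation],
) -> dict[str, Counter]:
    votes: dict[str, Counter] = {}
    for cls in classifications:
        for gene, label in cls.labels.items():
            loc = locations.get(gene)
            if loc is None:
                logger.warning("gene %s has no location; excluded from voting", gene)
                continue
            if loc.on_scaffold:
                continue
            votes.setdefault(loc.chromosome, Counter())[label] += 1
    return votes


def assign_chromosome_subgenomes(
    classifications: Sequence[HeptadClassification],
    locations: Mapping[str, GeneLocation],
    homoeolog_pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> list[ChromosomeAssignment]:
    """Majority-vote subgenome labels for chromosomes.

    A chromosome with more subB than subA labelled genes is B, and vice
    versa. When ``homoeolog_pairs`` is supplied, each pair is constrained to
    one A and one B member: ties take the complement of the partner, and if
    both partners lean the same way the weaker majority is flipped
    (``tie_broken`` flags any such resolution). Chromosomes with zero
    labelled genes are skipped with a warning.
    """
    votes = _chromosome_votes(classifications, locations)
    margin = {
        chrom: c.get("subB", 0) - c.get("subA", 0) for chrom, c in votes.items()
    }

    def make(chrom: str, subgenome: str, tie_broken: bool) -> ChromosomeAssignment:
        c = votes.get(chrom, Counter())
        return ChromosomeAssignment(
            chromosome=chrom,
            subgenome=subgenome,
            subA_count=c.get("subA", 0),
            subB_count=c.get("subB", 0),
            tie_broken=tie_broken,
        )

    assignments: list[ChromosomeAssignment] = []
    if homoeolog_pairs is None:
        for chrom in sorted(votes):
            m = margin[chrom]
            if m == 0:
                assignments.append(make(chrom, "A", tie_broken=True))
            else:
                assignments.append(make(chrom, "B" if m > 0 else "A", False))
        return assignments

    paired = {c for pair in homoeolog_pairs for c in pair}
    for chrom in sorted(votes):
        if chrom not in paired:
            logger.warning("chromosome %s not in any homoeologous pair", chrom)
    for c1, c2 in homoeolog_pairs:
        m1, m2 = margin.get(c1, 0), margin.get(c2, 0)
        if c1 not in votes and c2 not in votes:
            logger.warning("pair (%s, %s) has no labelled genes; skipped", c1, c2)
            continue
        if m1 == m2:
            # same margin both ways: deterministic break, first member gets B
            # when leaning B, else A
            first_b = m1 > 0 or (m1 == 0 and c1 < c2)
            assignments.append(make(c1, "B" if first_b else "A", True))
            assignments.append(make(c2, "A" if first_b else "B", True))
        elif m1 > m2:
            # flagged when the member's own majority did not force its label
            assignments.append(make(c1, "B", m1 <= 0))
            assignments.append(make(c2, "A", m2 >= 0))
        else:
            assignments.append(make(c1, "A", m1 >= 0))
            assignments.append(make(c2, "B", m2 <= 0))
    return assignments


# ---------------------------------------------------------------------------
# Homoeologous-exchange detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HEEvent:
    gene: str
    label: str  # phylogenetic label {subA, subB}
    host_chromosome: str
    host_subgenome: str  # disagrees with label by definition
    validated: Optional[bool] = None  # None = untested


@dataclass
class HEDetectionResult:
    events: list[HEEvent]
    n_scaffold_excluded: int
    n_missing_location: int


def detect_homoeologous_exchanges(
    classifications: Sequence[HeptadClassification],
    locations: Mapping[str, GeneLocation],
    assignments: Sequence[ChromosomeAssignment],
) -> HEDetectionResult:
    """Find genes whose phylogenetic subgenome label disagrees with the
    subgenome of their host chromosome.

    Scaffold-hosted genes are excluded and counted separately; genes with
    missing locations are excluded and logged.
    """
    chrom_subgenome = {a.chromosome: a.subgenome for a in assignments}
    events: list[HEEvent] = []
    n_scaffold = 0
    n_missing = 0
    for cls in classifications:
        for gene, label in cls.labels.items():
            loc = locations.get(gene)
            if loc is None:
                logger.warning("HE detection: gene %s has no location", gene)
                n_missing += 1
                continue
            if loc.on_scaffold:
                n_scaffold += 1
                continue
            host = chrom_subgenome.get(loc.chromosome)
            if host is None:
                logger.warning(
                    "HE detection: chromosome %s unassigned", loc.chromosome
                )
                continue
            if ("B" if label == "subB" else "A") != host:
                events.append(
                    HEEvent(
                        gene=gene,
                        label=label,
                        host_chromosome=loc.chromosome,
                        host_subgenome=host,
                    )
                )
    return HEDetectionResult(
        events=events,
        n_scaffold_excluded=n_scaffold,
        n_missing_location=n_missing,
    )


# ---------------------------------------------------------------------------
# HE validation by read-depth bias
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HEValidation:
    p_value: Optional[float]
    validated: Optional[bool]  # None = untested
    status: str  # {tested, untested}


def validate_he_read_bias(
    exchanged_counts: Sequence[float],
    hosted_counts: Sequence[float],
    direction: str = "exchanged_higher",
    alpha: float = 0.05,
) -> HEValidation:
    """One-sided rank-sum validation of HE events via progenitor read bias.

    More P. tetrazona genomic reads are expected on exchanged subB genes than
    on the hosted subA genes of the same subgenome (``exchanged_higher``);
    the mirror expectation for exchanged subA genes is ``exchanged_lower``.
    Counts should be normalised per kb of gene length before testing. Empty
    groups give an *untested* status rather than a failure.
    """
    if direction not in ("exchanged_higher", "exchanged_lower"):
        raise ValueError("direction must be exchanged_higher or exchanged_lower")
    exchanged = np.asarray(list(exchanged_counts), dtype=float)
    hosted = np.asarray(list(hosted_counts), dtype=float)
    if exchanged.size == 0 or hosted.size == 0:
        return HEValidation(p_value=None, validated=None, status="untested")
    alternative = "greater" if direction == "exchanged_higher" else "less"
    method = "exact" if (exchanged.size <= 8 and hosted.size <= 8) else "asymptotic"
    if method == "exact" and np.unique(
        np.concatenate([exchanged, hosted])
    ).size < exchanged.size + hosted.size:
        method = "asymptotic"
    res = stats.mannwhitneyu(exchanged, hosted, alternative=alternative, method=method)
    p = float(res.pvalue)
    return HEValidation(p_value=p, validated=p <= alpha, status="tested")


def normalize_counts_per_kb(
    counts: Mapping[str, float], locations: Mapping[str, GeneLocation]
) -> dict[str, float]:
    """Normalise per-gene read counts by gene length in kb."""
    out = {}
    for gene, count in counts.items():
        loc = locations[gene]
        out[gene] = count / ((loc.end - loc.start) / 1000.0)
    return out


# ---------------------------------------------------------------------------
# Region-level HE from windowed depth ratios
# ---------------------------------------------------------------------------


def detect_he_regions_from_depth(
    log2_depth_ratios: Sequence[float], fold_threshold: float = 1.0
) -> list[int]:
    """Region-level HE candidates from windowed log2(depth_A/depth_B) values.

    A window is called when its ratio's sign is inverted relative to the
    chromosome-wide median by more than ``fold_threshold`` log2 units
    (two-fold by default).
    """
    ratios = np.asarray(list(log2_depth_ratios), dtype=float)
    if ratios.size == 0:
        return []
    median = float(np.median(ratios))
    called = []
    for i, x in enumerate(ratios):
        if np.sign(x) != np.sign(median) and abs(x - median) > fold_threshold:
            called.append(i)
    return called
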