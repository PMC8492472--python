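"""Readers and writers for the standard formats the toolkit consumes.

All coordinates are 0-based half-open internally; conversion to and from the
1-based conventions of VCF happens only at the parsing boundary, and MAF
reverse-strand rows are converted to forward-strand intervals on read.
"""

from __future__ import annotations

import io
import logging
import math
import os
import tempfile
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO

logger = logging.getLogger("allokit")

#: species tags recognised in heptad gene-family trees
SPECIES_TAGS = frozenset(
    {"zebrafish", "pguichenoti", "ptetrazona", "carp", "goldfish"}
)

#: reserved chromosome prefix for unanchored genes
SCAFFOLD_PREFIX = "scaffold:"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class NewickParseError(FormatError):
    """Malformed newick; carries the offending character offset when known."""

    def __init__(self, message: str, offset: Optional[int] = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Gene trees (newick)
# ---------------------------------------------------------------------------


def split_leaf_label(label: str) -> tuple[Optional[str], str]:
    """Split a ``species|gene`` leaf label; plain labels get no species tag."""
    if "|" in label:
        tag, gene = label.split("|", 1)
        return tag, gene
    return None, label


@dataclass
class GeneTree:
    """A per-family gene tree with optional supports and branch lengths."""

    newick_string: str
    tree: dendropy.Tree

    @property
    def leaf_labels(self) -> list[tuple[Optional[str], str]]:
        return [
            split_leaf_label(leaf.taxon.label)
            for leaf in self.tree.leaf_node_iter()
        ]

    @property
    def branch_supports(self) -> list[int]:
        supports = []
        for node in self.tree.preorder_internal_node_iter():
            if node.label is not None:
                try:
                    supports.append(int(float(node.label)))
                except ValueError:
                    pass
        return supports

    @property
    def branch_lengths(self) -> list[float]:
        return [
            edge.length
            for edge in self.tree.preorder_edge_iter()
            if edge.length is not None
        ]

    def write(self) -> str:
        """Serialise back to newick (re-parsing yields the same topology)."""
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()


def _scan_newick_for_offset(text: str) -> Optional[int]:
    """Locate the first structurally offending character, if any."""
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
        elif ch == ";":
            if depth != 0:
                return i
    if depth != 0:
        return len(text)
    return None


def read_newick(text: str) -> GeneTree:
    """Parse a newick string into a :class:`GeneTree`.

    Supports and branch lengths are preserved; leaf labels must be unique.
    """
    offset = _scan_newick_for_offset(text)
    if offset is not None:
        raise NewickParseError("unbalanced newick", offset=offset)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed newick: {exc}", offset=None) from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise NewickParseError("duplicate leaf labels")
    return GeneTree(newick_string=text.strip(), tree=tree)


# ---------------------------------------------------------------------------
# MAF alignment blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockRow:
    """One aligned genome segment, forward-strand 0-based half-open."""

    genome_id: str
    chromosome: str
    start: int
    end: int
    strand: str  # '+' or '-'

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentBlock:
    block_id: str
    rows: list[BlockRow]

    @property
    def length(self) -> int:
        return max(row.span for row in self.rows)

    def __post_init__(self) -> None:
        for row in self.rows:
            if row.end <= row.start:
                raise FormatError(
                    f"block {self.block_id}: empty interval on {row.chromosome}"
                )


def _split_src(src: str) -> tuple[str, str]:
    if "." in src:
        genome, chrom = src.split(".", 1)
        return genome, chrom
    return src, src


def flip_strand_interval(start: int, size: int, src_size: int) -> tuple[int, int]:
    """Convert a reverse-strand MAF coordinate to a forward-strand interval."""
    fwd_start = src_size - start - size
    return fwd_start, fwd_start + size


def read_maf_blocks(text: str) -> list[AlignmentBlock]:
    """Parse MAF text into :class:`AlignmentBlock` objects.

    Negative-strand rows are converted to forward-strand 0-based half-open
    intervals using ``start' = srcSize - start - size``.
    """
    blocks: list[AlignmentBlock] = []
    handle = io.StringIO(text)
    try:
        alignments = list(AlignIO.parse(handle, "maf"))
    except Exception as exc:
        raise FormatError(f"malformed MAF: {exc}") from exc
    for i, aln in enumerate(alignments):
        rows = []
        for rec in aln:
            ann = rec.annotations
            start = int(ann["start"])
            size = int(ann["size"])
            strand = "+" if ann["strand"] in (1, "+") else "-"
            src_size = int(ann.get("srcSize", 0))
            genome, chrom = _split_src(rec.id)
            if strand == "-":
                if src_size <= 0:
                    raise FormatError(
                        f"block {i}: negative-strand row {rec.id} lacks a "
                        "source size; strand conversion impossible"
                    )
                fwd_start, fwd_end = flip_strand_interval(start, size, src_size)
            else:
                fwd_start, fwd_end = start, start + size
            rows.append(
                BlockRow(
                    genome_id=genome,
                    chromosome=chrom,
                    start=fwd_start,
                    end=fwd_end,
                    strand=strand,
                )
            )
        if len(rows) < 2:
            raise FormatError(f"block {i} has fewer than 2 rows")
        blocks.append(AlignmentBlock(block_id=f"block{i}", rows=rows))
    return blocks


def write_maf_blocks(
    blocks: Iterable[tuple[str, list[tuple[str, int, int, str, int, str]]]],
) -> str:
    """Format blocks as MAF text.

    Each block is ``(block_id, rows)`` with rows of
    ``(src, fwd_start, fwd_end, strand, src_size, seq_text)``; forward
    coordinates are converted back to strand-local MAF coordinates on write.
    """
    out = ["##maf version=1 scoring=none", ""]
    for _block_id, rows in blocks:
        out.append("a score=0")
        for src, start, end, strand, src_size, seq in rows:
            size = end - start
            if strand == "-":
                maf_start = src_size - end
            else:
                maf_start = start
            out.append(
                f"s {src} {maf_start} {size} {strand} {src_size} {seq}"
            )
        out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# VCF genotype matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Site:
    chromosome: str
    position: int  # 0-based internally
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes as alt-allele dosages (-1 = missing)."""

    sample_ids: list[str]
    sites: list[Site]
    genotypes: np.ndarray  # (n_sites, n_samples) int8 dosage, -1 missing
    population_of: dict[str, str] = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        last: dict[str, int] = {}
        for site in self.sites:
            prev = last.get(site.chromosome)
            if prev is not None and site.position <= prev:
                raise FormatError(
                    f"positions not strictly increasing on {site.chromosome}"
                )
            last[site.chromosome] = site.position

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([index[s] for s in samples], dtype=int)

    def population_samples(self, population: str) -> list[str]:
        return [s for s, p in self.population_of.items() if p == population]


_SNP_ALLELES = frozenset("ACGT")


def read_vcf_minimal(source: str) -> GenotypeMatrix:
    """Read a VCF 4.x file (path or text) into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped with a logged count; missing
    genotypes are preserved as missing (-1 dosage).
    """
    import cyvcf2

    tmp_path = None
    if "\n" in source or source.lstrip().startswith("##"):
        fd, tmp_path = tempfile.mkstemp(suffix=".vcf")
        with os.fdopen(fd, "w") as fh:
            fh.write(source)
        path = tmp_path
    else:
        path = source
    try:
        vcf = cyvcf2.VCF(path, gts012=False)
        if "##FORMAT=<ID=GT" not in vcf.raw_header:
            raise FormatError("VCF has no GT FORMAT field")
        samples = list(vcf.samples)
        sites: list[Site] = []
        rows: list[np.ndarray] = []
        dropped = 0
        for variant in vcf:
            if (
                len(variant.ALT) != 1
                or variant.REF not in _SNP_ALLELES
                or variant.ALT[0] not in _SNP_ALLELES
            ):
                dropped += 1
                continue
            dosages = np.empty(len(samples), dtype=np.int8)
            for j, gt in enumerate(variant.genotypes):
                a, b = gt[0], gt[1]
                dosages[j] = -1 if (a < 0 or b < 0) else a + b
            sites.append(
                Site(
                    chromosome=variant.CHROM,
                    position=variant.POS - 1,
                    ref=variant.REF,
                    alt=variant.ALT[0],
                )
            )
            rows.append(dosages)
        vcf.close()
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)
    if dropped:
        logger.info("read_vcf_minimal: dropped %d non-biallelic-SNP records", dropped)
    genotypes = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=samples, sites=sites, genotypes=genotypes, n_dropped=dropped
    )


# ---------------------------------------------------------------------------
# Location and expression TSVs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLocation:
    chromosome: str
    start: int
    end: int
    strand: str

    @property
    def on_scaffold(self) -> bool:
        return self.chromosome.startswith(SCAFFOLD_PREFIX)


def read_locations_tsv(source: str) -> dict[str, GeneLocation]:
    """Read a gene-location table (gene_id, chromosome, start, end, strand)."""
    handle = io.StringIO(source) if "\n" in source else source
    df = pd.read_csv(handle, sep="\t", dtype={"chromosome": str})
    required = {"gene_id", "chromosome", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"location TSV must have columns {sorted(required)}")
    return {
        row.gene_id: GeneLocation(
            chromosome=row.chromosome,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
        )
        for row in df.itertuples()
    }


def write_locations_tsv(locations: Mapping[str, GeneLocation]) -> str:
    lines = ["gene_id\tchromosome\tstart\tend\tstrand"]
    for gene, loc in locations.items():
        lines.append(f"{gene}\t{loc.chromosome}\t{loc.start}\t{loc.end}\t{loc.strand}")
    return "\n".join(lines) + "\n"


def read_expression_tsv(source: str) -> pd.DataFrame:
    """Read a TPM matrix (gene_id + one column per tissue/condition)."""
    handle = io.StringIO(source) if "\n" in source else source
    df = pd.read_csv(handle, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError("TPM values must be non-negative")
    return df


# ---------------------------------------------------------------------------
# Assembly anchoring summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnchoringSummary:
    anchored_fraction: float  # percent, 1 decimal
    mean_chromosome_size: float  # Mb, 2 decimals
    n_chromosomes: int


def summarize_anchoring(
    chromosome_lengths: Sequence[float], assembly_size: float
) -> AnchoringSummary:
    """Summarise how much of an assembly is anchored into pseudo-chromosomes.

    ``anchored_fraction`` is ``100 * anchored_total / assembly_size`` rounded
    half-up to 1 decimal; the mean chromosome size is rounded to 2 decimals.
    """
    n = len(chromosome_lengths)
    if n == 0:
        raise ValueError("at least one chromosome required")
    total = float(sum(chromosome_lengths))
    if not (assembly_size >= total > 0):
        raise ValueError("need assembly_size >= sum(chromosome_lengths) > 0")
    return AnchoringSummary(
        anchored_fraction=round_half_up(100.0 * total / assembly_size, 1),
        mean_chromosome_size=round_half_up(total / n, 2),
        n_chromosomes=n,
    )
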