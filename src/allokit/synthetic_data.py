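"""Synthetic-data generators with planted ground truth.

Every input the toolkit consumes can be generated here at desk scale:
heptad gene families evolved under a codon substitution process whose
synonymous branch lengths target the cyprinid Ks scales, homoeolog
expression panels with subgenome dominance and outgroup-correlation
structure, seven-genome alignment blocks with planted translocations and
inversions, and two-population genotype matrices with planted sweep
windows. All generators are deterministic under a fixed seed and record
their planted truth in a :class:`SimulationTruth`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneLocation,
    write_locations_tsv,
    write_maf_blocks,
    read_maf_blocks,
    read_vcf_minimal,
    GenotypeMatrix,
)
from .molecular_evolution import (
    GENETIC_CODE,
    STOP_CODONS,
    NUCLEOTIDES,
    synonymous_site_count,
)


@dataclass
class SimulationTruth:
    """Planted ground truth, sufficient to score every downstream detector."""

    seed: int
    subgenome_labels: dict[str, str] = field(default_factory=dict)
    chromosome_subgenomes: dict[str, str] = field(default_factory=dict)
    homoeolog_pairs: list[tuple[str, str]] = field(default_factory=list)
    he_genes: list[str] = field(default_factory=list)
    noisy_families: list[str] = field(default_factory=list)
    branch_ks: dict[str, float] = field(default_factory=dict)
    translocated_rows: list[tuple[str, str]] = field(default_factory=list)
    inverted_rows: list[tuple[str, str]] = field(default_factory=list)
    block_ancestral: dict[str, str] = field(default_factory=dict)
    ar_eligible_blocks: list[str] = field(default_factory=list)
    sweep_window_ids: list[int] = field(default_factory=list)
    dominance_bias: Optional[float] = None
    conserved_genes: list[str] = field(default_factory=list)
    divergent_pairs: list[str] = field(default_factory=list)
    dominant_subgenome: dict[str, str] = field(default_factory=dict)
    archetype_of: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(asdict(self), indent=1, default=default)


# ---------------------------------------------------------------------------
# Codon evolution
# ---------------------------------------------------------------------------

_SENSE_CODONS = sorted(set(GENETIC_CODE) - STOP_CODONS)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _random_codon_sequence(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return [_SENSE_CODONS[i] for i in idx]


def _total_syn_sites(codons: Sequence[str]) -> float:
    return sum(synonymous_site_count(c) for c in codons)


def _evolve_branch(
    codons: list[str],
    ks_length: float,
    rng: np.random.Generator,
    omega: float,
    kappa: float,
) -> list[str]:
    """Evolve a codon sequence along one branch of synonymous length ``ks_length``.

    Substitutions are proposed one nucleotide at a time with a
    transition/transversion weight ``kappa``; proposals creating stop codons
    are rejected, synonymous proposals are always accepted and nonsynonymous
    proposals accepted with probability ``omega``. The branch ends once the
    number of accepted synonymous events reaches a Poisson draw with mean
    ``ks_length`` times the branch-start synonymous site count, so realised
    synonymous divergence tracks the requested Ks scale.
    """
    codons = list(codons)
    if ks_length <= 0:
        return codons
    n = len(codons)
    target = rng.poisson(ks_length * _total_syn_sites(codons))
    accepted_syn = 0
    while accepted_syn < target:
        ci = int(rng.integers(0, n))
        pos = int(rng.integers(0, 3))
        codon = codons[ci]
        old = codon[pos]
        # transition gets weight kappa, the two transversions weight 1 each
        total_w = kappa + 2.0
        u = rng.random() * total_w
        if u < kappa:
            new = _TRANSITION[old]
        else:
            tvs = [b for b in NUCLEOTIDES if b != old and b != _TRANSITION[old]]
            new = tvs[0] if u < kappa + 1.0 else tvs[1]
        new_codon = codon[:pos] + new + codon[pos + 1:]
        if new_codon in STOP_CODONS:
            continue
        if GENETIC_CODE[new_codon] == GENETIC_CODE[codon]:
            codons[ci] = new_codon
            accepted_syn += 1
        elif rng.random() < omega:
            codons[ci] = new_codon
    return codons


# ---------------------------------------------------------------------------
# Heptad gene families
# ---------------------------------------------------------------------------

#: per-branch synonymous targets matching the observed cyprinid Ks modes
DEFAULT_KS_SPEC = {
    "A_vs_B": 0.19,      # orthologues across the A and B lineages
    "Pt_vs_Banc": 0.18,  # P. tetrazona vs the B-subgenome ancestor
    "ccB_gfB": 0.10,     # carp-B vs goldfish-B
    "ccA_gfA": 0.095,    # carp-A vs goldfish-A
}

CARP_CHROM_COUNT = 25  # homoeologous pairs per tetraploid


@dataclass
class HeptadFamily:
    family_id: str
    sequences: dict[str, str]  # leaf label ("species|gene") -> nt sequence
    tree_newick: str
    is_noisy: bool


@dataclass
class HeptadDataset:
    families: list[HeptadFamily]
    locations: dict[str, GeneLocation]
    truth: SimulationTruth

    def alignment_fasta(self, family: HeptadFamily) -> str:
        return "".join(
            f">{label}\n{seq}\n" for label, seq in sorted(family.sequences.items())
        )

    def trees_newick(self) -> str:
        return "".join(f.tree_newick + "\n" for f in self.families)

    def locations_tsv(self) -> str:
        return write_locations_tsv(self.locations)

    def pairs(self, kind: str) -> Iterator[tuple[str, str]]:
        """Yield aligned sequence pairs for a Ks comparison.

        ``kind``: ``A_vs_B`` (carp-A vs carp-B homoeologues), ``Pt_vs_Banc``
        (P. tetrazona vs carp-B), ``ccB_gfB`` or ``ccA_gfA``. Noisy families
        are skipped (their copies have no subgenome identity).
        """
        picks = {
            "A_vs_B": ("ccA", "ccB"),
            "Pt_vs_Banc": ("pt", "ccB"),
            "ccB_gfB": ("ccB", "gfB"),
            "ccA_gfA": ("ccA", "gfA"),
        }
        if kind not in picks:
            raise ValueError(f"unknown pair kind {kind!r}")
        want1, want2 = picks[kind]
        for fam in self.families:
            if fam.is_noisy:
                continue
            roles = self._roles(fam)
            yield fam.sequences[roles[want1]], fam.sequences[roles[want2]]

    def _roles(self, fam: HeptadFamily) -> dict[str, str]:
        roles: dict[str, str] = {}
        for label in fam.sequences:
            species, gene = label.split("|", 1)
            if species == "ptetrazona":
                roles["pt"] = label
            elif species in ("carp", "goldfish"):
                sub = self.truth.subgenome_labels.get(gene)
                key = ("cc" if species == "carp" else "gf") + (
                    "A" if sub == "subA" else "B"
                )
                roles[key] = label
        return roles

    def write_to_dir(self, path) -> None:
        import os

        os.makedirs(path, exist_ok=True)
        for fam in self.families:
            with open(os.path.join(path, f"{fam.family_id}.fasta"), "w") as fh:
                fh.write(self.alignment_fasta(fam))
        with open(os.path.join(path, "trees.nwk"), "w") as fh:
            fh.write(self.trees_newick())
        with open(os.path.join(path, "locations.tsv"), "w") as fh:
            fh.write(self.locations_tsv())
        with open(os.path.join(path, "truth.json"), "w") as fh:
            fh.write(self.truth.to_json())


def _heptad_depths(ks_spec: dict[str, float]) -> dict[str, float]:
    d_ab = ks_spec["A_vs_B"] / 2.0
    d_ptb = ks_spec["Pt_vs_Banc"] / 2.0
    d_b = ks_spec["ccB_gfB"] / 2.0
    d_a = ks_spec["ccA_gfA"] / 2.0
    if not (d_ab >= d_ptb >= d_b and d_ab >= d_a):
        raise ValueError(
            "ks_spec incompatible with the species topology: need "
            "A_vs_B >= Pt_vs_Banc >= ccB_gfB and A_vs_B >= ccA_gfA"
        )
    return {
        "zeb": max(0.21, 1.1 * d_ab),
        "pg": max(0.13, 1.05 * d_ab),
        "ab": d_ab,
        "ptb": d_ptb,
        "b": d_b,
        "a": d_a,
    }


def simulate_heptad_families(
    n_families: int,
    ks_spec: Optional[dict[str, float]] = None,
    he_rate: float = 0.0,
    topology_noise: float = 0.0,
    seed: int = 0,
    n_codons: int = 200,
    omega: float = 0.1,
    kappa: float = 2.0,
) -> HeptadDataset:
    """Simulate 1:1:1:2:2 heptad families with planted subgenome truth.

    Families evolve along the fixed species topology
    ``(zebrafish,(Pg,((Pt,(ccB,gfB)),(ccA,gfA))))`` under a codon process
    targeting the per-branch synonymous divergences in ``ks_spec``. A
    fraction ``he_rate`` of families has one tetraploid gene relocated to
    the homoeologous chromosome (a planted HE); a fraction
    ``topology_noise`` is emitted with a non-canonical topology (the two
    carp copies sister to each other inside the P. tetrazona clade) and no
    subgenome truth labels.
    """
    ks_spec = dict(DEFAULT_KS_SPEC if ks_spec is None else ks_spec)
    for name, rate in (("he_rate", he_rate), ("topology_noise", topology_noise)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if he_rate + topology_noise > 1.0:
        raise ValueError("he_rate + topology_noise must not exceed 1")
    if any(v < 0 for v in ks_spec.values()):
        raise ValueError("ks_spec values must be >= 0")
    depths = _heptad_depths(ks_spec)
    rng = np.random.default_rng(seed)

    truth = SimulationTruth(
        seed=seed,
        branch_ks=ks_spec,
        dominance_bias=None,
        params={
            "n_families": n_families,
            "he_rate": he_rate,
            "topology_noise": topology_noise,
            "n_codons": n_codons,
            "omega": omega,
            "kappa": kappa,
        },
    )
    # chromosome layout: cc01..cc25 = carp A subgenome, cc26..cc50 = carp B;
    # gf chromosomes mirror this.
    for i in range(1, CARP_CHROM_COUNT + 1):
        for prefix in ("cc", "gf"):
            truth.chromosome_subgenomes[f"{prefix}{i:02d}"] = "A"
            truth.chromosome_subgenomes[f"{prefix}{i + CARP_CHROM_COUNT:02d}"] = "B"
            truth.homoeolog_pairs.append(
                (f"{prefix}{i:02d}", f"{prefix}{i + CARP_CHROM_COUNT:02d}")
            )

    families: list[HeptadFamily] = []
    locations: dict[str, GeneLocation] = {}
    chrom_offset: dict[str, int] = {}

    def place(gene: str, chrom: str) -> None:
        start = chrom_offset.get(chrom, 0)
        locations[gene] = GeneLocation(
            chromosome=chrom, start=start, end=start + 1000, strand="+"
        )
        chrom_offset[chrom] = start + 10_000

    def evolve(seq, t):
        return _evolve_branch(seq, t, rng, omega, kappa)

    for i in range(n_families):
        fam = f"fam{i:04d}"
        is_noisy = rng.random() < topology_noise
        genes = {
            "zeb": f"{fam}_zeb",
            "pg": f"{fam}_pg",
            "pt": f"{fam}_pt",
            "cc1": f"{fam}_cc1",
            "cc2": f"{fam}_cc2",
            "gf1": f"{fam}_gf1",
            "gf2": f"{fam}_gf2",
        }
        # which tetraploid copy is the B copy is random per family
        cc_b, cc_a = ("cc1", "cc2") if rng.random() < 0.5 else ("cc2", "cc1")
        gf_b, gf_a = ("gf1", "gf2") if rng.random() < 0.5 else ("gf2", "gf1")

        root = _random_codon_sequence(n_codons, rng)
        zeb_seq = evolve(root, depths["zeb"])
        n1 = evolve(root, depths["zeb"] - depths["pg"])
        pg_seq = evolve(n1, depths["pg"])
        n2 = evolve(n1, depths["pg"] - depths["ab"])
        n3 = evolve(n2, depths["ab"] - depths["ptb"])
        pt_seq = evolve(n3, depths["ptb"])
        n4 = evolve(n3, depths["ptb"] - depths["b"])
        n5 = evolve(n2, depths["ab"] - depths["a"])
        if not is_noisy:
            seqs_by_role = {
                "zeb": zeb_seq,
                "pg": pg_seq,
                "pt": pt_seq,
                cc_b: evolve(n4, depths["b"]),
                gf_b: evolve(n4, depths["b"]),
                cc_a: evolve(n5, depths["a"]),
                gf_a: evolve(n5, depths["a"]),
            }
            tree = (
                f"(zebrafish|{genes['zeb']}:{depths['zeb']:.4f},"
                f"(pguichenoti|{genes['pg']}:{depths['pg']:.4f},"
                f"((ptetrazona|{genes['pt']}:{depths['ptb']:.4f},"
                f"(carp|{genes[cc_b]}:{depths['b']:.4f},"
                f"goldfish|{genes[gf_b]}:{depths['b']:.4f})"
                f"100:{depths['ptb'] - depths['b']:.4f})"
                f"100:{depths['ab'] - depths['ptb']:.4f},"
                f"(carp|{genes[cc_a]}:{depths['a']:.4f},"
                f"goldfish|{genes[gf_a]}:{depths['a']:.4f})"
                f"100:{depths['ab'] - depths['a']:.4f})"
                f"100:{depths['pg'] - depths['ab']:.4f})"
                f"100:{depths['zeb'] - depths['pg']:.4f});"
            )
            truth.subgenome_labels[genes[cc_b]] = "subB"
            truth.subgenome_labels[genes[gf_b]] = "subB"
            truth.subgenome_labels[genes[cc_a]] = "subA"
            truth.subgenome_labels[genes[gf_a]] = "subA"
        else:
            # non-canonical shape: carp copies sister inside the Pt clade,
            # goldfish copies sister outside it
            seqs_by_role = {
                "zeb": zeb_seq,
                "pg": pg_seq,
                "pt": pt_seq,
                "cc1": evolve(n4, depths["b"]),
                "cc2": evolve(n4, depths["b"]),
                "gf1": evolve(n5, depths["a"]),
                "gf2": evolve(n5, depths["a"]),
            }
            tree = (
                f"(zebrafish|{genes['zeb']}:{depths['zeb']:.4f},"
                f"(pguichenoti|{genes['pg']}:{depths['pg']:.4f},"
                f"((ptetrazona|{genes['pt']}:{depths['ptb']:.4f},"
                f"(carp|{genes['cc1']}:{depths['b']:.4f},"
                f"carp|{genes['cc2']}:{depths['b']:.4f})"
                f"100:{depths['ptb'] - depths['b']:.4f})"
                f"100:{depths['ab'] - depths['ptb']:.4f},"
                f"(goldfish|{genes['gf1']}:{depths['a']:.4f},"
                f"goldfish|{genes['gf2']}:{depths['a']:.4f})"
                f"100:{depths['ab'] - depths['a']:.4f})"
                f"100:{depths['pg'] - depths['ab']:.4f})"
                f"100:{depths['zeb'] - depths['pg']:.4f});"
            )
            truth.noisy_families.append(fam)

        species_of = {
            "zeb": "zebrafish", "pg": "pguichenoti", "pt": "ptetrazona",
            "cc1": "carp", "cc2": "carp", "gf1": "goldfish", "gf2": "goldfish",
        }
        sequences = {
            f"{species_of[role]}|{genes[role]}": "".join(seq)
            for role, seq in seqs_by_role.items()
        }
        families.append(
            HeptadFamily(
                family_id=fam, sequences=sequences, tree_newick=tree,
                is_noisy=is_noisy,
            )
        )

        # locations: each family sits on one homoeologous chromosome pair
        j = int(rng.integers(1, CARP_CHROM_COUNT + 1))
        home = {
            genes["zeb"]: f"dre{j:02d}",
            genes["pg"]: f"pgu{j:02d}",
            genes["pt"]: f"pte{j:02d}",
            genes[cc_a]: f"cc{j:02d}",
            genes[cc_b]: f"cc{j + CARP_CHROM_COUNT:02d}",
            genes[gf_a]: f"gf{j:02d}",
            genes[gf_b]: f"gf{j + CARP_CHROM_COUNT:02d}",
        }
        if (not is_noisy) and rng.random() < he_rate:
            moved_role = [cc_a, cc_b, gf_a, gf_b][int(rng.integers(0, 4))]
            gene = genes[moved_role]
            chrom = home[gene]
            prefix, num = chrom[:2], int(chrom[2:])
            partner = (
                num + CARP_CHROM_COUNT
                if num <= CARP_CHROM_COUNT
                else num - CARP_CHROM_COUNT
            )
            home[gene] = f"{prefix}{partner:02d}"
            truth.he_genes.append(gene)
        for gene, chrom in home.items():
            place(gene, chrom)

    return HeptadDataset(families=families, locations=locations, truth=truth)


# ---------------------------------------------------------------------------
# Expression panels
# ---------------------------------------------------------------------------

NINE_TISSUES = (
    "brain", "gill", "heart", "intestine", "kidney",
    "liver", "muscle", "skin", "spleen",
)


@dataclass
class ExpressionDataset:
    subA: pd.DataFrame      # pairs x contexts TPM for the subA homoeologues
    subB: pd.DataFrame
    outgroup: pd.DataFrame  # diploid outgroup orthologue TPM
    pairs: pd.DataFrame     # pair_id, subA_gene, subB_gene, outgroup_gene
    truth: SimulationTruth


def simulate_expression_panel(
    n_pairs: int,
    n_tissues: int = 9,
    dominance_bias: float = 0.55,
    conserved_fraction: float = 0.7,
    seed: int = 0,
    noise_sd: float = 0.15,
    dominance_boost: float = 2.0,
    n_archetypes: int = 8,
) -> ExpressionDataset:
    """Simulate TPM panels for homoeolog pairs plus outgroup orthologues.

    Each pair draws a tissue archetype (a log2 expression pattern); conserved
    pairs track the outgroup profile (Pearson r > 0.66 in expectation) while
    diverged pairs swap one homoeologue onto a different archetype. The subB
    copy of a pair is made dominant (uniformly boosted ``dominance_boost``-
    fold) with probability ``dominance_bias``, subA otherwise.
    """
    if not 0.0 <= dominance_bias <= 1.0:
        raise ValueError("dominance_bias must be in [0, 1]")
    if n_tissues < 3:
        raise ValueError("need at least 3 tissues/conditions")
    rng = np.random.default_rng(seed)
    contexts = (
        list(NINE_TISSUES) if n_tissues == 9
        else [f"context{i + 1}" for i in range(n_tissues)]
    )
    archetypes = np.full((n_archetypes, n_tissues), 3.0)
    for j in range(n_archetypes):
        archetypes[j, j % n_tissues] += 4.0

    truth = SimulationTruth(
        seed=seed,
        dominance_bias=dominance_bias,
        params={
            "n_pairs": n_pairs,
            "n_tissues": n_tissues,
            "conserved_fraction": conserved_fraction,
            "noise_sd": noise_sd,
            "dominance_boost": dominance_boost,
            "n_archetypes": n_archetypes,
        },
    )
    rows_a, rows_b, rows_og, pair_rows = [], [], [], []
    boost = math.log2(dominance_boost)
    for i in range(n_pairs):
        pid = f"pair{i:04d}"
        g = int(rng.integers(0, n_archetypes))
        magnitude = rng.normal(0.0, 0.5)
        base = archetypes[g] + magnitude
        og_log = base + rng.normal(0.0, noise_sd, n_tissues)
        a_log = base + rng.normal(0.0, noise_sd, n_tissues)
        b_log = base + rng.normal(0.0, noise_sd, n_tissues)
        gene_a, gene_b, gene_og = f"{pid}_A", f"{pid}_B", f"{pid}_og"
        truth.archetype_of[gene_a] = g
        truth.archetype_of[gene_b] = g
        conserved = rng.random() < conserved_fraction
        if conserved:
            truth.conserved_genes.extend([gene_a, gene_b])
        else:
            g2 = int((g + 1 + rng.integers(0, n_archetypes - 1)) % n_archetypes)
            diverged_is_a = rng.random() < 0.5
            div_log = archetypes[g2] + magnitude + rng.normal(0.0, noise_sd, n_tissues)
            if diverged_is_a:
                a_log = div_log
                truth.conserved_genes.append(gene_b)
                truth.archetype_of[gene_a] = g2
            else:
                b_log = div_log
                truth.conserved_genes.append(gene_a)
                truth.archetype_of[gene_b] = g2
            truth.divergent_pairs.append(pid)
        dom_b = rng.random() < dominance_bias
        if dom_b:
            b_log = b_log + boost
        else:
            a_log = a_log + boost
        truth.dominant_subgenome[pid] = "subB" if dom_b else "subA"
        rows_a.append(2.0 ** a_log)
        rows_b.append(2.0 ** b_log)
        rows_og.append(2.0 ** og_log)
        pair_rows.append((pid, gene_a, gene_b, gene_og))

    pairs = pd.DataFrame(
        pair_rows, columns=["pair_id", "subA_gene", "subB_gene", "outgroup_gene"]
    ).set_index("pair_id")
    subA = pd.DataFrame(rows_a, index=pairs["subA_gene"].tolist(), columns=contexts)
    subB = pd.DataFrame(rows_b, index=pairs["subB_gene"].tolist(), columns=contexts)
    outgroup = pd.DataFrame(
        rows_og, index=pairs["outgroup_gene"].tolist(), columns=contexts
    )
    return ExpressionDataset(
        subA=subA, subB=subB, outgroup=outgroup, pairs=pairs, truth=truth
    )


# ---------------------------------------------------------------------------
# Seven-genome alignment blocks
# ---------------------------------------------------------------------------

GENOMES7 = (
    "zebrafish", "pguichenoti", "ptetrazona",
    "carpA", "carpB", "goldfishA", "goldfishB",
)

AR_MIN_LENGTH = 1000
AR_MIN_SUPPORT = 4


@dataclass
class BlockDataset:
    maf_text: str
    homoeolog_map: dict[str, str]  # chromosome -> ancestral chromosome
    truth: SimulationTruth

    def blocks(self):
        return read_maf_blocks(self.maf_text)


def simulate_alignment_blocks(
    n_ancestral_chromosomes: int = 25,
    n_blocks: int = 300,
    transloc_rate: float = 0.0,
    inversion_rate: float = 0.0,
    seed: int = 0,
    min_length: int = 500,
    max_length: int = 5000,
) -> BlockDataset:
    """Simulate seven-genome MAF blocks with planted rearrangements.

    Each block descends from one ancestral chromosome; every genome row is
    independently translocated (moved to a chromosome mapping to a different
    ancestral chromosome) with probability ``transloc_rate`` and inverted
    (strand flipped) with probability ``inversion_rate``. Block lengths are
    uniform on [``min_length``, ``max_length``], deliberately straddling the
    1-kb ancestral-region cutoff.
    """
    for name, rate in (("transloc_rate", transloc_rate), ("inversion_rate", inversion_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_ancestral_chromosomes < 2 and transloc_rate > 0:
        raise ValueError("translocations need at least 2 ancestral chromosomes")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(
        seed=seed,
        params={
            "n_ancestral_chromosomes": n_ancestral_chromosomes,
            "n_blocks": n_blocks,
            "transloc_rate": transloc_rate,
            "inversion_rate": inversion_rate,
        },
    )
    homoeolog_map = {
        f"{genome}_chr{c:02d}": f"anc{c:02d}"
        for genome in GENOMES7
        for c in range(1, n_ancestral_chromosomes + 1)
    }
    src_size = 50_000_000
    offsets: dict[str, int] = {}
    bases = np.array(list("ACGT"))
    maf_blocks = []
    for i in range(n_blocks):
        block_id = f"block{i}"
        anc = int(rng.integers(1, n_ancestral_chromosomes + 1))
        length = int(rng.integers(min_length, max_length + 1))
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        truth.block_ancestral[block_id] = f"anc{anc:02d}"
        rows = []
        n_agree = 0
        for genome in GENOMES7:
            c = anc
            if rng.random() < transloc_rate:
                c = int(rng.integers(1, n_ancestral_chromosomes + 1))
                while c == anc:
                    c = int(rng.integers(1, n_ancestral_chromosomes + 1))
                truth.translocated_rows.append((block_id, genome))
            else:
                n_agree += 1
            strand = "+"
            if rng.random() < inversion_rate:
                strand = "-"
                truth.inverted_rows.append((block_id, genome))
            chrom = f"{genome}_chr{c:02d}"
            start = offsets.get(chrom, 0)
            offsets[chrom] = start + length + 100
            rows.append(
                (f"{genome}.{chrom}", start, start + length, strand, src_size, seq)
            )
        if length > AR_MIN_LENGTH and n_agree >= AR_MIN_SUPPORT:
            truth.ar_eligible_blocks.append(block_id)
        maf_blocks.append((block_id, rows))
    return BlockDataset(
        maf_text=write_maf_blocks(maf_blocks),
        homoeolog_map=homoeolog_map,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Two-population genotypes with planted sweeps
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    vcf_text: str
    populations: dict[str, str]  # sample -> {pop1, pop2}
    truth: SimulationTruth

    def genotype_matrix(self) -> GenotypeMatrix:
        gm = read_vcf_minimal(self.vcf_text)
        gm.population_of = dict(self.populations)
        return gm


def _sfs_frequencies(
    n_sites: int, n_hap: int, rng: np.random.Generator
) -> np.ndarray:
    """Derived-allele frequencies drawn from the neutral 1/i site-frequency spectrum."""
    i = np.arange(1, n_hap)
    w = 1.0 / i
    counts = rng.choice(i, size=n_sites, p=w / w.sum())
    return counts / n_hap


def simulate_two_population_genotypes(
    n_samples_per_pop: int = 20,
    chrom_length: int = 10_000_000,
    n_sweep_windows: int = 5,
    pi_background: float = 2e-3,
    pi_sweep: float = 5e-4,
    fst_sweep: float = 0.4,
    seed: int = 0,
    window_size: int = 100_000,
    missing_rate: float = 0.0,
) -> GenotypeDataset:
    """Simulate two-population diploid genotypes with planted sweep windows.

    Neutral windows draw sites from the neutral frequency spectrum at
    density matching ``pi_background`` with both populations sampling the
    same frequency (Fst ~ 0). Sweep windows perturb population 1 (the
    focal, domesticated-like strain) by a Balding–Nichols draw with
    ``F = max(fst_sweep, 1 - pi_sweep/pi_background)``, which reduces its
    expected diversity to ``pi_sweep`` and elevates differentiation.
    """
    if not pi_sweep < pi_background:
        raise ValueError("pi_sweep must be below pi_background")
    if not 0.0 < fst_sweep < 1.0:
        raise ValueError("fst_sweep must be in (0, 1)")
    if chrom_length < window_size:
        raise ValueError("chrom_length shorter than one window")
    rng = np.random.default_rng(seed)
    n_windows = chrom_length // window_size
    if n_sweep_windows > n_windows:
        raise ValueError("more sweep windows than windows")
    sweep_ids = sorted(
        int(w) for w in rng.choice(n_windows, size=n_sweep_windows, replace=False)
    )
    f_w = max(fst_sweep, 1.0 - pi_sweep / pi_background)
    n_hap = 4 * n_samples_per_pop
    a_n = float(np.sum(1.0 / np.arange(1, n_hap)))
    samples = [f"pop1_{i:02d}" for i in range(n_samples_per_pop)] + [
        f"pop2_{i:02d}" for i in range(n_samples_per_pop)
    ]
    populations = {
        s: ("pop1" if s.startswith("pop1") else "pop2") for s in samples
    }
    truth = SimulationTruth(
        seed=seed,
        sweep_window_ids=sweep_ids,
        params={
            "n_samples_per_pop": n_samples_per_pop,
            "chrom_length": chrom_length,
            "window_size": window_size,
            "pi_background": pi_background,
            "pi_sweep": pi_sweep,
            "fst_sweep": fst_sweep,
            "balding_nichols_F": f_w,
            "n_windows": n_windows,
        },
    )
    gt_str = np.array(["0/0", "0/1", "1/1"])
    ref_alt = [("A", "T"), ("C", "G"), ("G", "A"), ("T", "C")]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=chr1,length={chrom_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for w in range(n_windows):
        w_start = w * window_size
        n_sites = rng.poisson(pi_background * a_n * window_size)
        if n_sites == 0:
            continue
        positions = np.sort(
            rng.choice(window_size, size=min(n_sites, window_size), replace=False)
        )
        p = _sfs_frequencies(len(positions), n_hap, rng)
        if w in sweep_ids:
            alpha = p * (1.0 - f_w) / f_w
            beta = (1.0 - p) * (1.0 - f_w) / f_w
            p1 = rng.beta(alpha, beta)
        else:
            p1 = p
        p2 = p
        d1 = rng.binomial(2, p1[:, None], size=(len(positions), n_samples_per_pop))
        d2 = rng.binomial(2, p2[:, None], size=(len(positions), n_samples_per_pop))
        dosage = np.hstack([d1, d2])
        gts = gt_str[dosage]
        if missing_rate > 0:
            miss = rng.random(dosage.shape) < missing_rate
            gts = np.where(miss, "./.", gts)
        for k, pos in enumerate(positions):
            ref, alt = ref_alt[int(rng.integers(0, 4))]
            lines.append(
                f"chr1\t{w_start + int(pos) + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts[k])
            )
    return GenotypeDataset(
        vcf_text="\n".join(lines) + "\n", populations=populations, truth=truth
    )
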