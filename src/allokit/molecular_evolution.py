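"""Pairwise Ka/Ks estimation, Ks-mode estimation and molecular-clock dating.

The Ka/Ks estimator is Nei–Gojobori (1986) style: synonymous site fractions
are counted over the three single-nucleotide neighbours of each codon
position, observed differences are averaged over all minimal mutational
pathways between the two codons (pathways through stop codons are skipped),
and the Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3) is applied to the
per-site proportions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats

NUCLEOTIDES = "ACGT"

# standard genetic code (NCBI table 1, via biopython)
from Bio.Data.CodonTable import standard_dna_table as _TABLE

GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
for _stop in STOP_CODONS:
    GENETIC_CODE[_stop] = "*"


class KaKsError(ValueError):
    """Raised on alignments that violate the codon-alignment contract."""


@lru_cache(maxsize=None)
def synonymous_site_count(codon: str) -> float:
    """NG86 synonymous site count of one codon.

    Each position contributes the fraction of its three single-nucleotide
    neighbours that encode the same amino acid; changes to stop codons count
    as nonsynonymous, so every position carries total weight 1 and
    S + N = 3 per codon.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1:]
            if neighbour not in STOP_CODONS and GENETIC_CODE[neighbour] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons.

    All minimal mutational pathways (orderings of the differing positions)
    are weighted equally; pathways passing through a stop codon are skipped.
    If every pathway is blocked by stop codons, all pathways are used.
    """
    diff_positions = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathways: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_positions):
        sd = nd = 0
        current = codon1
        ok = True
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
            if (
                current not in STOP_CODONS
                and nxt not in STOP_CODONS
                and GENETIC_CODE[current] == GENETIC_CODE[nxt]
            ):
                sd += 1
            else:
                nd += 1
            current = nxt
        (pathways if ok else blocked).append((sd, nd))
    use = pathways if pathways else blocked
    sd_avg = sum(p[0] for p in use) / len(use)
    nd_avg = sum(p[1] for p in use) / len(use)
    return sd_avg, nd_avg


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    ka: Optional[float]
    ks: Optional[float]
    ratio: Optional[float]  # None when Ks undefined or zero
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    n_codons: int


def _codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def compute_kaks(seq1: str, seq2: str) -> KaKsResult:
    """NG86 Ka/Ks for a pairwise codon alignment.

    Sequences must have equal lengths divisible by 3 with no internal stop
    codons; codons containing gaps or ambiguous bases are dropped pairwise.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise KaKsError("aligned sequences differ in length")
    if len(seq1) % 3 != 0:
        raise KaKsError("alignment length not divisible by 3")
    s1 = s2 = 0.0
    sd = nd = 0.0
    kept = 0
    for c1, c2 in zip(_codons(seq1), _codons(seq2)):
        if not (set(c1) <= set(NUCLEOTIDES) and set(c2) <= set(NUCLEOTIDES)):
            continue  # gap- or N-containing codon: dropped pairwise
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise KaKsError("internal stop codon in alignment")
        kept += 1
        s1 += synonymous_site_count(c1)
        s2 += synonymous_site_count(c2)
        d_s, d_n = pathway_differences(c1, c2)
        sd += d_s
        nd += d_n
    if kept == 0:
        raise KaKsError("no analysable codons in alignment")
    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * kept - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if ka is None or ks is None or ks == 0.0:
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(
        ka=ka, ks=ks, ratio=ratio,
        s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd, n_codons=kept,
    )


# ---------------------------------------------------------------------------
# Ks distributions and dating
# ---------------------------------------------------------------------------

MIN_KS_VALUES = 30


@dataclass
class KsDistribution:
    values: np.ndarray
    mode: float
    bandwidth: float
    peaks: list[float] = field(default_factory=list)  # all local density maxima
    grid: np.ndarray = field(default_factory=lambda: np.empty(0))
    density: np.ndarray = field(default_factory=lambda: np.empty(0))


def estimate_ks_mode(
    values: Sequence[float], bandwidth: Optional[float] = None
) -> KsDistribution:
    """Gaussian-KDE mode of a Ks distribution on a 512-point grid over [0, max].

    ``bandwidth`` is an absolute kernel standard deviation; the default is
    Silverman's rule. At least 30 finite values are required (the mode is
    unstable below that).
    """
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if arr.size < MIN_KS_VALUES:
        raise ValueError(f"need >= {MIN_KS_VALUES} finite Ks values, got {arr.size}")
    std = arr.std(ddof=1)
    if bandwidth is None:
        kde = stats.gaussian_kde(arr, bw_method="silverman")
    else:
        if std == 0:
            std = 1.0
        kde = stats.gaussian_kde(arr, bw_method=bandwidth / std)
    bw = float(kde.factor * std)
    grid = np.linspace(0.0, float(arr.max()), 512)
    density = kde(grid)
    mode = float(grid[int(np.argmax(density))])
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] > density[2:])
    peaks = [float(g) for g in grid[1:-1][interior]]
    if not peaks:
        peaks = [mode]
    return KsDistribution(
        values=arr, mode=mode, bandwidth=bw, peaks=peaks, grid=grid, density=density
    )


@dataclass(frozen=True)
class ClockDate:
    ks_mode: float
    rate: float  # substitutions per synonymous site per year
    time_ma: float  # million years, exact

    @property
    def time_ma_1dp(self) -> float:
        from .io_formats import round_half_up

        return round_half_up(self.time_ma, 1)


#: synonymous molecular clock used for cyprinid divergence dating
DEFAULT_CLOCK_RATE = 3.51e-9


def ks_to_divergence_time(ks_mode: float, rate: float = DEFAULT_CLOCK_RATE) -> ClockDate:
    """Convert a Ks mode to a divergence time in Ma: T = Ks / (2 r) / 1e6.

    The factor 2 accounts for substitutions accumulating on both lineages.
    """
    if rate <= 0:
        raise ValueError("clock rate must be positive")
    if ks_mode < 0:
        raise ValueError("ks_mode must be non-negative")
    return ClockDate(ks_mode=ks_mode, rate=rate, time_ma=ks_mode / (2.0 * rate) / 1e6)


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------


def pairwise_identity(seq1: str, seq2: str, mode: str = "nucleotide") -> float:
    """Percent identity from a global alignment (matches / alignment columns)."""
    from Bio import Align

    if not seq1 or not seq2:
        raise ValueError("empty sequence")
    if mode not in ("nucleotide", "protein"):
        raise ValueError("mode must be 'nucleotide' or 'protein'")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if mode == "nucleotide":
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    else:
        from Bio.Align import substitution_matrices

        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    alignment = aligner.align(seq1.upper(), seq2.upper())[0]
    a, b = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * matches / len(a)


# ---------------------------------------------------------------------------
# Selection-symmetry comparison
# ---------------------------------------------------------------------------

EXACT_RANKSUM_MAX_N = 8


def compare_selection_symmetry(
    kaks_group_a: Sequence[Optional[float]],
    kaks_group_b: Sequence[Optional[float]],
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U comparison of two Ka/Ks ratio groups.

    Undefined ratios (None/NaN) are excluded; the exact null distribution is
    used when both groups have at most 8 values and no ties are present.
    """
    a = np.asarray([v for v in kaks_group_a if v is not None and np.isfinite(v)])
    b = np.asarray([v for v in kaks_group_b if v is not None and np.isfinite(v)])
    if a.size < 5 or b.size < 5:
        raise ValueError("each group needs >= 5 defined Ka/Ks ratios")
    if np.array_equal(np.sort(a), np.sort(b)):
        u = float(a.size * b.size / 2.0)
        return u, 1.0
    method = "exact" if (a.size <= EXACT_RANKSUM_MAX_N and b.size <= EXACT_RANKSUM_MAX_N) else "asymptotic"
    if method == "exact" and (np.unique(np.concatenate([a, b])).size < a.size + b.size):
        method = "asymptotic"  # ties: fall back to tie-corrected normal approximation
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
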