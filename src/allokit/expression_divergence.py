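"""Homoeolog expression divergence analysis for allo-tetraploid gene pairs.

Given TPM panels for the subA and subB homoeologues of each pair and, where
available, the diploid outgroup orthologue, this module computes per-tissue
expression dominance, conservation with the outgroup (Pearson r > 0.66 at
p <= 0.05 across shared tissues), pair-level divergence (top-decile
Euclidean distance or r < 0.66 on log2(TPM+1) profiles), average-linkage
expression clustering, functionalization classes (coexpressed / non-F /
sub-F / neo-F), cotranscription rates, pseudo-ancestral dosage, the
Ka/Ks-vs-divergence trend, differential-expression balance and
trans-splicing partner classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io_formats import GeneLocation, round_half_up
from .subgenome_assignment import ChromosomeAssignment

logger = logging.getLogger("allokit")

#: Pearson correlation threshold for expression conservation; at n = 9
#: contexts r = 0.666 is the two-sided 5% critical value, so the paired
#: thresholds (r > 0.66, p <= 0.05) are mutually consistent.
CONSERVATION_R = 0.66
CONSERVATION_P = 0.05
DIVERGENCE_DISTANCE_QUANTILE = 0.90

DEFAULT_EXPRESSION_FLOOR = 1.0  # TPM


@dataclass
class ExpressionPanel:
    """TPM matrices for homoeolog pairs and (optionally) outgroup orthologues.

    ``pairs`` is indexed by pair id with columns ``subA_gene``, ``subB_gene``
    and optionally ``outgroup_gene``; the gene ids index the rows of the
    matching TPM matrices, whose context columns must agree.
    """

    subA: pd.DataFrame
    subB: pd.DataFrame
    pairs: pd.DataFrame
    outgroup: Optional[pd.DataFrame] = None
    floor: float = DEFAULT_EXPRESSION_FLOOR

    def __post_init__(self) -> None:
        if list(self.subA.columns) != list(self.subB.columns):
            raise ValueError("subA and subB context columns differ")
        if self.outgroup is not None and list(self.outgroup.columns) != list(
            self.subA.columns
        ):
            raise ValueError("outgroup context columns differ")
        missing_a = set(self.pairs["subA_gene"]) - set(self.subA.index)
        missing_b = set(self.pairs["subB_gene"]) - set(self.subB.index)
        if missing_a or missing_b:
            raise ValueError("pair table references genes absent from the matrices")

    @property
    def contexts(self) -> list[str]:
        return list(self.subA.columns)

    def pair_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        a = self.subA.loc[self.pairs["subA_gene"]].to_numpy(float)
        b = self.subB.loc[self.pairs["subB_gene"]].to_numpy(float)
        return a, b

    def outgroup_array(self) -> np.ndarray:
        if self.outgroup is None or "outgroup_gene" not in self.pairs.columns:
            raise ValueError("panel has no outgroup orthologues")
        return self.outgroup.loc[self.pairs["outgroup_gene"]].to_numpy(float)


def _log2p1(x: np.ndarray) -> np.ndarray:
    return np.log2(x + 1.0)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p (t transform, n-2 df); NaN on zero variance."""
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Dominance
# ---------------------------------------------------------------------------


def dominance_analysis(panel: ExpressionPanel) -> pd.DataFrame:
    """Per-context homoeolog dominance counts with a χ² test against 50:50.

    A pair counts toward subA (subB) in a context when the subA (subB) TPM
    is strictly higher; equal values are ties. Pairs with both homoeologues
    below the expression floor in a context are excluded there.
    """
    a, b = panel.pair_arrays()
    rows = []
    for j, context in enumerate(panel.contexts):
        expressed = (a[:, j] >= panel.floor) | (b[:, j] >= panel.floor)
        n_a = int(np.sum(expressed & (a[:, j] > b[:, j])))
        n_b = int(np.sum(expressed & (b[:, j] > a[:, j])))
        n_tie = int(np.sum(expressed & (a[:, j] == b[:, j])))
        n_excluded = int(np.sum(~expressed))
        if n_a + n_b > 0:
            chi2, p = stats.chisquare([n_a, n_b])
            chi2, p = float(chi2), float(p)
        else:
            chi2, p = float("nan"), float("nan")
        rows.append((context, n_a, n_b, n_tie, n_excluded, chi2, p))
    return pd.DataFrame(
        rows,
        columns=[
            "context", "subA_dominant", "subB_dominant", "ties",
            "excluded", "chi2", "p_value",
        ],
    ).set_index("context")


def pair_dominance(panel: ExpressionPanel) -> pd.DataFrame:
    """Per-pair dominance: which homoeologue wins the majority of contexts.

    Complements :func:`dominance_analysis` (per-context counts) with the
    pair-level call used to estimate a subgenome-wide dominance bias.
    """
    a, b = panel.pair_arrays()
    wins_a = (a > b).sum(axis=1)
    wins_b = (b > a).sum(axis=1)
    dominant = np.where(
        wins_b > wins_a, "subB", np.where(wins_a > wins_b, "subA", "tie")
    )
    return pd.DataFrame(
        {"wins_subA": wins_a, "wins_subB": wins_b, "dominant": dominant},
        index=panel.pairs.index,
    )


# ---------------------------------------------------------------------------
# Conservation and divergence
# ---------------------------------------------------------------------------


def conservation_and_divergence(panel: ExpressionPanel) -> pd.DataFrame:
    """Per-pair conservation (vs outgroup) and divergence (between homoeologues).

    A homoeologue is conserved when its Pearson correlation with the
    outgroup orthologue exceeds 0.66 at p <= 0.05; a pair is divergent when
    its homoeolog-homoeolog Euclidean distance (log2(TPM+1) profiles)
    reaches the top decile across pairs, or the homoeolog correlation is
    below 0.66. Constant (zero-variance) profiles have undefined
    correlation and are classified diverged with a flag.
    """
    if len(panel.contexts) < 3:
        raise ValueError("need at least 3 contexts")
    a, b = panel.pair_arrays()
    la, lb = _log2p1(a), _log2p1(b)
    has_outgroup = panel.outgroup is not None and "outgroup_gene" in panel.pairs.columns
    log = None
    if has_outgroup:
        log = _log2p1(panel.outgroup_array())
    records = []
    distances = np.linalg.norm(la - lb, axis=1)
    threshold = float(np.quantile(distances, DIVERGENCE_DISTANCE_QUANTILE))
    for i, pair_id in enumerate(panel.pairs.index):
        r_pair, _ = _pearson(la[i], lb[i])
        undefined = math.isnan(r_pair)
        divergent = undefined or distances[i] >= threshold or r_pair < CONSERVATION_R
        rec = {
            "pair_id": pair_id,
            "euclidean_distance": float(distances[i]),
            "correlation": r_pair,
            "divergent": bool(divergent),
            "correlation_undefined": undefined,
        }
        if has_outgroup:
            for tag, profile in (("subA", la[i]), ("subB", lb[i])):
                r, p = _pearson(profile, log[i])
                rec[f"r_{tag}_outgroup"] = r
                rec[f"conserved_{tag}"] = bool(
                    (not math.isnan(r)) and r > CONSERVATION_R and p <= CONSERVATION_P
                )
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("pair_id")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_profiles(
    matrix: pd.DataFrame, k: int, log_transform: bool = True
) -> pd.Series:
    """Average-linkage agglomerative clustering cut to exactly k clusters.

    Distances are Euclidean on log2(TPM+1) profiles (``log_transform=False``
    for raw counts such as alternative-splicing numbers). Deterministic.
    """
    if k > len(matrix):
        raise ValueError("k exceeds the number of rows")
    data = matrix.to_numpy(float)
    if log_transform:
        data = _log2p1(data)
    link = hierarchy.linkage(data, method="average", metric="euclidean")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="cluster")


# ---------------------------------------------------------------------------
# Functionalization
# ---------------------------------------------------------------------------

FUNCTIONAL_CLASSES = ("non-F", "neo-F", "sub-F", "coexpressed")


def classify_functionalization(
    panel: ExpressionPanel,
    clusters: pd.Series,
    conservation: pd.DataFrame,
) -> pd.Series:
    """Assign each pair exactly one functional class.

    Precedence: (1) *non-F* when one homoeologue stays below the expression
    floor in every context; (2) *neo-F* when exactly one homoeologue is
    conserved with the outgroup and the two sit in different clusters;
    (3) *sub-F* when neither is conserved but the summed (pseudo-ancestral)
    profile is conserved with the outgroup; (4) *coexpressed* when both sit
    in the same cluster; (5) otherwise *neo-F*. Without outgroup data the
    pair is *unclassifiable*.
    """
    a, b = panel.pair_arrays()
    has_outgroup = panel.outgroup is not None and "outgroup_gene" in panel.pairs.columns
    log = _log2p1(panel.outgroup_array()) if has_outgroup else None
    lsum = _log2p1(a + b)
    out = {}
    for i, pair_id in enumerate(panel.pairs.index):
        gene_a = panel.pairs.iloc[i]["subA_gene"]
        gene_b = panel.pairs.iloc[i]["subB_gene"]
        silent_a = bool(np.all(a[i] < panel.floor))
        silent_b = bool(np.all(b[i] < panel.floor))
        if silent_a or silent_b:
            out[pair_id] = "non-F"
            continue
        if not has_outgroup:
            out[pair_id] = "unclassifiable"
            continue
        cons_a = bool(conservation.loc[pair_id, "conserved_subA"])
        cons_b = bool(conservation.loc[pair_id, "conserved_subB"])
        same_cluster = clusters.loc[gene_a] == clusters.loc[gene_b]
        if (cons_a != cons_b) and not same_cluster:
            out[pair_id] = "neo-F"
            continue
        if not cons_a and not cons_b:
            r, p = _pearson(lsum[i], log[i])
            if (not math.isnan(r)) and r > CONSERVATION_R and p <= CONSERVATION_P:
                out[pair_id] = "sub-F"
                continue
        out[pair_id] = "coexpressed" if same_cluster else "neo-F"
    return pd.Series(out, name="functional_class")


# ---------------------------------------------------------------------------
# Cotranscription and dosage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CotranscriptionSummary:
    n_pairs: int
    n_all_contexts: int
    percent_all_contexts: float
    n_at_least: int
    percent_at_least: float
    min_contexts: int


def cotranscription_summary(
    panel: ExpressionPanel, min_contexts: int = 3
) -> CotranscriptionSummary:
    """Count pairs with both homoeologues expressed (TPM >= floor).

    Reports pairs cotranscribed in every context and in at least
    ``min_contexts`` contexts, with percentages at 1-decimal precision.
    """
    a, b = panel.pair_arrays()
    both = (a >= panel.floor) & (b >= panel.floor)
    per_pair = both.sum(axis=1)
    n = len(panel.pairs)
    n_all = int(np.sum(per_pair == len(panel.contexts)))
    n_min = int(np.sum(per_pair >= min_contexts))
    return CotranscriptionSummary(
        n_pairs=n,
        n_all_contexts=n_all,
        percent_all_contexts=percent(n_all, n),
        n_at_least=n_min,
        percent_at_least=percent(n_min, n),
        min_contexts=min_contexts,
    )


def percent(numerator: int, denominator: int) -> float:
    """Percentage at 1-decimal, half-up — the printed-table convention."""
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * numerator / denominator, 1)


def pseudo_ancestral_dosage(panel: ExpressionPanel) -> pd.DataFrame:
    """Compare summed homoeologue TPM (pseudo-ancestral gene) with the
    diploid orthologue, per context.

    Returns per-context mean/median of (subA + subB − orthologue) and a
    Wilcoxon signed-rank p; all-zero differences give p = 1.
    """
    a, b = panel.pair_arrays()
    og = panel.outgroup_array()
    sums = a + b
    rows = []
    for j, context in enumerate(panel.contexts):
        diff = sums[:, j] - og[:, j]
        if np.allclose(diff, 0.0):
            p = 1.0
        else:
            try:
                _, p = stats.wilcoxon(diff[diff != 0.0])
                p = float(p)
            except ValueError:
                p = float("nan")
        rows.append((context, float(diff.mean()), float(np.median(diff)), p))
    return pd.DataFrame(
        rows, columns=["context", "mean_difference", "median_difference", "p_value"]
    ).set_index("context")


# ---------------------------------------------------------------------------
# Ka/Ks vs divergence trend
# ---------------------------------------------------------------------------


@dataclass
class KaksDivergenceTrend:
    bin_edges: list[float]
    divergent_fraction: list[float]
    n_per_bin: list[int]
    rho: float        # Spearman correlation of Ka/Ks bin index vs divergence
    p_value: float
    n_excluded: int   # pairs with undefined Ka/Ks


def kaks_divergence_trend(
    kaks_ratios: Sequence[Optional[float]],
    divergent_flags: Sequence[bool],
    n_bins: int = 5,
) -> KaksDivergenceTrend:
    """Divergent-pair fraction per Ka/Ks quantile bin with a rank trend test.

    Pairs with undefined ratios are excluded (and counted); bins are
    quantile-based so each holds roughly the same number of pairs.
    """
    ratios, flags = [], []
    n_excluded = 0
    for r, f in zip(kaks_ratios, divergent_flags):
        if r is None or not np.isfinite(r):
            n_excluded += 1
        else:
            ratios.append(float(r))
            flags.append(bool(f))
    if len(ratios) < n_bins * 10:
        raise ValueError(f"need at least {n_bins * 10} defined Ka/Ks ratios")
    ratios_arr = np.asarray(ratios)
    flags_arr = np.asarray(flags)
    binned = pd.qcut(ratios_arr, q=n_bins, labels=False, duplicates="drop")
    fractions, counts = [], []
    for b in range(int(binned.max()) + 1):
        mask = binned == b
        counts.append(int(mask.sum()))
        fractions.append(float(flags_arr[mask].mean()))
    edges = [float(x) for x in np.quantile(ratios_arr, np.linspace(0, 1, n_bins + 1))]
    if np.all(flags_arr) or not np.any(flags_arr):
        rho, p = 0.0, 1.0  # flat: no trend definable
    else:
        rho, p = stats.spearmanr(binned, flags_arr)
        rho, p = float(rho), float(p)
    return KaksDivergenceTrend(
        bin_edges=edges,
        divergent_fraction=fractions,
        n_per_bin=counts,
        rho=rho,
        p_value=p,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Differential-expression balance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DEGBalance:
    chi2: float
    p_value: float
    n_one_de: int       # pairs with exactly one DE homoeologue
    percent_one_de: float


def deg_balance_test(
    deg_flags_subA: Sequence[bool], deg_flags_subB: Sequence[bool]
) -> DEGBalance:
    """χ² test for equal differential-expression proportions by subgenome,
    plus the count of pairs with exactly one DE homoeologue."""
    a = np.asarray(deg_flags_subA, dtype=bool)
    b = np.asarray(deg_flags_subB, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors differ in length")
    table = np.array(
        [[a.sum(), (~a).sum()], [b.sum(), (~b).sum()]], dtype=float
    )
    if np.array_equal(table[0], table[1]):
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    n_one = int(np.sum(a ^ b))
    return DEGBalance(
        chi2=float(chi2),
        p_value=float(p),
        n_one_de=n_one,
        percent_one_de=percent(n_one, a.size),
    )


# ---------------------------------------------------------------------------
# Trans-splicing classification
# ---------------------------------------------------------------------------


@dataclass
class TransSplicingSummary:
    classes: dict[tuple[str, str], str]  # (gene5', gene3') -> class
    counts: dict[str, int]               # intra-A / intra-B / inter-subgenome
    n_scaffold_excluded: int
    n_unknown_skipped: int


def classify_trans_splicing(
    fusion_calls: Sequence[tuple[str, str]],
    assignments: Sequence[ChromosomeAssignment],
    locations: Mapping[str, GeneLocation],
) -> TransSplicingSummary:
    """Classify fusion-transcript (trans-splicing) partner pairs by subgenome.

    A call is *intra-A* or *intra-B* when both partners sit on chromosomes
    of one subgenome and *inter-subgenome* otherwise; scaffold-located
    partners are excluded with a count, unknown genes skipped and logged.
    """
    chrom_sub = {a.chromosome: a.subgenome for a in assignments}
    classes: dict[tuple[str, str], str] = {}
    counts = {"intra-A": 0, "intra-B": 0, "inter-subgenome": 0}
    n_scaffold = 0
    n_unknown = 0
    for gene5, gene3 in fusion_calls:
        locs = [locations.get(gene5), locations.get(gene3)]
        if any(l is None for l in locs):
            logger.warning("trans-splicing: unknown gene in (%s, %s)", gene5, gene3)
            n_unknown += 1
            continue
        if any(l.on_scaffold for l in locs):
            n_scaffold += 1
            continue
        subs = [chrom_sub.get(l.chromosome) for l in locs]
        if any(s is None for s in subs):
            logger.warning(
                "trans-splicing: unassigned chromosome in (%s, %s)", gene5, gene3
            )
            n_unknown += 1
            continue
        if subs[0] == subs[1]:
            cls = f"intra-{subs[0]}"
        else:
            cls = "inter-subgenome"
        classes[(gene5, gene3)] = cls
        counts[cls] += 1
    return TransSplicingSummary(
        classes=classes,
        counts=counts,
        n_scaffold_excluded=n_scaffold,
        n_unknown_skipped=n_unknown,
    )
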