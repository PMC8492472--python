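"""Windowed diversity statistics, Weir–Cockerham Fst, sweep calling and LD decay.

Statistics are computed per sliding window (100 kb with a 50-kb step by
default) from diploid genotype dosages: nucleotide diversity π, Watterson's
θw, Tajima's D, Fu & Li's D* and F* (the star variants, needing no
outgroup), the weighted Weir–Cockerham (1984) Fst between two populations,
its Z-transformation, joint top-quantile π-ratio/ZFst sweep calls and the
composite-LD r² decay curve with its half-maximum distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, round_half_up

DEFAULT_WINDOW = 100_000
DEFAULT_STEP = 50_000


# ---------------------------------------------------------------------------
# Per-site summaries
# ---------------------------------------------------------------------------


def _site_allele_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele counts and observed haplotype counts per site.

    ``dosages`` is (n_sites, n_samples) with -1 missing; sites use the
    observed allele number n at that site.
    """
    called = dosages >= 0
    n = 2 * called.sum(axis=1)
    alt = np.where(called, dosages, 0).sum(axis=1)
    return alt.astype(float), n.astype(float)


def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i**power))


# ---------------------------------------------------------------------------
# Neutrality-test constants
# ---------------------------------------------------------------------------


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return c1 / a1, c2 / (a1**2 + a2)


def _fu_li_constants(n: int) -> tuple[float, float, float, float]:
    """(u_D*, v_D*, u_F*, v_F*) after Fu & Li (1993) with the Simonsen
    et al. (1995) corrections to the F* variance."""
    a_n = _harmonic(n)
    b_n = _harmonic(n, 2)
    a_n1 = a_n + 1.0 / n  # a_{n+1}
    if n > 2:
        c_n = 2.0 * (n * a_n - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    else:
        c_n = 1.0
    d_n = (
        c_n
        + (n - 2) / ((n - 1) ** 2)
        + (2.0 / (n - 1)) * (1.5 - (2.0 * a_n1 - 3.0) / (n - 2) - 1.0 / n)
    )
    v_d = (
        (n / (n - 1.0)) ** 2 * b_n
        + a_n**2 * d_n
        - 2.0 * (n * a_n * (a_n + 1.0)) / ((n - 1.0) ** 2)
    ) / (a_n**2 + b_n)
    u_d = (n / (n - 1.0)) * (a_n - n / (n - 1.0)) - v_d
    v_f = (
        d_n
        + 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
        - (2.0 / (n - 1.0)) * (4.0 * b_n - 6.0 + 8.0 / n)
    ) / (a_n**2 + b_n)
    u_f = (
        (
            n / (n - 1.0)
            + (n + 1.0) / (3.0 * (n - 1.0))
            - 4.0 / (n * (n - 1.0))
            + 2.0 * (n + 1.0) / ((n - 1.0) ** 2) * (a_n1 - 2.0 * n / (n + 1.0))
        )
        / a_n
        - v_f
    )
    return u_d, v_d, u_f, v_f


# ---------------------------------------------------------------------------
# Windowed diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversityStats:
    chromosome: str
    start: int
    end: int
    n_segregating: int
    n_singletons: int
    pi: float        # per site
    theta_w: float   # per site
    tajima_d: Optional[float]
    fu_li_d_star: Optional[float]
    fu_li_f_star: Optional[float]
    partial_window: bool = False


def _window_grid(
    chrom_len: int, window_size: int, step: int
) -> Iterator[tuple[int, int, bool]]:
    start = 0
    while start < chrom_len:
        end = min(start + window_size, chrom_len)
        if end - start >= window_size / 2:
            yield start, end, (end - start) < window_size
        start += step


def window_diversity_stats(
    gm: GenotypeMatrix,
    population: Sequence[str] | str,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    chromosome_lengths: Optional[Mapping[str, int]] = None,
) -> list[DiversityStats]:
    """Windowed π, θw, Tajima's D and Fu & Li's D*/F* for one population.

    π sums the unbiased per-site heterozygosity 2c(n−c)/(n(n−1)) over sites
    (using the observed allele number n at each site) divided by the window
    length; θw = S/(a_n L). Windows with no segregating sites report
    π = θw = 0 with the D statistics missing. Terminal windows shorter than
    half the window size are dropped; retained partial windows are flagged.
    """
    samples = (
        gm.population_samples(population) if isinstance(population, str) else list(population)
    )
    if len(samples) < 4:
        raise ValueError("need at least 4 samples in the population")
    idx = gm.sample_indices(samples)
    dosages = gm.genotypes[:, idx]
    alt, n_obs = _site_allele_counts(dosages)
    positions = np.array([s.position for s in gm.sites])
    chroms = np.array([s.chromosome for s in gm.sites])

    out: list[DiversityStats] = []
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        pos_c, alt_c, n_c = positions[mask], alt[mask], n_obs[mask]
        chrom_len = (
            chromosome_lengths[chrom]
            if chromosome_lengths is not None
            else int(pos_c.max()) + 1
        )
        for start, end, partial in _window_grid(chrom_len, window_size, step):
            in_win = (pos_c >= start) & (pos_c < end)
            a, n = alt_c[in_win], n_c[in_win]
            usable = n >= 2
            a, n = a[usable], n[usable]
            seg = (a > 0) & (a < n)
            s_count = int(seg.sum())
            length = end - start
            if s_count == 0:
                out.append(
                    DiversityStats(
                        chromosome=str(chrom), start=start, end=end,
                        n_segregating=0, n_singletons=0, pi=0.0, theta_w=0.0,
                        tajima_d=None, fu_li_d_star=None, fu_li_f_star=None,
                        partial_window=partial,
                    )
                )
                continue
            a_seg, n_seg = a[seg], n[seg]
            het = 2.0 * a_seg * (n_seg - a_seg) / (n_seg * (n_seg - 1.0))
            pi_abs = float(het.sum())
            singletons = int(np.sum(np.minimum(a_seg, n_seg - a_seg) == 1.0))
            n_typ = int(np.median(n_seg))
            a1 = _harmonic(n_typ)
            theta_w = s_count / (a1 * length)
            e1, e2 = _tajima_constants(n_typ)
            denom = math.sqrt(e1 * s_count + e2 * s_count * (s_count - 1))
            tajima = (pi_abs - s_count / a1) / denom if denom > 0 else None
            u_d, v_d, u_f, v_f = _fu_li_constants(n_typ)
            denom_d = math.sqrt(u_d * s_count + v_d * s_count**2)
            d_star = (
                ((n_typ / (n_typ - 1.0)) * s_count - a1 * singletons) / denom_d
                if denom_d > 0
                else None
            )
            denom_f = math.sqrt(u_f * s_count + v_f * s_count**2)
            f_star = (
                (pi_abs - ((n_typ - 1.0) / n_typ) * singletons) / denom_f
                if denom_f > 0
                else None
            )
            out.append(
                DiversityStats(
                    chromosome=str(chrom), start=start, end=end,
                    n_segregating=s_count, n_singletons=singletons,
                    pi=pi_abs / length, theta_w=theta_w,
                    tajima_d=tajima, fu_li_d_star=d_star, fu_li_f_star=f_star,
                    partial_window=partial,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst
# ---------------------------------------------------------------------------


def _wc84_site_components(
    dos1: np.ndarray, dos2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham (1984) variance components for two populations.

    Returns (a, a+b+c) per site; monomorphic or under-sampled sites get 0/0.
    """
    r = 2.0
    comps_a = np.zeros(dos1.shape[0])
    comps_t = np.zeros(dos1.shape[0])
    for k in range(dos1.shape[0]):
        row1, row2 = dos1[k], dos2[k]
        g1, g2 = row1[row1 >= 0], row2[row2 >= 0]
        n1, n2 = g1.size, g2.size
        if n1 < 2 or n2 < 2:
            continue
        p1, p2 = g1.sum() / (2.0 * n1), g2.sum() / (2.0 * n2)
        h1 = np.mean(g1 == 1)
        h2 = np.mean(g2 == 1)
        n_bar = (n1 + n2) / 2.0
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        if p_bar <= 0.0 or p_bar >= 1.0:
            continue
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
        comps_a[k] = a
        comps_t[k] = a + b + c
    return comps_a, comps_t


@dataclass
class FstWindow:
    chromosome: str
    start: int
    end: int
    fst: float
    truncated: bool  # negative estimate truncated to 0
    n_sites: int


def weir_cockerham_fst(
    gm: GenotypeMatrix,
    pop1: Sequence[str] | str,
    pop2: Sequence[str] | str,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    chromosome_lengths: Optional[Mapping[str, int]] = None,
) -> list[FstWindow]:
    """Windowed weighted Weir–Cockerham Fst: Σa / Σ(a+b+c) over window sites.

    Negative window estimates are truncated to 0 and flagged.
    """
    s1 = gm.population_samples(pop1) if isinstance(pop1, str) else list(pop1)
    s2 = gm.population_samples(pop2) if isinstance(pop2, str) else list(pop2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each population needs at least 2 diploid samples")
    dos1 = gm.genotypes[:, gm.sample_indices(s1)]
    dos2 = gm.genotypes[:, gm.sample_indices(s2)]
    comp_a, comp_t = _wc84_site_components(dos1, dos2)
    positions = np.array([s.position for s in gm.sites])
    chroms = np.array([s.chromosome for s in gm.sites])
    out: list[FstWindow] = []
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        pos_c = positions[mask]
        a_c, t_c = comp_a[mask], comp_t[mask]
        chrom_len = (
            chromosome_lengths[chrom]
            if chromosome_lengths is not None
            else int(pos_c.max()) + 1
        )
        for start, end, _partial in _window_grid(chrom_len, window_size, step):
            in_win = (pos_c >= start) & (pos_c < end)
            denom = float(t_c[in_win].sum())
            n_sites = int(np.sum(t_c[in_win] != 0.0))
            fst = float(a_c[in_win].sum() / denom) if denom != 0.0 else 0.0
            truncated = fst < 0.0
            out.append(
                FstWindow(
                    chromosome=str(chrom), start=start, end=end,
                    fst=max(fst, 0.0), truncated=truncated, n_sites=n_sites,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Z-transformation and sweep calling
# ---------------------------------------------------------------------------


def zfst_transform(fst_values: Sequence[float]) -> np.ndarray:
    """Standardise Fst values to mean 0 and sample sd 1 (denominator n−1)."""
    x = np.asarray(list(fst_values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance: ZFst undefined")
    return (x - x.mean()) / sd


def two_population_scan(
    gm: GenotypeMatrix,
    pop1: Sequence[str] | str = "pop1",
    pop2: Sequence[str] | str = "pop2",
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    chromosome_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Joint windowed scan: per-population diversity, Fst, ZFst and π ratio.

    The π ratio is π(pop2)/π(pop1), so reduced diversity in the focal
    population 1 (the domesticated-like strain) yields a large ratio.
    """
    kwargs = dict(
        window_size=window_size, step=step, chromosome_lengths=chromosome_lengths
    )
    div1 = window_diversity_stats(gm, pop1, **kwargs)
    div2 = window_diversity_stats(gm, pop2, **kwargs)
    fst = weir_cockerham_fst(gm, pop1, pop2, **kwargs)
    rows = []
    for d1, d2, f in zip(div1, div2, fst):
        assert (d1.chromosome, d1.start) == (d2.chromosome, d2.start) == (
            f.chromosome, f.start
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = d2.pi / d1.pi if d1.pi > 0 else (np.inf if d2.pi > 0 else np.nan)
        rows.append(
            {
                "chromosome": d1.chromosome, "start": d1.start, "end": d1.end,
                "pi_pop1": d1.pi, "pi_pop2": d2.pi,
                "theta_w_pop1": d1.theta_w, "theta_w_pop2": d2.theta_w,
                "tajima_d_pop1": d1.tajima_d, "tajima_d_pop2": d2.tajima_d,
                "fu_li_d_star_pop1": d1.fu_li_d_star,
                "fu_li_f_star_pop1": d1.fu_li_f_star,
                "fst": f.fst, "fst_truncated": f.truncated,
                "pi_ratio": ratio,
            }
        )
    df = pd.DataFrame(rows)
    df["zfst"] = zfst_transform(df["fst"].to_numpy())
    return df


@dataclass(frozen=True)
class SweepCall:
    chromosome: str
    start: int
    end: int
    direction: str  # {selected_in_pop1, selected_in_pop2}
    pi_ratio: float
    zfst: float


@dataclass
class SweepScanResult:
    calls: list[SweepCall]
    ratio_high: float
    ratio_low: float
    zfst_high: float
    zfst_low: float
    degenerate: bool = False


def call_selective_sweeps(
    windows: pd.DataFrame, quantile: float = 0.05
) -> SweepScanResult:
    """Joint top-quantile sweep calling on π ratio and ZFst.

    Windows in the top ``quantile`` of both the π ratio (π2/π1) and ZFst
    are called selected in population 1; windows in the bottom ``quantile``
    of both are called selected in population 2. Thresholds are empirical
    quantiles of the scanned windows and are reported alongside the calls.
    """
    needed = {"pi_ratio", "zfst"}
    if not needed <= set(windows.columns):
        raise ValueError("windows must carry pi_ratio and zfst columns")
    usable = windows.dropna(subset=["pi_ratio", "zfst"])
    if len(usable) < 1.0 / quantile:
        raise ValueError("too few windows for the requested quantile")
    finite_ratio = usable["pi_ratio"].replace(np.inf, np.nan).dropna()
    ratio_for_q = usable["pi_ratio"].to_numpy()
    # np.quantile is happy with inf values (they sort to the top)
    r_hi = float(np.quantile(ratio_for_q, 1.0 - quantile))
    r_lo = float(np.quantile(ratio_for_q, quantile))
    z = usable["zfst"].to_numpy()
    z_hi = float(np.quantile(z, 1.0 - quantile))
    z_lo = float(np.quantile(z, quantile))
    degenerate = (
        np.isclose(r_hi, r_lo)
        or np.isclose(z_hi, z_lo)
        or finite_ratio.nunique() <= 1
    )
    calls: list[SweepCall] = []
    if not degenerate:
        for _, row in usable.iterrows():
            if row["pi_ratio"] >= r_hi and row["zfst"] >= z_hi:
                direction = "selected_in_pop1"
            elif row["pi_ratio"] <= r_lo and row["zfst"] <= z_lo:
                direction = "selected_in_pop2"
            else:
                continue
            calls.append(
                SweepCall(
                    chromosome=row["chromosome"], start=int(row["start"]),
                    end=int(row["end"]), direction=direction,
                    pi_ratio=float(row["pi_ratio"]), zfst=float(row["zfst"]),
                )
            )
    return SweepScanResult(
        calls=calls, ratio_high=r_hi, ratio_low=r_lo,
        zfst_high=z_hi, zfst_low=z_lo, degenerate=degenerate,
    )


def diversity_reduction_percent(pi_focal: float, pi_reference: float) -> float:
    """Percent diversity reduction of the focal strain relative to the
    reference: 100 (π_ref − π_focal)/π_ref, at 1-decimal precision."""
    if pi_reference <= 0:
        raise ValueError("reference diversity must be positive")
    return round_half_up(100.0 * (pi_reference - pi_focal) / pi_reference, 1)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


@dataclass
class LDCurve:
    bin_midpoints: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    half_decay_distance: Optional[float]


def ld_decay_curve(
    gm: GenotypeMatrix,
    population: Sequence[str] | str,
    max_distance: int = 500_000,
    bin_size: int = 10_000,
) -> LDCurve:
    """Composite-LD r² decay with distance, within chromosomes.

    r² between two sites is the squared Pearson correlation of unphased
    genotype dosages across samples (missing dosages excluded pairwise);
    monomorphic sites are excluded. The half-decay distance is the smallest
    bin midpoint whose mean r² falls to half the maximum bin mean.
    """
    samples = (
        gm.population_samples(population) if isinstance(population, str) else list(population)
    )
    dosages = gm.genotypes[:, gm.sample_indices(samples)].astype(float)
    dosages[dosages < 0] = np.nan
    positions = np.array([s.position for s in gm.sites])
    chroms = np.array([s.chromosome for s in gm.sites])
    n_bins = max_distance // bin_size
    sum_r2 = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=int)
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        pos_c = positions[mask]
        d_c = dosages[mask]
        keep = np.array([np.nanstd(row) > 0 for row in d_c])
        pos_c, d_c = pos_c[keep], d_c[keep]
        for i in range(len(pos_c)):
            j = i + 1
            while j < len(pos_c) and pos_c[j] - pos_c[i] <= max_distance:
                dist = pos_c[j] - pos_c[i]
                xi, xj = d_c[i], d_c[j]
                ok = ~(np.isnan(xi) | np.isnan(xj))
                if ok.sum() >= 4 and np.std(xi[ok]) > 0 and np.std(xj[ok]) > 0:
                    r = np.corrcoef(xi[ok], xj[ok])[0, 1]
                    b = min((dist - 1) // bin_size, n_bins - 1)
                    sum_r2[b] += r * r
                    count[b] += 1
                j += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(count > 0, sum_r2 / np.maximum(count, 1), np.nan)
    mids = (np.arange(n_bins) + 0.5) * bin_size
    valid = count > 0
    half_decay = None
    if valid.any():
        max_mean = np.nanmax(mean_r2[valid])
        for mid, m, v in zip(mids, mean_r2, valid):
            if v and m <= max_mean / 2.0:
                half_decay = float(mid)
                break
    return LDCurve(
        bin_midpoints=mids, mean_r2=mean_r2, n_pairs=count,
        half_decay_distance=half_decay,
    )
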