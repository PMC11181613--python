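"""Windowed selection-signature statistics and candidate calling.

Three complementary scans over sliding physical windows (default 100 kb
windows, 10 kb steps):

* Weir & Cockerham (1984) F_ST from per-site variance components a, b, c,
  combined per window as the ratio of sums  sum(a) / sum(a + b + c);
* nucleotide diversity pi per population (per-site unbiased heterozygosity
  m/(m-1) * 2*p*q summed over the window and divided by physical window
  length), and the diversity ratio pi_other / pi_target, oriented so LARGE
  values flag diversity loss in the target (putatively selected) population;
* Tajima's D in the target population, D = (theta_pi - S/a1) /
  sqrt(e1*S + e2*S*(S-1)) with the standard constants for n sampled
  chromosomes.

Candidate windows are called by empirical quantiles: the joint set takes
windows in the top q of both F_ST and pi-ratio; the Tajima set takes the
bottom q of D. SNPs inside candidate windows are the candidate loci; each
locus is extended by a +/- 50 kb flank and overlapping flanks merged into
candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, PopulationAssignment

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_snps", "fst",
    "pi_pop1", "pi_pop2", "pi_ratio", "tajima_d", "valid",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding physical windows: size and step in bp."""

    window_size: int = 100_000
    step: int = 10_000

    def validate(self) -> None:
        if not (self.window_size >= self.step > 0):
            raise ValueError("require window_size >= step > 0")


def make_windows(chrom_lengths: dict[str, int], spec: WindowSpec) -> pd.DataFrame:
    """Tile each chromosome with [start, start+size) windows advancing by
    ``step``; the final windows are clipped at the chromosome end. Coordinates
    are 0-based half-open; a 1-based site at pos p falls in [s, e) iff
    s <= p-1 < e."""
    spec.validate()
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + spec.window_size, length)))
            start += spec.step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# per-site statistics (vectorized over sites)

def _per_pop_counts(dosage: np.ndarray, idx: np.ndarray):
    """(diploid count, ALT frequency, observed-het frequency) per site."""
    sub = dosage[idx]
    obs = sub != MISSING
    n = obs.sum(axis=0).astype(float)
    alt = np.where(obs, sub, 0).sum(axis=0).astype(float)
    het = ((sub == 1) & obs).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1.0)), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1.0), np.nan)
    return n, p, h


def wc_fst_components(
    dosage: np.ndarray, idx1: np.ndarray, idx2: np.ndarray
):
    """Weir & Cockerham (1984) per-site variance components (a, b, c) for two
    populations, using site-specific sample sizes and observed heterozygosity.

    Sites where either population has no called genotype get components of 0
    and are reported unusable via the returned mask.
    """
    n1, p1, h1 = _per_pop_counts(dosage, idx1)
    n2, p2, h2 = _per_pop_counts(dosage, idx2)
    usable = (n1 > 0) & (n2 > 0)

    r = 2.0
    n1s = np.where(usable, n1, 1.0)
    n2s = np.where(usable, n2, 1.0)
    p1s = np.where(usable, p1, 0.0)
    p2s = np.where(usable, p2, 0.0)
    h1s = np.where(usable, h1, 0.0)
    h2s = np.where(usable, h2, 0.0)

    nbar = (n1s + n2s) / r
    nc = (r * nbar - (n1s**2 + n2s**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1s * p1s + n2s * p2s) / (r * nbar)
    s2 = (n1s * (p1s - pbar) ** 2 + n2s * (p2s - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1s * h1s + n2s * h2s) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
            / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
    c = hbar / 2.0

    # degenerate sites (nbar <= 1 or nc == 0) are unusable
    usable &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c, usable


def _pi_per_site(dosage: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Unbiased per-site pairwise diversity m/(m-1) * 2*p*q on the count
    scale (m = non-missing chromosome count); 0 where m < 2."""
    n, p, _ = _per_pop_counts(dosage, idx)
    m = 2.0 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(m >= 2, m / np.maximum(m - 1.0, 1.0) * 2.0 * p * (1.0 - p), 0.0)
    return np.nan_to_num(pi)


def wc_fst_window(dosage: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> float:
    """Ratio-of-sums Weir-Cockerham F_ST over one window's sites."""
    a, b, c, _ = wc_fst_components(dosage, idx1, idx2)
    den = (a + b + c).sum()
    return float(a.sum() / den) if den != 0 else float("nan")


def pi_window(dosage: np.ndarray, idx: np.ndarray, window_length: int) -> float:
    """Windowed nucleotide diversity: summed per-site unbiased heterozygosity
    divided by the physical window length in bp (clipped windows pass their
    clipped length)."""
    if window_length <= 0:
        raise ValueError("window_length must be > 0")
    return float(_pi_per_site(dosage, idx).sum() / window_length)


def pi_ratio(pi_target: float, pi_other: float) -> float:
    """Diversity ratio pi_other / pi_target; +inf when only the target is
    monomorphic (ranked above all finite values), NaN when both are 0."""
    if pi_target > 0:
        return pi_other / pi_target
    if pi_other > 0:
        return float("inf")
    return float("nan")


def tajima_constants(n: float) -> dict[str, float]:
    """Tajima (1989) normalization constants for n sampled chromosomes."""
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    i = np.arange(1, int(n))
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_window(
    dosage: np.ndarray, idx: np.ndarray
) -> float:
    """Tajima's D over one window's sites within one population.

    S counts segregating sites among the non-missing genotypes; theta_pi is
    the summed per-site unbiased pairwise diversity (count scale); n is the
    median non-missing chromosome count across the segregating sites. Returns
    NaN when S = 0 or n < 4.
    """
    n_dip, p, _ = _per_pop_counts(dosage, idx)
    m = 2.0 * n_dip
    seg = (m >= 2) & (p > 0) & (p < 1)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    n = float(np.median(m[seg]))
    if n < 4:
        return float("nan")
    theta_pi = float(np.sum(
        m[seg] / (m[seg] - 1.0) * 2.0 * p[seg] * (1.0 - p[seg])
    ))
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1.0)
    if var <= 0:
        return float("nan")
    return (theta_pi - S / k["a1"]) / np.sqrt(var)


# ---------------------------------------------------------------------------
# window scan

def compute_window_stats(
    g: GenotypeMatrix,
    pops: PopulationAssignment,
    target_pop: str,
    spec: WindowSpec = WindowSpec(),
    min_snps: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed F_ST, per-population pi, pi ratio and target-population
    Tajima's D over sliding windows.

    ``pi_ratio = pi_other / pi_target`` so large values indicate diversity
    loss in ``target_pop``; a window with pi_target = 0 and pi_other > 0 gets
    +inf (ranked above all finite ratios) and 0/0 gives NaN. Windows with
    fewer than ``min_snps`` SNPs, or an undefined F_ST denominator, are
    flagged invalid and excluded from quantile calling.
    """
    labels = pops.labels
    if len(labels) != 2:
        raise ValueError("selection scan requires exactly two populations")
    if target_pop not in labels:
        raise ValueError(f"unknown target population {target_pop!r}")
    other_pop = labels[0] if labels[1] == target_pop else labels[1]

    lengths = chrom_lengths or g.chrom_lengths
    if not lengths:
        raise ValueError("chromosome lengths unavailable for windowing")
    windows = make_windows(lengths, spec)

    idx1 = pops.indices(g, labels[0])
    idx2 = pops.indices(g, labels[1])
    idx_t = pops.indices(g, target_pop)
    a, b, c, usable = wc_fst_components(g.dosage, idx1, idx2)
    abc = a + b + c
    pi1_site = _pi_per_site(g.dosage, idx1)
    pi2_site = _pi_per_site(g.dosage, idx2)
    pi_site = {labels[0]: pi1_site, labels[1]: pi2_site}

    chrom_arr = g.sites["chrom"].to_numpy()
    pos_arr = g.sites["pos"].to_numpy()

    out = []
    for chrom, wgrp in windows.groupby("chrom", sort=False):
        cidx = np.flatnonzero(chrom_arr == chrom)
        cpos = pos_arr[cidx]
        for row in wgrp.itertuples():
            lo = np.searchsorted(cpos, row.start + 1, side="left")
            hi = np.searchsorted(cpos, row.end, side="right")
            sites = cidx[lo:hi]
            n_snps = len(sites)
            length = row.end - row.start

            num = a[sites].sum()
            den = abc[sites].sum()
            fst = num / den if den != 0 else float("nan")
            pi_t = pi_site[target_pop][sites].sum() / length
            pi_o = pi_site[other_pop][sites].sum() / length
            if pi_t > 0:
                ratio = pi_o / pi_t
            elif pi_o > 0:
                ratio = float("inf")
            else:
                ratio = float("nan")
            d = tajimas_d_window(g.dosage[:, sites], idx_t)
            valid = (n_snps >= min_snps) and np.isfinite(fst)
            pi_p1 = pi_site[labels[0]][sites].sum() / length
            pi_p2 = pi_site[labels[1]][sites].sum() / length
            out.append((chrom, row.start, row.end, n_snps, fst,
                        pi_p1, pi_p2, ratio, d, valid))
    df = pd.DataFrame(out, columns=WINDOW_COLUMNS)
    df.attrs["target_pop"] = target_pop
    df.attrs["other_pop"] = other_pop
    return df


@dataclass
class CandidateSet:
    """Candidate windows and member SNPs for one calling method."""

    method: str                   # "fst_pi_joint" or "tajima_low"
    target_pop: str
    windows: pd.DataFrame
    sites: pd.DataFrame           # columns chrom, pos
    cutoffs: dict[str, float] = field(default_factory=dict)


def _top_cutoff(values: np.ndarray, q: float) -> float:
    """Value of the k-th largest order statistic with k = ceil(q * n); the
    top-q set is {v >= cutoff}, ties at the cutoff included."""
    v = np.sort(values)[::-1]
    k = max(1, int(np.ceil(q * len(v))))
    return float(v[k - 1])


def _bottom_cutoff(values: np.ndarray, q: float) -> float:
    v = np.sort(values)
    k = max(1, int(np.ceil(q * len(v))))
    return float(v[k - 1])


def sites_in_windows(g: GenotypeMatrix, windows: pd.DataFrame) -> pd.DataFrame:
    """Distinct SNPs (chrom, pos) of ``g`` lying inside any given window."""
    keep = np.zeros(g.n_sites, dtype=bool)
    chrom_arr = g.sites["chrom"].to_numpy()
    pos_arr = g.sites["pos"].to_numpy()
    for chrom, wgrp in windows.groupby("chrom", sort=False):
        cmask = chrom_arr == chrom
        cpos = pos_arr[cmask]
        hit = np.zeros(len(cpos), dtype=bool)
        for row in wgrp.itertuples():
            lo = np.searchsorted(cpos, row.start + 1, side="left")
            hi = np.searchsorted(cpos, row.end, side="right")
            hit[lo:hi] = True
        idx = np.flatnonzero(cmask)[hit]
        keep[idx] = True
    return g.sites.loc[keep, ["chrom", "pos"]].reset_index(drop=True)


def call_candidates(
    stats: pd.DataFrame,
    g: GenotypeMatrix,
    q: float = 0.05,
) -> tuple[CandidateSet, CandidateSet]:
    """Quantile-based candidate calling over valid windows.

    Returns the joint set (windows in the top q of BOTH F_ST and pi-ratio)
    and the Tajima set (bottom q of D). Quantiles are empirical order
    statistics over valid windows only; ties at the cutoff are included.
    +inf pi ratios rank above all finite values; windows with undefined D
    are excluded from the D quantile.
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    valid = stats[stats["valid"]].copy()
    if len(valid) == 0:
        raise ValueError("no valid windows to call candidates from")
    target = stats.attrs.get("target_pop", "")

    fst_cut = _top_cutoff(valid["fst"].to_numpy(), q)
    ratio_vals = valid["pi_ratio"].to_numpy()
    ratio_ok = ~np.isnan(ratio_vals)
    ratio_cut = _top_cutoff(ratio_vals[ratio_ok], q)
    joint_mask = (
        (valid["fst"] >= fst_cut)
        & ~np.isnan(ratio_vals)
        & (valid["pi_ratio"] >= ratio_cut)
    )
    joint_windows = valid[joint_mask].reset_index(drop=True)

    d_vals = valid["tajima_d"].to_numpy()
    d_ok = np.isfinite(d_vals)
    if not d_ok.any():
        raise ValueError("no windows with defined Tajima's D")
    d_cut = _bottom_cutoff(d_vals[d_ok], q)
    taj_windows = valid[d_ok & (d_vals <= d_cut)].reset_index(drop=True)

    joint = CandidateSet(
        method="fst_pi_joint",
        target_pop=target,
        windows=joint_windows,
        sites=sites_in_windows(g, joint_windows),
        cutoffs={"fst": fst_cut, "pi_ratio": ratio_cut},
    )
    taj = CandidateSet(
        method="tajima_low",
        target_pop=target,
        windows=taj_windows,
        sites=sites_in_windows(g, taj_windows),
        cutoffs={"tajima_d": d_cut},
    )
    return joint, taj


REGION_COLUMNS = ["chrom", "start", "end", "methods", "n_sites"]


def extend_and_merge(
    candidates: CandidateSet,
    chrom_lengths: dict[str, int],
    flank: int = 50_000,
) -> pd.DataFrame:
    """Extend each candidate SNP by ``flank`` bp on both sides and merge.

    A 1-based site at pos p becomes the 0-based half-open interval
    [p - 1 - flank, p + flank), clipped to the chromosome; overlapping or
    book-ended intervals are merged. Returns sorted, non-overlapping regions.
    """
    rows = []
    sites = candidates.sites.sort_values(["chrom", "pos"])
    for chrom, grp in sites.groupby("chrom", sort=False):
        length = chrom_lengths.get(chrom)
        if length is None:
            raise ValueError(f"no length for chromosome {chrom!r}")
        cur_start = cur_end = None
        n_members = 0
        for pos in grp["pos"]:
            s = max(0, int(pos) - 1 - flank)
            e = min(length, int(pos) + flank)
            if cur_end is None:
                cur_start, cur_end, n_members = s, e, 1
            elif s <= cur_end:  # overlap or adjacency
                cur_end = max(cur_end, e)
                n_members += 1
            else:
                rows.append((chrom, cur_start, cur_end, candidates.method, n_members))
                cur_start, cur_end, n_members = s, e, 1
        if cur_end is not None:
            rows.append((chrom, cur_start, cur_end, candidates.method, n_members))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in regions.itertuples():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.methods}\t{row.n_sites}\n")
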