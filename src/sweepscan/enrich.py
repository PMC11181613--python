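"""Hypergeometric over-representation analysis of candidate genes.

Gene sets come from a GMT file; the background universe is the full gene
annotation (every gene in the GFF3), which keeps the test reproducible. The
p value for a set is the one-sided tail P(X >= k) of
X ~ Hypergeometric(N, K, n) computed by exact summation of the mass
function; the primary significance flag is raw p < alpha, with
Benjamini-Hochberg adjusted values reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, set[str]]
    background: set[str]

    @classmethod
    def from_gmt(cls, sets: dict[str, set[str]], background) -> "GeneSetCollection":
        bg = set(background)
        clean: dict[str, set[str]] = {}
        for name, members in sets.items():
            inside = members & bg
            dropped = len(members) - len(inside)
            if dropped:
                logger.warning(
                    "gene set %s: dropped %d ids outside background", name, dropped
                )
            if inside:
                clean[name] = inside
        return cls(clean, bg)


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file (name, description, member genes...).

    Duplicate genes within a set are counted once; empty sets are dropped
    with a warning. A line with fewer than 3 fields is an error.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = parts[0]
            members = {m for m in parts[2:] if m}
            if not members:
                logger.warning("read_gmt: dropping empty set %s", name)
                continue
            sets[name] = members
    if n_lines == 0:
        logger.warning("read_gmt: %s is empty", path)
    return sets


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation p = P(X >= k), X ~ Hypergeom(N, K, n).

    Computed by exact summation of the pmf from k to min(K, n). k is the
    candidate/set overlap, K the set size, n the candidate count, N the
    background size.
    """
    if n == 0:
        raise ValueError("no candidate genes in background (n = 0)")
    if K == 0:
        raise ValueError("empty gene set (K = 0)")
    if not (0 <= k <= min(K, n)):
        raise ValueError("overlap k outside [0, min(K, n)]")
    xs = np.arange(k, min(K, n) + 1)
    p = float(hypergeom.pmf(xs, N, K, n).sum())
    return min(p, 1.0)


ENRICH_COLUMNS = ["set_name", "k", "K", "n", "N", "p_hyper", "p_bh", "significant"]


def enrich_all(
    candidates,
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every set in the collection against the candidate list.

    Candidate ids outside the background are ignored. Records are sorted by
    raw hypergeometric p, then set name; ``significant`` is p_hyper < alpha.
    """
    cand = set(candidates) & collection.background
    if not cand:
        raise ValueError("no candidate genes inside the background universe")
    N = len(collection.background)
    n = len(cand)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(cand & members)
        p = hypergeom_test(k, K, n, N)
        rows.append((name, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_hyper"])
    if len(df):
        df["p_bh"] = multipletests(df["p_hyper"], method="fdr_bh")[1]
    else:
        df["p_bh"] = []
    df["significant"] = df["p_hyper"] < alpha
    return df.sort_values(["p_hyper", "set_name"]).reset_index(drop=True)
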