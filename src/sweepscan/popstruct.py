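"""Population-structure analyses: LD pruning, PCA, neighbor-joining, admixture.

These reproduce the standard pre-scan checks for a two-population cohort:
decorrelate markers with sliding-window r^2 pruning (PLINK indep-pairwise
semantics), look for clusters with Patterson-scaled PCA, build a
neighbor-joining tree over allele-sharing distances, and fit an
admixture-style binomial mixture by EM with cross-validation over K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import MISSING, GenotypeMatrix, PopulationAssignment

_EPS_F = 1e-6


@dataclass
class PrunedIndex:
    """Retained site indices after LD pruning, with the parameters used."""

    indices: np.ndarray
    window_snps: int
    step_snps: int
    r2_max: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("pruned indices must be strictly increasing")


def _pooled_maf(dosage: np.ndarray) -> np.ndarray:
    obs = dosage != MISSING
    n = obs.sum(axis=0)
    alt = np.where(obs, dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), 0.0)
    return np.minimum(p, 1.0 - p)


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise-complete
    observations; zero-variance vectors are treated as uncorrelated."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    vx = xs.var()
    vy = ys.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    c = np.cov(xs, ys, bias=True)[0, 1]
    return float(c * c / (vx * vy))


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 25,
    step_snps: int = 5,
    r2_max: float = 0.05,
) -> PrunedIndex:
    """Sliding-window greedy LD pruning on dosage correlation (composite LD).

    Within each window of ``window_snps`` retained sites (per chromosome), the
    pair with the highest r^2 above ``r2_max`` is found repeatedly and the
    member with the lower pooled MAF dropped (tie: the larger site index);
    then the window start advances by ``step_snps``.
    """
    if not (window_snps > step_snps > 0):
        raise ValueError("require window_snps > step_snps > 0")
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")

    maf = _pooled_maf(g.dosage)
    removed = np.zeros(g.n_sites, dtype=bool)
    chrom_arr = g.sites["chrom"].to_numpy()

    for chrom in dict.fromkeys(chrom_arr):  # preserve order
        idx = np.flatnonzero(chrom_arr == chrom)
        start = 0
        while start < len(idx):
            window = [j for j in idx[start:start + window_snps] if not removed[j]]
            while True:
                best = None
                best_r2 = r2_max
                for a in range(len(window)):
                    for b in range(a + 1, len(window)):
                        r2 = _r2(g.dosage[:, window[a]], g.dosage[:, window[b]])
                        if r2 > best_r2:
                            best_r2 = r2
                            best = (window[a], window[b])
                if best is None:
                    break
                i, j = best
                drop = j if maf[j] < maf[i] else (i if maf[i] < maf[j] else max(i, j))
                removed[drop] = True
                window.remove(drop)
            start += step_snps
    return PrunedIndex(np.flatnonzero(~removed), window_snps, step_snps, r2_max)


@dataclass
class PcaResult:
    coords: np.ndarray            # samples x n_components
    explained_variance_ratio: np.ndarray
    n_sites_used: int
    n_monomorphic_dropped: int


def pca(
    g: GenotypeMatrix,
    pruned: PrunedIndex | None = None,
    n_components: int = 10,
) -> PcaResult:
    """PCA of the genotype matrix with Patterson normalization.

    Missing dosages are mean-imputed per site; each site is centered by
    2*p-hat and scaled by sqrt(2*p-hat*(1-p-hat)); monomorphic sites are
    dropped. Components are ordered by decreasing eigenvalue of the sample
    covariance; the sign of each component is fixed so its first nonzero
    coordinate is positive.
    """
    if g.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components >= g.n_samples:
        raise ValueError("n_components must be < n_samples")
    d = g.dosage if pruned is None else g.dosage[:, pruned.indices]
    obs = d != MISSING
    n = obs.sum(axis=0)
    alt = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
    poly = (n > 0) & (p > 0) & (p < 1)
    n_drop = int(d.shape[1] - poly.sum())
    d = d[:, poly]
    p = p[poly]

    x = np.where(d == MISSING, 2.0 * p, d.astype(float))
    x = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    k = n_components
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for c in range(k):
        col = coords[:, c]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, c] = -col
    total = evals.sum()
    evr = evals[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(coords, evr, int(poly.sum()), n_drop)


def distance_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise allele-sharing distances d = 1 - IBS.

    IBS(i, j) = mean over sites non-missing in both samples of
    (2 - |dose_i - dose_j|) / 2. Errors if a pair shares no called site.
    """
    if g.n_samples < 3:
        raise ValueError("need at least 3 samples for a distance matrix")
    n = g.n_samples
    d = np.zeros((n, n))
    dose = g.dosage
    obs = dose != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            ok = obs[i] & obs[j]
            if not ok.any():
                raise ValueError(
                    f"samples {g.sample_ids[i]} and {g.sample_ids[j]} share no "
                    "non-missing sites"
                )
            ibs = np.mean((2.0 - np.abs(dose[i, ok] - dose[j, ok]).astype(float)) / 2.0)
            d[i, j] = d[j, i] = 1.0 - ibs
    return d


@dataclass
class NjTree:
    """Unrooted NJ tree serialized to Newick, with leaf labels preserved."""

    newick: str
    labels: list[str]
    negatives_clamped: bool = False

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions (each as the smaller-side frozenset,
        canonicalized to the side not containing the first label)."""
        sets = _newick_clades(self.newick)
        all_labels = frozenset(self.labels)
        out: set[frozenset[str]] = set()
        for s in sets:
            if 1 < len(s) < len(all_labels) - 1:
                comp = all_labels - s
                out.add(s if self.labels[0] not in s else frozenset(comp))
        return out


def _newick_clades(newick: str) -> list[frozenset[str]]:
    """Leaf sets of all internal nodes of a Newick string (simple parser
    sufficient for trees produced by nj_build)."""
    stack: list[list[str]] = []
    clades: list[frozenset[str]] = []
    token = ""
    leaves_at_level: list[str] = []

    def flush_token():
        nonlocal token
        if token:
            name = token.split(":")[0]
            if name and stack:
                stack[-1].append(name)
            token = ""

    for ch in newick:
        if ch == "(":
            stack.append([])
        elif ch == ",":
            flush_token()
        elif ch == ")":
            flush_token()
            done = stack.pop()
            clades.append(frozenset(done))
            if stack:
                stack[-1].extend(done)
        elif ch == ";":
            flush_token()
        else:
            token += ch
    return clades


def nj_build(d: np.ndarray, labels: list[str]) -> NjTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken by the smallest (i, j) index pair. Negative branch
    lengths are clamped to 0 and flagged. With 3 taxa the unique unrooted
    tree is returned with the closed-form three-point branch lengths.
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if len(labels) != n:
        raise ValueError("labels length mismatch")

    clamped = False

    def fmt(length: float) -> str:
        nonlocal clamped
        if length < 0:
            clamped = True
            length = 0.0
        return f"{length:.10g}"

    nodes = [str(l) for l in labels]
    D = d.copy()
    active = list(range(n))
    reps = {i: nodes[i] for i in active}

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        best = None
        best_q = np.inf
        for ai in range(r):
            for aj in range(ai + 1, r):
                q = (r - 2) * sub[ai, aj] - rowsum[ai] - rowsum[aj]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (ai, aj)
        ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (rowsum[ai] - rowsum[aj]) / (2.0 * (r - 2))
        lj = dij - li
        new_rep = f"({reps[i]}:{fmt(li)},{reps[j]}:{fmt(lj)})"
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for ak in range(r):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        new_idx = D.shape[0] - 1
        reps[new_idx] = new_rep
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    newick = f"({reps[a]}:{fmt(la)},{reps[b]}:{fmt(lb)},{reps[c]}:{fmt(lc)});"
    return NjTree(newick=newick, labels=list(labels), negatives_clamped=clamped)


@dataclass
class AncestryFit:
    """Result of the admixture EM fit.

    Q rows are ancestry fractions on the K-simplex; F holds per-component
    allele frequencies clipped to [1e-6, 1 - 1e-6]; ``loglik_trace`` is
    non-decreasing by the EM monotonicity property.
    """

    Q: np.ndarray
    F: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))


def _binom_loglik(dose, obs, P):
    het = (dose == 1) & obs
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(obs, dose * np.log(P) + (2.0 - dose) * np.log1p(-P), 0.0)
    return float(ll.sum()) + float(het.sum()) * np.log(2.0)


def admixture_em(
    g: GenotypeMatrix,
    pruned: PrunedIndex | None = None,
    K: int = 2,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> AncestryFit:
    """Maximum-likelihood admixture fit by EM.

    The model: dose_ij ~ Binomial(2, sum_k q_ik f_kj) with Q on the simplex.
    Missing genotypes are skipped in the likelihood. ``init`` overrides the
    seeded random initialization (used for permutation-invariance checks).
    """
    if not (1 <= K <= g.n_samples):
        raise ValueError("K must be in [1, n_samples]")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    d = g.dosage if pruned is None else g.dosage[:, pruned.indices]
    obs = d != MISSING
    dose = np.where(obs, d, 0).astype(float)
    I, J = d.shape

    rng = np.random.default_rng(seed)
    if init is not None:
        Q, F = init[0].copy(), init[1].copy()
    else:
        Q = rng.dirichlet(np.ones(K), size=I)
        F = rng.uniform(0.05, 0.95, size=(K, J))
    F = np.clip(F, _EPS_F, 1.0 - _EPS_F)

    trace = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = np.clip(Q @ F, _EPS_F, 1.0 - _EPS_F)
        ll = _binom_loglik(dose, obs, P)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood in admixture EM")
        trace.append(ll)
        if ll - prev_ll < tol and it > 1:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

        # E-step responsibilities, vectorized over k
        A = Q[:, :, None] * F[None, :, :] / P[:, None, :]          # I x K x J
        B = Q[:, :, None] * (1.0 - F[None, :, :]) / (1.0 - P[:, None, :])
        w = obs[:, None, :]
        Ealt = np.where(w, dose[:, None, :] * A, 0.0)
        Eref = np.where(w, (2.0 - dose[:, None, :]) * B, 0.0)

        Qn = (Ealt + Eref).sum(axis=2)
        Q = Qn / Qn.sum(axis=1, keepdims=True)
        denom = (Ealt + Eref).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(denom > 0, Ealt.sum(axis=0) / np.maximum(denom, 1e-300), F)
        F = np.clip(F, _EPS_F, 1.0 - _EPS_F)

    return AncestryFit(
        Q=Q, F=F, loglik=prev_ll, n_iter=it, converged=converged,
        loglik_trace=np.array(trace),
    )


def cv_error(
    g: GenotypeMatrix,
    pruned: PrunedIndex | None = None,
    K: int = 2,
    n_folds: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> float:
    """Cross-validated prediction error for a given K.

    Non-missing genotypes are split into ``n_folds`` random folds; each fold
    is masked in turn, the admixture model refit on the rest, and the masked
    doses scored by mean squared error against 2 * sum_k q_ik f_kj. The
    fold assignment is a deterministic function of ``seed``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    d = g.dosage if pruned is None else g.dosage[:, pruned.indices]
    obs_idx = np.argwhere(d != MISSING)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(obs_idx))
    folds = np.array_split(perm, n_folds)

    sub = GenotypeMatrix(
        list(g.sample_ids),
        (g.sites if pruned is None else g.sites.iloc[pruned.indices]).reset_index(drop=True),
        d,
        dict(g.chrom_lengths),
    )
    errors = []
    for f, fold in enumerate(folds):
        if len(fold) == 0:
            raise ValueError("fold with zero masked entries")
        mask_idx = obs_idx[fold]
        masked = sub.dosage.copy()
        held = masked[mask_idx[:, 0], mask_idx[:, 1]].astype(float)
        masked[mask_idx[:, 0], mask_idx[:, 1]] = MISSING
        gm = GenotypeMatrix(list(sub.sample_ids), sub.sites, masked, dict(sub.chrom_lengths))
        fit = admixture_em(gm, None, K=K, seed=seed + f + 1, max_iter=max_iter, tol=tol)
        pred = 2.0 * (fit.Q @ fit.F)[mask_idx[:, 0], mask_idx[:, 1]]
        errors.append(float(np.mean((held - pred) ** 2)))
    return float(np.mean(errors))


def match_q_to_labels(
    Q: np.ndarray, pops: PopulationAssignment, g: GenotypeMatrix
) -> float:
    """Mean absolute error between Q and the 0/1 population indicator after
    the best column permutation (K=2 convenience for recovery studies)."""
    labels = pops.labels
    ind = np.array([labels.index(pops.mapping[s]) for s in g.sample_ids], dtype=float)
    truth = np.stack([1.0 - ind, ind], axis=1)
    e1 = np.mean(np.abs(Q - truth))
    e2 = np.mean(np.abs(Q[:, ::-1] - truth))
    return float(min(e1, e2))
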