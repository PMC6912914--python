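"""Microsatellite summaries, pairwise Hedrick's G'ST, and DAPC.

The genotype container is a diploid multi-locus table with explicit
missing data (GenAlEx convention: allele 0 = missing).  Per-(locus,
population) summaries report observed heterozygosity, Nei's unbiased
expected heterozygosity, Fis and an exact/Monte-Carlo Hardy-Weinberg
test.  Pairwise population differentiation uses Hedrick's standardized
G'ST = GST / GST_max with the Nei & Chesser small-sample estimators of
HS and HT, averaged across loci before the ratio (the mmod convention).

DAPC (discriminant analysis of principal components) is a PCA reduction
of the individual x allele-count matrix followed by linear discriminant
analysis on the retained components, exposed as a scikit-learn style
estimator plus a convenience function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core import PairwiseMatrix

__all__ = [
    "GenotypeTable",
    "locus_pop_summary",
    "hwe_exact_test",
    "hedrick_gst_prime",
    "encode_allele_counts",
    "DAPC",
    "DAPCResult",
    "dapc",
]

MISSING = 0  # GenAlEx missing-allele code


@dataclass
class GenotypeTable:
    """Diploid multi-locus genotypes: calls[i, l] = (allele_a, allele_b).

    Alleles are positive integers (repeat sizes); 0 marks a missing call.
    Heterozygote (a, b) is identified with (b, a).
    """

    individuals: list[str]
    pop_labels: list[str]
    loci: list[str]
    calls: np.ndarray  # (n_ind, n_loci, 2) ints
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        n, L = len(self.individuals), len(self.loci)
        if L < 1:
            raise ValueError("need at least one locus")
        if self.calls.shape != (n, L, 2):
            raise ValueError("calls must have shape (n_individuals, n_loci, 2)")
        if len(self.pop_labels) != n:
            raise ValueError("pop_labels length mismatch")
        if np.any(self.calls < 0):
            raise ValueError("negative allele codes")
        # a missing half-call masks the whole genotype
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING
        # canonical order within the pair
        self.calls = np.sort(self.calls, axis=2)

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pops(self) -> list[str]:
        return sorted(set(self.pop_labels))

    def typed_mask(self) -> np.ndarray:
        """(n, n_loci) bool: genotype fully scored."""
        return (self.calls != MISSING).all(axis=2)

    def labels_at(self, level: str) -> list[str]:
        if level == "site":
            return self.pop_labels
        if level == "region":
            if self.region_labels is None:
                raise ValueError("no region labels in table")
            return self.region_labels
        raise ValueError(f"unknown level {level!r}")

    # -- GenAlEx-like CSV I/O ------------------------------------------------

    def to_csv(self, path: str) -> None:
        data: dict[str, list] = {"individual": self.individuals, "pop": self.pop_labels}
        for l, locus in enumerate(self.loci):
            data[f"{locus}_1"] = self.calls[:, l, 0]
            data[f"{locus}_2"] = self.calls[:, l, 1]
        pd.DataFrame(data).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "GenotypeTable":
        """Two columns per locus (``locus_1``, ``locus_2``); 0/blank missing."""
        df = pd.read_csv(path)
        ind = df.iloc[:, 0].astype(str).tolist()
        pops = df.iloc[:, 1].astype(str).tolist()
        allele_cols = df.columns[2:]
        if len(allele_cols) % 2 != 0:
            raise ValueError("expected two allele columns per locus")
        loci = [c[:-2] for c in allele_cols[::2]]
        calls = np.zeros((len(ind), len(loci), 2), dtype=int)
        for l in range(len(loci)):
            a = pd.to_numeric(df[allele_cols[2 * l]], errors="coerce").fillna(0)
            b = pd.to_numeric(df[allele_cols[2 * l + 1]], errors="coerce").fillna(0)
            calls[:, l, 0] = a.astype(int)
            calls[:, l, 1] = b.astype(int)
        return cls(individuals=ind, pop_labels=pops, loci=loci, calls=calls)


# ---------------------------------------------------------------------------
# per-locus, per-population summaries

def _allele_freqs(genos: np.ndarray) -> dict[int, float]:
    """Allele frequencies from an (m, 2) array of typed genotypes."""
    alleles, counts = np.unique(genos.ravel(), return_counts=True)
    total = counts.sum()
    return {int(a): c / total for a, c in zip(alleles, counts)}


def _table_log_prob(counts: dict[tuple[int, int], int], n: int) -> float:
    """Log of Levene's conditional probability of a genotype table given
    its allele counts."""
    from scipy.special import gammaln

    het = sum(c for (a, b), c in counts.items() if a != b)
    allele: dict[int, int] = {}
    log_perm = 0.0
    for (a, b), c in counts.items():
        allele[a] = allele.get(a, 0) + c
        allele[b] = allele.get(b, 0) + c
        log_perm += gammaln(c + 1)
    ac = np.array(sorted(allele.values()))
    return float(
        gammaln(n + 1) - log_perm + het * np.log(2.0)
        + gammaln(ac + 1).sum() - gammaln(2 * n + 1)
    )


def hwe_exact_test(
    genos: np.ndarray,
    method: str = "auto",
    n_shuffles: int = 10_000,
    seed: int = 2024,
) -> float:
    """Hardy-Weinberg exact test on an (m, 2) array of typed genotypes.

    Conditional on allele counts, sums the probability of all genotype
    tables no more probable than the observed one.  Two-allele loci are
    enumerated exactly (any sample size); with more alleles a seeded
    Monte-Carlo permutation of the allele vector is used by default
    (``method='exact'`` forces full recursive enumeration, feasible only
    for small samples).
    """
    genos = np.asarray(genos, dtype=int)
    if genos.ndim != 2 or genos.shape[1] != 2:
        raise ValueError("genos must be (m, 2)")
    genos = genos[(genos != MISSING).all(axis=1)]
    m = genos.shape[0]
    if m == 0:
        return float("nan")
    alleles = np.unique(genos)
    if len(alleles) == 1:
        return 1.0
    if method not in {"auto", "exact", "mc"}:
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" or (method == "auto" and len(alleles) == 2):
        if len(alleles) == 2:
            return _hwe_exact_biallelic(genos, alleles)
        return _hwe_exact_enumerate(genos, alleles)
    return _hwe_monte_carlo(genos, n_shuffles, seed)


def _hwe_exact_biallelic(genos: np.ndarray, alleles: np.ndarray) -> float:
    a, b = alleles
    m = genos.shape[0]
    nA = int((genos == a).sum())
    # heterozygote count shares parity with nA
    het_obs = int(((genos[:, 0] == a) ^ (genos[:, 1] == a)).sum())
    log_probs = []
    hets = []
    for het in range(nA % 2, min(nA, 2 * m - nA) + 1, 2):
        nAA = (nA - het) // 2
        nBB = m - nAA - het
        counts = {(a, a): nAA, (a, b): het, (b, b): nBB}
        counts = {k: v for k, v in counts.items() if v > 0}
        log_probs.append(_table_log_prob(counts, m))
        hets.append(het)
    log_probs = np.array(log_probs)
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    p_obs = probs[hets.index(het_obs)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def _hwe_exact_enumerate(genos: np.ndarray, alleles: np.ndarray) -> float:
    """Full enumeration of genotype tables with the observed allele counts."""
    m = genos.shape[0]
    allele_counts = {int(a): int((genos == a).sum()) for a in alleles}
    obs: dict[tuple[int, int], int] = {}
    for g in genos:
        key = (int(g[0]), int(g[1]))
        obs[key] = obs.get(key, 0) + 1
    lp_obs = _table_log_prob(obs, m)
    keys = sorted(allele_counts)
    pairs = [(keys[i], keys[j]) for i in range(len(keys)) for j in range(i, len(keys))]
    results: list[float] = []

    def rec(idx: int, remaining: dict[int, int], table: dict, n_left: int) -> None:
        if idx == len(pairs):
            if n_left == 0 and all(v == 0 for v in remaining.values()):
                results.append(_table_log_prob({k: v for k, v in table.items() if v},
                                               m))
            return
        a, b = pairs[idx]
        need = 2 if a == b else 1
        cmax = min(remaining[a] // (2 if a == b else 1),
                   remaining[b] if a != b else m, n_left)
        for c in range(cmax + 1):
            remaining[a] -= c * (2 if a == b else 1)
            if a != b:
                remaining[b] -= c
            table[(a, b)] = c
            rec(idx + 1, remaining, table, n_left - c)
            remaining[a] += c * (2 if a == b else 1)
            if a != b:
                remaining[b] += c
        del table[(a, b)]

    rec(0, dict(allele_counts), {}, m)
    lps = np.array(results)
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    return float(probs[lps <= lp_obs + 1e-9].sum())


def _hwe_monte_carlo(genos: np.ndarray, n_shuffles: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    m = genos.shape[0]
    pool = genos.ravel().copy()
    obs = np.sort(genos, axis=1)
    codes_obs = obs[:, 0] * (pool.max() + 1) + obs[:, 1]
    base = pool.max() + 1

    def table_lp(codes: np.ndarray) -> float:
        uniq, cnt = np.unique(codes, return_counts=True)
        table = {(int(c // base), int(c % base)): int(k) for c, k in zip(uniq, cnt)}
        return _table_log_prob(table, m)

    lp_obs = table_lp(codes_obs)
    hits = 0
    for _ in range(n_shuffles):
        rng.shuffle(pool)
        sim = np.sort(pool.reshape(m, 2), axis=1)
        lp = table_lp(sim[:, 0] * base + sim[:, 1])
        if lp <= lp_obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_shuffles + 1)


def locus_pop_summary(
    gt: GenotypeTable,
    hwe_method: str = "auto",
    hwe_shuffles: int = 10_000,
    hwe_seed: int = 2024,
) -> pd.DataFrame:
    """Per-(locus, population) Ho, unbiased He, Fis and HWE p-value.

    He uses Nei's unbiased estimator (2n/(2n-1)) (1 - sum p^2); Fis is
    1 - Ho/He, undefined (NaN) for monomorphic samples.
    """
    typed = gt.typed_mask()
    rows = []
    for pop in gt.pops:
        in_pop = np.array([p == pop for p in gt.pop_labels])
        for l, locus in enumerate(gt.loci):
            sel = in_pop & typed[:, l]
            m = int(sel.sum())
            if m == 0:
                rows.append({"locus": locus, "pop": pop, "n_typed": 0,
                             "Ho": np.nan, "He": np.nan, "Fis": np.nan,
                             "hwe_p": np.nan})
                continue
            g = gt.calls[sel, l, :]
            ho = float((g[:, 0] != g[:, 1]).mean())
            freqs = np.array(list(_allele_freqs(g).values()))
            he = (2 * m / (2 * m - 1)) * (1 - float((freqs ** 2).sum()))
            fis = 1 - ho / he if he > 0 else np.nan
            pval = hwe_exact_test(g, hwe_method, hwe_shuffles, hwe_seed) \
                if he > 0 else np.nan
            rows.append({"locus": locus, "pop": pop, "n_typed": m,
                         "Ho": ho, "He": he, "Fis": fis, "hwe_p": pval})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hedrick's G'ST

def _pair_hs_ht(gA: np.ndarray, gB: np.ndarray) -> tuple[float, float] | None:
    """Nei & Chesser estimators of HS and HT for one locus, two pops.

    ``gA``/``gB`` are (m, 2) typed genotype arrays.  Returns None when a
    side has no typed individuals.
    """
    nA, nB = gA.shape[0], gB.shape[0]
    if nA == 0 or nB == 0:
        return None
    n_harm = 2.0 / (1.0 / nA + 1.0 / nB)
    ho = (float((gA[:, 0] != gA[:, 1]).mean()) + float((gB[:, 0] != gB[:, 1]).mean())) / 2
    fa = _allele_freqs(gA)
    fb = _allele_freqs(gB)
    alleles = set(fa) | set(fb)
    pa = np.array([fa.get(x, 0.0) for x in alleles])
    pb = np.array([fb.get(x, 0.0) for x in alleles])
    hs_raw = 1 - ((pa ** 2).sum() + (pb ** 2).sum()) / 2
    pbar = (pa + pb) / 2
    ht_raw = 1 - (pbar ** 2).sum()
    hs = (n_harm / (n_harm - 1)) * (hs_raw - ho / (2 * n_harm))
    ht = ht_raw + hs / (2 * n_harm) - ho / (4 * n_harm)
    return float(hs), float(ht)


def hedrick_gst_prime(gt: GenotypeTable, level: str = "site") -> PairwiseMatrix:
    """Pairwise multi-locus Hedrick's G'ST between populations.

    For each pair: average the Nei & Chesser HS and HT estimates across
    loci, take GST = (HT - HS)/HT, and standardize by Hedrick's maximum
    GST_max = (k-1)(1-HS)/(k-1+HS) with k = 2.  Pairs monomorphic across
    all loci are 0 by convention (warned).  Small negative estimates from
    the sampling corrections are truncated to [0, 1].

    Pairs where either side has fewer than 5 typed individuals on average
    are flagged in ``meta['low_sample_pairs']`` rather than suppressed.
    """
    labels = gt.labels_at(level)
    pops = sorted(set(labels))
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    typed = gt.typed_mask()
    vals = np.zeros((len(pops), len(pops)))
    low_n: list[tuple[str, str]] = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            selA = np.array([p == pops[i] for p in labels])
            selB = np.array([p == pops[j] for p in labels])
            hs_list, ht_list = [], []
            n_typed_A, n_typed_B = [], []
            for l in range(gt.n_loci):
                gA = gt.calls[selA & typed[:, l], l, :]
                gB = gt.calls[selB & typed[:, l], l, :]
                res = _pair_hs_ht(gA, gB)
                if res is None:
                    continue
                hs_list.append(res[0])
                ht_list.append(res[1])
                n_typed_A.append(gA.shape[0])
                n_typed_B.append(gB.shape[0])
            if not hs_list:
                raise ValueError(f"no co-typed locus for pair {pops[i]},{pops[j]}")
            hs = float(np.mean(hs_list))
            ht = float(np.mean(ht_list))
            if ht <= 0:
                warnings.warn(
                    f"pair ({pops[i]}, {pops[j]}) monomorphic across loci; "
                    "G'ST set to 0 by convention"
                )
                g = 0.0
            else:
                gst = (ht - hs) / ht
                gst_max = (1 - hs) / (1 + hs)  # k = 2
                g = gst / gst_max if gst_max > 0 else 0.0
            vals[i, j] = vals[j, i] = min(max(g, 0.0), 1.0)
            if np.mean(n_typed_A) < 5 or np.mean(n_typed_B) < 5:
                low_n.append((pops[i], pops[j]))
    return PairwiseMatrix(labels=pops, values=vals,
                          metric_name="Hedrick_GST_prime",
                          meta={"low_sample_pairs": low_n})


# ---------------------------------------------------------------------------
# DAPC

def encode_allele_counts(gt: GenotypeTable) -> pd.DataFrame:
    """Individuals x alleles count matrix (0/1/2), NaN where untyped."""
    typed = gt.typed_mask()
    cols = {}
    for l, locus in enumerate(gt.loci):
        g = gt.calls[:, l, :]
        alleles = sorted(set(g[typed[:, l]].ravel()) - {MISSING})
        for a in alleles:
            counts = (g == a).sum(axis=1).astype(float)
            counts[~typed[:, l]] = np.nan
            cols[f"{locus}.{a}"] = counts
    return pd.DataFrame(cols, index=gt.individuals)


class _RidgedCovariance:
    """Empirical covariance with a vanishing relative ridge.

    Keeps the discriminant eigenproblem well posed when a group is
    (near-)clonal and its within-class scatter is singular; the ridge is
    far below numerical test tolerances for non-degenerate data.
    """

    def __init__(self, alpha: float = 1e-12):
        self.alpha = alpha

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        mu = X.mean(axis=0)
        Xc = X - mu
        cov = Xc.T @ Xc / X.shape[0]
        p = cov.shape[0]
        scale = max(float(np.trace(cov)) / p, 1.0)
        self.covariance_ = cov + self.alpha * scale * np.eye(p)
        self.location_ = mu
        return self


class DAPC(BaseEstimator, ClassifierMixin):
    """Discriminant analysis of principal components.

    PCA on the centered/scaled allele-count matrix (missing values
    mean-imputed) followed by linear discriminant analysis on the
    retained components.  ``n_pca`` retained principal components must
    not exceed the rank of the centered matrix; ``n_da`` discriminant
    axes are at most ``n_groups - 1``.

    Attributes (after ``fit``): ``coords_`` per-individual discriminant
    coordinates, ``posterior_`` group membership probabilities,
    ``var_explained_`` per discriminant axis, ``classes_``.
    """

    def __init__(self, n_pca: int = 60, n_da: int = 3):
        self.n_pca = n_pca
        self.n_da = n_da

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise ValueError("each group needs >= 2 members")
        n_da = min(self.n_da, len(classes) - 1)
        if n_da < 1:
            raise ValueError("need >= 2 groups")
        # mean-impute missing allele counts, then center and scale
        col_mean = np.nanmean(X, axis=0)
        Xi = np.where(np.isnan(X), col_mean[None, :], X)
        self.center_ = Xi.mean(axis=0)
        sd = Xi.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        self.impute_means_ = col_mean
        Z = (Xi - self.center_) / self.scale_
        rank = np.linalg.matrix_rank(Z)
        if self.n_pca > rank:
            raise ValueError(f"n_pca={self.n_pca} exceeds matrix rank {rank}")
        self.pca_ = PCA(n_components=self.n_pca, svd_solver="full").fit(Z)
        scores = self.pca_.transform(Z)
        self.lda_ = LinearDiscriminantAnalysis(
            solver="eigen", n_components=n_da,
            covariance_estimator=_RidgedCovariance(),
        ).fit(scores, y)
        self.classes_ = self.lda_.classes_
        self.n_da_ = n_da
        self.coords_ = self.lda_.transform(scores)[:, :n_da]
        self.posterior_ = self.lda_.predict_proba(scores)
        ev = self.lda_.explained_variance_ratio_
        self.var_explained_ = np.asarray(ev[:n_da])
        return self

    def _encode(self, X):
        X = np.asarray(X, dtype=float)
        Xi = np.where(np.isnan(X), self.impute_means_[None, :], X)
        return (Xi - self.center_) / self.scale_

    def transform(self, X):
        return self.lda_.transform(self.pca_.transform(self._encode(X)))[:, : self.n_da_]

    def predict(self, X):
        return self.lda_.predict(self.pca_.transform(self._encode(X)))

    def predict_proba(self, X):
        return self.lda_.predict_proba(self.pca_.transform(self._encode(X)))


@dataclass
class DAPCResult:
    n_pca: int
    n_da: int
    coords: pd.DataFrame
    group_assignments: pd.DataFrame
    var_explained: np.ndarray
    model: DAPC = field(repr=False, default=None)


def dapc(gt: GenotypeTable, groups: list[str], n_pca: int = 60, n_da: int = 3) -> DAPCResult:
    """Run DAPC on a genotype table with user-supplied group labels."""
    if len(groups) != gt.n:
        raise ValueError("groups length mismatch")
    X = encode_allele_counts(gt).to_numpy()
    model = DAPC(n_pca=n_pca, n_da=n_da).fit(X, np.asarray(groups))
    coords = pd.DataFrame(
        model.coords_, index=gt.individuals,
        columns=[f"LD{i + 1}" for i in range(model.coords_.shape[1])],
    )
    post = pd.DataFrame(model.posterior_, index=gt.individuals,
                        columns=list(model.classes_))
    return DAPCResult(n_pca=n_pca, n_da=model.n_da_, coords=coords,
                      group_assignments=post, var_explained=model.var_explained_,
                      model=model)
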