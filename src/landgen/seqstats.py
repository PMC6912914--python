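"""Diversity and neutrality statistics for aligned haplotype data.

Implements the standard single-locus summaries for an alignment of
mitochondrial or nuclear haplotypes: segregating sites S, haplotype
diversity Hd, nucleotide diversity per site (pi), mean pairwise
differences k, Watterson's theta, effective haplotype number and
evenness, and the frequency-spectrum neutrality tests Tajima's D,
Fu & Li's D* and F* (the no-outgroup "star" variants) and Fu's Fs.

Columns containing gaps, N or other ambiguity codes are removed before
analysis ("complete deletion", the DnaSP default); pairwise deletion is
available by flag.  Statistics requiring segregating sites are undefined
at S = 0 and raise rather than returning 0.

No p-values are attached to the neutrality statistics: significance in
the original analyses came from coalescent-simulation beta
approximations, which are a separate exercise from the statistics
themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from Bio import SeqIO

__all__ = [
    "SequenceAlignment",
    "DiversitySummary",
    "summarize_diversity",
    "tajimas_d",
    "fu_li_tests",
    "fus_fs",
    "per_site_summaries",
    "read_fasta",
]

_VALID = frozenset("ACGT")


@dataclass
class SequenceAlignment:
    """Equal-length DNA sequences with sample ids and optional site labels."""

    ids: list[str]
    seqs: list[str]
    site_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        if len(self.seqs) < 1:
            raise ValueError("empty alignment")
        self.seqs = [s.upper().replace("U", "T") for s in self.seqs]
        L = len(self.seqs[0])
        if L < 1:
            raise ValueError("zero-length sequences")
        if any(len(s) != L for s in self.seqs):
            raise ValueError("sequences are not aligned (unequal lengths)")
        if self.site_labels is not None and len(self.site_labels) != len(self.ids):
            raise ValueError("site_labels length mismatch")

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) array of single characters."""
        return np.array([list(s) for s in self.seqs])

    def subset(self, idx: list[int]) -> "SequenceAlignment":
        return SequenceAlignment(
            ids=[self.ids[i] for i in idx],
            seqs=[self.seqs[i] for i in idx],
            site_labels=None if self.site_labels is None
            else [self.site_labels[i] for i in idx],
        )


def read_fasta(path: str, labels_csv: str | None = None) -> SequenceAlignment:
    """Read an aligned FASTA file.

    Site labels may come from a sidecar CSV (``sample_id,site_id``) or, by
    convention, from a ``|site`` suffix in the FASTA headers.
    """
    ids, seqs = [], []
    for rec in SeqIO.parse(path, "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ValueError(f"no sequences in {path}")
    labels: list[str] | None = None
    if labels_csv is not None:
        df = pd.read_csv(labels_csv, dtype=str)
        lut = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        labels = [lut.get(i.split("|")[0], "") for i in ids]
    elif all("|" in i for i in ids):
        labels = [i.split("|")[-1] for i in ids]
        ids = [i.rsplit("|", 1)[0] for i in ids]
    return SequenceAlignment(ids=ids, seqs=seqs, site_labels=labels)


@dataclass
class DiversitySummary:
    n: int
    L: int
    S: int
    k_hap: int
    Hd: float
    pi_site: float
    k_pair: float
    theta_w: float
    n_eff_hap: float
    evenness: float
    tajima_d: float
    fuli_dstar: float
    fuli_fstar: float
    fu_fs: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# column handling and elementary counts

def _complete_deletion(mat: np.ndarray) -> np.ndarray:
    """Drop columns containing any character outside {A,C,G,T}."""
    ok = np.ones(mat.shape[1], dtype=bool)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        ok[j] = all(c in _VALID for c in col)
    return mat[:, ok]


def _segregating(mat: np.ndarray) -> tuple[int, int, int]:
    """Return (S, eta, eta_s): segregating sites, mutations, singletons.

    Mutations per site = number of alleles - 1 (infinite-sites reading of a
    multi-allelic column); singleton mutations = alleles seen in exactly one
    sequence, capped at the mutation count of the site.
    """
    S = eta = eta_s = 0
    for j in range(mat.shape[1]):
        _, counts = np.unique(mat[:, j], return_counts=True)
        k = len(counts)
        if k > 1:
            S += 1
            eta += k - 1
            eta_s += min(int((counts == 1).sum()), k - 1)
    return S, eta, eta_s


def _mean_pairwise_diff(mat: np.ndarray) -> float:
    n = mat.shape[0]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int((mat[i] != mat[j]).sum())
    return total / (n * (n - 1) / 2)


def _hap_freqs(mat: np.ndarray) -> np.ndarray:
    seqs = ["".join(r) for r in mat]
    _, counts = np.unique(seqs, return_counts=True)
    return counts / counts.sum()


def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float((1.0 / i ** power).sum())


# ---------------------------------------------------------------------------
# neutrality statistics

def _tajima_from_counts(n: int, S: float, k_pair: float) -> float:
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (k_pair - S / a1) / np.sqrt(var)


def tajimas_d(aln: SequenceAlignment) -> float:
    """Tajima's D: scaled difference between pi and Watterson's theta.

    Count-based, so columns with gaps or ambiguity are always removed
    (complete deletion) before counting.
    """
    mat = _complete_deletion(aln.matrix())
    if mat.shape[1] == 0:
        raise ValueError("no analyzable sites after column deletion")
    n = mat.shape[0]
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    S, _, _ = _segregating(mat)
    if S == 0:
        raise ValueError("Tajima's D is undefined at S = 0")
    return float(_tajima_from_counts(n, S, _mean_pairwise_diff(mat)))


def _fu_li_from_counts(n: int, eta: float, eta_s: float, k_pair: float) -> tuple[float, float]:
    a = _harmonic(n)
    b = _harmonic(n, 2)
    a1 = a + 1.0 / n  # a_{n+1}
    nf = float(n)
    c = 2 * (nf * a - 2 * (nf - 1)) / ((nf - 1) * (nf - 2))
    d = c + (nf - 2) / (nf - 1) ** 2 + (2 / (nf - 1)) * (
        1.5 - (2 * a1 - 3) / (nf - 2) - 1.0 / nf
    )
    # D* (Simonsen-corrected constants, the DnaSP-consistent forms)
    vD = ((nf / (nf - 1)) ** 2 * b + a ** 2 * d
          - 2 * (nf * a * (a + 1)) / ((nf - 1) ** 2)) / (a ** 2 + b)
    uD = (nf / (nf - 1)) * (a - nf / (nf - 1)) - vD
    dstar = ((nf / (nf - 1)) * eta - a * eta_s) / np.sqrt(uD * eta + vD * eta ** 2)
    # F*
    vF = (d + 2 * (nf ** 2 + nf + 3) / (9 * nf * (nf - 1))
          - (2 / (nf - 1)) * (4 * b - 6 + 8 / nf)) / (a ** 2 + b)
    uF = (nf / (nf - 1) + (nf + 1) / (3 * (nf - 1)) - 4 / (nf * (nf - 1))
          + 2 * (nf + 1) / (nf - 1) ** 2 * (a1 - 2 * nf / (nf + 1))) / a - vF
    fstar = (k_pair - ((nf - 1) / nf) * eta_s) / np.sqrt(uF * eta + vF * eta ** 2)
    return float(dstar), float(fstar)


def fu_li_tests(aln: SequenceAlignment) -> tuple[float, float]:
    """Fu & Li's D* and F* (star variants, no outgroup).

    Contrast the total number of mutations (and pi, for F*) against the
    count of singleton mutations; an excess of singletons drives both
    statistics negative.  Complete deletion of ambiguous columns.
    """
    mat = _complete_deletion(aln.matrix())
    if mat.shape[1] == 0:
        raise ValueError("no analyzable sites after column deletion")
    n = mat.shape[0]
    if n < 4:
        raise ValueError("Fu & Li tests require n >= 4")
    S, eta, eta_s = _segregating(mat)
    if S == 0:
        raise ValueError("Fu & Li statistics are undefined at S = 0")
    return _fu_li_from_counts(n, eta, eta_s, _mean_pairwise_diff(mat))


def _log_stirling_first(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    log_s = np.full((n + 1, n + 1), -np.inf)
    log_s[0, 0] = 0.0
    for m in range(1, n + 1):
        for k in range(1, m + 1):
            terms = []
            if log_s[m - 1, k - 1] > -np.inf:
                terms.append(log_s[m - 1, k - 1])
            if log_s[m - 1, k] > -np.inf:
                terms.append(np.log(m - 1) + log_s[m - 1, k])
            log_s[m, k] = logsumexp(terms) if terms else -np.inf
    return log_s[n]


def _log_ewens_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 1..n under the Ewens sampling distribution."""
    log_s = _log_stirling_first(n)
    log_rising = np.log(theta + np.arange(n)).sum()
    k = np.arange(1, n + 1)
    return log_s[1:] + k * np.log(theta) - log_rising


def fus_fs(aln: SequenceAlignment) -> float:
    """Fu's Fs: log-odds that a neutral sample shows >= the observed
    number of haplotypes given theta estimated by pi.

    S' = P(K >= k_obs | theta = k_pair) under the Ewens sampling
    distribution; Fs = ln(S' / (1 - S')).  Large negative values flag an
    excess of haplotypes relative to pairwise diversity.
    """
    mat = _complete_deletion(aln.matrix())  # counts need unambiguous columns
    if mat.shape[1] == 0:
        raise ValueError("no analyzable sites after column deletion")
    n = mat.shape[0]
    k_hap = len(_hap_freqs(mat))
    k_pair = _mean_pairwise_diff(mat)
    if k_hap < 2 or k_pair <= 0:
        raise ValueError("Fu's Fs requires >= 2 haplotypes and k_pair > 0")
    log_pmf = _log_ewens_pmf(n, k_pair)
    log_sp = logsumexp(log_pmf[k_hap - 1:])        # P(K >= k_hap)
    log_1m = logsumexp(log_pmf[: k_hap - 1]) if k_hap > 1 else -np.inf
    return float(log_sp - log_1m)


# ---------------------------------------------------------------------------
# summaries

def _prepare(aln: SequenceAlignment, site_handling: str) -> np.ndarray:
    mat = aln.matrix()
    if site_handling == "complete_deletion":
        mat = _complete_deletion(mat)
    elif site_handling != "pairwise_deletion":
        raise ValueError(f"unknown site_handling {site_handling!r}")
    if mat.shape[1] == 0:
        raise ValueError("no analyzable sites after column deletion")
    return mat


def summarize_diversity(
    aln: SequenceAlignment, site_handling: str = "complete_deletion"
) -> DiversitySummary:
    """Full single-locus diversity summary.

    Hd uses the small-sample correction n/(n-1)(1 - sum p^2); the
    effective haplotype number 1/sum p^2 is the count of equally frequent
    haplotypes giving the same diversity, and evenness divides it by the
    observed haplotype count.  Statistics that need S > 0 (and n >= 4)
    are reported as NaN when undefined.
    """
    if aln.n < 2:
        raise ValueError("diversity statistics require n >= 2")
    raw = _prepare(aln, site_handling)
    # haplotype identity, S and count-based statistics always work on the
    # complete-deletion matrix; pairwise deletion only changes pi_site
    mat = raw if site_handling == "complete_deletion" else _complete_deletion(raw)
    if mat.shape[1] == 0:
        raise ValueError("no analyzable sites after column deletion")
    n, L = mat.shape
    p = _hap_freqs(mat)
    sum_p2 = float((p ** 2).sum())
    Hd = n / (n - 1) * (1 - sum_p2)
    k_pair = _mean_pairwise_diff(mat)
    if site_handling == "pairwise_deletion":
        pi_site = _pairwise_pi(raw)
    else:
        pi_site = k_pair / L
    S, eta, eta_s = _segregating(mat)
    a1 = _harmonic(n)
    theta_w = S / a1
    n_eff = 1.0 / sum_p2
    k_hap = len(p)
    taj = dst = fst = fs = float("nan")
    if S > 0 and n >= 4:
        taj = float(_tajima_from_counts(n, S, k_pair))
        dst, fst = _fu_li_from_counts(n, eta, eta_s, k_pair)
    if k_hap >= 2 and k_pair > 0:
        fs = fus_fs(aln)
    return DiversitySummary(
        n=n, L=L, S=S, k_hap=k_hap, Hd=float(Hd), pi_site=float(pi_site),
        k_pair=float(k_pair), theta_w=float(theta_w), n_eff_hap=float(n_eff),
        evenness=float(n_eff / k_hap), tajima_d=taj, fuli_dstar=dst,
        fuli_fstar=fst, fu_fs=fs,
    )


def _pairwise_pi(mat: np.ndarray) -> float:
    """Mean pairwise proportion of differing sites, per-pair deletion."""
    n = mat.shape[0]
    valid = np.isin(mat, list(_VALID))
    props = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                continue
            props.append(int((mat[i][both] != mat[j][both]).sum()) / m)
    if not props:
        raise ValueError("no comparable sites in any pair")
    return float(np.mean(props))


def per_site_summaries(
    aln: SequenceAlignment, site_handling: str = "complete_deletion"
) -> pd.DataFrame:
    """One DiversitySummary row per site label.

    Groups with n < 2 are all-NA; groups below the sample-size floor of a
    statistic (e.g. n < 4 for Tajima's D) carry NaN in that column only,
    matching how per-site tables report NA for tiny samples.
    """
    if aln.site_labels is None:
        raise ValueError("alignment has no site labels")
    rows = []
    for label in sorted(set(aln.site_labels)):
        idx = [i for i, s in enumerate(aln.site_labels) if s == label]
        row: dict = {"site": label, "n": len(idx)}
        if len(idx) >= 2:
            try:
                summ = summarize_diversity(aln.subset(idx), site_handling)
                row.update(summ.to_dict())
            except ValueError:
                pass
        rows.append(row)
    cols = ["site", "n", "L", "S", "k_hap", "Hd", "pi_site", "k_pair",
            "theta_w", "n_eff_hap", "evenness", "tajima_d", "fuli_dstar",
            "fuli_fstar", "fu_fs"]
    return pd.DataFrame(rows).reindex(columns=cols).set_index("site")
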