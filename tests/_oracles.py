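"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the published formulas and
elementary definitions, deliberately NOT sharing code with the package:
per-site counting loops, explicit constants, dense linear algebra, and
enumeration.  Tests compare package output against these.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# sequence statistics (explicit loops over a list of equal-length strings)

def clean_columns(seqs: list[str]) -> list[str]:
    """Complete deletion: drop columns with anything outside ACGT."""
    L = len(seqs[0])
    keep = [j for j in range(L)
            if all(s[j] in "ACGT" for s in seqs)]
    return ["".join(s[j] for j in keep) for s in seqs]


def pairwise_diffs(seqs: list[str]) -> float:
    n = len(seqs)
    tot = 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += sum(a != b for a, b in zip(seqs[i], seqs[j]))
    return tot / (n * (n - 1) / 2)


def count_sites(seqs: list[str]) -> tuple[int, int, int]:
    """(segregating sites, mutations eta, singleton mutations eta_s)."""
    L = len(seqs[0])
    S = eta = eta_s = 0
    for j in range(L):
        col = [s[j] for s in seqs]
        alleles = {}
        for c in col:
            alleles[c] = alleles.get(c, 0) + 1
        k = len(alleles)
        if k > 1:
            S += 1
            eta += k - 1
            eta_s += min(sum(1 for v in alleles.values() if v == 1), k - 1)
    return S, eta, eta_s


def tajima_d_oracle(seqs: list[str]) -> float:
    """Tajima (1989) with the published constants, written out verbatim."""
    seqs = clean_columns(seqs)
    n = len(seqs)
    S, _, _ = count_sites(seqs)
    assert S > 0
    k = pairwise_diffs(seqs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1.0))


def fu_li_oracle(seqs: list[str]) -> tuple[float, float]:
    """Fu & Li (1993) D* and F* with the Simonsen-corrected constants."""
    seqs = clean_columns(seqs)
    n = float(len(seqs))
    _, eta, eta_s = count_sites(seqs)
    assert eta > 0
    pi = pairwise_diffs(seqs)
    an = sum(1.0 / i for i in range(1, int(n)))
    bn = sum(1.0 / i ** 2 for i in range(1, int(n)))
    an1 = an + 1.0 / n
    cn = 2.0 * (n * an - 2.0 * (n - 1.0)) / ((n - 1.0) * (n - 2.0))
    dn = cn + (n - 2.0) / (n - 1.0) ** 2 + (2.0 / (n - 1.0)) * (
        1.5 - (2.0 * an1 - 3.0) / (n - 2.0) - 1.0 / n)
    vD = ((n / (n - 1.0)) ** 2 * bn + an ** 2 * dn
          - 2.0 * (n * an * (an + 1.0)) / ((n - 1.0) ** 2)) / (an ** 2 + bn)
    uD = (n / (n - 1.0)) * (an - n / (n - 1.0)) - vD
    dstar = ((n / (n - 1.0)) * eta - an * eta_s) / np.sqrt(uD * eta + vD * eta ** 2)
    vF = (dn + 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
          - (2.0 / (n - 1.0)) * (4.0 * bn - 6.0 + 8.0 / n)) / (an ** 2 + bn)
    uF = (n / (n - 1.0) + (n + 1.0) / (3.0 * (n - 1.0)) - 4.0 / (n * (n - 1.0))
          + 2.0 * (n + 1.0) / (n - 1.0) ** 2 * (an1 - 2.0 * n / (n + 1.0))) / an - vF
    fstar = (pi - ((n - 1.0) / n) * eta_s) / np.sqrt(uF * eta + vF * eta ** 2)
    return dstar, fstar


def ewens_pmf_oracle(n: int, theta: float) -> np.ndarray:
    """P(K = k), k = 1..n, via the rising-factorial polynomial.

    theta (theta+1) ... (theta+n-1) = sum_k |s(n,k)| theta^k, so the
    unsigned Stirling numbers are polynomial coefficients obtainable by
    explicit polynomial multiplication — independent of any log-space
    recursion.
    """
    coeffs = np.array([1.0])  # polynomial in theta, lowest order first
    for m in range(n):
        # multiply by (theta + m)
        shifted = np.concatenate([[0.0], coeffs])
        coeffs = m * np.concatenate([coeffs, [0.0]]) + shifted
    rising = float(np.prod([theta + m for m in range(n)]))
    k = np.arange(1, n + 1)
    return coeffs[1:] * theta ** k / rising


# ---------------------------------------------------------------------------
# dense graph oracles

def dense_effective_resistance(n_nodes: int, edges: list[tuple[int, int, float]]) -> np.ndarray:
    """R_eff for all node pairs via the dense Laplacian pseudoinverse.

    ``edges`` carry conductances.
    """
    L = np.zeros((n_nodes, n_nodes))
    for i, j, c in edges:
        L[i, i] += c
        L[j, j] += c
        L[i, j] -= c
        L[j, i] -= c
    # exact pseudoinverse of a connected-graph Laplacian by deflation:
    # L^+ = (L + J/n)^{-1} - J/n  (avoids pinv's rcond truncation)
    J = np.ones((n_nodes, n_nodes)) / n_nodes
    Lp = np.linalg.inv(L + J) - J
    d = np.diag(Lp)
    return d[:, None] + d[None, :] - 2 * Lp


def mvn_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray,
               Z: np.ndarray, su2: float, se2: float) -> float:
    """Direct multivariate-normal log density with cov su2 ZZ' + se2 I."""
    from scipy.stats import multivariate_normal

    cov = su2 * (Z @ Z.T) + se2 * np.eye(len(y))
    return float(multivariate_normal(mean=X @ beta, cov=cov).logpdf(y))
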