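"""Statistical-parsimony (TCS-style) haplotype networks.

Distinct haplotypes are connected by unit mutational steps, in increasing
order of pairwise mutational distance, up to a parsimony connection limit
(conventionally the 95% limit).  Pairs whose distance exceeds the limit
stay in separate subnetworks.  The construction is a deterministic
minimum-spanning-network: within a distance level, edges between
components that were distinct at the start of the level are all added, so
alternative equal-length connections are retained as loops.  The original
TCS program resolves network ambiguities with partly undocumented
frequency/topology heuristics; this implementation trades those for
determinism while keeping the connection limit, which is the inferential
content of the method.

The connection limit is the largest number of steps ``j`` for which the
estimated probability is at least the confidence level that two
haplotypes differing at ``j`` of ``m`` sites are separated by exactly
``j`` mutations (no superimposed changes).  The probability is computed
under a two-state per-site Poisson mutation model with the per-site
difference probability integrated over its Beta posterior; see the
methods note for the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import beta as beta_dist

from .seqstats import SequenceAlignment, _complete_deletion

__all__ = [
    "HaplotypeSet",
    "collapse_haplotypes",
    "parsimony_probability",
    "parsimony_limit",
    "build_network",
    "network_tables",
]


@dataclass
class HaplotypeSet:
    """Distinct haplotypes with their sample counts and members."""

    haplotypes: list[str]
    counts: list[int]
    members: list[list[str]]
    group_labels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(sum(self.counts))

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    def ids(self) -> list[str]:
        return [f"H{i + 1}" for i in range(self.k)]


def collapse_haplotypes(aln: SequenceAlignment) -> HaplotypeSet:
    """Collapse an alignment to distinct haplotypes.

    Columns with gaps/ambiguity are removed first (consistent with the
    diversity statistics).  Order is stable and input-order invariant:
    decreasing count, ties broken lexicographically by sequence.
    """
    mat = _complete_deletion(aln.matrix())
    if mat.shape[1] == 0:
        raise ValueError("no analyzable sites after column deletion")
    seqs = ["".join(r) for r in mat]
    first_seen: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for i, s in enumerate(seqs):
        if s not in first_seen:
            first_seen[s] = i
            members[s] = []
        members[s].append(aln.ids[i])
    order = sorted(first_seen, key=lambda s: (-len(members[s]), s))
    groups: dict[str, list[str]] = {}
    if aln.site_labels is not None:
        lab = dict(zip(aln.ids, aln.site_labels))
        for s in order:
            groups[s] = [lab[m] for m in members[s]]
    return HaplotypeSet(
        haplotypes=order,
        counts=[len(members[s]) for s in order],
        members=[members[s] for s in order],
        group_labels=groups,
    )


# ---------------------------------------------------------------------------
# parsimony connection limit

def parsimony_probability(j: int, seq_len: int, grid: int = 4001) -> float:
    """P(two haplotypes differing at j of m sites differ by exactly j
    mutations).

    Per-site mutation counts are Poisson; a site differs iff it saw an odd
    number of changes (two-state model), so the per-site difference
    probability is q = (1 - exp(-2*lam))/2 and lam = -ln(1 - 2q)/2.  Given
    q, the chance a differing site carries exactly one hit is
    lam*exp(-lam)/q and the chance a matching site carries none is
    exp(-lam)/(1 - q).  q is integrated over its Beta(j+1, m-j+1)
    posterior (uniform prior) truncated to [0, 1/2).
    """
    m = int(seq_len)
    if m < 1 or j < 0 or j > m:
        raise ValueError("need 0 <= j <= seq_len, seq_len >= 1")
    if j == 0:
        return 1.0
    post = beta_dist(j + 1, m - j + 1)
    lo = max(post.ppf(1e-10), 1e-12)
    hi = min(post.ppf(1 - 1e-10), 0.5 - 1e-9)
    if hi <= lo:
        return 0.0
    q = np.linspace(lo, hi, grid)
    lam = -0.5 * np.log1p(-2 * q)
    log_f = post.logpdf(q)
    log_g = (j * (np.log(lam) - lam - np.log(q))
             + (m - j) * (-lam - np.log1p(-q)))
    shift = log_f.max()
    num = np.trapezoid(np.exp(log_f - shift + log_g), q)
    den = np.trapezoid(np.exp(log_f - shift), q)
    return float(num / den)


def parsimony_limit(seq_len: int, confidence: float = 0.95) -> int:
    """Largest j with parsimony probability >= confidence (floor of 1).

    Single mutational steps are always trusted, matching TCS behaviour,
    so the returned limit is at least 1 even at confidence levels the
    one-step probability cannot reach.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    j = 1
    while j < seq_len and parsimony_probability(j + 1, seq_len) >= confidence:
        j += 1
    return j


# ---------------------------------------------------------------------------
# network construction

def _hamming(a: str, b: str) -> int:
    return sum(c1 != c2 for c1, c2 in zip(a, b))


def build_network(
    hset: HaplotypeSet, limit: int, expand_intermediates: bool = True
) -> nx.Graph:
    """Minimum-spanning network under a parsimony connection limit.

    Edges are considered in increasing mutational distance; at each
    distance level, every pair joining components that were distinct at
    the start of the level is connected (ties therefore form loops).
    Pairs more than ``limit`` steps apart are never joined directly.
    Multi-step edges optionally expand into chains of unlabeled inferred
    intermediate nodes so that every drawn edge is one mutational step.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    ids = hset.ids()
    k = hset.k
    G = nx.Graph()
    for hid, hap, cnt, mem in zip(ids, hset.haplotypes, hset.counts, hset.members):
        G.add_node(hid, count=cnt, members=",".join(mem), inferred=False,
                   sequence=hap)
    dist = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            dist[i, j] = dist[j, i] = _hamming(hset.haplotypes[i], hset.haplotypes[j])
    # union-find over observed haplotypes
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # tie-break ordering within a level: higher-frequency first, then id
    n_inferred = 0
    for d in range(1, int(limit) + 1):
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k) if dist[i, j] == d]
        pairs.sort(key=lambda ij: (-(hset.counts[ij[0]] + hset.counts[ij[1]]),
                                   ij[0], ij[1]))
        comp_at_start = [find(i) for i in range(k)]
        added = []
        for i, j in pairs:
            if comp_at_start[i] != comp_at_start[j]:
                added.append((i, j))
        for i, j in added:
            if expand_intermediates and d > 1:
                chain = [ids[i]]
                for _ in range(d - 1):
                    n_inferred += 1
                    node = f"x{n_inferred}"
                    G.add_node(node, count=0, members="", inferred=True)
                    chain.append(node)
                chain.append(ids[j])
                for a, b in zip(chain[:-1], chain[1:]):
                    G.add_edge(a, b, steps=1)
            else:
                G.add_edge(ids[i], ids[j], steps=d)
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return G


def network_tables(G: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list (node_a, node_b, steps) and node table as DataFrames."""
    edges = pd.DataFrame(
        [(a, b, d.get("steps", 1)) for a, b, d in G.edges(data=True)],
        columns=["node_a", "node_b", "steps"],
    )
    nodes = pd.DataFrame(
        [(n, d.get("count", 0), d.get("inferred", False), d.get("members", ""))
         for n, d in G.nodes(data=True)],
        columns=["node", "count", "inferred", "members"],
    )
    return edges, nodes
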