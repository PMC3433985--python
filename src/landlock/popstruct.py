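"""Population structure: two-level AMOVA with phi-ST, and a statistical
parsimony haplotype network.

AMOVA partitions squared molecular distances among individuals into an
among-population and a within-population variance component (the
Excoffier–Smouse–Quattro decomposition).  With squared distances d2 and
populations of sizes n_p (total N, P populations):

    SSD_total  = (1/N)   * sum_{i<j} d2_ij
    SSD_within = sum_p (1/n_p) * sum_{i<j in p} d2_ij
    SSD_among  = SSD_total - SSD_within

    sigma2_w = SSD_within / (N - P)
    n_prime  = (N - sum_p n_p^2 / N) / (P - 1)
    sigma2_a = (SSD_among/(P-1) - sigma2_w) / n_prime      (clamped at 0)

    phi_ST   = sigma2_a / (sigma2_a + sigma2_w)

Significance comes from permuting individuals among populations with sizes
held fixed; ``p = (1 + #{phi_perm >= phi_obs}) / (B + 1)``.

The haplotype network joins haplotypes in order of increasing mutational step
count, adding a link when the pair is not yet connected or when the link is an
equally parsimonious alternative path (a reticulation); links above the
connection limit never merge components.  The connection limit is the largest
step count whose probability of being multiple-hit-free still reaches the
requested confidence (95% by convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .gendist import DistanceMatrix
from .seqdata import HaplotypeSet, encode


@dataclass
class AmovaResult:
    SSD_among: float
    SSD_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    percent_among: float
    percent_within: float
    phi_ST: float  # nan when total variance is 0
    p_value: float | None
    n_permutations: int
    clamped: bool = False  # sigma2_among was negative and clamped to 0

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "SSD_among", "SSD_within", "df_among", "df_within",
                "sigma2_among", "sigma2_within", "percent_among",
                "percent_within", "phi_ST", "p_value", "n_permutations",
                "clamped",
            )
        }


def _phi_from_groups(d2: np.ndarray, groups: list[np.ndarray]):
    """Variance decomposition given squared distances and index groups."""
    N = sum(len(g) for g in groups)
    P = len(groups)
    iu = np.triu_indices(N, k=1)
    ssd_total = d2[iu].sum() / N
    ssd_within = 0.0
    for g in groups:
        if len(g) > 1:
            block = d2[np.ix_(g, g)]
            ssd_within += np.triu(block, k=1).sum() / len(g)
    ssd_among = ssd_total - ssd_within
    df_a, df_w = P - 1, N - P
    sigma_w = ssd_within / df_w if df_w > 0 else 0.0
    sizes = np.array([len(g) for g in groups], dtype=float)
    n_prime = (N - (sizes**2).sum() / N) / df_a
    sigma_a = (ssd_among / df_a - sigma_w) / n_prime
    clamped = sigma_a < 0
    if clamped:
        sigma_a = 0.0
    total = sigma_a + sigma_w
    phi = sigma_a / total if total > 0 else float("nan")
    return ssd_among, ssd_within, df_a, df_w, sigma_a, sigma_w, phi, clamped


def amova_two_level(
    matrix: DistanceMatrix,
    populations,
    permutations: int | str = 10_000,
    rng: np.random.Generator | int | None = None,
) -> AmovaResult:
    """Two-level AMOVA (among vs within populations) on individual distances.

    Parameters
    ----------
    matrix : DistanceMatrix over individuals.
    populations : population label per individual, aligned with matrix labels.
    permutations : number of random reassignments for the phi-ST test; 0 to
        skip the test; the string ``"exhaustive"`` enumerates every distinct
        assignment of individuals to populations (small problems only).
    rng : seedable randomness for the permutation test.
    """
    populations = np.asarray(populations)
    n = len(matrix.labels)
    if populations.shape[0] != n:
        raise ValueError("one population label per individual required")
    pop_ids = list(dict.fromkeys(populations))
    if len(pop_ids) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    groups = [np.flatnonzero(populations == p) for p in pop_ids]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty population")
    if np.isnan(matrix.values).any():
        raise ValueError("AMOVA requires distances for all pairs")
    d2 = matrix.values**2

    ssd_a, ssd_w, df_a, df_w, s_a, s_w, phi, clamped = _phi_from_groups(d2, groups)
    total = s_a + s_w
    pct_a = 100.0 * s_a / total if total > 0 else float("nan")
    pct_w = 100.0 * s_w / total if total > 0 else float("nan")

    p_value = None
    n_perm = 0
    if permutations == "exhaustive":
        sizes = [len(g) for g in groups]
        count = 0
        n_total = 0
        for phi_p in _enumerate_phi(d2, sizes):
            n_total += 1
            if not np.isnan(phi) and phi_p >= phi - 1e-12:
                count += 1
        p_value = count / n_total if not np.isnan(phi) else None
        n_perm = n_total
    elif permutations and permutations > 0 and not np.isnan(phi):
        rng = np.random.default_rng(rng)
        sizes = np.array([len(g) for g in groups])
        bounds = np.cumsum(sizes)[:-1]
        count = 0
        idx = np.arange(n)
        for _ in range(int(permutations)):
            rng.shuffle(idx)
            perm_groups = np.split(idx.copy(), bounds)
            phi_p = _phi_from_groups(d2, perm_groups)[6]
            if phi_p >= phi - 1e-12:
                count += 1
        p_value = (count + 1) / (int(permutations) + 1)
        n_perm = int(permutations)

    return AmovaResult(
        SSD_among=float(ssd_a), SSD_within=float(ssd_w),
        df_among=df_a, df_within=df_w,
        sigma2_among=float(s_a), sigma2_within=float(s_w),
        percent_among=float(pct_a), percent_within=float(pct_w),
        phi_ST=float(phi), p_value=p_value, n_permutations=n_perm,
        clamped=clamped,
    )


def _enumerate_phi(d2: np.ndarray, sizes: list[int]):
    """Yield phi-ST for every distinct assignment of individuals to groups."""
    n = d2.shape[0]

    def assignments(remaining: tuple, sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(x for x in remaining if x not in combo)
            for tail in assignments(rest, sizes_left[1:]):
                yield [np.array(combo)] + tail

    for groups in assignments(tuple(range(n)), sizes):
        yield _phi_from_groups(d2, groups)[6]


# ---------------------------------------------------------------------------
# statistical parsimony network


def parsimony_probability(steps: int, seq_length: int) -> float:
    """Probability that ``steps`` substitutions hit ``steps`` distinct sites.

    This is the probability that a connection of the given step count is free
    of superimposed change when substitutions scatter uniformly and
    independently over the alignment: the falling-factorial (birthday-problem)
    product prod_{i=1}^{steps-1} (1 - i/L).  It is the dominant term in the
    probability that the observed differences equal the true number of
    substitutions, i.e. that the connection is parsimonious.
    """
    if steps < 1:
        return 1.0
    if steps > seq_length:
        return 0.0
    i = np.arange(1, steps, dtype=float)
    return float(np.exp(np.log1p(-i / seq_length).sum()))


def parsimony_connection_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest step count whose parsimony probability is >= ``confidence``.

    Monotone: non-increasing in confidence, non-decreasing in sequence
    length.  At 95% and mtDNA-scale alignments this is the usual
    statistical-parsimony connection limit (e.g. 15 steps at 2086 sites).
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    j = 1
    while j + 1 <= seq_length and parsimony_probability(j + 1, seq_length) >= confidence:
        j += 1
    return j


def step_count_matrix(haps: HaplotypeSet) -> np.ndarray:
    """Integer site-mismatch counts between all haplotype pairs."""
    matrix = np.stack([encode(s) for s in haps.sequences()])
    n = matrix.shape[0]
    steps = np.zeros((n, n), dtype=int)
    for i in range(n):
        diff = (matrix[i] != matrix[i + 1:]).sum(axis=1) if i + 1 < n else []
        for k, d in enumerate(diff, start=i + 1):
            steps[i, k] = steps[k, i] = int(d)
    return steps


@dataclass
class NetworkGraph:
    """Parsimony network over sampled haplotypes.

    ``graph`` is a networkx Graph whose nodes are haplotype ids (with
    ``frequency`` and per-population composition attributes) and whose edges
    carry ``steps`` and ``inferred_intermediates = steps - 1`` (unsampled
    nodes implied by a multi-step link).
    """

    graph: nx.Graph
    connection_limit: int

    @property
    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def edge_table(self):
        import pandas as pd

        rows = [
            {"a": a, "b": b, "steps": d["steps"],
             "inferred_intermediates": d["inferred_intermediates"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["a", "b", "steps", "inferred_intermediates"])

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, data in g.nodes(data=True):
            comp = data.pop("populations", None)
            if comp is not None:
                data["populations"] = ";".join(f"{k}:{v}" for k, v in comp.items())
        nx.write_graphml(g, str(path))


def build_parsimony_network(
    haps: HaplotypeSet,
    steps: np.ndarray | None = None,
    limit: int | None = None,
    confidence: float = 0.95,
) -> NetworkGraph:
    """Join haplotypes by increasing step count into a parsimony network.

    Pairs are processed level by level in order of increasing step count
    (lexicographic id order inside a level, for determinism).  A link is added
    when its step count is within the connection limit and the two haplotypes
    were in different components *at the start of that level*: all pairs that
    first become connectable at the same level are joined, so equally
    parsimonious alternatives (e.g. a one-step triangle) are retained as
    reticulations, while links that merely duplicate a cheaper or equal path
    built at an earlier level are redundant and dropped.  Components are never
    merged by links above the limit, so the output may be disconnected.
    """
    ids = haps.ids
    if steps is None:
        steps = step_count_matrix(haps)
    seq_length = len(next(iter(haps.haplotypes.values()))) if len(haps) else 0
    if limit is None:
        limit = parsimony_connection_limit(max(seq_length, 1), confidence)

    g = nx.Graph()
    freqs = haps.frequencies
    for i, hap in enumerate(ids):
        row = freqs.loc[hap]
        g.add_node(
            hap,
            frequency=int(row.sum()),
            populations={str(p): int(c) for p, c in row.items() if c > 0},
        )
    by_level: dict[int, list[tuple[str, str]]] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            s = int(steps[i, j])
            if 1 <= s <= limit:
                by_level.setdefault(s, []).append((ids[i], ids[j]))
    for s in sorted(by_level):
        # connectivity snapshot at level start: pairs joined within a level
        # do not suppress each other, which is what retains reticulations
        comp_of: dict[str, int] = {}
        for k, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_of[node] = k
        for a, b in sorted(by_level[s]):
            if comp_of[a] != comp_of[b]:
                g.add_edge(a, b, steps=s, inferred_intermediates=s - 1)
    return NetworkGraph(graph=g, connection_limit=int(limit))
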