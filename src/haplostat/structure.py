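"""Population structure: pairwise distances, Hudson's FST, AMOVA and SAMOVA.

The hierarchical analysis of molecular variance partitions squared
pairwise haplotype distances into among-group, among-population-within-
group and within-population components with unequal-sample-size
coefficients, yielding the Phi-statistics Phi_CT, Phi_SC and Phi_ST and
their permutation p-values. SAMOVA searches, by simulated annealing over
geographically contiguous groupings of populations, for the K-group
partition maximising F_CT.

For sequences compared by Hamming distance the pairwise difference count
*is* the squared Euclidean distance between site-indicator vectors, so
difference counts enter the sums of squares directly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError

from .seqio import HaplotypeTable, PopulationMap

__all__ = [
    "DistanceMatrix",
    "Partition",
    "AmovaResult",
    "SamovaResult",
    "pairwise_differences",
    "hamming_matrix",
    "hudson_fst",
    "hudson_fst_components",
    "fst_matrix",
    "amova",
    "amova_permutation_test",
    "contiguity_graph",
    "samova",
    "enumerate_contiguous_partitions",
]


# ---------------------------------------------------------------------------
# Distances


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise nucleotide differences (counts)."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if np.diag(d).any():
            raise ValueError("nonzero diagonal in distance matrix")


def hamming_matrix(seqs: list[str]) -> np.ndarray:
    """Pairwise Hamming distance counts between equal-length strings."""
    arr = np.array([list(s) for s in seqs], dtype="U1")
    n = arr.shape[0]
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        diff = (arr[i + 1 :] != arr[i]).sum(axis=1)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return d


def pairwise_differences(table: HaplotypeTable, expand: bool = False) -> DistanceMatrix:
    """Distance matrix between haplotypes, or between expanded samples.

    In expanded mode each haplotype is replicated by its total count and
    labels become ``<hapid>.<k>``.
    """
    d_hap = hamming_matrix(list(table.haplotype_sequences))
    if not expand:
        return DistanceMatrix(labels=tuple(table.haplotype_ids), d=d_hap)
    counts = np.asarray(table.counts).sum(axis=1)
    idx = np.repeat(np.arange(table.n_haplotypes), counts)
    labels = []
    for h, c in enumerate(counts):
        labels.extend(f"{table.haplotype_ids[h]}.{k + 1}" for k in range(int(c)))
    return DistanceMatrix(labels=tuple(labels), d=d_hap[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Hudson's FST


def _mean_within(seqs: list[str]) -> float:
    """Mean pairwise difference over the C(n,2) distinct pairs in a deme."""
    d = hamming_matrix(seqs)
    n = len(seqs)
    return float(d[np.triu_indices(n, k=1)].mean())


def hudson_fst_components(
    seqs_a: list[str], seqs_b: list[str]
) -> tuple[float, float]:
    """(Hw, Hb) for Hudson's FST: Hw the unweighted average of the two
    demes' mean within-deme pairwise differences (distinct pairs), Hb the
    mean between-deme pairwise difference (all cross pairs)."""
    if len(seqs_a) < 2 or len(seqs_b) < 2:
        raise ValueError("hudson_fst requires n >= 2 on each side")
    hw = 0.5 * (_mean_within(seqs_a) + _mean_within(seqs_b))
    arr_a = np.array([list(s) for s in seqs_a], dtype="U1")
    arr_b = np.array([list(s) for s in seqs_b], dtype="U1")
    hb = float(
        np.mean(
            [(arr_a[i] != arr_b[j]).sum() for i in range(len(seqs_a)) for j in range(len(seqs_b))]
        )
    )
    return hw, hb


def hudson_fst(seqs_a: list[str], seqs_b: list[str]) -> float:
    """Hudson/Slatkin/Maddison FST = 1 - Hw/Hb from sequence samples.

    Undifferentiated demes give values near 0 (the estimator has a small
    negative small-sample offset, -1/(n-1) for literal duplicate demes).
    Negative estimates are returned as computed; identical monomorphic
    demes (Hb = 0) yield NaN.
    """
    hw, hb = hudson_fst_components(seqs_a, seqs_b)
    if hb == 0.0:
        return float("nan")
    return 1.0 - hw / hb


def fst_matrix(
    table: HaplotypeTable,
    popmap: PopulationMap,
    level: str = "population",
    group_method: str = "pooled",
) -> "pd.DataFrame":
    """Pairwise FST among populations or among groups.

    At group level, ``pooled`` (default) pools all sequences of a group
    into one deme; ``average`` averages the pairwise population FSTs
    across the two groups instead.
    """
    import pandas as pd

    if level == "population":
        units = [(p, [p]) for p in table.populations]
    elif level == "group":
        units = [
            (g, [p for p in table.populations if popmap.group_of(p) == g])
            for g in popmap.groups
        ]
    else:
        raise ValueError(f"unknown level {level!r}")
    names = [u for u, _ in units]
    out = np.full((len(units), len(units)), np.nan)
    for i, (_, mi) in enumerate(units):
        for j in range(i + 1, len(units)):
            mj = units[j][1]
            if level == "group" and group_method == "average":
                vals = []
                for pi_ in mi:
                    for pj in mj:
                        si, sj = table.expand([pi_]), table.expand([pj])
                        if len(si) >= 2 and len(sj) >= 2:
                            vals.append(hudson_fst(si, sj))
                val = float(np.nanmean(vals)) if vals else float("nan")
            else:
                si, sj = table.expand(mi), table.expand(mj)
                if len(si) < 2 or len(sj) < 2:
                    val = float("nan")
                else:
                    val = hudson_fst(si, sj)
            out[i, j] = out[j, i] = val
    return pd.DataFrame(out, index=names, columns=names)


# ---------------------------------------------------------------------------
# AMOVA


@dataclass(frozen=True)
class Partition:
    """Assignment of populations to groups 0..K-1."""

    mapping: dict[str, int]

    def __post_init__(self) -> None:
        groups = set(self.mapping.values())
        if groups != set(range(len(groups))):
            raise ValueError("group indices must be 0..K-1 with no gaps")

    @property
    def k(self) -> int:
        return len(set(self.mapping.values()))

    @classmethod
    def from_groups(cls, groups: list[list[str]]) -> "Partition":
        mapping = {}
        for g, members in enumerate(groups):
            if not members:
                raise ValueError("empty group in partition")
            for p in members:
                mapping[p] = g
        return cls(mapping)

    def groups_of(self, populations: list[str]) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.k)]
        for p in populations:
            out[self.mapping[p]].append(p)
        return out

    def canonical(self, populations: list[str]) -> tuple[tuple[int, ...], ...]:
        """Canonical form: groups as sorted population-index tuples, sorted
        by their smallest member. Used for deterministic tie-breaking."""
        idx = {p: i for i, p in enumerate(populations)}
        groups = [tuple(sorted(idx[p] for p in g)) for g in self.groups_of(populations)]
        return tuple(sorted(groups))


@dataclass
class AmovaResult:
    """Variance components and Phi-statistics of a three-level AMOVA."""

    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    phi_ct: float
    phi_sc: float
    phi_st: float
    ssd: dict[str, float]
    df: dict[str, int]
    p_values: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.sigma_a + self.sigma_b + self.sigma_c

    @property
    def percentages(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {"among_groups": 0.0, "among_pops_within_groups": 0.0, "within_pops": 0.0}
        return {
            "among_groups": 100.0 * self.sigma_a / tot,
            "among_pops_within_groups": 100.0 * self.sigma_b / tot,
            "within_pops": 100.0 * self.sigma_c / tot,
        }


def _pop_level_arrays(table: HaplotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Population-pair sums of squared distances and population sizes.

    S[p, q] = sum over individuals i in p, j in q of d2(i, j), both orders,
    computed as C^T D C from the haplotype count matrix C and haplotype
    distance matrix D.
    """
    d_hap = hamming_matrix(list(table.haplotype_sequences))
    c = np.asarray(table.counts, dtype=float)
    s = c.T @ d_hap @ c
    n = c.sum(axis=0)
    return s, n


def _components(
    s: np.ndarray, n: np.ndarray, labels: np.ndarray, k: int
) -> tuple[float, float, float, dict[str, float], dict[str, int]]:
    """Solve variance components from population-pair sums of squares."""
    n_tot = float(n.sum())
    p_count = len(n)
    ssd_t = float(s.sum()) / (2.0 * n_tot)
    ssd_wp = float(sum(s[p, p] / (2.0 * n[p]) for p in range(p_count) if n[p] > 0))
    ssd_wg = 0.0
    sg_over_ng = 0.0  # sum over groups of (sum n_p^2)/N_g
    ng2 = 0.0
    for g in range(k):
        idx = np.nonzero(labels == g)[0]
        n_g = float(n[idx].sum())
        if n_g == 0:
            continue
        ssd_wg += float(s[np.ix_(idx, idx)].sum()) / (2.0 * n_g)
        sg_over_ng += float((n[idx] ** 2).sum()) / n_g
        ng2 += n_g**2
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_t - ssd_wg

    df_wp = int(n_tot) - p_count
    df_ap = p_count - k
    df_ag = k - 1

    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
    if df_ap > 0:
        n1 = (n_tot - sg_over_ng) / df_ap
        ms_ap = ssd_ap / df_ap
        sigma_b = (ms_ap - sigma_c) / n1 if n1 > 0 else 0.0
    else:
        sigma_b = 0.0
    n2 = (sg_over_ng - float((n**2).sum()) / n_tot) / df_ag
    n3 = (n_tot - ng2 / n_tot) / df_ag
    ms_ag = ssd_ag / df_ag
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3 if n3 > 0 else 0.0

    ssd = {
        "among_groups": ssd_ag,
        "among_pops_within_groups": ssd_ap,
        "within_pops": ssd_wp,
        "total": ssd_t,
    }
    df = {"among_groups": df_ag, "among_pops_within_groups": df_ap, "within_pops": df_wp}
    return sigma_a, sigma_b, sigma_c, ssd, df


def _phi(sigma_a: float, sigma_b: float, sigma_c: float) -> tuple[float, float, float]:
    tot = sigma_a + sigma_b + sigma_c
    phi_ct = sigma_a / tot if tot != 0 else float("nan")
    phi_st = (sigma_a + sigma_b) / tot if tot != 0 else float("nan")
    denom = sigma_b + sigma_c
    phi_sc = sigma_b / denom if denom != 0 else float("nan")
    return phi_ct, phi_sc, phi_st


def amova(
    table: HaplotypeTable, popmap: PopulationMap, partition: Partition | dict[str, int]
) -> AmovaResult:
    """Three-level AMOVA from squared pairwise haplotype differences.

    Negative variance components are retained as computed (not truncated);
    percentages are taken over the raw total.
    """
    if isinstance(partition, dict):
        partition = Partition(partition)
    pops = list(table.populations)
    if len(pops) < 2:
        raise ValueError("AMOVA requires at least two populations")
    missing = [p for p in pops if p not in partition.mapping]
    if missing:
        raise ValueError(f"partition does not cover populations: {missing}")
    s, n = _pop_level_arrays(table)
    labels = np.array([partition.mapping[p] for p in pops])
    sigma_a, sigma_b, sigma_c, ssd, df = _components(s, n, labels, partition.k)
    phi_ct, phi_sc, phi_st = _phi(sigma_a, sigma_b, sigma_c)
    return AmovaResult(sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st, ssd, df)


def _perm_count_ct(labels: np.ndarray, k: int) -> float:
    """Number of distinct reassignments of populations to groups of the
    same sizes (coarse lower bound on the permutation space)."""
    sizes = [int((labels == g).sum()) for g in range(k)]
    total = math.factorial(len(labels))
    for s_ in sizes:
        total //= math.factorial(s_)
    return float(total)


def amova_permutation_test(
    table: HaplotypeTable,
    popmap: PopulationMap,
    partition: Partition | dict[str, int],
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA with permutation p-values for Phi_CT, Phi_SC and Phi_ST.

    Permutation schemes: Phi_CT permutes whole populations among groups;
    Phi_SC permutes individuals among populations within groups; Phi_ST
    permutes individuals among populations. p = (#{perm >= obs} + 1) /
    (n_perm + 1). A ``degenerate`` flag is set in ``p_values`` when the
    permutation space for Phi_CT has fewer than 20 distinct states.
    """
    if isinstance(partition, dict):
        partition = Partition(partition)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    result = amova(table, popmap, partition)
    pops = list(table.populations)
    labels = np.array([partition.mapping[p] for p in pops])
    k = partition.k
    d_hap = hamming_matrix(list(table.haplotype_sequences))
    c = np.asarray(table.counts, dtype=float)
    n = c.sum(axis=0)

    # individual-level representation: haplotype index per individual + pop
    hap_of_ind = []
    pop_of_ind = []
    for h in range(c.shape[0]):
        for p in range(c.shape[1]):
            cnt = int(c[h, p])
            hap_of_ind.extend([h] * cnt)
            pop_of_ind.extend([p] * cnt)
    hap_of_ind = np.array(hap_of_ind)
    pop_of_ind = np.array(pop_of_ind)

    def components_for(c_mat: np.ndarray, lab: np.ndarray):
        s = c_mat.T @ d_hap @ c_mat
        return _components(s, c_mat.sum(axis=0), lab, k)

    ge_ct = ge_sc = ge_st = 0
    for _ in range(n_perm):
        # Phi_CT: permute population labels among groups
        perm_lab = labels[rng.permutation(len(labels))]
        sa, sb, sc_, _, _ = components_for(c, perm_lab)
        p_ct, _, _ = _phi(sa, sb, sc_)
        if np.isfinite(p_ct) and np.isfinite(result.phi_ct) and p_ct >= result.phi_ct:
            ge_ct += 1

        # Phi_SC: permute individuals among populations within their group
        new_pop = pop_of_ind.copy()
        for g in range(k):
            pops_g = np.nonzero(labels == g)[0]
            mask = np.isin(pop_of_ind, pops_g)
            new_pop[mask] = new_pop[mask][rng.permutation(int(mask.sum()))]
        c_perm = np.zeros_like(c)
        np.add.at(c_perm, (hap_of_ind, new_pop), 1.0)
        sa, sb, sc_, _, _ = components_for(c_perm, labels)
        _, p_sc, _ = _phi(sa, sb, sc_)
        if np.isfinite(p_sc) and np.isfinite(result.phi_sc) and p_sc >= result.phi_sc:
            ge_sc += 1

        # Phi_ST: permute individuals among all populations
        new_pop = pop_of_ind[rng.permutation(len(pop_of_ind))]
        c_perm = np.zeros_like(c)
        np.add.at(c_perm, (hap_of_ind, new_pop), 1.0)
        sa, sb, sc_, _, _ = components_for(c_perm, labels)
        _, _, p_st = _phi(sa, sb, sc_)
        if np.isfinite(p_st) and np.isfinite(result.phi_st) and p_st >= result.phi_st:
            ge_st += 1

    result.p_values = {
        "phi_ct": (ge_ct + 1) / (n_perm + 1),
        "phi_sc": (ge_sc + 1) / (n_perm + 1),
        "phi_st": (ge_st + 1) / (n_perm + 1),
        "degenerate": float(_perm_count_ct(labels, k) < 20),
    }
    return result


# ---------------------------------------------------------------------------
# Geographic contiguity


def contiguity_graph(popmap: PopulationMap) -> nx.Graph:
    """Delaunay-triangulation neighbour graph over population coordinates.

    Coordinates (lon, lat) are treated as planar. Degenerate geometry
    (collinear points, < 3 populations) falls back to a nearest-neighbour
    chain; duplicated coordinates are deterministically jittered by 1e-6
    degrees.
    """
    coords = popmap.coordinates()
    pops = list(coords)
    if len(pops) < 2:
        raise ValueError("contiguity graph requires >= 2 populations")
    pts = np.array([[coords[p][1], coords[p][0]] for p in pops], dtype=float)
    # deterministic jitter for exact duplicates
    seen: dict[tuple[float, float], int] = {}
    for i in range(len(pts)):
        key = (pts[i, 0], pts[i, 1])
        if key in seen:
            seen[key] += 1
            pts[i] += 1e-6 * seen[key]
        else:
            seen[key] = 0
    g = nx.Graph()
    g.add_nodes_from(pops)
    if len(pops) == 2:
        g.add_edge(pops[0], pops[1])
        return g
    try:
        tri = Delaunay(pts)
    except QhullError:
        tri = None
    if tri is not None:
        for simplex in tri.simplices:
            for a, b in itertools.combinations(simplex, 2):
                g.add_edge(pops[a], pops[b])
        return g
    # collinear fallback: greedy nearest-neighbour chain
    start = int(np.lexsort((pts[:, 1], pts[:, 0]))[0])
    unvisited = set(range(len(pops))) - {start}
    current = start
    while unvisited:
        nxt = min(unvisited, key=lambda j: float(((pts[j] - pts[current]) ** 2).sum()))
        g.add_edge(pops[current], pops[nxt])
        unvisited.discard(nxt)
        current = nxt
    return g


# ---------------------------------------------------------------------------
# SAMOVA


@dataclass
class SamovaResult:
    """Best contiguous K-partition found by simulated annealing."""

    k: int
    partition: Partition
    f_ct: float
    p_value: float | None
    trace: list[tuple[int, float]]  # (run index, final F_CT)
    rng_seed: int | None


def _is_connected(graph: nx.Graph, members: list[str]) -> bool:
    if not members:
        return False
    sub = graph.subgraph(members)
    return nx.is_connected(sub)


def _random_contiguous_partition(
    graph: nx.Graph, pops: list[str], k: int, rng: np.random.Generator
) -> np.ndarray:
    """Region-growing random initialisation of a contiguous K-partition."""
    labels = np.full(len(pops), -1)
    idx = {p: i for i, p in enumerate(pops)}
    seeds = rng.choice(len(pops), size=k, replace=False)
    for g, s_ in enumerate(seeds):
        labels[s_] = g
    while (labels == -1).any():
        frontier = [
            (i, labels[idx[nbr]])
            for i, p in enumerate(pops)
            if labels[i] == -1
            for nbr in graph.neighbors(p)
            if labels[idx[nbr]] != -1
        ]
        if not frontier:  # disconnected graph guarded earlier; safety net
            i = int(np.nonzero(labels == -1)[0][0])
            labels[i] = int(rng.integers(k))
            continue
        i, g = frontier[int(rng.integers(len(frontier)))]
        labels[i] = int(g)
    return labels


def _group_connected(
    neighbors: dict[int, list[int]], labels: np.ndarray, group: int, skip: int
) -> bool:
    """BFS connectivity of {i : labels[i] == group, i != skip} over integer
    adjacency lists; fast path for the annealing inner loop."""
    members = [i for i in range(len(labels)) if labels[i] == group and i != skip]
    if not members:
        return False
    member_set = set(members)
    seen = {members[0]}
    stack = [members[0]]
    while stack:
        v = stack.pop()
        for w in neighbors[v]:
            if w in member_set and w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(members)


def _fct_of_labels(s: np.ndarray, n: np.ndarray, labels: np.ndarray, k: int) -> float:
    sigma_a, sigma_b, sigma_c, _, _ = _components(s, n, labels, k)
    tot = sigma_a + sigma_b + sigma_c
    return sigma_a / tot if tot != 0 else float("-inf")


def samova(
    table: HaplotypeTable,
    popmap: PopulationMap,
    k: int,
    n_runs: int = 100,
    seed: int | None = None,
    n_iter: int = 10_000,
    t0: float = 1.0,
    cooling: float = 0.99,
    cool_every: int = 100,
    n_perm: int = 0,
    graph: nx.Graph | None = None,
) -> SamovaResult:
    """Spatial AMOVA: maximise F_CT over contiguous K-partitions.

    Runs ``n_runs`` independent simulated-annealing searches, each started
    from a random contiguous partition; proposals move one boundary
    population to an adjacent group, rejected outright when they would
    disconnect or empty the source group. Improvements are always
    accepted, otherwise acceptance probability is exp(dF/T) under
    geometric cooling (factor ``cooling`` every ``cool_every`` proposals).
    Ties in the best F_CT break to the lexicographically smallest
    canonical partition. ``n_perm > 0`` adds a permutation p-value for the
    winning partition.
    """
    pops = list(table.populations)
    if not 2 <= k <= len(pops):
        raise ValueError(f"K={k} outside 2..{len(pops)}")
    if graph is None:
        graph = contiguity_graph(popmap)
    if not nx.is_connected(graph):
        raise ValueError("contiguity graph is disconnected")
    s, n = _pop_level_arrays(table)
    idx = {p: i for i, p in enumerate(pops)}
    neighbors = {i: [idx[q] for q in graph.neighbors(p)] for p, i in idx.items()}
    rng_master = np.random.default_rng(seed)
    run_seeds = rng_master.integers(0, 2**31 - 1, size=n_runs)

    best_f = float("-inf")
    best_labels: np.ndarray | None = None
    trace: list[tuple[int, float]] = []

    for run in range(n_runs):
        rng = np.random.default_rng(int(run_seeds[run]))
        labels = _random_contiguous_partition(graph, pops, k, rng)
        f = _fct_of_labels(s, n, labels, k)
        run_best_f, run_best_labels = f, labels.copy()
        temp = t0
        for it in range(n_iter):
            if it and it % cool_every == 0:
                temp *= cooling
            i = int(rng.integers(len(pops)))
            g_from = labels[i]
            # candidate target groups among neighbours
            targets = sorted({int(labels[j]) for j in neighbors[i] if labels[j] != g_from})
            if not targets:
                continue
            g_to = targets[int(rng.integers(len(targets)))]
            if not _group_connected(neighbors, labels, int(g_from), i):
                continue
            labels[i] = g_to
            f_new = _fct_of_labels(s, n, labels, k)
            df_ = f_new - f
            if df_ > 0 or rng.random() < math.exp(min(df_ / max(temp, 1e-12), 0.0)):
                f = f_new
                if f > run_best_f:
                    run_best_f, run_best_labels = f, labels.copy()
            else:
                labels[i] = g_from
        trace.append((run, run_best_f))
        if run_best_f > best_f + 1e-12:
            best_f, best_labels = run_best_f, run_best_labels
        elif abs(run_best_f - best_f) <= 1e-12 and best_labels is not None:
            cand = _labels_to_partition(run_best_labels, pops)
            cur = _labels_to_partition(best_labels, pops)
            if cand.canonical(pops) < cur.canonical(pops):
                best_labels = run_best_labels

    assert best_labels is not None
    partition = _labels_to_partition(best_labels, pops)
    p_value = None
    if n_perm > 0:
        res = amova_permutation_test(
            table, popmap, partition, n_perm=n_perm, seed=int(rng_master.integers(2**31 - 1))
        )
        p_value = res.p_values["phi_ct"]
    return SamovaResult(k=k, partition=partition, f_ct=best_f, p_value=p_value,
                        trace=trace, rng_seed=seed)


def _labels_to_partition(labels: np.ndarray, pops: list[str]) -> Partition:
    # renumber groups by order of first appearance for a canonical mapping
    remap: dict[int, int] = {}
    mapping: dict[str, int] = {}
    for p, lab in zip(pops, labels):
        g = remap.setdefault(int(lab), len(remap))
        mapping[p] = g
    return Partition(mapping)


def enumerate_contiguous_partitions(
    graph: nx.Graph, pops: list[str], k: int
) -> list[Partition]:
    """All partitions of ``pops`` into K non-empty contiguous groups.

    Exhaustive (set-partition enumeration filtered by subgraph
    connectivity); intended for small problems and as a test oracle.
    """
    results = []

    def partitions(collection: list[str]):
        if len(collection) == 1:
            yield [collection]
            return
        first, rest = collection[0], collection[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
            yield [[first]] + smaller

    for part in partitions(list(pops)):
        if len(part) != k:
            continue
        if all(_is_connected(graph, g) for g in part):
            results.append(Partition.from_groups(part))
    return results
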