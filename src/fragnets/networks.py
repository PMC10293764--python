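"""Fragments networks: building, grading and selection.

A fragments network fixes one candidate formula per peak (the nodes) and
draws an undirected edge between every pair whose formulas are chemically
consistent -- one a proper sub-formula of the other, the difference being
the neutral loss.  The *grade* is the number of edges; the annotation of
the whole spectrum is the assignment with the maximum grade, ties broken by
the smallest summed mass error and then lexicographically, so selection is
deterministic.

A spectrum with ``k_i`` candidates at peak ``i`` spans ``prod(k_i)``
networks.  Exhaustive enumeration is exact and is kept as the reference
mode (with a configurable cap, implemented as a depth-first search with an
upper-bound prune); above the cap a deterministic greedy hill-climb with
single-candidate perturbation restarts takes over.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

from .chem import FormulaVector, consistent, format_formula, neutral_loss
from .space import Candidate

__all__ = [
    "FragmentsNetwork",
    "NetworkCapExceeded",
    "count_networks",
    "build_network",
    "select_best",
]


class NetworkCapExceeded(RuntimeError):
    """Exact enumeration would exceed the configured assignment cap."""


@dataclass(frozen=True)
class FragmentsNetwork:
    """One candidate per peak plus all chemically consistent pairs."""

    assignment: tuple[Candidate, ...]
    edges: frozenset[tuple[int, int]]
    grade: int
    total_error_ppm: float

    @property
    def n_nodes(self) -> int:
        return len(self.assignment)

    def degree(self, i: int) -> int:
        return sum(1 for e in self.edges if i in e)

    def formulas(self) -> tuple[str, ...]:
        return tuple(format_formula(c.formula) for c in self.assignment)

    def neutral_losses(self) -> dict[tuple[int, int], FormulaVector]:
        """Neutral-loss formula per edge, keyed (parent_idx, child_idx)."""
        out = {}
        for i, j in self.edges:
            a, b = self.assignment[i].formula, self.assignment[j].formula
            if consistent(a, b):
                out[(i, j)] = neutral_loss(a, b)
            else:
                out[(j, i)] = neutral_loss(b, a)
        return out

    def to_graph(self):
        """The network as a ``networkx.Graph`` with formula/mass attributes."""
        import networkx as nx

        g = nx.Graph()
        for i, cand in enumerate(self.assignment):
            g.add_node(i, formula=format_formula(cand.formula),
                       predicted_mz=cand.predicted_mz,
                       error_ppm=cand.error_ppm)
        for (i, j), loss in self.neutral_losses().items():
            g.add_edge(i, j, neutral_loss=format_formula(loss))
        return g

    def _key(self) -> tuple:
        return (-self.grade, self.total_error_ppm, self.formulas())


def count_networks(candidate_counts: Sequence[int]) -> int:
    """Number of distinct assignments: the product of per-peak candidate
    counts.  Peaks without candidates are excluded from network construction
    upstream, so every count must be at least one here."""
    if any(c < 1 for c in candidate_counts):
        raise ValueError("every peak entering network construction needs >= 1 candidate")
    return math.prod(candidate_counts)


def build_network(assignment: Sequence[Candidate]) -> FragmentsNetwork:
    """Materialise the network for one assignment: edges are all unordered
    pairs whose ions are consistent in either direction."""
    cands = tuple(assignment)
    edges = set()
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            a, b = cands[i].formula, cands[j].formula
            if consistent(a, b) or consistent(b, a):
                edges.add((i, j))
    return FragmentsNetwork(
        assignment=cands,
        edges=frozenset(edges),
        grade=len(edges),
        total_error_ppm=sum(c.error_ppm for c in cands),
    )


def _pairwise_tables(candidates_per_peak: Sequence[Sequence[Candidate]]):
    """cons[i][j][a][b] == 1 iff candidate a of peak i and candidate b of
    peak j are consistent in either direction (i < j)."""
    n = len(candidates_per_peak)
    cons: dict[tuple[int, int], list[list[int]]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            table = [
                [
                    1 if (consistent(a.formula, b.formula)
                          or consistent(b.formula, a.formula)) else 0
                    for b in candidates_per_peak[j]
                ]
                for a in candidates_per_peak[i]
            ]
            cons[(i, j)] = table
    return cons


def _select_exact(candidates_per_peak, cap):
    n = len(candidates_per_peak)
    total = count_networks([len(c) for c in candidates_per_peak])
    if total > cap:
        raise NetworkCapExceeded(
            f"{total} assignments exceed the exact-mode cap of {cap}; "
            "use greedy mode or tighten the tolerances"
        )
    cons = _pairwise_tables(candidates_per_peak)
    # Upper bound on edges still obtainable once peaks 0..k-1 are fixed:
    # every pair involving at least one unfixed peak could still connect,
    # i.e. C(n,2) - C(k,2).
    remaining_bound = [n * (n - 1) // 2 - k * (k - 1) // 2 for k in range(n + 1)]
    best: FragmentsNetwork | None = None
    choice = [0] * n

    def descend(k: int, partial_grade: int, partial_err: float) -> None:
        nonlocal best
        if best is not None and partial_grade + remaining_bound[k] < best.grade:
            return
        if k == n:
            net = build_network([candidates_per_peak[i][choice[i]] for i in range(n)])
            if best is None or net._key() < best._key():
                best = net
            return
        for a in range(len(candidates_per_peak[k])):
            gain = sum(cons[(i, k)][choice[i]][a] for i in range(k))
            choice[k] = a
            descend(k + 1, partial_grade + gain,
                    partial_err + candidates_per_peak[k][a].error_ppm)

    descend(0, 0, 0.0)
    assert best is not None
    return best


def _select_greedy(candidates_per_peak):
    n = len(candidates_per_peak)

    def climb(start: Sequence[int]) -> FragmentsNetwork:
        current = list(start)
        net = build_network([candidates_per_peak[i][a] for i, a in enumerate(current)])
        improved = True
        while improved:
            improved = False
            best_move = None
            best_net = net
            for i in range(n):
                for a in range(len(candidates_per_peak[i])):
                    if a == current[i]:
                        continue
                    trial = current.copy()
                    trial[i] = a
                    cand_net = build_network(
                        [candidates_per_peak[k][t] for k, t in enumerate(trial)]
                    )
                    if cand_net._key() < best_net._key():
                        best_net, best_move = cand_net, trial
            if best_move is not None:
                current, net, improved = best_move, best_net, True
        return net

    # deterministic seed: minimum-error candidate at every node (enumerate_
    # formulas sorts by |error| so index 0 is that candidate)
    seed = [0] * n
    best = climb(seed)
    # restart from every single-candidate perturbation of the seed optimum
    base = [candidates_per_peak[i].index(c) if c in candidates_per_peak[i] else 0
            for i, c in enumerate(best.assignment)]
    for i in range(n):
        for a in range(len(candidates_per_peak[i])):
            if a == base[i]:
                continue
            start = base.copy()
            start[i] = a
            net = climb(start)
            if net._key() < best._key():
                best = net
    return best


def select_best(
    candidates_per_peak: Sequence[Sequence[Candidate]],
    mode: str = "exact",
    cap: int = 10**6,
) -> FragmentsNetwork:
    """The maximum-grade fragments network over all assignments.

    ``mode='exact'`` enumerates (depth-first with an upper-bound prune) and
    is guaranteed optimal but refuses instances above ``cap`` assignments;
    ``mode='greedy'`` hill-climbs from the minimum-error seed with
    single-candidate perturbation restarts and is deterministic but only
    locally optimal.
    """
    if not candidates_per_peak or any(len(c) == 0 for c in candidates_per_peak):
        raise ValueError("every peak entering selection needs at least one candidate")
    if mode == "exact":
        return _select_exact(candidates_per_peak, cap)
    if mode == "greedy":
        return _select_greedy(candidates_per_peak)
    raise ValueError("mode must be 'exact' or 'greedy'")
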