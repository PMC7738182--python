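"""Evolutionary trajectory enumeration and mutation-network export.

A trajectory is an ordering in which a variant's n substitutions are
acquired one at a time; there are n! of them. A step is "improving" when
the fold-improvement rises by more than a relative threshold (default 16%,
the typical EC50 measurement error, so a smaller gain is indistinguishable
from noise). A trajectory accessible to stepwise selection must improve at
every step. The greedy most-plausible path picks, at each point, the
remaining substitution whose addition yields the fittest next genotype —
which also selects the least-deleterious option when no improvement exists.

The full subset lattice is exported as a directed mutation network (2^n
nodes, n*2^(n-1) edges from each genotype to its one-substitution
supersets) via networkx for rendering in standard graph tools.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterator, Literal, Sequence

import networkx as nx

from .landscape import FitnessLandscape, Substitution

__all__ = [
    "StepRule",
    "TrajectoryReport",
    "enumerate_trajectories",
    "classify_step",
    "count_accessible",
    "greedy_plausible_path",
    "build_network",
    "export_network",
    "read_edge_csv",
]

_MAX_N = 12  # 12! ~ 4.8e8 permutations; beyond this enumeration is impractical


@dataclass(frozen=True)
class StepRule:
    """Relative-improvement threshold for one evolutionary step.

    A step from fold f to fold f' improves iff f' > f * (1 + threshold),
    strictly. The default 0.16 treats gains within the ~16% average EC50
    measurement error as not demonstrably upward.
    """

    threshold: float = 0.16

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError(f"threshold must be >= 0, got {self.threshold}")


@dataclass(frozen=True)
class TrajectoryReport:
    total: int
    accessible_count: int
    accessible_paths: tuple[tuple[Substitution, ...], ...] | None = None
    greedy_path: tuple[Substitution, ...] | None = None
    skipped: int = 0

    @property
    def accessible_fraction(self) -> float:
        return self.accessible_count / self.total


def enumerate_trajectories(n: int) -> Iterator[tuple[int, ...]]:
    """Iterate all n! orderings of n substitution indices, lexicographically.

    Yields index tuples so callers can map onto any substitution list
    without materialising the factorial-sized collection.
    """
    if not 1 <= n <= _MAX_N:
        raise ValueError(
            f"n={n} outside [1, {_MAX_N}]: trajectory enumeration is factorial in n"
        )
    return permutations(range(n))


def classify_step(f_from: float, f_to: float, rule: StepRule = StepRule()) -> bool:
    """Is the step from fold f_from to f_to an improvement under the rule?"""
    if not (f_from > 0 and f_to > 0):
        raise ValueError("fold values must be positive")
    return f_to > f_from * (1.0 + rule.threshold)


def count_accessible(
    landscape: FitnessLandscape,
    rule: StepRule = StepRule(),
    list_accessible: bool = False,
    allow_incomplete: bool = False,
) -> TrajectoryReport:
    """Count trajectories whose every step improves under the rule.

    Requires a complete landscape by default; with ``allow_incomplete`` the
    orderings touching a missing genotype are skipped with a warning (and
    reported in ``skipped``), which biases the fraction and is opt-in only.
    """
    landscape.require_complete(allow_incomplete)
    n = landscape.n
    subs = landscape.substitutions
    means = {m: landscape.mean(m) for m in landscape.masks}
    total = math.factorial(n)
    accessible = 0
    skipped = 0
    paths: list[tuple[Substitution, ...]] = []
    for perm in enumerate_trajectories(n):
        mask = 0
        f = means[0]
        ok = True
        for i in perm:
            nxt = mask | (1 << i)
            if nxt not in means:
                skipped += 1
                ok = False
                break
            f_next = means[nxt]
            if not classify_step(f, f_next, rule):
                ok = False
                break
            mask, f = nxt, f_next
        if ok:
            accessible += 1
            if list_accessible:
                paths.append(tuple(subs[i] for i in perm))
    return TrajectoryReport(
        total=total,
        accessible_count=accessible,
        accessible_paths=tuple(paths) if list_accessible else None,
        skipped=skipped,
    )


def greedy_plausible_path(
    landscape: FitnessLandscape, allow_incomplete: bool = False
) -> tuple[Substitution, ...]:
    """The most-plausible stepwise trajectory under greedy selection.

    At each step the remaining substitution maximising the resulting
    genotype's mean fitness is chosen. When some addition improves on the
    current genotype this picks the biggest gain; when none does it picks
    the smallest loss — one rule covers both regimes. Ties break toward the
    lowest residue position for determinism.
    """
    landscape.require_complete(allow_incomplete)
    n = landscape.n
    subs = landscape.substitutions
    mask = 0
    path: list[Substitution] = []
    remaining = list(range(n))
    while remaining:
        candidates = []
        for i in remaining:
            nxt = mask | (1 << i)
            if nxt in landscape:
                # substitutions are position-sorted, so index i is the tiebreak
                candidates.append((-landscape.mean(nxt), i))
        if not candidates:
            raise ValueError(
                f"no measured genotype extends {landscape.genotype_string(mask)!r}"
            )
        _, best = min(candidates)
        mask |= 1 << best
        remaining.remove(best)
        path.append(subs[best])
    return tuple(path)


def build_network(
    landscape: FitnessLandscape,
    rule: StepRule = StepRule(),
    greedy: Sequence[Substitution] | None = None,
) -> nx.DiGraph:
    """The full mutation network as a directed graph.

    Nodes are canonical genotype strings with attributes ``layer`` (number
    of substitutions, for radial/layered layouts), ``bits`` (canonical
    bitstring) and ``fold`` (mean fold-improvement, for node colour/size).
    Edges run from each genotype to its one-substitution supersets with
    ``delta`` (fold difference), ``improving`` (step rule) and
    ``on_greedy_path`` attributes.
    """
    landscape.require_complete()
    if greedy is not None:
        valid = set(landscape.substitutions)
        if set(greedy) != valid or len(greedy) != len(valid):
            raise ValueError("greedy path must be a permutation of this landscape's substitutions")
    n = landscape.n
    greedy_edges: set[tuple[int, int]] = set()
    if greedy is not None:
        mask = 0
        for sub in greedy:
            nxt = mask | (1 << landscape._index[sub])
            greedy_edges.add((mask, nxt))
            mask = nxt
    g = nx.DiGraph(name=landscape.name)
    for mask in range(2**n):
        g.add_node(
            landscape.genotype_string(mask),
            layer=bin(mask).count("1"),
            bits=landscape.genotype_bits(mask),
            fold=landscape.mean(mask),
        )
    for mask in range(2**n):
        f_from = landscape.mean(mask)
        for i in range(n):
            if mask >> i & 1:
                continue
            nxt = mask | (1 << i)
            f_to = landscape.mean(nxt)
            g.add_edge(
                landscape.genotype_string(mask),
                landscape.genotype_string(nxt),
                delta=f_to - f_from,
                improving=classify_step(f_from, f_to, rule),
                on_greedy_path=(mask, nxt) in greedy_edges,
            )
    return g


def _write_dot(g: nx.DiGraph, path: Path) -> None:
    # minimal DOT writer: one node statement per genotype, attrs as plain k=v
    with open(path, "w") as fh:
        fh.write(f'digraph "{g.name or "mutation_network"}" {{\n')
        for node, attrs in g.nodes(data=True):
            fh.write(
                f'  "{node}" [layer={attrs["layer"]}, fold={attrs["fold"]:.6g}];\n'
            )
        for u, v, attrs in g.edges(data=True):
            style = "bold" if attrs["on_greedy_path"] else ("solid" if attrs["improving"] else "dashed")
            fh.write(
                f'  "{u}" -> "{v}" [delta={attrs["delta"]:.6g}, '
                f'improving={str(attrs["improving"]).lower()}, style={style}];\n'
            )
        fh.write("}\n")


def export_network(
    network: nx.DiGraph,
    fmt: Literal["graphml", "dot", "edge-csv"],
    path: str | Path,
) -> None:
    """Write the network as GraphML, DOT, or an edge-list CSV."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "dot":
        _write_dot(network, path)
    elif fmt == "edge-csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["from", "to", "delta", "improving", "on_greedy_path"])
            for u, v, attrs in network.edges(data=True):
                writer.writerow(
                    [u, v, f"{attrs['delta']:.12g}", attrs["improving"], attrs["on_greedy_path"]]
                )
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected graphml, dot, or edge-csv)")


def read_edge_csv(path: str | Path) -> nx.DiGraph:
    """Rebuild network topology and edge attributes from an edge-list CSV."""
    g = nx.DiGraph()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            g.add_edge(
                row["from"],
                row["to"],
                delta=float(row["delta"]),
                improving=row["improving"] == "True",
                on_greedy_path=row["on_greedy_path"] == "True",
            )
    return g
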