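"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: brute-force
scans, exhaustive closures and (coarse-to-fine) grid searches.
"""

from __future__ import annotations

import itertools
from typing import Callable, Mapping, Sequence

import numpy as np


def lca_by_path_intersection(tree, taxa) -> str:
    """Deepest member of the intersection of root-paths."""
    common = None
    for t in taxa:
        ancestors = set(tree.path_from_root(t))
        common = ancestors if common is None else common & ancestors
    assert common
    return max(common, key=tree.depth)


def pfd_prefix_by_scan(evalues: Sequence[float], target: float) -> int:
    """Largest rank r (over all ranks) with E_r / r <= target."""
    ranked = sorted(evalues)
    best = 0
    for r in range(1, len(ranked) + 1):
        if ranked[r - 1] / r <= target:
            best = r
    return best


def components_by_matrix_closure(n: int, adjacency: np.ndarray) -> list[frozenset[int]]:
    """Connected components via boolean transitive closure of the adjacency matrix."""
    reach = adjacency.astype(bool) | np.eye(n, dtype=bool)
    for _ in range(n):
        new = reach | (reach @ reach)
        if (new == reach).all():
            break
        reach = new
    seen: set[int] = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        comp = frozenset(np.flatnonzero(reach[i]).tolist())
        seen.update(comp)
        comps.append(comp)
    return comps


def stage1_loglik(groups: Mapping[frozenset, float], w: Mapping[str, float]) -> float:
    return sum(gw * np.log(sum(w[t] for t in taxa)) for taxa, gw in groups.items())


def grid_argmax_1d(f: Callable[[float], float], step: float = 1e-5) -> float:
    """Exhaustive 1-D grid search over (0, 1)."""
    grid = np.arange(step, 1.0, step)
    values = np.array([f(x) for x in grid])
    return float(grid[np.argmax(values)])


def grid_argmax_nd(
    f: Callable[[tuple[float, ...]], float],
    n_params: int,
    coarse: float = 1e-2,
    fine: float = 1e-5,
) -> tuple[float, ...]:
    """Coarse-to-fine grid search over (0,1)^n; each pass refines the window
    around the current argmax until the requested resolution is reached."""
    lo = np.zeros(n_params)
    hi = np.ones(n_params)
    step = coarse
    best = None
    while True:
        axes = [np.arange(max(l, 1e-9) + step, h, step) for l, h in zip(lo, hi)]
        axes = [a if len(a) else np.array([(l + h) / 2]) for a, l, h in zip(axes, lo, hi)]
        best = max(itertools.product(*axes), key=f)
        if step <= fine:
            return tuple(float(x) for x in best)
        lo = np.maximum(0.0, np.array(best) - 2 * step)
        hi = np.minimum(1.0, np.array(best) + 2 * step)
        step /= 10.0
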