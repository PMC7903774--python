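"""Balanced top-N selection, correlation sweeps, and directional decomposition.

The core procedure: rank proteins by their log2 fold change, take a balanced
subset (N/2 most up-regulated plus N/2 most down-regulated), and correlate
protein fold changes with each transcriptome layer's fold changes over the
subset's pairwise-complete pairs. Sweeping N downward (default 700 → 100 in
steps of 100) shows which RNA layer tracks the proteomic change ever more
tightly as the strongest protein changes are isolated; splitting the top 50
up- from the top 50 down-regulated proteins localizes the concordance by
direction.

No p-values accompany the sweep correlations: the subsets are selected by
ranking, so nominal correlation p-values would be invalid. A permutation
null (:func:`permutation_null`) is exposed instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, UndefinedCorrelationError
from .quantify import PROTEIN_COLUMN

DEFAULT_N_GRID = (700, 600, 500, 400, 300, 200, 100)
METHODS = ("pearson", "spearman")


@dataclass
class RankedSubset:
    """Balanced ranked subset of a matched-profile table.

    ``up_ids`` holds the n/2 largest positive protein fold changes in
    decreasing order, ``down_ids`` the n/2 most negative in increasing
    (most-negative-first) order. When a sign runs out, all genes of that
    sign are taken and the shortfall recorded.
    """

    n_requested: int
    up_ids: list[str]
    down_ids: list[str]
    shortfall_up: int = 0
    shortfall_down: int = 0

    @property
    def ids(self) -> list[str]:
        return self.up_ids + self.down_ids


@dataclass
class SweepResult:
    layer: str
    n: int
    r: float  # NaN when undefined; see `note`
    n_pairs: int
    method: str
    note: str | None = None


@dataclass
class DirectionalResult:
    layer: str
    direction: str  # "up" | "down"
    n: int  # requested per-direction size
    r: float
    n_pairs: int
    method: str
    n_selected: int = 0
    note: str | None = None


def select_top_balanced(profiles: pd.DataFrame, n: int) -> RankedSubset:
    """Select the n/2 most up- and n/2 most down-regulated proteins.

    Boundary ties are broken by lexical identifier order, which makes the
    selection invariant to the input row order. Genes with fold change
    exactly zero belong to neither direction.
    """
    if n <= 0 or n % 2:
        raise ParameterError(f"subset size must be a positive even integer, got {n}")
    if profiles.empty:
        raise ParameterError("profiles table is empty")
    half = n // 2
    fc = profiles[PROTEIN_COLUMN]

    up = fc[fc > 0].sort_index().sort_values(ascending=False, kind="stable")
    down = fc[fc < 0].sort_index().sort_values(ascending=True, kind="stable")
    up_ids = list(up.index[:half])
    down_ids = list(down.index[:half])
    return RankedSubset(
        n_requested=n,
        up_ids=up_ids,
        down_ids=down_ids,
        shortfall_up=half - len(up_ids),
        shortfall_down=half - len(down_ids),
    )


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, int]:
    """Pairwise-complete Pearson or Spearman correlation.

    Returns ``(r, n_pairs)``. Raises :class:`UndefinedCorrelationError`
    (never a silent NaN) when fewer than 3 complete pairs remain or either
    margin has zero variance.
    """
    if method not in METHODS:
        raise ParameterError(f"method must be one of {METHODS}, got {method!r}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ParameterError(f"length mismatch: {xa.shape} vs {ya.shape}")
    mask = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[mask], ya[mask]
    n_pairs = int(mask.sum())
    if n_pairs < 3:
        raise UndefinedCorrelationError(
            f"only {n_pairs} complete pair(s); need at least 3"
        )
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("zero variance in one of the margins")
    if method == "pearson":
        r = stats.pearsonr(xa, ya).statistic
    else:
        r = stats.spearmanr(xa, ya).statistic
    if not math.isfinite(r):
        raise UndefinedCorrelationError("correlation not finite")
    return float(r), n_pairs


def _layer_columns(profiles: pd.DataFrame, layers: Sequence[str] | None) -> list[str]:
    if layers is None:
        return [c for c in profiles.columns if c != PROTEIN_COLUMN]
    missing = [l for l in layers if l not in profiles.columns]
    if missing:
        raise ParameterError(f"layers not present in profiles: {missing}")
    return list(layers)


def sweep_concordance(
    profiles: pd.DataFrame,
    n_grid: Sequence[int] | None = None,
    layers: Sequence[str] | None = None,
    method: str = "pearson",
) -> list[SweepResult]:
    """Correlate protein vs transcript fold changes over a descending N grid.

    For each subset size N and each layer, the balanced top-N subset is
    selected by protein fold change and the correlation computed over that
    subset's pairwise-complete pairs. Undefined cells (too few pairs, zero
    variance) are recorded with ``r = NaN`` and an explanatory note instead
    of aborting the sweep. Results are ordered by (layer, N descending).
    """
    grid = list(DEFAULT_N_GRID if n_grid is None else n_grid)
    if not grid:
        raise ParameterError("n_grid must be nonempty")
    if any(b >= a for a, b in zip(grid, grid[1:])):
        raise ParameterError(f"n_grid must be strictly descending, got {grid}")
    cols = _layer_columns(profiles, layers)

    subsets = {n: select_top_balanced(profiles, n) for n in grid}
    results: list[SweepResult] = []
    for layer in cols:
        for n in grid:
            sub = profiles.loc[subsets[n].ids]
            try:
                r, n_pairs = correlate(
                    sub[PROTEIN_COLUMN], sub[layer], method=method
                )
                results.append(SweepResult(layer, n, r, n_pairs, method))
            except UndefinedCorrelationError as exc:
                n_pairs = int(
                    (sub[PROTEIN_COLUMN].notna() & sub[layer].notna()).sum()
                )
                results.append(
                    SweepResult(layer, n, float("nan"), n_pairs, method, str(exc))
                )
    return results


def directional_concordance(
    profiles: pd.DataFrame,
    n_per_direction: int = 50,
    layers: Sequence[str] | None = None,
    method: str = "pearson",
) -> list[DirectionalResult]:
    """Correlate the top up- and top down-regulated proteins separately.

    ``up`` takes the ``n_per_direction`` largest positive protein fold
    changes, ``down`` the most negative; each side is correlated against
    each transcript layer on its own. If fewer genes of a sign exist, all
    available are used and ``n_selected`` records the actual count.
    """
    if n_per_direction < 3:
        raise ParameterError(
            f"n_per_direction must be >= 3, got {n_per_direction}"
        )
    cols = _layer_columns(profiles, layers)
    subset = select_top_balanced(profiles, 2 * n_per_direction)
    sides = {"up": subset.up_ids, "down": subset.down_ids}

    results: list[DirectionalResult] = []
    for layer in cols:
        for direction, ids in sides.items():
            sub = profiles.loc[ids]
            try:
                r, n_pairs = correlate(sub[PROTEIN_COLUMN], sub[layer], method=method)
                note = None
            except UndefinedCorrelationError as exc:
                r = float("nan")
                n_pairs = int((sub[PROTEIN_COLUMN].notna() & sub[layer].notna()).sum())
                note = str(exc)
            results.append(
                DirectionalResult(
                    layer, direction, n_per_direction, r, n_pairs, method,
                    n_selected=len(ids), note=note,
                )
            )
    return results


def permutation_null(
    profiles: pd.DataFrame,
    layer: str,
    n: int,
    n_permutations: int = 200,
    method: str = "pearson",
    seed: int | None = None,
) -> np.ndarray:
    """Null distribution of the top-N sweep correlation for one layer.

    The layer's values are permuted across all profiles (breaking any
    gene-wise association while keeping both marginals), the balanced top-N
    subset is re-correlated, and the permuted r values are returned.
    Undefined permuted correlations are skipped.
    """
    if layer not in profiles.columns:
        raise ParameterError(f"layer {layer!r} not present in profiles")
    rng = np.random.default_rng(seed)
    subset = select_top_balanced(profiles, n)
    prot = profiles.loc[subset.ids, PROTEIN_COLUMN].to_numpy()
    values = profiles[layer].to_numpy()
    positions = profiles.index.get_indexer(subset.ids)

    out = []
    for _ in range(n_permutations):
        perm = rng.permutation(values)
        try:
            r, _ = correlate(prot, perm[positions], method=method)
            out.append(r)
        except UndefinedCorrelationError:
            continue
    return np.asarray(out)


def sweep_to_frame(results: Sequence[SweepResult]) -> pd.DataFrame:
    """Tabulate sweep results as ``layer, n, n_pairs, method, r``."""
    return pd.DataFrame(
        [
            {"layer": s.layer, "n": s.n, "n_pairs": s.n_pairs,
             "method": s.method, "r": s.r}
            for s in results
        ]
    )


def directional_to_frame(results: Sequence[DirectionalResult]) -> pd.DataFrame:
    """Tabulate directional results as ``layer, direction, n, n_pairs, r``."""
    return pd.DataFrame(
        [
            {"layer": d.layer, "direction": d.direction, "n": d.n,
             "n_pairs": d.n_pairs, "method": d.method, "r": d.r}
            for d in results
        ]
    )
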