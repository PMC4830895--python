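"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force (exhaustive
scans, explicit combinatorial sums, BFS flood fill) and never call the
implementation paths they check.
"""

from __future__ import annotations

from collections import deque
from math import comb
from typing import List, Tuple

import numpy as np
import pytest

from toxsignal import SimConfig


@pytest.fixture
def small_p65_config() -> SimConfig:
    """9-cell, 2-h, 256-px movie: fast enough for per-test rendering."""
    return SimConfig(seed=11, n_cells=9, image_size=256, duration_min=120)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


# ---------------------------------------------------------------------------
# peak-detection oracle: exhaustive local-maxima scan + exact prominence


def oracle_local_maxima(y: np.ndarray) -> List[int]:
    """All indices that are strict local maxima (plateaus report their
    first sample), by direct definition."""
    n = len(y)
    maxima = []
    for i in range(1, n - 1):
        if y[i] <= y[i - 1]:
            continue
        # walk right across any plateau of equal values
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        if j + 1 < n and y[j + 1] < y[i]:
            maxima.append(i)
    return maxima


def oracle_prominence(y: np.ndarray, i: int) -> float:
    """Prominence by exhaustive search for the nearest higher terrain on
    each side and the minima in between."""
    n = len(y)
    higher_left = [j for j in range(i) if y[j] > y[i]]
    lo_l = max(higher_left) + 1 if higher_left else 0
    left_min = min(y[lo_l : i + 1])
    higher_right = [j for j in range(i + 1, n) if y[j] > y[i]]
    hi_r = min(higher_right) if higher_right else n
    right_min = min(y[i:hi_r])
    return float(y[i] - max(left_min, right_min))


def oracle_detect(
    y: np.ndarray, times: np.ndarray, min_prominence: float, min_separation_min: float
) -> List[int]:
    """Full reference detector: prominence filter then greedy suppression
    (highest first, earliest on ties)."""
    cands = [i for i in oracle_local_maxima(y) if oracle_prominence(y, i) >= min_prominence]
    kept: List[int] = []
    for i in sorted(cands, key=lambda i: (-y[i], i)):
        if all(abs(times[i] - times[j]) >= min_separation_min for j in kept):
            kept.append(i)
    return sorted(kept)


# ---------------------------------------------------------------------------
# flood-fill connected-component oracle


def flood_fill_count(mask: np.ndarray) -> int:
    """Number of 8-connected foreground components via BFS."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            q = deque([(r0, c0)])
            seen[r0, c0] = True
            while q:
                r, c = q.popleft()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            q.append((rr, cc))
    return count


# ---------------------------------------------------------------------------
# hypergeometric upper-tail oracle


def hypergeom_tail(k_obs: int, universe: int, pathway: int, selected: int) -> float:
    """P(X >= k_obs) as the explicit combinatorial sum."""
    total = comb(universe, selected)
    s = 0
    for k in range(k_obs, min(pathway, selected) + 1):
        s += comb(pathway, k) * comb(universe - pathway, selected - k)
    return s / total
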