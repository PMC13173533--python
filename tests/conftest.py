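"""Shared fixtures: small synthetic panels and independent numeric oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import syncomdesign as scd


@pytest.fixture(scope="session")
def small_panel():
    """12-strain, 15-enzyme, 9-metabolite panel with its pathway map."""
    cfg = scd.GeneratorConfig(n_strains=12, n_enzymes=15, n_metabolites=9, seed=1)
    profiles, pathway_map = scd.generate_profiles(cfg)
    return profiles, pathway_map


@pytest.fixture(scope="session")
def small_graph(small_panel):
    profiles, pathway_map = small_panel
    return scd.build_graph(profiles, pathway_map)


@pytest.fixture(scope="session")
def toy_profiles():
    """Hand-written 3-strain presence table over 4 enzymes."""
    return pd.DataFrame(
        [[1, 0, 2, 0], [1, 0, 2, 0], [0, 3, 0, 1]],
        index=["A", "B", "C"],
        columns=["e1", "e2", "e3", "e4"],
    )


# ---------------------------------------------------------------------------
# independent oracles


def cox_de_boor(i: int, d: int, x: float, t: np.ndarray) -> float:
    """Textbook Cox-de Boor recursion for the i-th degree-d B-spline at x."""
    if d == 0:
        # half-open spans, closed at the right end of the domain
        if t[i] <= x < t[i + 1] or (x == t[-1] and t[i] < t[i + 1] == t[-1]):
            return 1.0
        return 0.0
    left = 0.0
    if t[i + d] > t[i]:
        left = (x - t[i]) / (t[i + d] - t[i]) * cox_de_boor(i, d - 1, x, t)
    right = 0.0
    if t[i + d + 1] > t[i + 1]:
        right = (t[i + d + 1] - x) / (t[i + d + 1] - t[i + 1]) * cox_de_boor(i + 1, d - 1, x, t)
    return left + right


def lz76_reference(s: str) -> int:
    """Definition-level LZ76 exhaustive-history parse, phrase by phrase."""
    n = len(s)
    if n == 0:
        return 0
    count, i = 0, 0
    while i < n:
        length = 1
        # extend while the candidate phrase occurs in the text preceding its
        # own last symbol (history + phrase body)
        while i + length <= n and s[i : i + length] in s[: i + length - 1]:
            length += 1
        length = min(length, n - i)
        count += 1
        i += length
    return count
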