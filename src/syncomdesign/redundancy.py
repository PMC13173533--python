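"""Functional-redundancy scoring via Lempel-Ziv complexity and Shannon entropy.

A community whose members carry near-identical enzyme repertoires compresses
well: the LZ76 phrase count of the concatenated presence/absence profiles is
barely larger than that of a single member. The redundancy score exploits
this: redundancy = 1 - C(concatenation) / sum_i C(member_i), clipped to
[0, 1], where C is the LZ76 exhaustive-history phrase count — a computable
stand-in for Kolmogorov complexity. Profiles are binarized (enzyme presence)
and serialized in a canonical order (enzymes sorted by identifier, strains
sorted by ID) so the score is invariant to how the subset is listed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RedundancyScore", "lz_complexity", "profile_entropy", "community_redundancy"]


@dataclass(frozen=True)
class RedundancyScore:
    community: tuple[str, ...]
    lz_individual: tuple[int, ...]
    lz_concat: int
    entropy_mean: float  # mean per-strain Shannon entropy of counts, bits
    redundancy: float  # in [0, 1]


def lz_complexity(s: str) -> int:
    """LZ76 exhaustive-history phrase count of a binary string.

    The production parse scans left to right; each new phrase is the shortest
    substring that has not appeared as a substring of the previously seen text
    extended by the phrase minus its last symbol (Lempel & Ziv 1976 /
    Kaspar & Schuster 1987 counting). The empty string has complexity 0.
    """
    if any(ch not in "01" for ch in s):
        raise ValueError("lz_complexity expects a string over the alphabet {0,1}")
    n = len(s)
    if n == 0:
        return 0
    c = 1  # first symbol is always a phrase
    i = 1  # start of the current phrase
    while i < n:
        # longest prefix of s[i:] occurring in s[0 : i + L - 1] (history may
        # overlap the phrase itself, per the exhaustive-history definition)
        length = 0
        while i + length < n and s.find(s[i : i + length + 1], 0, i + length) != -1:
            length += 1
        c += 1
        i += length + 1
    return c


def profile_entropy(counts, base: float = 2.0) -> float:
    """Shannon entropy (bits by default) of a nonnegative count profile."""
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("entropy of an all-zero profile is undefined")
    p = x[x > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def _binary_string(row: np.ndarray) -> str:
    return "".join("1" if v > 0 else "0" for v in row)


def community_redundancy(profiles: pd.DataFrame, members: list[str] | None = None) -> RedundancyScore:
    """Redundancy score of a strain subset from its enzyme-count profiles.

    Parameters
    ----------
    profiles : DataFrame
        Strain x enzyme counts (rows indexed by strain ID, columns by enzyme
        identifier). Binarized internally.
    members : list of str, optional
        Subset of row labels; defaults to every strain in ``profiles``.
    """
    if members is None:
        members = list(profiles.index)
    if len(members) < 2:
        raise ValueError("community redundancy needs at least 2 members")
    if len(set(members)) != len(members):
        # duplicated members are meaningful (they maximize redundancy) but the
        # canonical strain ordering must keep the duplicates
        pass
    missing = [m for m in members if m not in profiles.index]
    if missing:
        raise KeyError(f"strains not in profile table: {missing}")

    enzymes = sorted(profiles.columns)
    strains = sorted(members)
    sub = profiles.loc[strains, enzymes].to_numpy()

    strings = [_binary_string(row) for row in sub]
    lz_ind = tuple(lz_complexity(s) for s in strings)
    lz_cat = lz_complexity("".join(strings))

    entropies = []
    for row in sub:
        if row.sum() > 0:
            entropies.append(profile_entropy(row))
    entropy_mean = float(np.mean(entropies)) if entropies else 0.0

    denom = sum(lz_ind)
    red = 0.0 if denom == 0 else float(np.clip(1.0 - lz_cat / denom, 0.0, 1.0))
    return RedundancyScore(
        community=tuple(strains),
        lz_individual=lz_ind,
        lz_concat=lz_cat,
        entropy_mean=entropy_mean,
        redundancy=red,
    )
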