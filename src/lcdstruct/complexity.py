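"""Shannon-entropy LCD calling and proteome-level LCD abundance summaries.

A low-complexity domain (LCD) is called wherever a fixed-length scanning
window (default 12 residues, the classic SEG window) has Shannon entropy

    SE = - sum_i (n_i / L) * log2(n_i / L)

at or below a threshold (default 2.2 bits), where ``n_i`` is the count of the
i-th amino acid in the window and ``L`` the window length.  Every qualifying
window is typed by the amino acid(s) attaining the maximum count; a tie makes
the window *ambiguous*.  Overlapping or adjacent same-type windows are merged
into maximal regions for region counting and residue-coverage statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    AMINO_ACIDS,
    AA_INDEX,
    N_AA,
    PHYSICOCHEMICAL_GROUPS,
    AnnotatedChain,
)


class NonCanonicalWindowError(ValueError):
    """The window contains a non-canonical residue; entropy is undefined."""


@dataclass(frozen=True)
class ComplexityParams:
    """Window length, entropy threshold (bits) and alphabet size."""

    window_length: int = 12
    entropy_threshold: float = 2.2
    alphabet_size: int = 20

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        hi = math.log2(min(self.alphabet_size, self.window_length))
        if not 0.0 <= self.entropy_threshold <= hi:
            raise ValueError(
                f"entropy_threshold must lie in [0, log2(min(N, L))] = [0, {hi:.4f}]"
            )


@dataclass(frozen=True)
class LCDSegment:
    """One low-complexity window: coordinates, entropy and type assignment.

    ``types`` is the exact argmax set of the window's composition; the segment
    is ambiguous when more than one amino acid attains the maximum count.
    Coordinates are 0-based half-open.
    """

    chain_id: str
    start: int
    end: int
    entropy: float
    types: frozenset[str]

    @property
    def ambiguous(self) -> bool:
        return len(self.types) > 1


def shannon_entropy(window: str) -> float:
    """Shannon entropy of a window's amino-acid composition, in bits.

    Invariant under permutation of the window; lies in
    ``[0, log2(min(20, len(window)))]``.

    Raises
    ------
    NonCanonicalWindowError
        If the window contains a residue outside the canonical alphabet
        (callers skip such windows).
    """
    L = len(window)
    counts: dict[str, int] = {}
    for ch in window:
        if ch not in AA_INDEX:
            raise NonCanonicalWindowError(f"non-canonical residue {ch!r}")
        counts[ch] = counts.get(ch, 0) + 1
    return -sum((n / L) * math.log2(n / L) for n in counts.values()) + 0.0


def window_counts(chain: AnnotatedChain, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding composition counts for every start position.

    Returns ``(counts, valid)`` where ``counts`` is an ``(n_windows, 20)``
    integer array and ``valid`` flags windows free of non-canonical residues.
    Empty arrays when the chain is shorter than ``w``.
    """
    n = len(chain)
    if n < w:
        return np.zeros((0, N_AA), dtype=np.int32), np.zeros(0, dtype=bool)
    idx = chain.seq_indices
    onehot = np.zeros((n, N_AA + 1), dtype=np.int32)
    onehot[np.arange(n), idx] = 1
    cum = np.zeros((n + 1, N_AA + 1), dtype=np.int32)
    np.cumsum(onehot, axis=0, out=cum[1:])
    win = cum[w:] - cum[:-w]
    return win[:, :N_AA], win[:, N_AA] == 0


def window_entropies(counts: np.ndarray, w: int) -> np.ndarray:
    """Vectorised entropy (bits) for each row of a window-count matrix."""
    p = counts / float(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def call_lcds(
    chain: AnnotatedChain, params: ComplexityParams = ComplexityParams()
) -> list[LCDSegment]:
    """Emit every low-complexity window of the chain with its typing.

    A window qualifies when it contains no 'X' and its entropy is at or below
    the threshold.  Chains shorter than the window yield an empty list.
    """
    w = params.window_length
    counts, valid = window_counts(chain, w)
    if counts.shape[0] == 0:
        return []
    ent = window_entropies(counts, w)
    hits = np.flatnonzero(valid & (ent <= params.entropy_threshold))
    segments = []
    for i in hits:
        row = counts[i]
        mx = row.max()
        types = frozenset(AMINO_ACIDS[j] for j in np.flatnonzero(row == mx))
        segments.append(
            LCDSegment(chain.chain_id, int(i), int(i) + w, float(ent[i]), types)
        )
    return segments


def merge_segments(
    segments: Iterable[LCDSegment], type_aa: str
) -> list[tuple[int, int]]:
    """Maximal unions of overlapping/adjacent windows typed ``type_aa``.

    A window participates for type ``t`` whenever ``t`` is in its argmax set
    (ambiguous windows contribute to every tied type).  Returned regions are
    disjoint and sorted by start.
    """
    ivals = sorted(
        (s.start, s.end) for s in segments if type_aa in s.types
    )
    merged: list[tuple[int, int]] = []
    for start, end in ivals:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass(frozen=True)
class LCDSummary:
    """Proteome-level LCD abundance tables.

    ``per_type`` is indexed by amino acid with columns
    ``n_proteins_unambiguous``, ``n_proteins_ambiguous``, ``n_windows``,
    ``n_merged_regions`` and ``pct_residues_in_lcds`` (NaN when the proteome
    has no residues of that type).  ``per_group`` is indexed by
    physicochemical group with columns ``n_proteins`` and ``n_regions``; a
    protein or region with LCDs of several member types counts once.
    """

    per_type: pd.DataFrame
    per_group: pd.DataFrame
    n_proteins: int = 0


def proteome_lcd_summary(
    chains: Sequence[AnnotatedChain],
    params: ComplexityParams = ComplexityParams(),
) -> LCDSummary:
    """LCD abundance per type and per physicochemical group.

    A protein counts in a type's *unambiguous* stratum when it has at least
    one window whose argmax set is exactly that type, and in the *ambiguous*
    stratum when it has only tied windows of that type.  Group counts are over
    proteins/regions with any member-type LCD (not the sum over members).
    """
    cols = {
        aa: {"n_proteins_unambiguous": 0, "n_proteins_ambiguous": 0,
             "n_windows": 0, "n_merged_regions": 0,
             "covered": 0, "total": 0}
        for aa in AMINO_ACIDS
    }
    group_proteins = {g: 0 for g in PHYSICOCHEMICAL_GROUPS}
    group_regions = {g: 0 for g in PHYSICOCHEMICAL_GROUPS}

    for chain in chains:
        segments = call_lcds(chain, params)
        seq = chain.sequence
        chain_types: set[str] = set()
        unambiguous_types: set[str] = set()
        for s in segments:
            chain_types |= s.types
            if not s.ambiguous:
                unambiguous_types |= s.types
        for aa in AMINO_ACIDS:
            cols[aa]["total"] += seq.count(aa)
        for aa in chain_types:
            if aa in unambiguous_types:
                cols[aa]["n_proteins_unambiguous"] += 1
            else:
                cols[aa]["n_proteins_ambiguous"] += 1
            regions = merge_segments(segments, aa)
            cols[aa]["n_windows"] += sum(1 for s in segments if aa in s.types)
            cols[aa]["n_merged_regions"] += len(regions)
            cols[aa]["covered"] += sum(
                seq.count(aa, start, end) for start, end in regions
            )
        for group, members in PHYSICOCHEMICAL_GROUPS.items():
            hits = chain_types & members
            if hits:
                group_proteins[group] += 1
                group_segments = [s for s in segments if s.types & members]
                # union across member types, so shared windows count once
                ivals = sorted({(s.start, s.end) for s in group_segments})
                n_regions, last_end = 0, -1
                for start, end in ivals:
                    if start > last_end:
                        n_regions += 1
                        last_end = end
                    else:
                        last_end = max(last_end, end)
                group_regions[group] += n_regions

    per_type = pd.DataFrame.from_dict(cols, orient="index")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_type["pct_residues_in_lcds"] = np.where(
            per_type["total"] > 0,
            100.0 * per_type["covered"] / per_type["total"].replace(0, np.nan),
            np.nan,
        )
    per_type = per_type.drop(columns=["covered", "total"])
    per_type.index.name = "lcd_type"
    per_group = pd.DataFrame(
        {"n_proteins": group_proteins, "n_regions": group_regions}
    )
    per_group.index.name = "group"
    return LCDSummary(per_type, per_group, n_proteins=len(chains))


def residue_fraction_in_lcds(
    chains: Sequence[AnnotatedChain],
    params: ComplexityParams = ComplexityParams(),
) -> dict[str, float]:
    """Percentage of each amino acid lying inside same-type LCD regions.

    For type ``t``: 100 x (t residues inside the merged union of t-typed LCD
    regions) / (all t residues in the proteome); NaN when the proteome has no
    ``t`` residues.  Shared residues of overlapping windows count once.
    """
    covered = {aa: 0 for aa in AMINO_ACIDS}
    total = {aa: 0 for aa in AMINO_ACIDS}
    for chain in chains:
        segments = call_lcds(chain, params)
        seq = chain.sequence
        for aa in AMINO_ACIDS:
            total[aa] += seq.count(aa)
        seen = {aa for s in segments for aa in s.types}
        for aa in seen:
            for start, end in merge_segments(segments, aa):
                covered[aa] += seq.count(aa, start, end)
    return {
        aa: (100.0 * covered[aa] / total[aa]) if total[aa] > 0 else float("nan")
        for aa in AMINO_ACIDS
    }
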