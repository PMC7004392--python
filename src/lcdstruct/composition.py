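"""Exhaustive window scanning and composition-binned structure profiling.

Every chain is scanned with a sliding window (step 1); windows containing a
non-canonical residue are excluded.  Windows are grouped into *residue-count
bins* — all windows holding exactly ``k`` copies of the amino acid of
interest — and the arithmetic mean fraction of each structure category is
computed per bin.  Overlapping windows each contribute independently (no
deduplication): the statistics are window-level by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .complexity import ComplexityParams, window_counts, window_entropies
from .core import (
    AMINO_ACIDS,
    AA_INDEX,
    N_AA,
    NEGATIVE_RESIDUES,
    POSITIVE_RESIDUES,
    AnnotatedChain,
    CategoryMap,
)

DEFAULT_WIDTHS: tuple[int, ...] = tuple(range(10, 101, 10))


@dataclass(frozen=True)
class WindowView:
    """One scanned window: composition counts plus category counts."""

    chain_id: str
    start: int
    width: int
    counts: np.ndarray  # (20,) composition counts
    category_counts: np.ndarray  # per analysis category

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.width:
            raise ValueError("composition counts must sum to the window width")
        if int(self.category_counts.sum()) != self.width:
            raise ValueError("category counts must sum to the window width")


def category_fractions(window: WindowView) -> np.ndarray:
    """Per-category fractions of the window (sum to 1)."""
    return window.category_counts / float(window.width)


def _category_count_matrix(
    chain: AnnotatedChain, w: int, cmap: CategoryMap
) -> np.ndarray:
    """(n_windows, n_categories) sliding category counts."""
    n = len(chain)
    cat = cmap.residue_categories(chain)
    onehot = np.zeros((n, cmap.n_categories), dtype=np.int32)
    onehot[np.arange(n), cat] = 1
    cum = np.zeros((n + 1, cmap.n_categories), dtype=np.int32)
    np.cumsum(onehot, axis=0, out=cum[1:])
    return cum[w:] - cum[:-w]


def chain_window_arrays(
    chain: AnnotatedChain, w: int, cmap: CategoryMap
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised window view of one chain.

    Returns ``(counts, cat_counts, valid)``; rows align with window starts
    ``0..len(chain)-w``.  All arrays are empty when the chain is shorter than
    ``w`` (such chains are skipped per-analysis, not rejected at I/O).
    """
    counts, valid = window_counts(chain, w)
    if counts.shape[0] == 0:
        return counts, np.zeros((0, cmap.n_categories), dtype=np.int32), valid
    return counts, _category_count_matrix(chain, w, cmap), valid


def scan_windows(
    chain: AnnotatedChain, w: int, cmap: CategoryMap | None = None
) -> Iterator[WindowView]:
    """Yield every canonical window of width ``w`` (step 1).

    Windows containing a non-canonical residue are omitted; a chain shorter
    than ``w`` yields nothing.
    """
    if w < 1:
        raise ValueError("window width must be >= 1")
    cmap = cmap or CategoryMap.default()
    counts, cats, valid = chain_window_arrays(chain, w, cmap)
    for i in np.flatnonzero(valid):
        yield WindowView(chain.chain_id, int(i), w, counts[i], cats[i])


def composition_frequency_table(
    chains: Sequence[AnnotatedChain],
    widths: Iterable[int] = DEFAULT_WIDTHS,
) -> pd.DataFrame:
    """Window- and chain-level composition frequencies per (amino acid, width).

    For every amino acid ``a`` and width ``w``, windows are binned by their
    count of ``a`` (percent composition ``100*k/w``).  ``n_windows`` counts
    every canonical window in the bin; ``n_chains`` counts each chain once per
    bin it attains.
    """
    widths = tuple(widths)
    n_windows: dict[tuple[str, int, int], int] = {}
    n_chains: dict[tuple[str, int, int], int] = {}
    for chain in chains:
        for w in widths:
            counts, valid = window_counts(chain, w)
            if counts.shape[0] == 0:
                continue
            counts = counts[valid]
            for j, aa in enumerate(AMINO_ACIDS):
                ks, freq = np.unique(counts[:, j], return_counts=True)
                for k, f in zip(ks, freq):
                    key = (aa, w, int(k))
                    n_windows[key] = n_windows.get(key, 0) + int(f)
                    n_chains[key] = n_chains.get(key, 0) + 1
    rows = [
        {
            "amino_acid": aa,
            "width": w,
            "k": k,
            "pct_composition": 100.0 * k / w,
            "n_windows": n_windows[(aa, w, k)],
            "n_chains": n_chains[(aa, w, k)],
        }
        for (aa, w, k) in sorted(n_windows)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "amino_acid", "width", "k", "pct_composition", "n_windows", "n_chains",
        ],
    )


@dataclass(frozen=True)
class CompositionBinProfile:
    """Mean structure-category fractions per residue-count bin.

    ``table`` is indexed by ``k`` (0..width) with an ``n_windows`` column and
    one mean-fraction column per category; bins with no windows hold NaN.
    """

    amino_acid: str
    width: int
    table: pd.DataFrame


def opposite_charge_mask(counts: np.ndarray) -> np.ndarray:
    """True for windows where positive (K/R) and negative (D/E) co-occur."""
    pos = sum(counts[:, AA_INDEX[a]] for a in sorted(POSITIVE_RESIDUES))
    neg = sum(counts[:, AA_INDEX[a]] for a in sorted(NEGATIVE_RESIDUES))
    return (pos > 0) & (neg > 0)


def bin_profiles(
    chains: Sequence[AnnotatedChain],
    amino_acid: str,
    w: int = 12,
    exclude_opposite_charges: bool = False,
    cmap: CategoryMap | None = None,
) -> CompositionBinProfile:
    """Composition-binned mean structure profile for one amino acid.

    Windows are grouped by their count of ``amino_acid``; per bin the
    arithmetic mean of the per-window category fractions is reported together
    with the bin sample size.  With ``exclude_opposite_charges``, windows in
    which K/R and D/E co-occur are dropped before binning.
    """
    cmap = cmap or CategoryMap.default()
    j = AA_INDEX[amino_acid]
    sums = np.zeros((w + 1, cmap.n_categories))
    n = np.zeros(w + 1, dtype=np.int64)
    for chain in chains:
        counts, cats, valid = chain_window_arrays(chain, w, cmap)
        if counts.shape[0] == 0:
            continue
        keep = valid.copy()
        if exclude_opposite_charges:
            keep &= ~opposite_charge_mask(counts)
        counts, cats = counts[keep], cats[keep]
        ks = counts[:, j]
        frac = cats / float(w)
        np.add.at(sums, ks, frac)
        np.add.at(n, ks, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(n[:, None] > 0, sums / np.maximum(n, 1)[:, None], np.nan)
    table = pd.DataFrame(means, columns=list(cmap.names))
    table.insert(0, "n_windows", n)
    table.index.name = "k"
    return CompositionBinProfile(amino_acid, w, table)


def lcd_class_ss_profile(
    chains: Sequence[AnnotatedChain],
    params: ComplexityParams = ComplexityParams(),
    cmap: CategoryMap | None = None,
) -> pd.DataFrame:
    """Mean structure profile per LCD type, plus pooled baselines.

    Rows: one per amino-acid LCD type (mean over all low-complexity windows
    whose argmax set contains the type; NaN when no such windows), a pooled
    ``LCDs`` row over every qualifying window, and a ``PDB`` row over every
    canonical window of the proteome.
    """
    cmap = cmap or CategoryMap.default()
    w = params.window_length
    ncat = cmap.n_categories
    type_sums = np.zeros((N_AA, ncat))
    type_n = np.zeros(N_AA, dtype=np.int64)
    lcd_sum, lcd_n = np.zeros(ncat), 0
    pdb_sum, pdb_n = np.zeros(ncat), 0
    for chain in chains:
        counts, cats, valid = chain_window_arrays(chain, w, cmap)
        if counts.shape[0] == 0:
            continue
        frac = cats / float(w)
        pdb_sum += frac[valid].sum(axis=0)
        pdb_n += int(valid.sum())
        ent = window_entropies(counts, w)
        qual = valid & (ent <= params.entropy_threshold)
        if not qual.any():
            continue
        lcd_sum += frac[qual].sum(axis=0)
        lcd_n += int(qual.sum())
        qcounts = counts[qual]
        qfrac = frac[qual]
        is_max = qcounts == qcounts.max(axis=1, keepdims=True)
        type_sums += is_max.T @ qfrac
        type_n += is_max.sum(axis=0)
    rows = {}
    for j, aa in enumerate(AMINO_ACIDS):
        mean = type_sums[j] / type_n[j] if type_n[j] > 0 else np.full(ncat, np.nan)
        rows[aa] = np.concatenate([[type_n[j]], mean])
    rows["LCDs"] = np.concatenate(
        [[lcd_n], lcd_sum / lcd_n if lcd_n else np.full(ncat, np.nan)]
    )
    rows["PDB"] = np.concatenate(
        [[pdb_n], pdb_sum / pdb_n if pdb_n else np.full(ncat, np.nan)]
    )
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["n_windows"] + list(cmap.names)
    )
    out["n_windows"] = out["n_windows"].astype(np.int64)
    out.index.name = "lcd_type"
    return out


def subsidiary_composition(
    chains: Sequence[AnnotatedChain],
    w: int = 12,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Mean residue frequencies within each type's highly-enriched windows.

    Rows are LCD types (windows with >= ``ceil(w*min_fraction)`` copies of the
    defining amino acid), columns amino acids; each row is the mean per-window
    frequency vector and sums to 1.  Types with no enriched windows hold NaN.
    """
    threshold = int(np.ceil(w * min_fraction))
    sums = np.zeros((N_AA, N_AA))
    n = np.zeros(N_AA, dtype=np.int64)
    for chain in chains:
        counts, valid = window_counts(chain, w)
        if counts.shape[0] == 0:
            continue
        counts = counts[valid]
        freq = counts / float(w)
        enriched = counts >= threshold  # (n_windows, 20) membership per type
        sums += enriched.T @ freq
        n += enriched.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(n[:, None] > 0, sums / np.maximum(n, 1)[:, None], np.nan)
    out = pd.DataFrame(means, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
    out.insert(0, "n_windows", n)
    out.index.name = "lcd_type"
    return out
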