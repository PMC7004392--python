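"""Annotation-enrichment statistics per LCD type.

For each LCD type the chains carrying that type are compared against the
whole non-redundant chain set (the reference deliberately *includes* the LCD
chains; the resulting mild non-independence is reported in output metadata,
not corrected, to keep the statistic's definition simple and explicit).  Each
(type, annotation) pair gets a two-sided Fisher exact p-value on raw counts,
a natural-log odds ratio

    lnOR = ln( [f_LCD / (1 - f_LCD)] / [f_PDB / (1 - f_PDB)] )

with a Haldane-Anscombe 0.5 pseudocount when any cell is zero, and a
Holm-Sidak adjusted p-value computed within the LCD type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap

logger = logging.getLogger("lcdstruct")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: LCD-type chains vs reference chains, with/without annotation."""

    a: int  # LCD-type chains with the annotation
    b: int  # LCD-type chains without
    c: int  # reference chains with
    d: int  # reference chains without

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("table cells must be non-negative integers")


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric point probabilities
    (same margins) no larger than the observed table's.

    A zero margin makes the table degenerate; p = 1 is returned and logged.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        logger.info("degenerate contingency table %s: p = 1", (a, b, c, d))
        return 1.0
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def log_odds_ratio(f_lcd: float, f_pdb: float) -> float:
    """Natural-log odds ratio of two frequencies (both strictly interior).

    Antisymmetric under argument swap; zero when the frequencies agree.  For
    boundary frequencies use :func:`log_odds_ratio_from_counts`, which applies
    the Haldane-Anscombe pseudocount.
    """
    for f in (f_lcd, f_pdb):
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequencies must lie in [0, 1]")
        if f in (0.0, 1.0):
            raise ValueError(
                "boundary frequency: use log_odds_ratio_from_counts for the "
                "pseudocount fallback"
            )
    return math.log((f_lcd / (1 - f_lcd)) / (f_pdb / (1 - f_pdb)))


def log_odds_ratio_from_counts(table: ContingencyTable) -> tuple[float, bool]:
    """lnOR from raw counts; Haldane-Anscombe 0.5 pseudocount on zero cells.

    Returns ``(lnOR, pseudocount_applied)``.  When any cell is zero, 0.5 is
    added to all four counts and the frequencies recomputed.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    pseudo = 0 in (a, b, c, d)
    if pseudo:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    f_lcd = a / (a + b)
    f_pdb = c / (c + d)
    return log_odds_ratio(f_lcd, f_pdb), pseudo


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Sidak adjusted p-values, in the input order.

    Sorting ascending, ``adj_(i) = max_{j<=i} 1 - (1 - p_(j))^(m - j + 1)``,
    clipped to 1; the result is monotone over the sorted order and invariant
    (up to reordering) under input permutation.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # log1p(-1) for p == 1 is benign
        return multipletests(p, method="holm-sidak")[1]


def annotation_enrichment(
    lcd_chains_by_type: Mapping[str, Iterable[str]],
    annotation_map: AnnotationMap,
    reference_chains: Iterable[str],
) -> pd.DataFrame:
    """Enrichment records for every (LCD type, annotation) pair.

    The reference is the full chain set; every annotation present in the
    reference is tested against each type, and Holm-Sidak adjustment is
    applied within each type.  Types with zero chains are skipped with a
    warning.  Columns: ``lcd_type, annotation_id, annotation_name, a, b, c,
    d, f_lcd, f_pdb, lnor, p_raw, p_adjusted, pseudocount_applied``.
    """
    reference = sorted(set(reference_chains))
    n_ref = len(reference)
    ref_with: dict[str, int] = {}
    for cid in reference:
        for ann in annotation_map.annotations_for(cid):
            ref_with[ann] = ref_with.get(ann, 0) + 1
    annotations = sorted(ref_with)

    frames = []
    for lcd_type in sorted(lcd_chains_by_type):
        type_chains = set(lcd_chains_by_type[lcd_type])
        missing = type_chains - set(reference)
        if missing:
            raise ValueError(
                f"type {lcd_type}: chains {sorted(missing)[:3]}... not in reference"
            )
        n_type = len(type_chains)
        if n_type == 0:
            logger.warning("LCD type %s has zero chains; skipped", lcd_type)
            continue
        rows = []
        for ann in annotations:
            a = sum(
                1 for cid in type_chains
                if ann in annotation_map.annotations_for(cid)
            )
            table = ContingencyTable(
                a, n_type - a, ref_with[ann], n_ref - ref_with[ann]
            )
            lnor, pseudo = log_odds_ratio_from_counts(table)
            rows.append(
                {
                    "lcd_type": lcd_type,
                    "annotation_id": ann,
                    "annotation_name": annotation_map.names.get(ann, ""),
                    "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                    "f_lcd": table.a / n_type,
                    "f_pdb": table.c / n_ref,
                    "lnor": lnor,
                    "p_raw": fisher_exact_two_sided(table),
                    "pseudocount_applied": pseudo,
                }
            )
        frame = pd.DataFrame(rows)
        frame["p_adjusted"] = holm_sidak(frame["p_raw"].to_numpy())
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=[
                "lcd_type", "annotation_id", "annotation_name",
                "a", "b", "c", "d", "f_lcd", "f_pdb", "lnor",
                "p_raw", "pseudocount_applied", "p_adjusted",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def top_enriched(
    records: pd.DataFrame, k: int = 10, alpha: float = 0.05
) -> pd.DataFrame:
    """Up to ``k`` significantly enriched annotations per LCD type.

    Filters ``p_adjusted <= alpha`` and ``lnor > 0``; sorts ascending by
    adjusted p, ties broken by descending lnOR then annotation id.
    """
    sig = records[(records["p_adjusted"] <= alpha) & (records["lnor"] > 0)]
    sig = sig.sort_values(
        ["lcd_type", "p_adjusted", "lnor", "annotation_id"],
        ascending=[True, True, False, True],
    )
    return sig.groupby("lcd_type", group_keys=False).head(k).reset_index(drop=True)
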