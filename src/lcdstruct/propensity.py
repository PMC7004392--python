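"""Regression of observed LCD structure content against propensity scales.

For each amino acid ``a`` the 12-residue windows of the proteome are split
into *highly-enriched LCDs* (>= 50% composition of ``a``) and the
complementary *non-LCD* pool.  Within each pool the fraction of ``a``
occurrences annotated alpha-helix (or beta-sheet) is the observed statistic;
it is regressed by ordinary least squares against each published propensity
scale, with the scale on the x-axis so a residual is the vertical displacement
of the observed fraction from the fitted line (positive = more structure than
the scale predicts).  Proline is excluded from every regression, as are amino
acids a scale does not score, scale-specific exclusions, and (for the
enriched pool) amino acids with fewer than ``min_count`` occurrences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import AMINO_ACIDS, AA_INDEX, AnnotatedChain, CategoryMap
from .io import PropensityScale

logger = logging.getLogger("lcdstruct")

KIND_CATEGORY = {"helix": "alpha_helix", "sheet": "beta_sheet"}

# Machine-readable reasons an amino acid was left out of a regression,
# in priority order.
REASON_PROLINE = "proline_rule"
REASON_SCALE_MISSING = "scale_missing"
REASON_SCALE_EXCLUSION = "scale_exclusion"
REASON_LOW_COUNT = "low_count"


class InsufficientDataError(ValueError):
    """Fewer than three amino acids survive the exclusion rules."""

    def __init__(self, scale_name: str, excluded: Mapping[str, str]):
        self.excluded = dict(excluded)
        super().__init__(
            f"scale {scale_name!r}: fewer than 3 usable amino acids "
            f"(exclusions: {self.excluded})"
        )


@dataclass(frozen=True)
class WindowSet:
    """A pool of windows for one amino acid: (chain, window starts) pairs."""

    amino_acid: str
    width: int
    context: str  # "enriched_lcd" | "non_lcd"
    members: tuple[tuple[AnnotatedChain, np.ndarray], ...]

    @property
    def n_windows(self) -> int:
        return sum(len(starts) for _, starts in self.members)


@dataclass(frozen=True)
class ObservedFraction:
    """Observed structure fractions of one amino acid within a window pool.

    ``n`` is the total number of occurrences of the amino acid across the
    pool's windows (a residue covered by m windows counts m times);
    ``fractions`` maps category name to the fraction of those occurrences
    annotated in the category (NaN when ``n`` is 0).
    """

    amino_acid: str
    context: str
    n: int
    fractions: dict[str, float]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of observed fractions against one propensity scale."""

    scale_name: str
    slope: float
    intercept: float
    pearson_r: float
    residuals: dict[str, float]  # observed - fitted, per included amino acid
    included: tuple[str, ...]
    excluded: dict[str, str]  # amino acid -> reason code


def build_enriched_sets(
    chains: Sequence[AnnotatedChain],
    amino_acid: str,
    w: int = 12,
    min_fraction: float = 0.5,
) -> tuple[WindowSet, WindowSet]:
    """Partition all canonical ``w``-windows by the count of ``amino_acid``.

    Windows with at least ``ceil(w * min_fraction)`` copies form the
    highly-enriched pool; every other canonical window is non-LCD.
    """
    from .complexity import window_counts

    threshold = int(np.ceil(w * min_fraction))
    j = AA_INDEX[amino_acid]
    enriched: list[tuple[AnnotatedChain, np.ndarray]] = []
    non_lcd: list[tuple[AnnotatedChain, np.ndarray]] = []
    for chain in chains:
        counts, valid = window_counts(chain, w)
        if counts.shape[0] == 0:
            continue
        ks = counts[:, j]
        hi = np.flatnonzero(valid & (ks >= threshold))
        lo = np.flatnonzero(valid & (ks < threshold))
        if hi.size:
            enriched.append((chain, hi))
        if lo.size:
            non_lcd.append((chain, lo))
    return (
        WindowSet(amino_acid, w, "enriched_lcd", tuple(enriched)),
        WindowSet(amino_acid, w, "non_lcd", tuple(non_lcd)),
    )


def _occurrence_category_counts(
    chain: AnnotatedChain,
    starts: np.ndarray,
    amino_acid: str,
    w: int,
    cmap: CategoryMap,
) -> np.ndarray:
    """Counts of ``amino_acid`` occurrences per category over the windows."""
    is_a = chain.seq_indices == AA_INDEX[amino_acid]
    cat = cmap.residue_categories(chain)
    out = np.zeros(cmap.n_categories, dtype=np.int64)
    for c in range(cmap.n_categories):
        ind = (is_a & (cat == c)).astype(np.int64)
        cum = np.concatenate([[0], np.cumsum(ind)])
        out[c] = int((cum[starts + w] - cum[starts]).sum())
    return out


def observed_fractions(
    windows: WindowSet,
    cmap: CategoryMap | None = None,
    categories: tuple[str, ...] = ("alpha_helix", "beta_sheet"),
) -> ObservedFraction:
    """Fraction of the pool's defining residue annotated in each category.

    The denominator is every occurrence of the amino acid in the pool's
    windows (with window multiplicity); disorder-masked occurrences count in
    the denominator only, so fractions over structural categories can sum to
    less than 1.  An empty pool yields NaN fractions.
    """
    cmap = cmap or CategoryMap.default()
    totals = np.zeros(cmap.n_categories, dtype=np.int64)
    for chain, starts in windows.members:
        totals += _occurrence_category_counts(
            chain, starts, windows.amino_acid, windows.width, cmap
        )
    n = int(totals.sum())
    fractions = {
        c: (totals[cmap.index_of(c)] / n) if n > 0 else float("nan")
        for c in categories
    }
    return ObservedFraction(windows.amino_acid, windows.context, n, fractions)


def residue_level_nonlcd_fraction(
    chains: Sequence[AnnotatedChain],
    amino_acid: str,
    w: int = 12,
    min_fraction: float = 0.5,
    cmap: CategoryMap | None = None,
    categories: tuple[str, ...] = ("alpha_helix", "beta_sheet"),
) -> ObservedFraction:
    """Residue-level variant of the non-LCD statistic.

    Each occurrence of the amino acid counts once, and is excluded when it
    lies inside any highly-enriched window of that amino acid (rather than
    pooling whole windows).  Selected with ``nonlcd_mode="residue"``.
    """
    from .complexity import window_counts

    cmap = cmap or CategoryMap.default()
    threshold = int(np.ceil(w * min_fraction))
    j = AA_INDEX[amino_acid]
    totals = np.zeros(cmap.n_categories, dtype=np.int64)
    for chain in chains:
        is_a = chain.seq_indices == j
        covered = np.zeros(len(chain), dtype=bool)
        counts, valid = window_counts(chain, w)
        if counts.shape[0]:
            for s in np.flatnonzero(valid & (counts[:, j] >= threshold)):
                covered[s : s + w] = True
        keep = is_a & ~covered
        cat = cmap.residue_categories(chain)
        for c in range(cmap.n_categories):
            totals[c] += int((keep & (cat == c)).sum())
    n = int(totals.sum())
    fractions = {
        c: (totals[cmap.index_of(c)] / n) if n > 0 else float("nan")
        for c in categories
    }
    return ObservedFraction(amino_acid, "non_lcd", n, fractions)


def observed_fraction_table(
    chains: Sequence[AnnotatedChain],
    w: int = 12,
    min_fraction: float = 0.5,
    cmap: CategoryMap | None = None,
    nonlcd_mode: str = "window",
) -> pd.DataFrame:
    """Observed helix/sheet fractions for all 20 amino acids, both contexts.

    Returns a tidy frame with columns ``amino_acid, context, n, f_alpha_helix,
    f_beta_sheet``.
    """
    if nonlcd_mode not in ("window", "residue"):
        raise ValueError("nonlcd_mode must be 'window' or 'residue'")
    cmap = cmap or CategoryMap.default()
    rows = []
    for aa in AMINO_ACIDS:
        enriched, non_lcd = build_enriched_sets(chains, aa, w, min_fraction)
        obs_e = observed_fractions(enriched, cmap)
        if nonlcd_mode == "window":
            obs_n = observed_fractions(non_lcd, cmap)
        else:
            obs_n = residue_level_nonlcd_fraction(chains, aa, w, min_fraction, cmap)
        for obs in (obs_e, obs_n):
            rows.append(
                {
                    "amino_acid": aa,
                    "context": obs.context,
                    "n": obs.n,
                    "f_alpha_helix": obs.fractions["alpha_helix"],
                    "f_beta_sheet": obs.fractions["beta_sheet"],
                }
            )
    return pd.DataFrame(rows)


def _exclusions(
    observed: Mapping[str, float],
    scale: PropensityScale,
    counts: Mapping[str, int] | None,
    min_count: int,
) -> dict[str, str]:
    out: dict[str, str] = {}
    values = scale.value_map
    for aa in observed:
        if aa == "P":
            out[aa] = REASON_PROLINE
        elif aa not in values:
            out[aa] = REASON_SCALE_MISSING
        elif aa in scale.excluded:
            out[aa] = REASON_SCALE_EXCLUSION
        elif counts is not None and counts.get(aa, 0) < min_count:
            out[aa] = REASON_LOW_COUNT
        elif not np.isfinite(observed[aa]):
            out[aa] = REASON_LOW_COUNT
    return out


def fit_scale_regression(
    observed: Mapping[str, float],
    scale: PropensityScale,
    min_count: int = 50,
    counts: Mapping[str, int] | None = None,
) -> RegressionResult:
    """OLS of observed fractions (y) on scale values (x).

    Residuals are ``observed - fitted`` (positive = above the line) and sum
    to zero over the included amino acids.  ``lower_is_more`` scales are
    sign-flipped before fitting.

    Raises
    ------
    InsufficientDataError
        If fewer than three amino acids survive the exclusions; the error
        carries the per-amino-acid reason codes.
    """
    excluded = _exclusions(observed, scale, counts, min_count)
    included = tuple(aa for aa in observed if aa not in excluded)
    if len(included) < 3:
        raise InsufficientDataError(scale.name, excluded)
    values = scale.oriented_values()
    x = np.array([values[aa] for aa in included])
    y = np.array([observed[aa] for aa in included])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = fit.params
    r, _ = stats.pearsonr(x, y)
    residuals = dict(zip(included, (y - fit.fittedvalues)))
    return RegressionResult(
        scale_name=scale.name,
        slope=float(slope),
        intercept=float(intercept),
        pearson_r=float(r),
        residuals={aa: float(v) for aa, v in residuals.items()},
        included=included,
        excluded=excluded,
    )


def correlation_matrix(
    series: Mapping[str, Mapping[str, float]],
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pairwise |Pearson r| over pairwise-complete amino acids, sorted.

    ``series`` maps a name (scale or derived statistic) to its per-amino-acid
    values; pairs sharing fewer than ``min_shared`` finite amino acids get
    NaN (logged).  Rows/columns are ordered by descending mean |r|.
    """
    names = list(series)
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            shared = [
                aa
                for aa in series[a]
                if aa in series[b]
                and np.isfinite(series[a][aa])
                and np.isfinite(series[b][aa])
            ]
            if len(shared) < min_shared:
                logger.warning(
                    "correlation %s vs %s: only %d shared amino acids",
                    a, b, len(shared),
                )
                continue
            x = np.array([series[a][aa] for aa in shared])
            y = np.array([series[b][aa] for aa in shared])
            if a == b:
                r = 1.0
            else:
                r = float(abs(stats.pearsonr(x, y)[0]))
            mat.loc[a, b] = mat.loc[b, a] = r
    order = mat.mean(axis=1, skipna=True).sort_values(ascending=False).index
    return mat.loc[order, order]


def residual_summary(
    observed: Mapping[str, float],
    scales: Iterable[PropensityScale],
    min_count: int = 50,
    counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Residual distribution per amino acid across a family of scales.

    Fits each scale in turn and collects residuals; the frame is indexed by
    amino acid with ``n_scales, mean, median, min, max`` columns.  An amino
    acid excluded from one scale is simply absent from that scale's residuals.
    """
    per_aa: dict[str, list[float]] = {}
    for scale in scales:
        try:
            res = fit_scale_regression(observed, scale, min_count, counts)
        except InsufficientDataError as err:
            logger.warning("residual_summary: %s", err)
            continue
        for aa, r in res.residuals.items():
            per_aa.setdefault(aa, []).append(r)
    rows = {
        aa: {
            "n_scales": len(v),
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
        }
        for aa, v in sorted(per_aa.items())
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "amino_acid"
    return out


def dose_residuals(
    chains: Sequence[AnnotatedChain],
    scales: Sequence[PropensityScale],
    kind: str,
    w: int = 12,
    min_count: int = 50,
    cmap: CategoryMap | None = None,
) -> pd.DataFrame:
    """Mean regression residual per (amino acid, residue-count bin).

    For each bin ``k`` the observed statistic is the fraction of the defining
    residue annotated in the kind's category among windows holding exactly
    ``k`` copies; a per-scale regression across amino acids is fitted at each
    ``k`` and the residuals averaged over scales.  Bins with fewer than
    ``min_count`` occurrences are dropped; a ``k`` with fewer than three
    eligible amino acids yields NaN.
    """
    from .complexity import window_counts

    if kind not in KIND_CATEGORY:
        raise ValueError("kind must be 'helix' or 'sheet'")
    cmap = cmap or CategoryMap.default()
    cat_idx = cmap.index_of(KIND_CATEGORY[kind])

    # occurrence counts of aa (total / in-category) per (aa, k)
    total = np.zeros((len(AMINO_ACIDS), w + 1), dtype=np.int64)
    in_cat = np.zeros_like(total)
    for chain in chains:
        counts, valid = window_counts(chain, w)
        if counts.shape[0] == 0:
            continue
        cat = cmap.residue_categories(chain)
        for j, aa in enumerate(AMINO_ACIDS):
            ind_a = (chain.seq_indices == j).astype(np.int64)
            ind_ac = (ind_a.astype(bool) & (cat == cat_idx)).astype(np.int64)
            cum_a = np.concatenate([[0], np.cumsum(ind_a)])
            cum_ac = np.concatenate([[0], np.cumsum(ind_ac)])
            starts = np.arange(counts.shape[0])
            wa = cum_a[starts + w] - cum_a[starts]
            wac = cum_ac[starts + w] - cum_ac[starts]
            ks = counts[:, j]
            keep = valid
            np.add.at(total[j], ks[keep], wa[keep])
            np.add.at(in_cat[j], ks[keep], wac[keep])

    rows = []
    for k in range(1, w + 1):
        observed: dict[str, float] = {}
        counts_k: dict[str, int] = {}
        for j, aa in enumerate(AMINO_ACIDS):
            counts_k[aa] = int(total[j, k])
            observed[aa] = (
                in_cat[j, k] / total[j, k] if total[j, k] > 0 else float("nan")
            )
        per_aa: dict[str, list[float]] = {}
        for scale in scales:
            try:
                res = fit_scale_regression(observed, scale, min_count, counts_k)
            except InsufficientDataError:
                continue
            for aa, r in res.residuals.items():
                per_aa.setdefault(aa, []).append(r)
        for aa in AMINO_ACIDS:
            vals = per_aa.get(aa)
            rows.append(
                {
                    "amino_acid": aa,
                    "k": k,
                    "n": counts_k[aa],
                    "mean_residual": float(np.mean(vals)) if vals else float("nan"),
                    "n_scales": len(vals) if vals else 0,
                }
            )
    return pd.DataFrame(rows)
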