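"""Enriched/non-LCD pools, OLS against propensity scales, residual audits."""

from __future__ import annotations

import math

import numpy as np
import pytest

from lcdstruct.core import AMINO_ACIDS, CategoryMap
from lcdstruct.io import PropensityScale
from lcdstruct.propensity import (
    InsufficientDataError,
    REASON_LOW_COUNT,
    REASON_PROLINE,
    REASON_SCALE_EXCLUSION,
    REASON_SCALE_MISSING,
    build_enriched_sets,
    correlation_matrix,
    dose_residuals,
    fit_scale_regression,
    observed_fraction_table,
    observed_fractions,
    residual_summary,
)

CMAP = CategoryMap.default()
NON_P = [aa for aa in AMINO_ACIDS if aa != "P"]


def _scale(values, name="s", kind="helix", orientation="higher_is_more",
           excluded=frozenset()):
    return PropensityScale(name, kind, tuple(values.items()), orientation,
                           frozenset(excluded))


class TestEnrichedSets:
    def test_threshold_boundary(self, make_chain):
        six = make_chain("AAAAAACDEFGH")
        five = make_chain("AAAAACDEFGHI")
        enr6, non6 = build_enriched_sets([six], "A")
        enr5, non5 = build_enriched_sets([five], "A")
        assert enr6.n_windows == 1 and non6.n_windows == 0
        assert enr5.n_windows == 0 and non5.n_windows == 1

    def test_partition_is_exhaustive(self, small_proteome):
        from lcdstruct.composition import scan_windows

        total = sum(
            len(list(scan_windows(c, 12))) for c in small_proteome.chains
        )
        enr, non = build_enriched_sets(small_proteome.chains, "A")
        assert enr.n_windows + non.n_windows == total

    def test_pigeonhole_at_most_two_types(self, small_proteome):
        from lcdstruct.complexity import window_counts

        for chain in small_proteome.chains[:10]:
            counts, valid = window_counts(chain, 12)
            enriched_types = (counts >= 6).sum(axis=1)
            assert (enriched_types[valid] <= 2).all()


class TestObservedFractions:
    def test_fraction_counts_occurrences(self, make_chain):
        chain = make_chain("A" * 12, "HHHHHHHHH---")
        enr, _ = build_enriched_sets([chain], "A")
        obs = observed_fractions(enr, CMAP)
        assert obs.n == 12
        assert obs.fractions["alpha_helix"] == pytest.approx(0.75)

    def test_disorder_counts_in_denominator_only(self, make_chain):
        chain = make_chain("A" * 12, "H" * 12, disorder="---------XXX")
        enr, _ = build_enriched_sets([chain], "A")
        obs = observed_fractions(enr, CMAP)
        assert obs.n == 12
        assert obs.fractions["alpha_helix"] == pytest.approx(0.75)
        assert sum(obs.fractions.values()) < 1.0

    def test_empty_pool_is_nan(self, make_chain):
        enr, _ = build_enriched_sets([make_chain("ACDEFGHIKLMN")], "A")
        obs = observed_fractions(enr, CMAP)
        assert obs.n == 0 and math.isnan(obs.fractions["alpha_helix"])

    def test_overlapping_windows_count_with_multiplicity(self, make_chain):
        chain = make_chain("A" * 13, "H" * 13)
        enr, _ = build_enriched_sets([chain], "A")
        assert observed_fractions(enr, CMAP).n == 24  # 2 windows x 12

    def test_residue_mode_differs_from_window_mode(self, medium_proteome):
        tw = observed_fraction_table(medium_proteome.chains, nonlcd_mode="window")
        tr = observed_fraction_table(medium_proteome.chains, nonlcd_mode="residue")
        non_w = tw[tw.context == "non_lcd"].set_index("amino_acid")
        non_r = tr[tr.context == "non_lcd"].set_index("amino_acid")
        # residue mode counts each occurrence once: strictly fewer counts
        assert (non_r["n"] < non_w["n"]).all()


class TestFitScaleRegression:
    def test_collinear_points(self):
        obs = {"A": 0.0, "C": 1.0, "D": 2.0}
        scale = _scale({"A": 0.0, "C": 1.0, "D": 2.0})
        res = fit_scale_regression(obs, scale)
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert all(abs(r) < 1e-12 for r in res.residuals.values())

    def test_hand_normal_equations_example(self):
        # x = (0,1,2), y = (0,0,3): slope 1.5, intercept -0.5,
        # residuals (0.5, -1.0, 0.5) by direct normal equations
        obs = {"A": 0.0, "C": 0.0, "D": 3.0}
        scale = _scale({"A": 0.0, "C": 1.0, "D": 2.0})
        res = fit_scale_regression(obs, scale)
        assert res.slope == pytest.approx(1.5, abs=1e-10)
        assert res.intercept == pytest.approx(-0.5, abs=1e-10)
        assert res.residuals["A"] == pytest.approx(0.5, abs=1e-10)
        assert res.residuals["C"] == pytest.approx(-1.0, abs=1e-10)
        assert res.residuals["D"] == pytest.approx(0.5, abs=1e-10)

    def test_residuals_sum_to_zero(self, rng):
        for _ in range(25):
            aas = list(rng.choice(NON_P, size=10, replace=False))
            obs = dict(zip(aas, rng.random(10)))
            scale = _scale(dict(zip(aas, rng.normal(size=10))))
            res = fit_scale_regression(obs, scale)
            assert abs(sum(res.residuals.values())) < 1e-9

    def test_exclusion_reason_codes(self):
        obs = {
            "A": 0.1, "C": 0.2, "D": 0.3, "E": 0.25, "F": 0.15,
            "G": 0.4, "P": 0.5, "W": 0.6,
        }
        scale = _scale(
            {"A": 0.0, "C": 1.0, "D": 2.0, "E": 1.5, "F": 0.5, "G": 3.0, "P": 1.0},
            excluded=frozenset("G"),
        )
        counts = {aa: 100 for aa in obs}
        counts["C"] = 10
        res = fit_scale_regression(obs, scale, min_count=50, counts=counts)
        assert res.excluded == {
            "P": REASON_PROLINE,
            "W": REASON_SCALE_MISSING,
            "G": REASON_SCALE_EXCLUSION,
            "C": REASON_LOW_COUNT,
        }
        assert set(res.included) == {"A", "D", "E", "F"}

    def test_insufficient_data_error_names_exclusions(self):
        obs = {"A": 0.1, "P": 0.5, "W": 0.6}
        scale = _scale({"A": 0.0, "P": 1.0})
        with pytest.raises(InsufficientDataError) as err:
            fit_scale_regression(obs, scale)
        assert err.value.excluded == {
            "P": REASON_PROLINE,
            "W": REASON_SCALE_MISSING,
        }

    def test_orientation_flip_negates_slope(self, rng):
        aas = NON_P[:10]
        obs = dict(zip(aas, rng.random(10)))
        vals = dict(zip(aas, rng.normal(size=10)))
        hi = _scale(vals, orientation="higher_is_more")
        lo = _scale(vals, orientation="lower_is_more")
        res_hi = fit_scale_regression(obs, hi)
        res_lo = fit_scale_regression(obs, lo)
        assert res_lo.slope == pytest.approx(-res_hi.slope)
        assert abs(res_lo.pearson_r) == pytest.approx(abs(res_hi.pearson_r))

    def test_noise_scales_mean_absolute_residual(self, rng):
        # y = affine(scale) + N(0, sigma): E|resid| ~= sigma*sqrt(2/pi)
        # (shrunk slightly by the hat matrix: factor ~ sqrt((n-2)/n))
        aas = NON_P  # 19 points
        vals = dict(zip(aas, rng.normal(size=len(aas))))
        scale = _scale(vals)
        for sigma in (0.02, 0.05, 0.1):
            mean_abs = []
            for _ in range(400):
                obs = {
                    aa: 0.3 + 0.2 * vals[aa] + sigma * rng.normal() for aa in aas
                }
                res = fit_scale_regression(obs, scale)
                mean_abs.append(np.mean(np.abs(list(res.residuals.values()))))
            expected = sigma * math.sqrt(2 / math.pi)
            assert np.mean(mean_abs) == pytest.approx(expected, rel=0.12)


class TestCorrelationMatrix:
    def test_identity_symmetry_and_affine(self, rng):
        aas = NON_P[:12]
        base = dict(zip(aas, rng.normal(size=12)))
        affine = {aa: 2.0 * v - 1.0 for aa, v in base.items()}
        other = dict(zip(aas, rng.normal(size=12)))
        mat = correlation_matrix({"base": base, "affine": affine, "other": other})
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T, atol=1e-12)
        assert mat.loc["base", "affine"] == pytest.approx(1.0, abs=1e-12)

    def test_sparse_overlap_is_nan(self):
        a = {"A": 1.0, "C": 2.0, "D": 3.0}
        b = {"A": 1.0, "W": 2.0, "Y": 3.0}
        mat = correlation_matrix({"a": a, "b": b})
        assert math.isnan(mat.loc["a", "b"])

    def test_sorted_by_mean_correlation(self, rng):
        aas = NON_P[:12]
        base = dict(zip(aas, rng.normal(size=12)))
        twin = {aa: v + 0.01 * rng.normal() for aa, v in base.items()}
        noise = dict(zip(aas, rng.normal(size=12)))
        mat = correlation_matrix({"noise": noise, "base": base, "twin": twin})
        means = mat.mean(axis=1)
        assert list(means.index) == list(means.sort_values(ascending=False).index)


class TestResidualSummary:
    def test_affine_observed_gives_zero_residuals(self, rng):
        aas = NON_P[:10]
        vals = dict(zip(aas, rng.normal(size=10)))
        obs = {aa: 0.1 + 0.3 * v for aa, v in vals.items()}
        summary = residual_summary(obs, [_scale(vals, name="s1")])
        assert np.allclose(summary["mean"].to_numpy(), 0.0, atol=1e-10)

    def test_scale_specific_exclusion_absent_from_that_scale(self, rng):
        aas = NON_P[:10]
        vals = dict(zip(aas, rng.normal(size=10)))
        obs = dict(zip(aas, rng.random(10)))
        s1 = _scale(vals, name="s1")
        s2 = _scale(vals, name="s2", excluded=frozenset("A"))
        summary = residual_summary(obs, [s1, s2])
        assert summary.loc["A", "n_scales"] == 1
        assert summary.loc["C", "n_scales"] == 2


class TestDoseResiduals:
    def test_matches_naive_loop_oracle(self, small_proteome, rng):
        from lcdstruct.composition import scan_windows

        aas = NON_P
        scales = [
            _scale(dict(zip(aas, rng.normal(size=len(aas)))), name=f"s{i}")
            for i in range(2)
        ]
        got = dose_residuals(
            small_proteome.chains, scales, "helix", min_count=10
        ).set_index(["amino_acid", "k"])

        # naive recount: per (aa, k) occurrence totals via python loops
        w, ci = 12, CMAP.index_of("alpha_helix")
        total = {(aa, k): 0 for aa in AMINO_ACIDS for k in range(w + 1)}
        in_cat = dict(total)
        for chain in small_proteome.chains:
            cat = CMAP.residue_categories(chain)
            for win in scan_windows(chain, w, CMAP):
                window = chain.sequence[win.start : win.start + w]
                for aa in set(window):
                    k = window.count(aa)
                    total[(aa, k)] += k
                    in_cat[(aa, k)] += sum(
                        1
                        for i in range(win.start, win.start + w)
                        if chain.sequence[i] == aa and cat[i] == ci
                    )
        for k in range(1, w + 1):
            observed = {
                aa: (in_cat[(aa, k)] / total[(aa, k)]) if total[(aa, k)] else np.nan
                for aa in AMINO_ACIDS
            }
            counts_k = {aa: total[(aa, k)] for aa in AMINO_ACIDS}
            per_aa: dict[str, list[float]] = {}
            for scale in scales:
                try:
                    res = fit_scale_regression(observed, scale, 10, counts_k)
                except InsufficientDataError:
                    continue
                for aa, r in res.residuals.items():
                    per_aa.setdefault(aa, []).append(r)
            for aa in AMINO_ACIDS:
                want = np.mean(per_aa[aa]) if aa in per_aa else np.nan
                have = got.loc[(aa, k), "mean_residual"]
                assert (np.isnan(want) and np.isnan(have)) or have == pytest.approx(
                    want, abs=1e-9
                )

    def test_sparse_bins_are_nan(self, make_chain):
        scales = [_scale({"A": 0.0, "C": 1.0, "D": 2.0})]
        out = dose_residuals([make_chain("ACDACDACDACD")], scales, "helix")
        assert out["mean_residual"].isna().all()  # min_count=50 never met
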