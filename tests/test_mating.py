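"""Isolation-index estimation and GLM tests for displacement in mate choice."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcdkit import mating
from rcdkit.datasets import mating_trial_table
from rcdkit.mating import (
    IsolationIndexModel,
    MatingCountTable,
    TrialRecord,
    bootstrap_ipsi,
    compute_ipsi,
    tabulate_trials,
)


def _ipsi_oracle(cc, cf, fc, ff):
    """Hand-coded PSI arithmetic, independent of the implementation."""
    T = cc + cf + fc + ff
    row_c, row_f = cc + cf, fc + ff
    col_c, col_f = cc + fc, cf + ff
    psi_cc = cc / (row_c * col_c / T)
    psi_cf = cf / (row_c * col_f / T)
    psi_fc = fc / (row_f * col_c / T)
    psi_ff = ff / (row_f * col_f / T)
    return (psi_cc + psi_ff - psi_cf - psi_fc) / (psi_cc + psi_ff + psi_cf + psi_fc)


class TestComputeIpsi:
    @pytest.mark.parametrize(
        "counts, location, expected",
        [
            ([54, 4, 28, 33], "sympatric", 0.55),
            ([38, 40, 49, 86], "allopatric", 0.13),
            ([10, 0, 0, 10], "sympatric", 1.0),
            ([10, 10, 10, 10], "sympatric", 0.0),
        ],
    )
    def test_point_estimates(self, counts, location, expected):
        table = MatingCountTable(counts, [200] * 4, location)
        assert round(compute_ipsi(table).i_psi, 2) == pytest.approx(expected)

    def test_brute_force_oracle_small_tables(self):
        """All 2x2 mating tables with T <= 12 and nonzero marginals."""
        checked = 0
        for cc in range(13):
            for cf in range(13 - cc):
                for fc in range(13 - cc - cf):
                    for ff in range(13 - cc - cf - fc):
                        if min(cc + cf, fc + ff, cc + fc, cf + ff) == 0:
                            continue
                        table = MatingCountTable(
                            [cc, cf, fc, ff], [20] * 4, "sympatric"
                        )
                        got = compute_ipsi(table).i_psi
                        assert got == pytest.approx(_ipsi_oracle(cc, cf, fc, ff))
                        assert -1 <= got <= 1
                        checked += 1
        assert checked > 100

    @given(
        counts=st.tuples(*[st.integers(1, 40)] * 4),
        factor=st.integers(2, 9),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, counts, factor):
        t1 = MatingCountTable(list(counts), [50] * 4, "sympatric")
        t2 = MatingCountTable([c * factor for c in counts], [400] * 4, "sympatric")
        assert compute_ipsi(t1).i_psi == pytest.approx(compute_ipsi(t2).i_psi)

    @given(counts=st.tuples(*[st.integers(1, 40)] * 4))
    @settings(max_examples=50, deadline=None)
    def test_species_swap_and_transpose_invariance(self, counts):
        cc, cf, fc, ff = counts
        base = compute_ipsi(MatingCountTable([cc, cf, fc, ff], [50] * 4, "sympatric")).i_psi
        swapped = compute_ipsi(MatingCountTable([ff, fc, cf, cc], [50] * 4, "sympatric")).i_psi
        transposed = compute_ipsi(MatingCountTable([cc, fc, cf, ff], [50] * 4, "sympatric")).i_psi
        assert swapped == pytest.approx(base)
        assert transposed == pytest.approx(base)

    def test_empty_marginal_is_an_error(self):
        table = MatingCountTable([0, 0, 5, 5], [10] * 4, "sympatric")
        with pytest.raises(ValueError, match="empty marginal"):
            compute_ipsi(table)


class TestBootstrap:
    def test_published_tables_inference(self):
        symp = bootstrap_ipsi(mating_trial_table("sympatric"), n_boot=10_000, seed=11)
        assert symp.se_boot == pytest.approx(0.076, abs=0.008)
        assert symp.t_stat == pytest.approx(symp.i_psi / symp.se_boot)
        assert symp.p_value < 0.01
        assert symp.p_value_normal < 1e-6

    def test_se_stable_across_seeds(self):
        """CV of the bootstrap SE across seeds is small at n_boot = 10,000."""
        table = mating_trial_table("sympatric")
        ses = [bootstrap_ipsi(table, n_boot=10_000, seed=s).se_boot for s in (1, 2, 3, 4)]
        assert np.std(ses) / np.mean(ses) < 0.05

    def test_degenerate_table_zero_se(self):
        est = bootstrap_ipsi(
            MatingCountTable([10, 0, 0, 10], [20] * 4, "sympatric"),
            n_boot=1000, seed=5,
        )
        assert est.i_psi == 1.0
        assert est.se_boot == 0.0

    def test_recompute_expected_variant_runs(self):
        est = bootstrap_ipsi(
            mating_trial_table("sympatric"), n_boot=1000, seed=3, recompute_expected=True
        )
        assert 0.04 < est.se_boot < 0.12

    def test_guards(self):
        table = mating_trial_table("sympatric")
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ipsi(table, n_boot=10, seed=1)
        with pytest.raises(ValueError, match="seed"):
            bootstrap_ipsi(table, n_boot=1000)

    def test_model_object_surface(self):
        res = IsolationIndexModel(mating_trial_table("allopatric")).fit(n_boot=1000, seed=2)
        assert "I_PSI" in res.summary()
        assert res.location_class == "allopatric"


def _trial(i, f_sp, m_sp, loc, mounted, durations=(), **kw):
    return TrialRecord(
        trial_id=f"t{i}", male_species=m_sp, female_species=f_sp,
        male_site="x", female_site="y", location_class=loc,
        mounted=mounted, mount_durations=list(durations), **kw,
    )


class TestTabulate:
    def test_hand_tally(self):
        recs = [
            _trial(0, "cingulata", "cingulata", "sympatric", True, [5.0]),
            _trial(1, "cingulata", "cingulata", "sympatric", False),
            _trial(2, "cingulata", "filosa", "sympatric", False),
            _trial(3, "filosa", "cingulata", "sympatric", True, [2.0, 3.0]),
            _trial(4, "filosa", "filosa", "sympatric", True, [10.0]),
            _trial(5, "filosa", "filosa", "sympatric", True, [1.0]),
            _trial(6, "filosa", "filosa", "sympatric", False),
            _trial(7, "cingulata", "filosa", "sympatric", None),  # unusable
        ]
        table = tabulate_trials(recs, "sympatric")
        assert table.cell("cingulata", "cingulata") == (1, 2)
        assert table.cell("cingulata", "filosa") == (0, 1)
        assert table.cell("filosa", "cingulata") == (1, 1)
        assert table.cell("filosa", "filosa") == (2, 3)
        assert table.n_trials == 7  # the unusable trial is dropped

    def test_empty_cell_is_an_error(self):
        recs = [
            _trial(0, "cingulata", "cingulata", "sympatric", True, [5.0]),
            _trial(1, "cingulata", "filosa", "sympatric", False),
            _trial(2, "filosa", "cingulata", "sympatric", False),
        ]
        with pytest.raises(ValueError, match="no trials in cell"):
            tabulate_trials(recs, "sympatric")

    def test_no_trials_is_an_error(self):
        with pytest.raises(ValueError, match="no trials"):
            tabulate_trials([], "sympatric")

    def test_record_validation(self):
        with pytest.raises(ValueError, match="different sites"):
            TrialRecord("a", "cingulata", "cingulata", "s1", "s1", "sympatric", False)
        with pytest.raises(ValueError, match="durations"):
            _trial(0, "cingulata", "cingulata", "sympatric", True, [])


class TestInteractionGLM:
    def _make_records(self, probs, n_per_cell, rng):
        recs = []
        i = 0
        for loc in ("sympatric", "allopatric"):
            for f_sp in ("cingulata", "filosa"):
                for m_sp in ("cingulata", "filosa"):
                    p = probs[(loc, f_sp, m_sp)]
                    for _ in range(n_per_cell):
                        mounted = bool(rng.random() < p)
                        recs.append(
                            _trial(
                                i, f_sp, m_sp, loc, mounted,
                                [float(rng.lognormal(3, 1))] if mounted else (),
                                researcher=["R1", "R2"][i % 2],
                                time_block=["AM", "PM"][(i // 2) % 2],
                            )
                        )
                        i += 1
        return recs

    def test_detects_generated_interaction(self, rng):
        """Halved sympatric heterospecific mounting is detected at n=200/cell."""
        probs = {}
        for loc in ("sympatric", "allopatric"):
            for f_sp in ("cingulata", "filosa"):
                for m_sp in ("cingulata", "filosa"):
                    hetero = f_sp != m_sp
                    p = 0.5
                    if hetero and loc == "sympatric":
                        p = 0.25
                    probs[(loc, f_sp, m_sp)] = p
        recs = self._make_records(probs, 200, rng)
        res = mating.three_way_interaction_test(recs, "mounting")
        assert res.df == 1
        assert res.p_value < 0.05

    def test_exactly_balanced_outcomes_give_zero_statistic(self):
        recs = []
        i = 0
        for loc in ("sympatric", "allopatric"):
            for f_sp in ("cingulata", "filosa"):
                for m_sp in ("cingulata", "filosa"):
                    for mounted in [True] * 10 + [False] * 10:
                        recs.append(
                            _trial(i, f_sp, m_sp, loc, mounted, [5.0] if mounted else ())
                        )
                        i += 1
        res = mating.three_way_interaction_test(recs, "mounting")
        assert res.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_duration_response_detects_short_sympatric_heterospecific(self, rng):
        recs = []
        i = 0
        for loc in ("sympatric", "allopatric"):
            for f_sp in ("cingulata", "filosa"):
                for m_sp in ("cingulata", "filosa"):
                    mu = 2.0 if (f_sp != m_sp and loc == "sympatric") else 4.0
                    for _ in range(60):
                        recs.append(
                            _trial(
                                i, f_sp, m_sp, loc, True,
                                [float(rng.lognormal(mu, 0.8))],
                                male_size_mm=float(rng.normal(18, 2)),
                                female_size_mm=float(rng.normal(20, 2)),
                                female_maturity=str(rng.choice(["maturing", "mature"])),
                            )
                        )
                        i += 1
        res = mating.three_way_interaction_test(recs, "log_duration")
        assert res.df == 1
        assert res.p_value < 0.01


class TestSpermDuration:
    def _records(self, slope, n, rng, intercept=-2.4):
        recs = []
        for i in range(n):
            dur = float(rng.lognormal(3.5, 1.2))
            eta = intercept + slope * math.log(dur)
            sperm = bool(rng.random() < 1 / (1 + math.exp(-eta)))
            recs.append(
                _trial(i, "cingulata", "filosa", "sympatric", True, [dur],
                       sperm_in_bursa=sperm)
            )
        return recs

    def test_recovers_generated_slope(self, rng):
        res = mating.sperm_duration_test(self._records(0.59, 300, rng))
        assert abs(res.slope_logit - 0.59) < 2 * res.se
        assert res.df == 1

    def test_null_slope_ci_covers_zero(self, rng):
        res = mating.sperm_duration_test(self._records(0.0, 300, rng))
        assert abs(res.slope_logit) < 2.5 * res.se

    def test_degenerate_response_flagged(self):
        recs = [
            _trial(i, "cingulata", "filosa", "sympatric", True, [10.0], sperm_in_bursa=True)
            for i in range(20)
        ]
        res = mating.sperm_duration_test(recs)
        assert res.separation_flag

    def test_too_few_trials_is_an_error(self):
        recs = [
            _trial(i, "cingulata", "filosa", "sympatric", True, [10.0], sperm_in_bursa=bool(i % 2))
            for i in range(5)
        ]
        with pytest.raises(ValueError, match=">= 10"):
            mating.sperm_duration_test(recs)


def test_trials_csv_round_trip(tmp_path, rng):
    from rcdkit.synth import TrialSimConfig, gen_trials

    recs = gen_trials(TrialSimConfig(n_trials_per_cell=5), seed=3)
    path = tmp_path / "trials.csv"
    mating.write_trials_csv(recs, path)
    back = mating.read_trials_csv(path)
    assert len(back) == len(recs)
    for a, b in zip(recs, back):
        assert (a.trial_id, a.male_species, a.female_species, a.location_class) == (
            b.trial_id, b.male_species, b.female_species, b.location_class
        )
        assert a.mounted == b.mounted
        assert np.allclose(a.mount_durations, b.mount_durations)
        assert a.sperm_in_bursa == b.sperm_in_bursa


def test_insertion_rate():
    recs = [
        _trial(0, "cingulata", "cingulata", "sympatric", True, [5.0], insertion_observed=True),
        _trial(1, "cingulata", "cingulata", "sympatric", True, [5.0], insertion_observed=False),
        _trial(2, "cingulata", "cingulata", "sympatric", True, [5.0], insertion_observed=True),
        _trial(3, "cingulata", "cingulata", "sympatric", False),
    ]
    assert mating.insertion_rate(recs) == pytest.approx(2 / 3)
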