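"""Count tables, priors, reweighting and the per-cell logistic fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import singlerecall as sr
from singlerecall._util import DEL, FORWARD, REVERSE, sigmoid
from singlerecall.error_model import (
    MutationRateMatrix,
    ReweightedCell,
    STATUS_CONSTANT,
    STATUS_OK,
    build_priors,
    count_qscores,
    fit_cell,
    reweight,
)

from conftest import make_record, perfect_reads


def ref4():
    return sr.ReferenceSequence("ref", "ACGT")


class TestCountQscores:
    def test_perfect_reads(self):
        reference = ref4()
        table = count_qscores(perfect_reads(reference, 10, q=15), reference)
        for p, base in enumerate(reference.codes):
            assert table.counts[p, FORWARD, base, 15] == 10
            assert table.counts[p, FORWARD].sum() == 10  # nothing else counted
        assert np.all(table.counts[:, REVERSE] == 0)

    def test_single_error_lands_in_its_cell(self):
        reference = ref4()
        reads = perfect_reads(reference, 1, q=15)
        # observe A (Q=7) where the reference has G at position 2
        err = make_record("e", [0, 1, 0, 3], [15, 15, 7, 15])
        table = count_qscores(reads + [err], reference)
        assert table.counts[2, FORWARD, 0, 7] == 1

    def test_counts_match_simulation_ledger(self, small_exp):
        """Every injected wild-type error is recovered in the count table."""
        exp = small_exp
        records = [sr.assign_deletion_qscores(r) for r in exp.wt_reads]
        table = count_qscores(records, exp.reference)
        expected = np.zeros((len(exp.reference), 2, 5), dtype=int)
        n_wt_reads = 0
        for rid, info in exp.ledger.reads.items():
            if info["variant"] != "wt":
                continue
            n_wt_reads += 1
            s = 0 if info["strand"] == "+" else 1
            for p, sym, _q in info["errors"]:
                expected[p, s, "ACGT-".index(sym)] += 1
        assert n_wt_reads == len(exp.wt_reads)
        observed = table.counts.sum(axis=3)
        ref_codes = exp.reference.codes
        for s in (FORWARD, REVERSE):
            mism = np.ones((len(exp.reference), 5), dtype=bool)
            mism[np.arange(len(exp.reference)), ref_codes] = False
            assert np.array_equal(observed[:, s, :][mism], expected[:, s, :][mism])

    def test_count_conservation(self, small_exp):
        """Per (position, strand), counts sum to the reads covering it."""
        records = [sr.assign_deletion_qscores(r) for r in small_exp.wt_reads]
        table = count_qscores(records, small_exp.reference)
        n_fwd = sum(1 for r in records if r.strand == FORWARD)
        n_rev = len(records) - n_fwd
        cov = table.coverage()
        assert np.all(cov[:, FORWARD] == n_fwd) and np.all(cov[:, REVERSE] == n_rev)

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError, match="no wild-type reads"):
            count_qscores([], ref4())

    def test_unscored_deletions_rejected(self):
        rec = make_record("r", [0, DEL, 2, 3], [10, -1, 10, 10])
        with pytest.raises(ValueError, match="unscored deletion"):
            count_qscores([rec], ref4())


class TestPriorRight:
    def test_uniform_case(self):
        # uniform rates, uniform base composition, <m>=3, L=300 -> 1/300 each
        reference = sr.ReferenceSequence("ref", "ACGT" * 75)
        matrix = MutationRateMatrix.uniform(mean_mutations=3.0)
        priors = sr.compute_prior_right(matrix, reference)
        off_diag = priors.p_prior_right[:, :4][~np.eye(4, dtype=bool)]
        assert np.allclose(off_diag, 1 / 300)

    def test_linear_in_mean_mutations(self):
        reference = sr.ReferenceSequence("ref", "ACGTGGTTAC")
        m1 = sr.compute_prior_right(MutationRateMatrix.uniform(1.0), reference)
        m2 = sr.compute_prior_right(MutationRateMatrix.uniform(2.0), reference)
        assert np.allclose(m2.p_prior_right, 2 * m1.p_prior_right)

    def test_zero_rate_stays_zero(self):
        rates = np.ones((4, 4)) - np.eye(4)
        rates[0, 2] = 0.0  # forbid A->G
        priors = sr.compute_prior_right(
            MutationRateMatrix(rates, mean_mutations=2.0), ref4()
        )
        assert priors.p_prior_right[0, 2] == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_expected_mutation_count_conserved(self, seed):
        """sum_n counts_ref(n) * p_prior_right(n->n') recovers <m> exactly."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(30, 400))
        reference = sr.random_reference(L, seed=seed + 1)
        rates = rng.uniform(0, 5, size=(4, 4)) * (1 - np.eye(4))
        dels = rng.uniform(0, 1, size=4) if rng.uniform() < 0.5 else np.zeros(4)
        # keep the load small enough that per-site priors stay probabilities
        mm = float(rng.uniform(0.1, L / 40))
        matrix = MutationRateMatrix(rates, mean_mutations=mm, del_rates=dels)
        priors = sr.compute_prior_right(matrix, reference)
        counts = reference.base_counts()
        total = float(counts @ priors.p_prior_right.sum(axis=1))
        assert total == pytest.approx(mm, abs=1e-12 * max(1, mm))


class TestPriorError:
    def test_empirical_fraction(self):
        reference = ref4()
        reads = perfect_reads(reference, 93, q=12)
        for i in range(7):
            bad = make_record(f"e{i}", [0, 1, 2, 3], [12, 12, 8, 12])
            bad.symbols[0] = 2  # read G where reference has A
            reads.append(bad)
        table = count_qscores(reads, reference)
        p = sr.compute_prior_error(table, reference)
        assert p[0, FORWARD, 2] == pytest.approx(0.07)
        assert p[1, FORWARD, 0] == 0.0  # no errors at that cell
        assert np.isnan(p[0, REVERSE, 2])  # zero coverage is flagged, not 0

    def test_hotspot_rate_recovered_within_binomial_error(self, small_exp):
        """The simulator's programmed hotspot rate is recovered from the
        wild-type count table within 4 binomial standard errors."""
        exp = small_exp
        records = [sr.assign_deletion_qscores(r) for r in exp.wt_reads]
        table = count_qscores(records, exp.reference)
        p = sr.compute_prior_error(table, exp.reference)
        for hp in exp.profile.hotspots:
            for s in (FORWARD, REVERSE):
                n = table.coverage(int(hp), s)
                if n < 30:
                    continue
                rate = exp.profile.sub_rates[s, hp].sum() + exp.profile.del_rates[s, hp]
                observed = np.nansum(p[hp, s])
                se = np.sqrt(rate * (1 - rate) / n)
                assert abs(observed - rate) < 4 * se + 1e-9


class TestReweight:
    def setup_cell(self, c_wt, c_mut, p_right=0.01, p_err=0.05):
        """Build a 4-nt study with direct control of the table and priors."""
        reference = ref4()
        table_counts = np.zeros((4, 2, 5, 51), dtype=np.int64)
        for q, n in c_wt.items():
            table_counts[0, FORWARD, 0, q] = n  # ref base A at pos 0
        for q, n in c_mut.items():
            table_counts[0, FORWARD, 2, q] = n  # errors read as G
        from singlerecall.error_model import QscoreCountTable, PriorTable

        table = QscoreCountTable(table_counts, n_reads=sum(c_wt.values()))
        pr = np.zeros((4, 5))
        pr[0, 2] = p_right
        pe = np.full((4, 2, 5), np.nan)
        pe[0, FORWARD, 2] = p_err
        priors = PriorTable(p_prior_right=pr, p_prior_error=pe)
        return table, priors, reference

    def test_equal_mass_gives_half(self):
        # same Q distribution and equal prior mass in both classes -> 0.5
        table, priors, reference = self.setup_cell(
            {10: 50, 20: 50}, {10: 50, 20: 50}, p_right=0.03, p_err=0.03
        )
        cell = reweight(table, priors, 0, 2, FORWARD, reference)
        assert np.allclose(cell.n_correct, 0.5)

    def test_zero_prior_error_gives_one(self):
        table, priors, reference = self.setup_cell({10: 40, 20: 60}, {}, p_err=0.0)
        # no errors observed, prior error 0 -> certainty of correctness
        priors.p_prior_error[0, FORWARD, 2] = 0.0
        cell = reweight(table, priors, 0, 2, FORWARD, reference)
        assert cell.defined and np.allclose(cell.n_correct, 1.0)

    def test_monotone_in_prior_error(self):
        table, priors, reference = self.setup_cell(
            {8: 30, 14: 40, 20: 30}, {6: 20, 10: 15, 14: 5}, p_err=0.01
        )
        lo = reweight(table, priors, 0, 2, FORWARD, reference)
        priors.p_prior_error[0, FORWARD, 2] = 0.10
        hi = reweight(table, priors, 0, 2, FORWARD, reference)
        assert np.all(hi.n_correct <= lo.n_correct + 1e-15)
        assert np.any(hi.n_correct < lo.n_correct)

    def test_undefined_bins_are_excluded_not_zero_filled(self):
        table, priors, reference = self.setup_cell({10: 5}, {30: 2})
        cell = reweight(table, priors, 0, 2, FORWARD, reference)
        assert set(cell.qs) == {10, 30}


def make_cell(qs, ys, ws):
    qs = np.asarray(qs, float)
    return ReweightedCell(
        ref_pos=0, symbol=1, strand=0,
        qs=np.asarray(qs), n_correct=np.asarray(ys, float),
        weights=np.asarray(ws, float),
        p_mutation=np.zeros_like(qs), p_wildtype=np.zeros_like(qs), defined=True,
    )


class TestFitCell:
    def test_flat_half_gives_constant(self):
        b0, b1, status = fit_cell(make_cell([5, 10, 20], [0.5, 0.5, 0.5], [10, 10, 10]))
        assert b1 == 0.0 and sigmoid(b0) == pytest.approx(0.5)

    def test_all_correct_is_separation_fallback(self):
        b0, b1, status = fit_cell(make_cell([5, 10, 20], [1.0, 1.0, 1.0], [5, 5, 5]))
        assert status == STATUS_CONSTANT and b1 == 0.0
        assert sigmoid(b0) >= 1 - 1e-6 - 1e-12

    def test_matches_statsmodels_glm(self):
        """Independent route: the damped-Newton fit agrees with a
        statsmodels binomial GLM on random well-posed cells."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        for _ in range(30):
            k = int(rng.integers(3, 6))
            qs = np.sort(rng.choice(np.arange(1, 41), size=k, replace=False))
            ys = rng.uniform(0.05, 0.95, size=k)
            ws = rng.uniform(1, 100, size=k)
            b0, b1, status = fit_cell(make_cell(qs, ys, ws))
            assert status == STATUS_OK
            X = sm.add_constant(qs.astype(float))
            glm = sm.GLM(ys, X, family=sm.families.Binomial(), var_weights=ws)
            res = glm.fit(tol=1e-12, maxiter=200)
            ours = sigmoid(b0 + b1 * qs)
            theirs = sigmoid(res.params[0] + res.params[1] * qs)
            assert np.max(np.abs(ours - theirs)) < 1e-6

    def test_prediction_clamped(self, small_model):
        model = small_model.model_
        qs = np.arange(0, 51)
        for p in range(0, model.L, 17):
            for s in (FORWARD, REVERSE):
                for n in range(5):
                    if model.status[p, s, n] == 255:
                        continue
                    pred = model.predict(p, s, n, qs)
                    assert np.all(pred >= 1e-6) and np.all(pred <= 1 - 1e-6)


class TestPriorShift:
    def test_larger_mutation_prior_never_lowers_acceptance(self):
        """Scaling up p_prior_right raises the posterior probability that
        an observed mismatch is a real mutation at every defined Qscore
        bin (the reweighting effect behind the curve shift), and the
        overall fitted acceptance rises with it."""
        rng = np.random.default_rng(3)
        c_wt = {int(q): int(n) for q, n in zip(rng.integers(5, 30, 6),
                                               rng.integers(10, 80, 6))}
        c_mut = {int(q): int(n) for q, n in zip(rng.integers(1, 20, 4),
                                                rng.integers(1, 20, 4))}
        t = TestReweight()
        table, priors, reference = t.setup_cell(c_wt, c_mut, p_right=0.002, p_err=0.04)
        lo_cell = reweight(table, priors, 0, 2, FORWARD, reference)
        lo = fit_cell(lo_cell)
        priors.p_prior_right[0, 2] = 0.02  # x10 mutation prior
        hi_cell = reweight(table, priors, 0, 2, FORWARD, reference)
        hi = fit_cell(hi_cell)
        # exact pointwise monotonicity of the reweighted posterior
        assert np.array_equal(lo_cell.qs, hi_cell.qs)
        assert np.all(hi_cell.n_correct >= lo_cell.n_correct - 1e-15)
        assert np.any(hi_cell.n_correct > lo_cell.n_correct)
        # the fitted curves inherit the shift on average over the data
        qs = hi_cell.qs.astype(float)
        mean_hi = np.average(sigmoid(hi[0] + hi[1] * qs), weights=hi_cell.weights)
        mean_lo = np.average(sigmoid(lo[0] + lo[1] * qs), weights=lo_cell.weights)
        assert mean_hi > mean_lo


class TestTrain:
    def test_cell_cardinality_small(self):
        reference = sr.random_reference(10, seed=5)
        reads = perfect_reads(reference, 30, q=20)
        reads += perfect_reads(reference, 30, q=18, strand=REVERSE)
        model = sr.train(reads, reference, MutationRateMatrix.uniform(1.0), min_reads=10)
        assert model.n_cells == 10 * 4 * 2

    def test_save_load_round_trip(self, tmp_path, small_model):
        """A reloaded model predicts identically on a probe grid."""
        model = small_model.model_
        path = tmp_path / "model.single"
        model.save(path)
        back = sr.FitModel.load(path)
        assert back.reference_checksum == model.reference_checksum
        qs = np.arange(1, 41)
        for p in range(0, model.L, 13):
            for s in (FORWARD, REVERSE):
                for n in range(5):
                    if model.status[p, s, n] == 255:
                        assert back.status[p, s, n] == 255
                        continue
                    assert np.array_equal(
                        model.predict(p, s, n, qs), back.predict(p, s, n, qs)
                    )

    def test_few_reads_warns_but_trains(self, caplog):
        reference = sr.random_reference(6, seed=2)
        reads = perfect_reads(reference, 5, q=20)
        with caplog.at_level("WARNING"):
            model = sr.train(reads, reference, MutationRateMatrix.uniform(1.0))
        assert model.n_cells == 6 * 4 * 2
        assert any("wild-type reads" in r.message for r in caplog.records)

    def test_every_cell_scorable(self, small_model):
        """All cells carry finite coefficients and a status, even where
        the wild-type data were empty."""
        model = small_model.model_
        active = model.status != 255
        assert np.all(np.isfinite(model.b0[active]))
        assert np.all(np.isfinite(model.b1[active]))
        assert active.sum() == model.L * 4 * 2
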