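"""Cohen's kappa and ICC(A,1) against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from psgagree.agreement import (
    average_channel_kappa,
    cohen_kappa,
    icc_a1,
    pairwise_kappa,
)
from psgagree.discretize import ContingencyTable, EpochGrid, LabelSequence
from psgagree.errors import AlignmentError, DegenerateDataError, DomainError

BIN = ("absent", "present")


def _table(counts, alphabet=BIN):
    return ContingencyTable(alphabet, np.asarray(counts, dtype=np.int64))


def _seqs(rng, m, n=500):
    grid = EpochGrid(0.0, 0.5, n, BIN)
    return {f"s{i:02d}": LabelSequence(grid,
                                       rng.integers(0, 2, n).astype(np.int16))
            for i in range(m)}


def icc_oracle(data):
    """Brute-force two-way ANOVA decomposition of the A,1 coefficient."""
    data = np.asarray(data, float)
    n, k = data.shape
    grand = data.mean()
    msr = k * sum((row.mean() - grand) ** 2 for row in data) / (n - 1)
    msc = n * sum((col.mean() - grand) ** 2 for col in data.T) / (k - 1)
    sse = sum((data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestCohenKappa:
    def test_hand_computed_2x2_example(self):
        res = cohen_kappa(_table([[40, 10], [5, 45]]))
        assert res.p_observed == pytest.approx(0.85)
        assert res.p_expected == pytest.approx(0.50)
        assert res.kappa == pytest.approx(0.70)

    def test_perfect_agreement(self):
        assert cohen_kappa(_table([[30, 0], [0, 70]])).kappa == 1.0

    def test_independent_raters_give_near_zero_kappa(self):
        rng = np.random.default_rng(11)
        n = 100_000
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        counts = np.zeros((2, 2), dtype=np.int64)
        np.add.at(counts, (a, b), 1)
        assert abs(cohen_kappa(_table(counts)).kappa) < 0.02

    def test_alphabet_permutation_invariance(self, rng):
        counts = rng.integers(0, 50, (5, 5))
        perm = rng.permutation(5)
        t1 = _table(counts, tuple("abcde"))
        t2 = _table(counts[np.ix_(perm, perm)], tuple("abcde"))
        assert cohen_kappa(t1).kappa == pytest.approx(cohen_kappa(t2).kappa)

    def test_rater_symmetry(self, rng):
        counts = rng.integers(0, 50, (5, 5))
        assert cohen_kappa(_table(counts, tuple("abcde"))).kappa == \
            pytest.approx(cohen_kappa(_table(counts.T, tuple("abcde"))).kappa)

    def test_degenerate_all_absent_pair(self):
        res = cohen_kappa(_table([[100, 0], [0, 0]]))
        assert res.kappa == 1.0 and res.degenerate

    def test_empty_table_is_domain_error(self):
        with pytest.raises(DomainError):
            cohen_kappa(_table([[0, 0], [0, 0]]))


class TestPairwiseKappa:
    def test_twelve_scorers_give_66_pairs(self, rng):
        results = pairwise_kappa(_seqs(rng, 12))
        assert len(results) == 66
        pairs = [r.pair for r in results]
        assert pairs == sorted(pairs)  # lexicographic order

    def test_two_scorers_give_one_pair(self, rng):
        assert len(pairwise_kappa(_seqs(rng, 2))) == 1

    def test_identical_sequences_give_kappa_one(self, rng):
        seqs = _seqs(rng, 4)
        first = next(iter(seqs.values()))
        same = {sid: first for sid in seqs}
        assert all(r.kappa == 1.0 for r in pairwise_kappa(same))

    def test_mismatched_grids_rejected(self, rng):
        seqs = _seqs(rng, 2)
        grid2 = EpochGrid(0.0, 0.5, 400, BIN)
        seqs["s01"] = LabelSequence(grid2, np.zeros(400, dtype=np.int16))
        with pytest.raises(AlignmentError):
            pairwise_kappa(seqs)


class TestChannelAveraging:
    def _kr(self, kappa, pair=("a", "b")):
        from psgagree.agreement import KappaResult

        return KappaResult(kappa, 0.9, 0.5, 100, pair, "tib")

    def test_idempotence(self):
        assert average_channel_kappa(self._kr(0.8), self._kr(0.8)).kappa == 0.8

    def test_mean_of_extremes(self):
        res = average_channel_kappa(self._kr(1.0), self._kr(0.0))
        assert res.kappa == 0.5 and res.n == 200

    def test_betweenness(self, rng):
        for _ in range(20):
            x, y = rng.uniform(-1, 1, 2)
            k = average_channel_kappa(self._kr(x), self._kr(y)).kappa
            assert min(x, y) <= k <= max(x, y)

    def test_pair_mismatch_rejected(self):
        with pytest.raises(DomainError):
            average_channel_kappa(self._kr(0.5), self._kr(0.5, pair=("a", "c")))


class TestIccA1:
    def test_matches_brute_force_anova_oracle(self, rng):
        for _ in range(20):
            n, k = int(rng.integers(3, 9)), int(rng.integers(2, 7))
            data = rng.normal(size=(n, k)) + 2 * rng.normal(size=(n, 1))
            assert icc_a1(data).icc == pytest.approx(icc_oracle(data),
                                                     abs=1e-10)

    def test_matches_pingouin_estimate_and_ci(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(5):
            n, k = int(rng.integers(4, 9)), int(rng.integers(2, 6))
            data = rng.normal(size=(n, k)) + 2 * rng.normal(size=(n, 1))
            res = icc_a1(data, r0=0.0)
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "ratings": data.ravel()})
            row = pg.intraclass_corr(df, targets="targets", raters="raters",
                                     ratings="ratings")
            row = row[row.Type == "ICC(A,1)"].iloc[0]
            assert res.icc == pytest.approx(row.ICC, abs=1e-10)
            assert res.ci_low == pytest.approx(row.CI95[0], abs=0.005)
            assert res.ci_high == pytest.approx(row.CI95[1], abs=0.005)
            assert res.p_value == pytest.approx(row.pval, rel=1e-8)

    def test_identical_raters_give_icc_one(self):
        col = np.array([1.0, 2.0, 5.0, 7.0])
        data = np.column_stack([col, col, col])
        assert icc_a1(data).icc == pytest.approx(1.0)

    def test_example_5x2_ladder_matrix(self):
        data = np.array([[1, 2], [2, 3], [3, 4], [4, 5], [5, 6]], float)
        assert icc_a1(data).icc == pytest.approx(icc_oracle(data), abs=1e-10)

    def test_rater_offset_lowers_absolute_agreement(self, rng):
        data = rng.normal(size=(6, 3)) + 2 * rng.normal(size=(6, 1))
        shifted = data.copy()
        shifted[:, 0] += 1.5
        assert icc_a1(shifted).icc < icc_a1(data).icc

    def test_concordant_data_significant_against_zero(self):
        rng = np.random.default_rng(3)
        subjects = rng.uniform(0, 100, size=(8, 1))
        data = subjects + rng.normal(0, 0.5, size=(8, 10))
        res = icc_a1(data, r0=0.0)
        assert res.p_value < 1e-4

    def test_r0_at_estimate_is_not_significant(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 10, size=(6, 1)) + rng.normal(0, 1, size=(6, 5))
        res = icc_a1(data, r0=0.0)
        res2 = icc_a1(data, r0=max(res.icc - 0.01, 0.0))
        assert res2.p_value > 0.05

    def test_constant_matrix_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            icc_a1(np.full((4, 3), 2.5))

    def test_ci_brackets_estimate(self, rng):
        data = rng.normal(size=(7, 4)) + rng.normal(size=(7, 1))
        res = icc_a1(data)
        assert res.ci_low <= res.icc <= res.ci_high
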