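"""Entropy-family math: closed forms, limits, pseudo-additivity, features."""

import math

import numpy as np
import pytest
from scipy.stats import entropy as scipy_entropy

from seqentropy import (
    Alphabet,
    EntropySpec,
    KmerDistribution,
    SequenceRecord,
    extract_features,
    extract_table,
    read_feature_csv,
    renyi_entropy,
    shannon_entropy,
    tsallis_entropy,
    write_feature_csv,
)
from seqentropy.synthetic_fixtures import worked_examples


def dist(counts: dict[str, int]) -> KmerDistribution:
    k = len(next(iter(counts)))
    return KmerDistribution(k=k, counts=counts, total_windows=sum(counts.values()))


def product_dist(a: KmerDistribution, b: KmerDistribution) -> KmerDistribution:
    """Joint distribution of two independent k-mer distributions."""
    counts = {
        wa + wb: ca * cb for wa, ca in a.counts.items() for wb, cb in b.counts.items()
    }
    return KmerDistribution(
        k=a.k + b.k, counts=counts, total_windows=a.total_windows * b.total_windows
    )


def random_dist(rng: np.random.Generator, max_support: int = 12) -> KmerDistribution:
    m = int(rng.integers(2, max_support + 1))
    counts = {f"w{i}": int(c) for i, c in enumerate(rng.integers(1, 50, size=m))}
    return dist(counts)


UNIFORM4 = dist({"A": 1, "C": 1, "G": 1, "T": 1})
CERTAIN = dist({"A": 7})
DIMERS_ACGTACGT = dist({"AC": 2, "CG": 2, "GT": 2, "TA": 1})


class TestShannon:
    def test_uniform_four(self):
        assert shannon_entropy(UNIFORM4) == pytest.approx(2.0)

    def test_certainty(self):
        assert shannon_entropy(CERTAIN) == 0.0

    def test_worked_dimer_distribution(self):
        assert shannon_entropy(DIMERS_ACGTACGT) == pytest.approx(1.9502, abs=1e-3)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = random_dist(rng)
            assert shannon_entropy(d) == pytest.approx(
                scipy_entropy(d.prob_array(), base=2), abs=1e-12
            )

    def test_empty_distribution_is_zero(self):
        assert shannon_entropy(KmerDistribution(k=3, counts={}, total_windows=0)) == 0.0


class TestTsallis:
    def test_two_even_outcomes_q2(self):
        assert tsallis_entropy(dist({"A": 1, "B": 1}), 2.0) == pytest.approx(0.5)

    def test_uniform_four_q2(self):
        assert tsallis_entropy(UNIFORM4, 2.0) == pytest.approx(0.75)

    def test_certainty_any_q(self):
        for q in (0.3, 1.0, 2.0, 7.0):
            assert tsallis_entropy(CERTAIN, q) == 0.0

    def test_worked_dimer_distribution_q2(self):
        assert tsallis_entropy(DIMERS_ACGTACGT, 2.0) == pytest.approx(36 / 49)

    def test_nonpositive_q_rejected(self):
        for q in (0.0, -1.0):
            with pytest.raises(ValueError, match="q"):
                tsallis_entropy(UNIFORM4, q)


class TestRenyi:
    def test_uniform_is_log_support_for_every_q(self):
        for q in (0.5, 2.0, 5.0):
            assert renyi_entropy(UNIFORM4, q) == pytest.approx(2.0)

    def test_worked_three_outcome_q2(self):
        d = dist({"A": 2, "B": 1, "C": 1})  # probs 0.5, 0.25, 0.25
        assert renyi_entropy(d, 2.0) == pytest.approx(-math.log2(0.375))

    def test_certainty(self):
        assert renyi_entropy(CERTAIN, 7.0) == 0.0

    def test_nonpositive_q_rejected(self):
        with pytest.raises(ValueError, match="q"):
            renyi_entropy(UNIFORM4, -0.5)


class TestClosedFormsAndBounds:
    @pytest.mark.parametrize("m", [2, 4, 16, 20])
    @pytest.mark.parametrize("q", [0.5, 2.0, 3.0, 5.0])
    def test_uniform_closed_forms(self, m, q):
        d = dist({f"w{i}": 1 for i in range(m)})
        assert shannon_entropy(d) == pytest.approx(math.log2(m))
        assert renyi_entropy(d, q) == pytest.approx(math.log2(m))
        assert tsallis_entropy(d, q) == pytest.approx((1 - m ** (1 - q)) / (q - 1))

    def test_limits_at_q_one(self):
        """Tsallis q->1 is Shannon in nats; Renyi q->1 is Shannon in bits."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            d = random_dist(rng)
            hs = shannon_entropy(d)
            for q in (1 - 1e-6, 1 + 1e-6):
                assert abs(tsallis_entropy(d, q) - hs * math.log(2)) <= 1e-4
                assert abs(renyi_entropy(d, q) - hs) <= 1e-4
            # exact-q=1 path uses the analytic limit directly
            assert tsallis_entropy(d, 1.0) == pytest.approx(hs * math.log(2))
            assert renyi_entropy(d, 1.0) == pytest.approx(hs)

    def test_monotone_nonincreasing_in_q(self):
        rng = np.random.default_rng(13)
        qs = [0.2, 0.5, 0.9, 1.0, 1.5, 2.0, 4.0, 8.0]
        for _ in range(20):
            d = random_dist(rng)
            ts = [tsallis_entropy(d, q) for q in qs]
            rs = [renyi_entropy(d, q) for q in qs]
            assert all(a >= b - 1e-12 for a, b in zip(ts, ts[1:]))
            assert all(a >= b - 1e-12 for a, b in zip(rs, rs[1:]))

    def test_pseudo_additivity_and_extensivity_regimes(self):
        """H_T(AxB) = H_T(A)+H_T(B)+(1-q)H_T(A)H_T(B); Shannon adds exactly."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            a, b = random_dist(rng, 8), random_dist(rng, 8)
            ab = product_dist(a, b)
            for q in (0.5, 2.0, 3.0):
                ht_a, ht_b = tsallis_entropy(a, q), tsallis_entropy(b, q)
                ht_ab = tsallis_entropy(ab, q)
                assert ht_ab == pytest.approx(
                    ht_a + ht_b + (1 - q) * ht_a * ht_b, abs=1e-9
                )
                if ht_a > 1e-9 and ht_b > 1e-9:
                    if q < 1:  # superextensive
                        assert ht_ab > ht_a + ht_b
                    else:  # subextensive
                        assert ht_ab < ht_a + ht_b
            assert shannon_entropy(ab) == pytest.approx(
                shannon_entropy(a) + shannon_entropy(b), abs=1e-9
            )

    def test_nonnegative_and_bounded_by_uniform(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            d = random_dist(rng)
            m = d.support_size
            for q in (0.5, 2.0, 5.0):
                ht, hr = tsallis_entropy(d, q), renyi_entropy(d, q)
                assert 0 <= ht <= (1 - m ** (1 - q)) / (q - 1) + 1e-12
                assert 0 <= hr <= math.log2(m) + 1e-12
            assert 0 <= shannon_entropy(d) <= math.log2(m) + 1e-12


class TestExtractFeatures:
    def test_composition_of_worked_distributions(self, dna_record):
        fv = extract_features(dna_record, EntropySpec(family="tsallis", q=2.0, k_max=2))
        np.testing.assert_allclose(fv.values, [0.75, 36 / 49])

    def test_single_symbol_sequence_all_zero(self):
        rec = SequenceRecord(id="a", residues="AAAAAAAA", alphabet=Alphabet.DNA)
        for family in ("tsallis", "shannon", "renyi"):
            fv = extract_features(rec, EntropySpec(family=family, q=3.0, k_max=3))
            np.testing.assert_array_equal(fv.values, [0.0, 0.0, 0.0])

    def test_default_spec_yields_24_values(self):
        rng = np.random.default_rng(1)
        rec = SequenceRecord(
            id="a",
            residues="".join(rng.choice(list("ACGT"), size=120)),
            alphabet=Alphabet.DNA,
        )
        fv = extract_features(rec, EntropySpec())
        assert len(fv.values) == 24
        assert np.isfinite(fv.values).all()
        assert (fv.values >= 0).all()

    def test_degenerate_ks_flagged(self):
        rec = SequenceRecord(id="a", residues="ACG", alphabet=Alphabet.DNA)
        fv = extract_features(rec, EntropySpec(k_max=5))
        assert fv.degenerate_ks == (4, 5)
        assert fv.values[3] == fv.values[4] == 0.0

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            EntropySpec(family="tsallis", q=-1.0)
        with pytest.raises(ValueError):
            EntropySpec(family="boltzmann")


class TestFeatureTable:
    def _records(self, n=10):
        rng = np.random.default_rng(4)
        return [
            SequenceRecord(
                id=f"r{i}",
                residues="".join(rng.choice(list("ACGT"), size=60)),
                alphabet=Alphabet.DNA,
                label="pos" if i % 2 else "neg",
            )
            for i in range(n)
        ]

    def test_shape_and_header(self):
        table = extract_table(self._records(), EntropySpec(k_max=24))
        assert table.frame.shape == (10, 26)
        assert list(table.frame.columns) == ["id"] + [f"k{i}" for i in range(1, 25)] + ["label"]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_table([], EntropySpec())

    def test_mixed_alphabets_rejected(self):
        recs = self._records(2) + [
            SequenceRecord(id="p", residues="MKVLW", alphabet=Alphabet.PROTEIN, label="pos")
        ]
        with pytest.raises(ValueError, match="mixed"):
            extract_table(recs, EntropySpec(k_max=2))
        extract_table(recs, EntropySpec(k_max=2), allow_mixed=True)

    def test_csv_determinism_and_round_trip(self, tmp_path):
        recs = self._records()
        spec = EntropySpec(family="renyi", q=0.5, k_max=6)
        t1, t2 = extract_table(recs, spec), extract_table(recs, spec)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_feature_csv(t1, p1)
        write_feature_csv(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()  # byte-identical CSV
        back = read_feature_csv(p1)
        assert list(back.frame.columns) == list(t1.frame.columns)
        np.testing.assert_allclose(back.X, t1.X, rtol=1e-9)
        assert (back.y == t1.y).all()

    def test_header_validation(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,k1,k2\nx,0.1,0.2\n")
        with pytest.raises(ValueError, match="label"):
            read_feature_csv(p)
        p.write_text("id,k2,k1,label\nx,0.1,0.2,pos\n")
        with pytest.raises(ValueError, match="k1"):
            read_feature_csv(p)


def test_worked_example_records_are_stable():
    recs = worked_examples()
    assert len(recs) == 5
    by_id = {r.id: r for r in recs}
    assert by_id["ex_acgtacgt"].residues == "ACGTACGT"
    assert by_id["ex_acgtacgt"].length == 8
    assert [r.id for r in worked_examples()] == [r.id for r in recs]
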