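"""Diversity statistics: closed forms, oracles, invariants, printed tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ssrkit as sk
from ssrkit.diversity import round_half_up

from _oracles import pic_double_loop


def _matrix(genotypes, locus="locA", populations=None):
    """Matrix with the given calls at ``locus`` (None = missing).

    A second always-scored dummy locus keeps every sample valid (the
    container requires at least one scored locus per sample).
    """
    calls = np.array(
        [[g if g is not None else (0, 0), (1, 1)] for g in genotypes]
    )
    n = len(genotypes)
    return sk.GenotypeMatrix(
        tuple(f"s{i}" for i in range(n)),
        tuple(populations or ["p"] * n),
        (locus, "dummy"),
        calls,
    )


def _freq_vectors(max_alleles=6):
    return (
        st.lists(
            st.floats(0.05, 1.0), min_size=1, max_size=max_alleles
        ).map(lambda ws: [w / sum(ws) for w in ws])
    )


class TestAlleleFrequencies:
    def test_counting(self):
        f = sk.allele_frequencies(_matrix([(100, 100), (100, 104)]), "locA")
        assert f.freqs == {100: 0.75, 104: 0.25}
        assert f.n_genes == 4

    def test_missing_excluded_from_denominator(self):
        f = sk.allele_frequencies(_matrix([(100, 100), None]), "locA")
        assert f.freqs == {100: 1.0}
        assert f.n_genes == 2

    def test_unknown_locus(self):
        with pytest.raises(sk.GenotypeError, match="unknown locus"):
            sk.allele_frequencies(_matrix([(100, 100)]), "nope")

    def test_zero_scored_subset_empty_map(self):
        m = _matrix([(100, 100), None])
        f = sk.allele_frequencies(m, "locA", subset=["s1"])
        assert f.freqs == {} and f.n_genes == 0

    def test_packaged_ssr30_alleles(self, passiflora):
        f = sk.allele_frequencies(passiflora, "ssr30")
        assert sorted(f.freqs) == [248, 252, 256, 260]


class TestLocusStats:
    def test_biallelic_even(self):
        st_ = sk.locus_stats(_matrix([(1, 2), (1, 2)]), "locA")
        assert st_.he == pytest.approx(0.5)
        assert st_.ne == pytest.approx(2.0)
        assert st_.shannon == pytest.approx(math.log(2))
        assert st_.pic == pytest.approx(0.375)

    def test_monomorphic(self):
        st_ = sk.locus_stats(_matrix([(7, 7)]), "locA")
        assert (st_.na, st_.ne) == (1, 1.0)
        assert st_.he == st_.shannon == st_.pic == st_.ho == 0.0

    def test_four_equifrequent_alleles(self):
        m = _matrix([(1, 2), (3, 4), (1, 2), (3, 4)])
        st_ = sk.locus_stats(m, "locA")
        assert st_.ne == pytest.approx(4.0)
        assert st_.shannon == pytest.approx(math.log(4))
        assert st_.he == pytest.approx(0.75)
        assert st_.pic == pytest.approx(0.703125)

    def test_ho_over_scored_samples(self):
        m = _matrix([(1, 1), (1, 2), (2, 2), None])
        assert sk.locus_stats(m, "locA").ho == pytest.approx(1 / 3)

    def test_zero_scored_reports_zeros(self):
        m = _matrix([(1, 1), None])
        st_ = sk.locus_stats(m, "locA", subset=["s1"])
        assert (st_.na, st_.ne, st_.he, st_.ho, st_.pic) == (0, 0, 0, 0, 0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(_freq_vectors())
    def test_pic_matches_double_loop_oracle(self, p):
        freqs = sk.AlleleFrequencies("locA", dict(enumerate(p, 1)), 2)
        m = _matrix([(1, 1)])
        st_ = sk.locus_stats(m, "locA", freqs=freqs)
        assert st_.pic == pytest.approx(pic_double_loop(p), abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(_freq_vectors())
    def test_pic_bounded_by_he(self, p):
        freqs = sk.AlleleFrequencies("locA", dict(enumerate(p, 1)), 2)
        st_ = sk.locus_stats(_matrix([(1, 1)]), "locA", freqs=freqs)
        assert st_.pic <= st_.he + 1e-12
        if len(p) > 1:
            assert st_.pic < st_.he

    def test_he_equals_one_minus_inverse_ne(self, passiflora):
        for locus in passiflora.locus_names:
            st_ = sk.locus_stats(passiflora, locus)
            assert st_.he == pytest.approx(1 - 1 / st_.ne, abs=1e-12)

    def test_invariant_under_sample_and_allele_relabelling(self):
        base = [(1, 2), (2, 3), (1, 1), None, (3, 3)]
        relabel = {1: 104, 2: 92, 3: 200}
        permuted = [base[i] for i in (4, 2, 0, 1, 3)]
        recoded = [
            None if g is None else (relabel[g[0]], relabel[g[1]])
            for g in permuted
        ]
        a = sk.locus_stats(_matrix(base), "locA")
        b = sk.locus_stats(_matrix(recoded), "locA")
        for field in ("na", "ne", "shannon", "ho", "he", "pic"):
            assert getattr(a, field) == pytest.approx(getattr(b, field))


class TestSummaryTables:
    def test_locus_table_allele_counts(self, passiflora):
        df = sk.locus_summary_table(passiflora)
        expected = {
            "ssr18": 10, "ssr32": 15, "ssr39": 15, "ssr30": 4,
            "ssr1": 5, "ssr2": 7, "ssr3": 6, "ssr34": 7,
        }
        for locus, na in expected.items():
            assert df.loc[locus, "Na"] == na
        assert df.loc["Mean", "Na"] == pytest.approx(8.625)

    def test_population_table_sparse_singleton(self, passiflora):
        row = sk.population_summary_table(passiflora).loc[
            "P. xishuangbannaensis"
        ]
        assert row["Na"] == pytest.approx(0.750)
        assert row["Ne"] == pytest.approx(0.750)
        assert row["Ho"] == pytest.approx(0.125)
        assert row["He"] == pytest.approx(0.5 / 8)
        assert row["I"] == pytest.approx(math.log(2) / 8)
        assert row["n"] == 1

    def test_population_table_largest_group(self, passiflora):
        df = sk.population_summary_table(passiflora)
        assert df.loc["P. edulis", "Na"] == pytest.approx(2.750)
        assert df.loc["P. edulis", "n"] == 20

    def test_monomorphic_population_zeros(self, passiflora):
        df = sk.population_summary_table(passiflora)
        for pop in ("P. miniata Xishuangbanna Red", "P. serrulata"):
            assert df.loc[pop, "He"] == 0.0
            assert df.loc[pop, "I"] == 0.0
            assert df.loc[pop, "Ho"] == 0.0


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0625, 0.063), (0.5625, 0.563), (0.08664, 0.087), (1.0, 1.0)],
    )
    def test_half_up(self, value, expected):
        assert round_half_up(value) == expected


class TestHardyWeinbergAgreement:
    def test_ho_tracks_he_in_large_panmictic_sample(self):
        # one population, two equifrequent alleles: E[Ho] = He = 0.5
        errs = []
        for seed in range(5):
            spec = sk.SimSpec(
                n_populations=1, samples_per_population=500, n_loci=1,
                alleles_per_locus=2, concentration=50.0,
                missing_rate=0.0, seed=seed,
            )
            m = sk.simulate_genotypes(spec).matrix
            st_ = sk.locus_stats(m, m.locus_names[0])
            errs.append(abs(st_.ho - st_.he))
        # binomial sd of Ho at n=500 is ~0.022
        assert np.mean(errs) < 3 * 0.022
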