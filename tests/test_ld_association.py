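from fractions import Fraction
from math import comb

import numpy as np
import pytest

from kircontent import (
    AL,
    HaplotypeTable,
    LocusRegistry,
    association_ratios,
    fisher_ld,
    pairing_frequency,
)


def fisher_two_tailed_oracle(a, b, c, d):
    """Exact two-tailed Fisher p by rational hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    def prob(x):
        return Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)
    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return float(sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs))


def table_from_counts(a, b, c, d):
    """Haplotype table whose (A,B) joint frequencies scale back to the counts."""
    n = a + b + c + d
    reg = LocusRegistry(("A", "B"))
    vecs = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=bool)
    freqs = np.array([a, b, c, d], dtype=float) / n
    return HaplotypeTable(reg, ("pp", "pn", "np", "nn"), vecs, freqs), n


class TestPairingFrequency:
    def test_perfect_association(self, two_locus_registry, make_haplotype_table):
        table = make_haplotype_table(two_locus_registry, {"11": 0.6, "00": 0.4})
        res = pairing_frequency(table, "A", "B")
        assert res.observed == pytest.approx(1.0)
        assert res.expected == pytest.approx(0.6 * 0.6 + 0.4 * 0.4)

    def test_gene_with_itself(self, two_locus_registry, make_haplotype_table):
        table = make_haplotype_table(two_locus_registry, {"10": 0.3, "01": 0.7})
        assert pairing_frequency(table, "A", "A").observed == pytest.approx(1.0)

    def test_symmetry(self, two_locus_registry, make_haplotype_table):
        table = make_haplotype_table(
            two_locus_registry, {"11": 0.2, "10": 0.3, "01": 0.1, "00": 0.4}
        )
        ab = pairing_frequency(table, "A", "B")
        ba = pairing_frequency(table, "B", "A")
        assert (ab.observed, ab.expected) == (ba.observed, ba.expected)

    def test_observed_equals_expected_under_independence(self, two_locus_registry, make_haplotype_table):
        pa, pb = 0.3, 0.6
        table = make_haplotype_table(
            two_locus_registry,
            {
                "11": pa * pb,
                "10": pa * (1 - pb),
                "01": (1 - pa) * pb,
                "00": (1 - pa) * (1 - pb),
            },
        )
        res = pairing_frequency(table, "A", "B")
        assert res.observed == pytest.approx(res.expected)

    def test_brute_force_summation_on_random_tables(self):
        rng = np.random.default_rng(23)
        reg = LocusRegistry(("A", "B", "C"))
        for _ in range(25):
            k = int(rng.integers(2, 9))
            vecs = rng.integers(0, 2, size=(k, 3)).astype(bool)
            uniq = {v.tobytes(): v for v in vecs}
            vecs = np.array(list(uniq.values()))
            freqs = rng.dirichlet(np.ones(len(vecs)))
            table = HaplotypeTable(
                reg, tuple(f"h{i}" for i in range(len(vecs))), vecs, freqs
            )
            res = pairing_frequency(table, "A", "B")
            obs = sum(
                f for v, f in zip(vecs, freqs) if v[0] == v[1]
            )
            pa = sum(f for v, f in zip(vecs, freqs) if v[0])
            pb = sum(f for v, f in zip(vecs, freqs) if v[1])
            assert res.observed == pytest.approx(obs)
            assert res.expected == pytest.approx(pa * pb + (1 - pa) * (1 - pb))

    def test_unknown_locus_rejected(self, two_locus_registry, make_haplotype_table):
        table = make_haplotype_table(two_locus_registry, {"10": 1.0})
        with pytest.raises(KeyError):
            pairing_frequency(table, "A", "Z")


class TestFisher:
    def test_balanced_table_p_one(self):
        table, n = table_from_counts(5, 5, 5, 5)
        assert fisher_ld(table, "A", "B", n).fisher_p == pytest.approx(1.0)

    def test_perfect_ld_small_p(self):
        table, n = table_from_counts(10, 0, 0, 10)
        res = fisher_ld(table, "A", "B", n)
        assert res.fisher_p == pytest.approx(2 / comb(20, 10))
        assert res.significant

    def test_two_singletons_p_one(self):
        table, n = table_from_counts(1, 0, 0, 1)
        assert fisher_ld(table, "A", "B", n).fisher_p == pytest.approx(1.0)

    def test_zero_marginal_reports_one(self, caplog):
        table, n = table_from_counts(0, 0, 5, 5)  # gene A absent everywhere
        res = fisher_ld(table, "A", "B", n)
        assert res.fisher_p == 1.0

    def test_agrees_with_enumeration_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            cells = rng.multinomial(int(rng.integers(4, 31)), [0.25] * 4)
            a, b, c, d = (int(x) for x in cells)
            table, n = table_from_counts(a, b, c, d)
            got = fisher_ld(table, "A", "B", n).fisher_p
            want = fisher_two_tailed_oracle(a, b, c, d)
            if min(a + b, c + d, a + c, b + d) == 0:
                want = 1.0
            assert got == pytest.approx(want, abs=1e-10), (a, b, c, d)


class TestAssociationRatios:
    def four_cell(self, make_haplotype_table, f11, f10, f01, f00):
        reg = LocusRegistry(("ref", "g"))
        return make_haplotype_table(reg, {"11": f11, "10": f10, "01": f01, "00": f00})

    def test_ubiquitous_gene_ratio_one(self, make_haplotype_table):
        table = self.four_cell(make_haplotype_table, 0.4, 0.0, 0.6, 0.0)
        (res,) = association_ratios(table, "ref")
        assert res.ratio == pytest.approx(1.0)

    def test_sevenfold_enrichment(self, make_haplotype_table):
        table = self.four_cell(make_haplotype_table, 0.35, 0.15, 0.05, 0.45)
        (res,) = association_ratios(table, "ref")
        assert res.ratio == pytest.approx(7.0)

    def test_absolute_linkage_sentinel(self, make_haplotype_table):
        table = self.four_cell(make_haplotype_table, 0.3, 0.2, 0.0, 0.5)
        (res,) = association_ratios(table, "ref")
        assert res.ratio == AL

    def test_gene_absent_everywhere_is_nan(self, make_haplotype_table):
        table = self.four_cell(make_haplotype_table, 0.0, 0.5, 0.0, 0.5)
        (res,) = association_ratios(table, "ref")
        assert np.isnan(res.ratio)

    def test_fixed_reference_rejected(self, make_haplotype_table):
        table = self.four_cell(make_haplotype_table, 0.6, 0.4, 0.0, 0.0)
        with pytest.raises(ValueError, match="fixed"):
            association_ratios(table, "ref")

    def test_constraint_substitutes_partner_and_flags(self, make_haplotype_table):
        reg = LocusRegistry(("ref", "g", "p"))
        # g never typed with ref, but declared absolutely linked to p
        table = make_haplotype_table(
            reg, {"101": 0.4, "100": 0.1, "001": 0.1, "000": 0.4}
        )
        results = {r.gene: r for r in association_ratios(table, "ref", constraints=[("g", "p")])}
        assert results["g"].constrained
        assert results["g"].ratio == pytest.approx(results["p"].ratio)

    def test_ratio_invariant_under_frequency_rescaling(self, make_haplotype_table):
        # scaling all haplotype masses by a constant and renormalizing is a no-op
        reg = LocusRegistry(("ref", "g"))
        raw = {"11": 0.14, "10": 0.06, "01": 0.02, "00": 0.18}
        total = sum(raw.values())
        table = make_haplotype_table(reg, {k: v / total for k, v in raw.items()})
        (res,) = association_ratios(table, "ref")
        assert res.ratio == pytest.approx(7.0)
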