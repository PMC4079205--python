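"""Class substitution frequencies, neutral expectations, Fisher tests."""

from itertools import permutations
from math import comb

import numpy as np
import pytest

from splicesel.ancestral import ControlObservations, SubstitutionCounts
from splicesel.sites import NUC_INDEX, ConsensusTable
from splicesel.substitution import (
    CN_TO_NC,
    NC_TO_CN,
    NeutralRates,
    class_frequency,
    expected_frequency,
    neutral_rates,
    obs_vs_exp_test,
    pooled_class_counts,
)


def make_counts(offset_matrices, site_type="donor"):
    from splicesel.sites import site_offsets

    offs = site_offsets(site_type)
    counts = np.zeros((len(offs), 4, 4), dtype=np.int64)
    for off, entries in offset_matrices.items():
        j = offs.index(off)
        for (z, x), c in entries.items():
            counts[j, NUC_INDEX[z], NUC_INDEX[x]] = c
    n_rec = int(counts.sum(axis=(1, 2)).max())
    return SubstitutionCounts(
        site_type=site_type,
        offsets=tuple(offs),
        counts=counts,
        ambiguous=np.zeros(len(offs), dtype=np.int64),
        excluded=np.zeros(len(offs), dtype=np.int64),
        n_records=n_rec,
    )


class TestClassFrequency:
    def test_single_cn_exit_rate(self, consensus):
        counts = make_counts({4: {("A", "A"): 990, ("A", "G"): 10}})
        est = class_frequency(counts, consensus, "donor", 4, CN_TO_NC)
        assert (est.k, est.n) == (10, 1000)
        assert est.q == pytest.approx(0.01)
        assert est.ci_low <= est.q <= est.ci_high

    def test_within_class_moves_are_not_exits(self):
        table = ConsensusTable({("donor", 4): {"T", "C"}})
        counts = make_counts({4: {("T", "C"): 5, ("T", "T"): 95}})
        est = class_frequency(counts, table, "donor", 4, CN_TO_NC)
        assert (est.k, est.n, est.q) == (0, 100, 0.0)

    def test_nc_to_cn_pools_all_nonconsensus_ancestors(self, consensus):
        counts = make_counts(
            {4: {("G", "A"): 3, ("G", "G"): 45, ("G", "C"): 2, ("C", "C"): 50}}
        )
        est = class_frequency(counts, consensus, "donor", 4, NC_TO_CN)
        assert (est.k, est.n) == (3, 100)
        assert est.q == pytest.approx(0.03)

    def test_invariant_offset_rejected(self, consensus):
        counts = make_counts({4: {("A", "A"): 1}})
        with pytest.raises(ValueError):
            class_frequency(counts, consensus, "donor", 1, CN_TO_NC)
        with pytest.raises(ValueError):
            class_frequency(counts, consensus, "acceptor", -4, CN_TO_NC)

    def test_invariant_under_nc_relabeling(self, consensus):
        # permuting the identities of the Nc nucleotides must not change q
        rng = np.random.default_rng(0)
        mat = rng.integers(0, 50, size=(4, 4))
        nc_codes = [NUC_INDEX[x] for x in "CGT"]  # Cn at donor +4 is {A}
        base = make_counts({4: {}})
        base.counts[base.offsets.index(4)] = mat
        ref_qs = {
            d: class_frequency(base, consensus, "donor", 4, d).q
            for d in (CN_TO_NC, NC_TO_CN)
        }
        for perm in permutations(nc_codes):
            m = mat.copy()
            idx = list(range(4))
            for a, b in zip(nc_codes, perm):
                idx[a] = b
            m = m[np.ix_(idx, idx)]
            other = make_counts({4: {}})
            other.counts[other.offsets.index(4)] = m
            for d in (CN_TO_NC, NC_TO_CN):
                assert class_frequency(other, consensus, "donor", 4, d).q == ref_qs[d]


def make_neutral(a_exits=(2, 2), g_exits=(3, 3), n_each=1000):
    """Neutral rates with ancestral-A exits to C/T and ancestral-G exits to C/T."""
    mat = np.zeros((4, 4), dtype=np.int64)
    a, c, g, t = (NUC_INDEX[x] for x in "ACGT")
    mat[a, c], mat[a, t] = a_exits
    mat[a, a] = n_each - sum(a_exits)
    mat[g, c], mat[g, t] = g_exits
    mat[g, g] = n_each - sum(g_exits)
    mat[c, c] = n_each
    mat[t, t] = n_each
    return NeutralRates(
        {"intronic-control": mat.copy(), "fourfold-control": mat.copy()}
    )


class TestNeutralRates:
    def test_rate_from_raw_pools(self):
        anc = np.full(2000, NUC_INDEX["A"], dtype=np.int8)
        desc = anc.copy()
        desc[:8] = NUC_INDEX["G"]
        pools = {
            "intronic-control": {
                "anc": anc,
                "desc": desc,
                "score": np.zeros(2000),
                "cpg": np.zeros(2000, dtype=bool),
            }
        }
        nr = neutral_rates(ControlObservations(pools))
        assert nr.rate("A", {"G"}, "intronic-control") == pytest.approx(0.004)

    def test_score_filter_keeps_strictly_below_threshold(self):
        scores = np.array([0.1, 0.59, 0.61, 2.0])
        anc = np.full(4, NUC_INDEX["A"], dtype=np.int8)
        pools = {
            "intronic-control": {
                "anc": anc,
                "desc": anc.copy(),
                "score": scores,
                "cpg": np.zeros(4, dtype=bool),
            }
        }
        nr = neutral_rates(ControlObservations(pools), score_threshold=0.6)
        assert nr.opportunities("A", "intronic-control") == 2
        flipped = neutral_rates(
            ControlObservations(pools), score_threshold=0.6, keep_below=False
        )
        assert flipped.opportunities("A", "intronic-control") == 2

    def test_rates_additive_over_disjoint_targets(self):
        nr = make_neutral()
        total = nr.rate("A", {"C", "G", "T"}, "intronic-control")
        parts = sum(
            nr.rate("A", {x}, "intronic-control") for x in ("C", "G", "T")
        )
        assert total == pytest.approx(parts)

    def test_empty_filtered_pool_rejected(self):
        anc = np.full(3, NUC_INDEX["A"], dtype=np.int8)
        pools = {
            "intronic-control": {
                "anc": anc,
                "desc": anc.copy(),
                "score": np.full(3, 5.0),
                "cpg": np.zeros(3, dtype=bool),
            }
        }
        with pytest.raises(ValueError):
            neutral_rates(ControlObservations(pools))


class TestExpectedFrequency:
    def test_composition_weighted_mean(self):
        # donor +3 has Cn {A, G}; exits are to the Nc set {C, T}
        table = ConsensusTable.default()
        nr = make_neutral(a_exits=(2, 2), g_exits=(3, 3))
        q_exp, k_e, n_e = expected_frequency(
            {"A": 700, "G": 300}, nr, table, "donor", 3, CN_TO_NC, n_obs=1000
        )
        assert q_exp == pytest.approx(0.7 * 0.004 + 0.3 * 0.006)
        assert k_e == pytest.approx(q_exp * 1000)

    def test_single_nucleotide_composition(self):
        table = ConsensusTable.default()
        nr = make_neutral()
        q_exp, _, _ = expected_frequency(
            {"A": 500}, nr, table, "donor", 4, CN_TO_NC
        )
        assert q_exp == pytest.approx(nr.rate("A", {"C", "G", "T"}, "intronic-control"))

    def test_missing_composition_rejected(self):
        table = ConsensusTable.default()
        with pytest.raises(ValueError):
            expected_frequency({}, make_neutral(), table, "donor", 4, CN_TO_NC)


def fisher_enumeration(k1, n1, k2, n2):
    """Brute-force two-sided Fisher p over all tables with fixed margins."""
    row1, row2 = n1, n2
    col1 = k1 + k2
    total = n1 + n2

    def prob(a):
        return (
            comb(row1, a) * comb(row2, col1 - a) / comb(total, col1)
        )

    p_obs = prob(k1)
    p = 0.0
    for a in range(max(0, col1 - row2), min(row1, col1) + 1):
        pa = prob(a)
        if pa <= p_obs * (1 + 1e-9):
            p += pa
    return p


class TestObsVsExpTest:
    def test_identical_proportions_give_p_one(self):
        assert obs_vs_exp_test(10, 1000, 10, 1000) == pytest.approx(1.0)

    def test_extreme_table_is_vanishingly_unlikely(self):
        assert obs_vs_exp_test(0, 100, 100, 100) < 1e-20

    @pytest.mark.parametrize(
        "table", [(2, 10, 3, 10), (1, 12, 7, 9), (0, 5, 4, 8), (6, 14, 2, 11)]
    )
    def test_matches_margin_fixed_enumeration(self, table):
        k1, n1, k2, n2 = table
        assert obs_vs_exp_test(k1, n1, k2, n2) == pytest.approx(
            fisher_enumeration(k1, n1, k2, n2), rel=1e-9
        )

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert obs_vs_exp_test(0, 10, 0, 20) == 1.0


class TestPooling:
    def test_pooled_equals_weighted_mean_of_offsets(self, consensus):
        counts = make_counts(
            {
                4: {("A", "A"): 900, ("A", "G"): 10, ("G", "G"): 90},
                5: {("G", "G"): 500, ("G", "T"): 4, ("A", "A"): 96},
            }
        )
        nr = make_neutral()
        pooled, q_exp = pooled_class_counts(counts, nr, consensus, CN_TO_NC)
        per = []
        for off in (4, 5):
            est = class_frequency(counts, consensus, "donor", off, CN_TO_NC)
            per.append((est.k, est.n))
        k = sum(k for k, _ in per)
        n = sum(n for _, n in per)
        assert (pooled.k, pooled.n) == (k, n)
        assert pooled.q == pytest.approx(
            sum(kk for kk, _ in per) / sum(nn for _, nn in per)
        )
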