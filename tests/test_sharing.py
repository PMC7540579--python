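"""N_f counting, permutation null, p-values and the significance table."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from sgscan import (
    CandidateSet,
    DataError,
    SignificanceTable,
    count_sharing,
    empirical_pvalues,
    format_pvalue,
    permutation_null,
    select_n_crit,
)

from conftest import make_variants


def brute_force_nf(variants, candidates, d_kb):
    """O(M*N*k) reference: each individual counted once per variant."""
    D = d_kb * 1000.0
    nf = np.zeros(len(variants), dtype=int)
    for v in range(len(variants)):
        for cs in candidates:
            hit = any(
                c == variants.chrom[v] and abs(p - variants.pos[v]) <= D
                for c, p in cs.positions
            )
            nf[v] += bool(hit)
    return nf


def pooled_closed_form(M, r, N, k, t_values):
    """Exact pooled P(N_f >= t) on a uniform grid: per-variant window size
    w_i = min(i, r) + min(M-1-i, r) + 1, individual hit probability
    q_i = 1 - C(M-w_i, k)/C(M, k), N_f ~ Binomial(N, q_i), averaged over i."""
    w_mult = {}
    for i in range(r):
        w = i + r + 1
        w_mult[w] = w_mult.get(w, 0) + 2
    w_mult[2 * r + 1] = w_mult.get(2 * r + 1, 0) + (M - 2 * r)
    out = np.zeros(len(t_values))
    for w, mult in w_mult.items():
        q = 1.0
        for j in range(k):
            q *= (M - w - j) / (M - j)
        q = 1.0 - q
        for a, t in enumerate(t_values):
            p_ge = 1.0 - sum(
                comb(N, j) * q**j * (1 - q) ** (N - j) for j in range(t)
            )
            out[a] += mult * p_ge
    return out / M


class TestCountSharing:
    def test_no_candidates_all_zero(self):
        vt = make_variants(10)
        empty = [CandidateSet("a", []), CandidateSet("b", [])]
        prof = count_sharing(vt, empty, 50)
        assert prof.nf.sum() == 0
        assert prof.n_individuals == 2

    def test_closed_boundary_at_exactly_d(self):
        vt = make_variants(3, spacing=10_000)  # pos 1000, 11000, 21000
        cs = [CandidateSet("a", [("chr1", 11000 + 2000)])]  # 2 kb right of v1
        nf = count_sharing(vt, cs, 2).nf
        assert nf.tolist() == [0, 1, 0]  # exactly d*1000 bp away counts
        cs2 = [CandidateSet("a", [("chr1", 11000 + 2001)])]
        assert count_sharing(vt, cs2, 2).nf.tolist() == [0, 0, 0]

    def test_individual_counted_once_despite_multiple_candidates(self):
        vt = make_variants(5)
        cs = [CandidateSet("a", [("chr1", 1000), ("chr1", 2000), ("chr1", 3000)])]
        nf = count_sharing(vt, cs, 5).nf
        assert nf.max() == 1

    def test_cross_chromosome_candidates_never_match(self):
        vt = make_variants(5, chrom="chr1")
        cs = [CandidateSet("a", [("chr2", 3000)])]
        with pytest.raises(DataError, match="chr2"):
            count_sharing(vt, cs, 50)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            M = int(rng.integers(5, 120))
            vt = make_variants(M, spacing=int(rng.integers(500, 5000)))
            N = int(rng.integers(1, 8))
            cands = []
            for i in range(N):
                k = int(rng.integers(0, 5))
                idx = rng.choice(M, size=k, replace=False)
                cands.append(
                    CandidateSet(f"i{i}", [("chr1", int(vt.pos[j])) for j in idx])
                )
            d = float(rng.choice([2, 5, 20, 50]))
            np.testing.assert_array_equal(
                count_sharing(vt, cands, d).nf, brute_force_nf(vt, cands, d)
            )

    def test_monotone_in_d(self, rng):
        vt = make_variants(200)
        cands = [
            CandidateSet(
                f"i{i}",
                [("chr1", int(p)) for p in rng.choice(vt.pos, 4, replace=False)],
            )
            for i in range(6)
        ]
        profiles = [count_sharing(vt, cands, d).nf for d in (2, 5, 20, 50, 200)]
        for a, b in zip(profiles, profiles[1:]):
            assert np.all(a <= b)


class TestPermutationNull:
    def test_deterministic_given_seed(self):
        vt = make_variants(300)
        a = permutation_null(vt, [3, 4, 5], 20, 50, seed=9)
        b = permutation_null(vt, [3, 4, 5], 20, 50, seed=9)
        np.testing.assert_array_equal(a.sample_counts, b.sample_counts)
        c = permutation_null(vt, [3, 4, 5], 20, 50, seed=10)
        assert not np.array_equal(a.sample_counts, c.sample_counts)

    def test_relabeling_individuals_leaves_null_unchanged(self):
        # the null depends on the k-list only, not on who carries which k
        vt = make_variants(300)
        a = permutation_null(vt, [3, 3, 3], 20, 50, seed=9)
        b = permutation_null(vt, [3, 3, 3], 20, 50, seed=9)
        np.testing.assert_array_equal(a.sample_counts, b.sample_counts)

    def test_p_of_zero_is_one_and_monotone(self):
        vt = make_variants(300)
        nt = permutation_null(vt, [3, 4], 20, 100, seed=1)
        assert nt.p_of(0) == 1.0
        t = np.arange(0, nt.n_individuals + 2)
        p = np.asarray(nt.p_of(t))
        assert np.all(np.diff(p) <= 1e-12)
        assert np.all(p >= nt.floor - 1e-15)

    def test_k_exceeding_variant_count_errors(self):
        vt = make_variants(10)
        with pytest.raises(DataError):
            permutation_null(vt, [11], 20, 10, seed=0)

    def test_per_variant_floor_with_observed(self):
        # observed N_f at the target cannot be beaten by any random sample
        vt = make_variants(400)
        target = 200
        cands = [
            CandidateSet(f"i{j}", [("chr1", int(vt.pos[target]))]) for j in range(6)
        ]
        prof = count_sharing(vt, cands, 2)
        nt = permutation_null(
            vt, [1] * 6, 2, 1000, seed=3, observed=prof,
            mode="per_variant", target_index=target,
        )
        assert nt.p_of(int(prof.nf[target])) == pytest.approx(1 / 1000)

    def test_pooled_null_matches_closed_form_small(self):
        M, N, k, r = 2000, 10, 5, 50  # d = 50 kb on a 1 kb grid
        vt = make_variants(M)
        nt = permutation_null(vt, [k] * N, 50, 400, seed=5)
        expected = pooled_closed_form(M, r, N, k, [1, 2, 3])
        for t in range(1, 4):
            se = nt.mc_se(t)
            assert abs(nt.p_of(t) - expected[t - 1]) <= 4 * se, (
                f"t={t}: {nt.p_of(t)} vs {expected[t-1]} (se {se})"
            )


class TestEmpiricalPvalues:
    def test_equal_nf_equal_p_and_zero_gives_one(self):
        vt = make_variants(50)
        cands = [CandidateSet("a", [("chr1", 1000)]), CandidateSet("b", [("chr1", 1000)])]
        prof = count_sharing(vt, cands, 2)
        nt = permutation_null(vt, [1, 1], 2, 200, seed=4, observed=prof)
        p = empirical_pvalues(prof, nt)
        assert np.all(p[prof.nf == 0] == 1.0)
        for v in np.unique(prof.nf):
            assert len(np.unique(p[prof.nf == v])) == 1

    def test_d_mismatch_rejected(self):
        vt = make_variants(50)
        prof = count_sharing(vt, [CandidateSet("a", [("chr1", 1000)])], 2)
        nt = permutation_null(vt, [1], 5, 100, seed=4)
        with pytest.raises(ValueError, match="d="):
            empirical_pvalues(prof, nt)

    def test_format_pvalue_floor(self):
        assert format_pvalue(1e-4, 10_000) == "<0.0001"
        assert format_pvalue(0.0338, 10_000) == "0.0338"


class TestSignificanceTable:
    def sig(self, column, d=50.0):
        t = np.arange(1, len(column) + 1)
        return SignificanceTable(pd.DataFrame({d: column}, index=pd.Index(t, name="N_f")))

    def test_flagged_t_is_minimal_significant(self):
        st = self.sig([0.5, 0.06, 0.01, 0.001])
        assert st.flagged_t(50) == 3
        assert select_n_crit(st, 50, floor=3) == 3

    def test_floor_applies(self):
        st = self.sig([0.04, 0.01, 0.001])
        assert st.flagged_t(50) == 1
        assert select_n_crit(st, 50, floor=3) == 3

    def test_floor_not_binding_when_t_larger(self):
        st = self.sig([0.9, 0.5, 0.20, 0.08, 0.03, 0.001])
        assert select_n_crit(st, 50, floor=3) == 5

    def test_no_significant_threshold_errors(self):
        st = self.sig([0.9, 0.5, 0.2])
        with pytest.raises(DataError, match="d = 50"):
            select_n_crit(st, 50)

    def test_tsv_round_trip(self, tmp_path):
        vt = make_variants(300)
        nulls = {
            d: permutation_null(vt, [2, 3], d, 100, seed=6) for d in (5.0, 50.0)
        }
        st = SignificanceTable.from_nulls(nulls)
        st.to_tsv(tmp_path / "sig.tsv")
        back = SignificanceTable.from_tsv(tmp_path / "sig.tsv")
        pd.testing.assert_frame_equal(back.table, st.table, check_names=False)
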