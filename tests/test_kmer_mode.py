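"""Reference-free estimator internals: windows, phi, p-values, alpha,
bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pliqc.digest import junction_set, parse_enzyme
from pliqc.kmer_index import count_sequences
from pliqc.kmer_mode import (
    LibraryParams,
    alpha_fragment,
    bootstrap,
    collect_observations,
    empirical_pvalue_table,
    feasible_window,
    find_junction,
    flanking_kmers,
    lookup_pvalue,
    relative_frequency,
)


@pytest.fixture(scope="module")
def dpnii_junctions():
    return junction_set(parse_enzyme("DpnII"))


# -- geometry -------------------------------------------------------------


@pytest.mark.parametrize(
    "l_read, k, l_la, expected",
    [(150, 24, 8, (25, 117)), (58, 24, 8, (25, 25)), (100, 16, 10, (17, 73))],
)
def test_feasible_window(l_read, k, l_la, expected):
    assert feasible_window(l_read, k, l_la) == expected


def test_feasible_window_too_short():
    with pytest.raises(ValueError, match="read unusable"):
        feasible_window(57, 24, 8)


def test_find_junction(dpnii_junctions):
    rng = np.random.default_rng(0)
    bases = list("ACGT")
    read = "".join(rng.choice(bases, 150))
    read = read.replace("GATCGATC", "ACCTTGCA")  # scrub chance occurrences
    w = feasible_window(150, 24, 8)
    planted = read[:60] + "GATCGATC" + read[68:]
    assert find_junction(planted, dpnii_junctions, w) == (60, "GATCGATC")
    early = "GATCGATC" + read[8:]
    assert find_junction(early, dpnii_junctions, w) == "outside"
    assert find_junction(read, dpnii_junctions, w) is None


def test_find_junction_prefers_leftmost_in_window(dpnii_junctions):
    read = "A" * 150
    read = read[:10] + "GATCGATC" + read[18:40] + "GATCGATC" + read[48:]
    w = feasible_window(150, 24, 8)
    x, motif = find_junction(read, dpnii_junctions, w)
    assert (x, motif) == (40, "GATCGATC")  # position 10 is outside the window


@pytest.mark.parametrize(
    "x, left, right, inner",
    [
        (60, (35, 36, 37), (67, 68, 69), (59, 60, 61)),
        (25, (0, 1, 2), (32, 33, 34), (24, 25, 26)),
        (117, (92, 93, 94), (124, 125, 126), (116, 117, 118)),
    ],
)
def test_flanking_kmer_positions(x, left, right, inner):
    k, l_la = 24, 8
    read = "".join(
        np.random.default_rng(1).choice(list("ACGT"), 150)
    )
    inner_k, outer_k = flanking_kmers(read, x, k, l_la)
    assert inner_k == [read[s : s + k] for s in inner]
    assert outer_k == [read[s : s + k] for s in left + right]
    assert all(len(s) == k for s in inner_k + outer_k)
    # the last right-outer k-mer of x=117 ends exactly at the read end
    if x == 117:
        assert right[-1] + k == 150


# -- relative frequency ---------------------------------------------------


def test_relative_frequency_identity():
    phi, reason = relative_frequency([10, 10, 10], [10] * 6, f_bar=10)
    assert reason is None and phi == pytest.approx(1.0)


def test_relative_frequency_geometric_means():
    phi, reason = relative_frequency([2, 4, 8], [16] * 6, f_bar=10)
    assert reason is None
    assert phi == pytest.approx(4 / 16)  # GM(2,4,8) = 4


def test_relative_frequency_rejections():
    phi, reason = relative_frequency([1, 1, None], [10] * 6, f_bar=10)
    assert phi is None and reason == "missing k-mer"
    phi, reason = relative_frequency([10, 10, 10], [3] * 6, f_bar=10)
    assert phi is None and reason == "low outer coverage"  # 3 < 10/2.5
    # inner coverage is deliberately unconstrained
    phi, reason = relative_frequency([1, 1, 1], [10] * 6, f_bar=10)
    assert reason is None


# -- empirical p-values ---------------------------------------------------


def test_pvalue_table_worked_example():
    t = empirical_pvalue_table([0.2, 0.2, 0.5, 1.0])
    assert t.n == 3
    np.testing.assert_allclose(t.unique_phis, [0.2, 0.5, 1.0])
    np.testing.assert_allclose(t.pvals, [0.50, 0.75, 1.00])


def test_pvalue_table_degenerate():
    with pytest.raises(ValueError, match="insufficient null"):
        empirical_pvalue_table([0.5, 0.5, 0.5])


@given(
    st.lists(st.floats(0.01, 100.0), min_size=2, max_size=1000).filter(
        lambda xs: len(set(xs)) >= 2
    )
)
@settings(max_examples=200, deadline=None)
def test_pvalues_match_brute_force_rank(phis):
    """p-hat equals the independent rank computation
    (#unique <= phi + 1)/(n + 1) on random null sets."""
    t = empirical_pvalue_table(phis)
    uniq = sorted(set(phis))
    n = len(uniq)
    for phi in uniq:
        r = sum(1 for u in uniq if u <= phi)
        expect = (r + 1) / (n + 1)
        got = float(lookup_pvalue(t, phi))
        assert got == pytest.approx(expect)
    assert t.pvals[-1] == pytest.approx(1.0)
    assert np.all(np.diff(t.pvals) > 0)
    assert np.all((t.pvals > 0) & (t.pvals <= 1))


def test_lookup_pvalue_examples():
    t = empirical_pvalue_table([0.2, 0.2, 0.5, 1.0])
    assert float(lookup_pvalue(t, 0.6)) == pytest.approx(0.75)
    assert float(lookup_pvalue(t, 0.2)) == pytest.approx(0.50)
    assert float(lookup_pvalue(t, 0.1)) == pytest.approx(0.25)  # floor 1/(n+1)


def test_lookup_pvalue_monotone():
    rng = np.random.default_rng(5)
    t = empirical_pvalue_table(rng.lognormal(size=200))
    q = np.sort(rng.lognormal(size=500))
    p = lookup_pvalue(t, q)
    assert np.all(np.diff(p) >= 0)


# -- unobserved fraction --------------------------------------------------


def alpha_boolean_oracle(lengths, l_la, mean_insert=None):
    """Base-by-base mask oracle for the plain (non-window-aware) alpha."""
    if len(lengths) == 1:
        (l,) = lengths
        mask = np.zeros(l, dtype=bool)
        mask[: l - l_la] = True
        return 1.0 - mask.mean()
    l1, l2 = lengths
    L = int(round(mean_insert))
    mask = np.zeros(L, dtype=bool)
    mask[: max(0, min(l1 - (l_la - 1), L))] = True
    mask[max(0, L - l2 + (l_la - 1)):] = True
    return 1.0 - mask.mean()


def test_alpha_closed_forms():
    assert alpha_fragment([100], 8) == pytest.approx(0.08)
    assert alpha_fragment([150, 150], 8, 300) == pytest.approx(14 / 300)
    # full overlap: each read's 3' blind spot is covered by its mate
    assert alpha_fragment([150, 150], 8, 200) == pytest.approx(0.0)


def test_alpha_matches_boolean_oracle():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        l_la = int(rng.integers(4, 12))
        if rng.random() < 0.3:
            lengths = [int(rng.integers(l_la + 1, 400))]
            mean_insert = None
        else:
            lengths = [int(rng.integers(30, 300)), int(rng.integers(30, 300))]
            mean_insert = int(rng.integers(max(lengths), 800))
        got = alpha_fragment(lengths, l_la, mean_insert)
        expect = alpha_boolean_oracle(lengths, l_la, mean_insert)
        assert got == pytest.approx(expect, abs=1e-12)


def test_alpha_monotone_in_mean_insert():
    prev = -1.0
    for lbar in range(300, 901, 50):
        a = alpha_fragment([150, 150], 8, lbar)
        assert a >= prev
        prev = a


def test_alpha_window_aware_exceeds_plain():
    plain = alpha_fragment([150, 150], 8, 300)
    aware = alpha_fragment([150, 150], 8, 300, k=24, account_flanks=True)
    assert aware == pytest.approx(1 - 186 / 293)
    assert aware > plain


def test_alpha_window_aware_oracle():
    """Enumeration oracle: fraction of junction-start positions where the
    nine k-mers cannot all be extracted from either read."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        k = int(rng.integers(8, 28))
        l_la = int(rng.integers(4, 11))
        l1 = int(rng.integers(2 * k + l_la + 2, 2 * k + l_la + 150))
        l2 = int(rng.integers(2 * k + l_la + 2, 2 * k + l_la + 150))
        L = int(rng.integers(max(l1, l2), max(l1, l2) + 400))
        detectable = np.zeros(L - l_la + 1, dtype=bool)
        lo1, hi1 = k + 1, l1 - l_la - k - 1
        for u in range(lo1, hi1 + 1):
            if u < detectable.size:
                detectable[u] = True
        lo2, hi2 = L - l2 + k + 1, L - l_la - k - 1
        for u in range(lo2, hi2 + 1):
            if 0 <= u < detectable.size:
                detectable[u] = True
        expect = 1.0 - detectable.mean()
        got = alpha_fragment([l1, l2], l_la, L, k=k, account_flanks=True)
        assert got == pytest.approx(expect, abs=1e-9)


# -- bootstrap ------------------------------------------------------------


def _table(phi, lam, alpha, junctions, k=24):
    from pliqc.kmer_mode import ObservationTable

    return ObservationTable(
        phi=np.asarray(phi, dtype=float),
        lam=np.asarray(lam, dtype=np.uint8),
        alpha=np.asarray(alpha, dtype=float),
        k=k,
        junctions=junctions,
    )


def _params(junctions, **kw):
    kw.setdefault("mean_insert", 300)
    kw.setdefault("seed", 3)
    return LibraryParams(junctions=junctions, **kw)


def test_bootstrap_no_junctions(dpnii_junctions):
    t = _table([1.0, 1.1, 0.9], [0, 0, 0], [0.1] * 3, dpnii_junctions)
    res = bootstrap(t, _params(dpnii_junctions), np.random.default_rng(0))
    assert res.no_junctions
    assert res.rho_obs.point == res.rho_lib.point == 0.0
    assert res.rho_obs.ci_low == res.rho_obs.ci_high == 0.0


def test_bootstrap_floor_pvalue_limit(dpnii_junctions):
    """Junction phis far below every null phi: each contributes
    1 - 1/(n+1), so rho_obs -> (#junction / |T|) * n/(n+1)."""
    rng = np.random.default_rng(1)
    n0 = 400
    null_phi = np.linspace(0.8, 1.2, n0)
    phi = np.concatenate([null_phi, [1e-4] * 100])
    lam = np.array([0] * n0 + [1] * 100)
    t = _table(phi, lam, np.zeros(phi.size), dpnii_junctions)
    res = bootstrap(t, _params(dpnii_junctions, n_boot=200), rng)
    # resampling keeps the junction fraction ~100/500 and n_unique ~ large
    assert res.rho_obs.point == pytest.approx(0.2, rel=0.05)
    assert res.rho_obs.ci_low <= 0.2 <= res.rho_obs.ci_high


def test_bootstrap_alpha_zero_means_no_correction(dpnii_junctions):
    rng = np.random.default_rng(2)
    phi = np.concatenate([np.linspace(0.5, 2, 300), [1e-3] * 30])
    lam = np.array([0] * 300 + [1] * 30)
    t = _table(phi, lam, np.zeros(phi.size), dpnii_junctions)
    res = bootstrap(t, _params(dpnii_junctions), rng)
    assert np.allclose(res.rho_lib_samples, res.rho_samples)


def test_bootstrap_correction_scales(dpnii_junctions):
    rng = np.random.default_rng(3)
    phi = np.concatenate([np.linspace(0.5, 2, 300), [1e-3] * 30])
    lam = np.array([0] * 300 + [1] * 30)
    t = _table(phi, lam, np.full(phi.size, 0.5), dpnii_junctions)
    res = bootstrap(t, _params(dpnii_junctions), rng)
    assert res.rho_lib.point == pytest.approx(2 * res.rho_obs.point, rel=1e-9)


def test_bootstrap_interval_orders(dpnii_junctions):
    rng = np.random.default_rng(4)
    phi = np.concatenate([rng.lognormal(0, 0.3, 500), rng.lognormal(-4, 0.3, 60)])
    lam = np.array([0] * 500 + [1] * 60)
    t = _table(phi, lam, np.full(phi.size, 0.2), dpnii_junctions)
    res = bootstrap(t, _params(dpnii_junctions), rng)
    for iv in (res.rho_obs, res.alpha_lib, res.rho_lib):
        assert iv.ci_low <= iv.point <= iv.ci_high
    assert 0 <= res.rho_obs.point <= res.rho_lib.point <= 1
    assert np.all((res.rho_samples >= 0) & (res.rho_samples <= 1))


def test_bootstrap_ci_width_shrinks_with_table_size(dpnii_junctions):
    """CI width scales roughly like 1/sqrt(|T|) for a fixed signal."""
    rng0 = np.random.default_rng(8)
    widths = {}
    for n in (400, 6400):
        rng = np.random.default_rng(9)
        n1 = n // 10
        phi = np.concatenate(
            [rng0.lognormal(0, 0.3, n - n1), rng0.lognormal(-4, 0.3, n1)]
        )
        lam = np.array([0] * (n - n1) + [1] * n1)
        t = _table(phi, lam, np.zeros(n), dpnii_junctions)
        res = bootstrap(t, _params(dpnii_junctions, n_boot=200), rng)
        widths[n] = res.rho_obs.ci_high - res.rho_obs.ci_low
    ratio = widths[400] / widths[6400]
    assert 2.0 < ratio < 8.0  # ideal 4.0


def test_literal_sum_variant_differs(dpnii_junctions):
    phi = np.concatenate([np.linspace(0.5, 2, 300), [1e-3] * 30])
    lam = np.array([0] * 300 + [1] * 30)
    t = _table(phi, lam, np.zeros(phi.size), dpnii_junctions)
    res_d = bootstrap(t, _params(dpnii_junctions), np.random.default_rng(0))
    res_s = bootstrap(
        t, _params(dpnii_junctions, literal_sum=True), np.random.default_rng(0)
    )
    # with true (rare) junctions, the 1-p form attributes them to PL while
    # the literal sum attributes almost nothing
    assert res_d.rho_obs.point > 5 * res_s.rho_obs.point


# -- collection -----------------------------------------------------------


def _uniform_db_reads(rng, n=120, length=150):
    """Junction-free reads sharing a 500 bp source so coverage is deep."""
    src = "".join(rng.choice(list("ACGT"), 500))
    src = src.replace("GATCGATC", "ACCTTGCA")
    starts = rng.integers(0, 500 - length, n)
    return [src[s : s + length] for s in starts]


def test_collect_all_null(dpnii_junctions):
    rng = np.random.default_rng(12)
    reads = _uniform_db_reads(rng)
    db = count_sequences(reads, 24)
    frags = list(zip(reads[::2], reads[1::2]))
    params = LibraryParams(mean_insert=300, junctions=dpnii_junctions, seed=1)
    t = collect_observations(frags, db, params, np.random.default_rng(1))
    assert t.n_junction == 0
    assert len(t) > 0
    assert all(p > 0 for p in t.phi)


def test_collect_junction_in_read2(dpnii_junctions):
    rng = np.random.default_rng(13)
    reads = _uniform_db_reads(rng, n=200)
    r2 = reads[1]
    r2 = r2[:60] + "GATCGATC" + r2[68:]
    frags = [(reads[0], r2)]
    db = count_sequences(reads + [r2], 24)
    params = LibraryParams(mean_insert=300, junctions=dpnii_junctions, seed=1)
    t = collect_observations(frags, db, params, np.random.default_rng(1))
    assert len(t) == 1 and t.n_junction == 1


def test_collect_missing_kmer_rejects_fragment(dpnii_junctions):
    rng = np.random.default_rng(14)
    reads = _uniform_db_reads(rng, n=200)
    alien = "".join(rng.choice(list("ACGT"), 150))
    alien = alien[:60] + "GATCGATC" + alien[68:]
    db = count_sequences(reads, 24)  # alien read NOT counted
    params = LibraryParams(mean_insert=300, junctions=dpnii_junctions, seed=1)
    with pytest.raises(ValueError, match="zero accepted"):
        collect_observations([(alien, alien)], db, params,
                             np.random.default_rng(1))


def test_collect_short_reads_counted(dpnii_junctions):
    rng = np.random.default_rng(15)
    reads = _uniform_db_reads(rng, n=200)
    db = count_sequences(reads, 24)
    params = LibraryParams(mean_insert=300, junctions=dpnii_junctions, seed=1)
    frags = [("ACGT", "ACGT"), (reads[0], reads[1])]
    t = collect_observations(frags, db, params, np.random.default_rng(1))
    assert t.rejections["read_too_short"] == 1
    assert t.n_attempted == 2


def test_collect_handles_mixed_merged_and_paired(dpnii_junctions):
    """Merged fragments (1-tuples) and pairs (2-tuples) coexist in one run,
    with the merged fragments using the full-insert unobserved mask."""
    rng = np.random.default_rng(16)
    reads = _uniform_db_reads(rng, n=300, length=150)
    merged = _uniform_db_reads(rng, n=50, length=280)
    db = count_sequences(reads + merged, 24)
    frags = [(m,) for m in merged[:20]] + list(zip(reads[::2], reads[1::2]))
    params = LibraryParams(mean_insert=300, junctions=dpnii_junctions, seed=1)
    t = collect_observations(frags, db, params, np.random.default_rng(1))
    assert len(t) > 100
    a_pair = alpha_fragment([150, 150], 8, 300, k=24, account_flanks=True)
    a_merged = alpha_fragment([280], 8, k=24, account_flanks=True)
    assert {round(a, 12) for a in t.alpha} == {
        round(a_pair, 12), round(a_merged, 12)
    }


def test_iter_fragments_merged(tmp_path, dpnii_junctions):
    from pliqc.kmer_mode import iter_fragments

    fq = tmp_path / "m.fastq"
    fq.write_text("@m1\nACGTACGT\n+\nIIIIIIII\n")
    frags = list(iter_fragments(merged=fq))
    assert frags == [("ACGTACGT",)]
    with pytest.raises(ValueError, match="both R1 and R2"):
        list(iter_fragments(r1=fq))


def test_params_validation(dpnii_junctions):
    with pytest.raises(ValueError, match="exceed the longest junction"):
        LibraryParams(mean_insert=300, junctions=dpnii_junctions, k=8)
    with pytest.raises(ValueError, match="positive"):
        LibraryParams(mean_insert=0, junctions=dpnii_junctions)
    with pytest.raises(ValueError, match="accepted range"):
        LibraryParams(mean_insert=300, junctions=dpnii_junctions, k=40)
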