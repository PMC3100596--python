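import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hylaxy.datamodel import (
    MISSING,
    NULL,
    Dataset,
    Genotype,
    LocusDef,
)
from hylaxy.linkage import (
    build_map,
    estimate_two_point,
    family_two_point_loglik,
    haldane_cm,
    haldane_compose,
    haldane_theta,
    mtest,
    pool_datasets,
    two_point_loglik,
)
from hylaxy.simulate import PedigreeSimConfig, simulate_pedigrees
from conftest import make_family, random_small_dataset


# ---------------------------------------------------------------------------
# Independent brute-force oracle: explicit enumeration of phases and
# transmissions, with compatibility rules restated from first principles.


def _oracle_compatible(obs: Genotype, x, y) -> bool:
    if obs.is_untyped:
        return True
    o = obs.alleles
    if MISSING in o:
        seen = o[0] if o[1] is MISSING else o[1]
        return seen in (x, y)
    pair = tuple(sorted((x, y), key=lambda a: (a is NULL, a if a is not NULL else 0)))
    obs_sorted = tuple(sorted(o, key=lambda a: (a is NULL, a if a is not NULL else 0)))
    if NULL in obs_sorted:
        return pair == obs_sorted
    if o[0] == o[1]:
        return pair in ((o[0], o[0]), (o[0], NULL))
    return pair == obs_sorted


def _oracle_free_ok(obs: Genotype, y) -> bool:
    cands = [a for a in obs.alleles if a is not MISSING] + [NULL, "anything"]
    return any(
        _oracle_compatible(obs, x if x != "anything" else y, y) for x in cands
    ) or _oracle_compatible(obs, y, y)


def brute_force_family_lik(family, locusA, locusB, theta_m, theta_f):
    """Likelihood by exhaustive enumeration over parental phases and the
    four ordered gametes of each typed parent."""

    def typed(parent):
        gA, gB = parent.genotype(locusA), parent.genotype(locusB)
        return not (gA.has_missing or gB.has_missing)

    def phases(parent):
        gA, gB = parent.genotype(locusA), parent.genotype(locusB)
        a1, a2 = gA.alleles
        b1, b2 = gB.alleles
        # two phase assignments, prior 1/2 each
        return [((a1, b1), (a2, b2)), ((a1, b2), (a2, b1))]

    def gamete_probs(hap_pair, theta):
        (a1, b1), (a2, b2) = hap_pair
        return [
            ((a1, b1), (1 - theta) / 2),
            ((a2, b2), (1 - theta) / 2),
            ((a1, b2), theta / 2),
            ((a2, b1), theta / 2),
        ]

    father, mother = family.father, family.mother
    f_typed, m_typed = typed(father), typed(mother)
    f_phases = phases(father) if f_typed else [None]
    m_phases = phases(mother) if m_typed else [None]
    total = 0.0
    for fp in f_phases:
        for mp in m_phases:
            prod = 1.0
            for off in family.offspring:
                oA, oB = off.genotype(locusA), off.genotype(locusB)
                if oA.is_untyped and oB.is_untyped:
                    continue
                p_off = 0.0
                fg = gamete_probs(fp, theta_m) if fp else [(None, 1.0)]
                mg = gamete_probs(mp, theta_f) if mp else [(None, 1.0)]
                any_ok = False
                for gf, pf in fg:
                    for gm, pm in mg:
                        if gf is None and gm is None:
                            ok = True
                        elif gf is None:
                            ok = _oracle_free_ok(oA, gm[0]) and _oracle_free_ok(oB, gm[1])
                        elif gm is None:
                            ok = _oracle_free_ok(oA, gf[0]) and _oracle_free_ok(oB, gf[1])
                        else:
                            ok = _oracle_compatible(oA, gf[0], gm[0]) and _oracle_compatible(
                                oB, gf[1], gm[1]
                            )
                        if ok:
                            p_off += pf * pm
                            any_ok = True
                if not any_ok:
                    p_off = 1.0  # dropout-suspected offspring is marginalized
                prod *= p_off
            total += prod / (len(f_phases) * len(m_phases))
    return total


PHASE_KNOWN_FATHER = {
    "A": Genotype(100, 102),
    "B": Genotype(200, 202),
}
HOM_MOTHER = {"A": Genotype(104, 104), "B": Genotype(204, 204)}


def _informative_family(n_par, n_rec):
    """Father double-het, mother homozygous: n_par parental + n_rec
    recombinant paternal meioses (relative to phase (100,200)/(102,202))."""
    kids = []
    for _ in range(n_par):
        kids.append(("M", {"A": Genotype(100, 104), "B": Genotype(200, 204)}))
    for _ in range(n_rec):
        kids.append(("M", {"A": Genotype(100, 104), "B": Genotype(202, 204)}))
    return make_family(PHASE_KNOWN_FATHER, HOM_MOTHER, kids)


class TestFamilyLoglik:
    def test_fully_informative_binomial_shape(self):
        # 10 paternal meioses, 0 recombinant; phase summed with prior 1/2:
        # L(t) = 1/2 [((1-t)/2)^10 + (t/2)^10]
        fam = _informative_family(10, 0)
        l0 = family_two_point_loglik(fam, "A", "B", 0.0, 0.0)
        l5 = family_two_point_loglik(fam, "A", "B", 0.5, 0.0)
        expected0 = math.log(0.5 * (0.5 ** 10))
        expected5 = math.log(0.25 ** 10)  # both phases equal at 0.5
        assert math.isclose(l0, expected0, rel_tol=1e-12)
        assert math.isclose(l5, expected5, rel_tol=1e-12)
        # maximized at theta_m = 0
        grid = np.linspace(0, 0.5, 101)
        surf = two_point_loglik(
            Dataset(loci=[LocusDef("A"), LocusDef("B")], families=[fam]),
            "A", "B", grid, np.array([0.0]),
        )
        assert grid[int(np.argmax(surf[:, 0]))] == 0.0

    def test_uninformative_offspring_gives_zero_loglik(self):
        fam = make_family(
            PHASE_KNOWN_FATHER, HOM_MOTHER,
            [("M", {})],  # untyped offspring: no information
        )
        for tm in (0.0, 0.2, 0.5):
            assert family_two_point_loglik(fam, "A", "B", tm, 0.3) == 0.0

    def test_matches_bruteforce_enumeration(self, rng):
        checked = 0
        for _ in range(40):
            ds = random_small_dataset(rng, n_families=1, max_offspring=4)
            fam = ds.families[0]
            for tm, tf in ((0.0, 0.0), (0.1, 0.3), (0.25, 0.25), (0.5, 0.4)):
                expected = brute_force_family_lik(fam, "A", "B", tm, tf)
                got = family_two_point_loglik(fam, "A", "B", tm, tf)
                assert math.isclose(math.exp(got), expected, rel_tol=1e-10)
                checked += 1
        assert checked == 160


class TestEstimateTwoPoint:
    def test_mle_equals_recombinant_fraction(self):
        # 10 meioses, 2 recombinant -> theta_m = 0.2
        fam = _informative_family(8, 2)
        ds = Dataset(loci=[LocusDef("A"), LocusDef("B")], families=[fam])
        est = estimate_two_point(ds, "A", "B")
        assert math.isclose(est.theta_m, 0.2, abs_tol=1e-9)
        assert math.isnan(est.theta_f) and math.isnan(est.lod_f)
        assert est.n_inf_m == 10 and est.n_inf_f == 0
        assert est.lod_m > 0

    def test_locus_swap_symmetry(self, rng):
        ds = random_small_dataset(rng, n_families=3, max_offspring=4)
        try:
            e1 = estimate_two_point(ds, "A", "B")
            e2 = estimate_two_point(ds, "B", "A")
        except ValueError:
            pytest.skip("random dataset uninformative")
        assert e1.theta_m == e2.theta_m and e1.theta_f == e2.theta_f

    def test_parameter_recovery_on_simulated_truth(self):
        cfg = PedigreeSimConfig.default(
            n_loci=2, n_families=100, offspring_per_family=20, seed=21,
            theta_f=[0.4], theta_m=[0.0],
        )
        ds, _ = simulate_pedigrees(cfg)
        est = estimate_two_point(ds, "L1", "L2")
        assert est.theta_m == 0.0
        assert abs(est.theta_f - 0.4) < 0.05
        assert est.lod_m > 3  # complete linkage in males is decisive

    def test_matches_fine_grid_oracle(self, rng):
        grid = np.round(np.arange(0, 0.5005, 0.001), 3)
        n_checked = 0
        for _ in range(50):
            ds = random_small_dataset(rng, n_families=2, max_offspring=4)
            try:
                est = estimate_two_point(ds, "A", "B")
            except ValueError:
                continue
            surf = two_point_loglik(ds, "A", "B", grid, grid)
            i, j = np.unravel_index(int(np.argmax(surf)), surf.shape)
            best = surf[i, j]
            got = two_point_loglik(
                ds, "A", "B",
                0.25 if math.isnan(est.theta_m) else est.theta_m,
                0.25 if math.isnan(est.theta_f) else est.theta_f,
            )
            # the optimizer's point is as good as the exhaustive grid's
            assert got >= best - 1e-9
            if not math.isnan(est.theta_m):
                assert abs(est.theta_m - grid[i]) <= 1e-3 + 1e-12 or math.isclose(
                    got, best, abs_tol=1e-9
                )
            n_checked += 1
        assert n_checked >= 30

    def test_error_when_nothing_informative(self):
        fam = make_family(HOM_MOTHER_AS_FATHER, HOM_MOTHER,
                          [("M", {"A": Genotype(104, 104)})])
        ds = Dataset(loci=[LocusDef("A"), LocusDef("B")], families=[fam])
        with pytest.raises(ValueError, match="no informative"):
            estimate_two_point(ds, "A", "B")


HOM_MOTHER_AS_FATHER = {"A": Genotype(104, 104), "B": Genotype(204, 204)}


class TestMTest:
    def test_identical_groups_lambda_zero(self):
        fam = _informative_family(8, 2)
        ds = Dataset(loci=[LocusDef("A"), LocusDef("B")], families=[fam])
        r = mtest([ds, ds], "A", "B", "M")
        assert r.statistic == 0.0 and r.p == 1.0

    def test_single_group_degenerate(self):
        fam = _informative_family(8, 2)
        ds = Dataset(loci=[LocusDef("A"), LocusDef("B")], families=[fam])
        r = mtest([ds], "A", "B", "M")
        assert r.df == 0 and r.statistic == 0.0 and r.p == 1.0

    def test_matches_binomial_closed_form(self):
        # phase-known samples with 1/10 and 4/10 recombinants; with the
        # phase prior the rare phase is negligible only at interior theta,
        # so build truly phase-known sibships: father het at A only is not
        # enough — instead check against the binomial Lambda to grid
        # accuracy using single-phase-dominant data is fragile; use the
        # closed form on the profile likelihood instead.
        g1 = _informative_family(9, 1)
        g2 = _informative_family(6, 4)
        ds1 = Dataset(loci=[LocusDef("A"), LocusDef("B")], families=[g1])
        ds2 = Dataset(loci=[LocusDef("A"), LocusDef("B")], families=[g2])
        r = mtest([ds1, ds2], "A", "B", "M", grid_step=0.001)

        def binom_ll(t, r_, n):
            # phase-summed: log(1/2) + log(((1-t)/2)^(n-r) (t/2)^r + sym)
            val = 0.5 * (((1 - t) / 2) ** (n - r_) * (t / 2) ** r_
                         + ((1 - t) / 2) ** r_ * (t / 2) ** (n - r_))
            return math.log(val) if val > 0 else -math.inf

        grid = np.linspace(0, 0.5, 501)
        l1 = np.array([binom_ll(t, 1, 10) for t in grid])
        l2 = np.array([binom_ll(t, 4, 10) for t in grid])
        lam_expected = 2 * (l1.max() + l2.max() - (l1 + l2).max())
        assert math.isclose(r.statistic, lam_expected, abs_tol=1e-6)
        assert 0 < r.p < 1

    def test_permutation_p_reasonable_under_null(self):
        groups = []
        for g in range(3):
            cfg = PedigreeSimConfig.default(
                n_loci=2, n_families=10, offspring_per_family=10,
                seed=300 + g, theta_f=[0.3],
            )
            ds, _ = simulate_pedigrees(cfg)
            groups.append(ds)
        r = mtest(groups, "L1", "L2", "F", n_perm=200, seed=1)
        assert r.p_perm is not None and r.p_perm > 0.01

    def test_both_sexes_returned_by_default(self):
        fam = make_family(
            PHASE_KNOWN_FATHER,
            {"A": Genotype(104, 106), "B": Genotype(204, 206)},
            [("M", {"A": Genotype(100, 104), "B": Genotype(200, 204)})] * 3
            + [("F", {"A": Genotype(102, 106), "B": Genotype(202, 206)})] * 3,
        )
        ds = Dataset(loci=[LocusDef("A"), LocusDef("B")], families=[fam])
        out = mtest([ds, ds], "A", "B")
        assert set(out) == {"M", "F"}
        assert out["M"].statistic == 0.0 and out["F"].statistic == 0.0


class TestPooling:
    def test_pool_with_self_doubles_counts(self):
        fam = _informative_family(8, 2)
        ds = Dataset(loci=[LocusDef("A"), LocusDef("B")], families=[fam])
        pooled = pool_datasets([ds, ds])
        e1 = estimate_two_point(ds, "A", "B")
        e2 = estimate_two_point(pooled, "A", "B")
        assert e2.n_inf_m == 2 * e1.n_inf_m
        assert e2.theta_m == e1.theta_m

    def test_pool_preserves_individual_count(self):
        cfg = PedigreeSimConfig.default(
            n_loci=2, n_families=5, offspring_per_family=5, seed=31,
            theta_f=[0.4], n_adult_males=3,
        )
        ds, _ = simulate_pedigrees(cfg)
        pooled = pool_datasets([ds, ds])
        assert (
            len(list(pooled.all_individuals()))
            == 2 * len(list(ds.all_individuals()))
        )

    def test_iid_halves_agree_with_whole(self):
        cfg = PedigreeSimConfig.default(
            n_loci=2, n_families=60, offspring_per_family=20, seed=32,
            theta_f=[0.35],
        )
        ds, _ = simulate_pedigrees(cfg)
        half1 = Dataset(loci=ds.loci, families=ds.families[:30])
        half2 = Dataset(loci=ds.loci, families=ds.families[30:])
        pooled = pool_datasets([half1, half2])
        e_pool = estimate_two_point(pooled, "L1", "L2")
        e_all = estimate_two_point(ds, "L1", "L2")
        assert abs(e_pool.theta_f - e_all.theta_f) < 0.02
        assert e_pool.theta_m == e_all.theta_m

    def test_conflicting_loci_rejected(self):
        d1 = Dataset(loci=[LocusDef("A"), LocusDef("B")])
        d2 = Dataset(loci=[LocusDef("A"), LocusDef("C")])
        with pytest.raises(ValueError, match="conflicting"):
            pool_datasets([d1, d2])


class TestMap:
    def test_haldane_closed_form(self):
        assert math.isclose(haldane_cm(0.3), 45.81, abs_tol=0.005)
        assert haldane_cm(0.0) == 0.0

    @given(st.floats(min_value=0.0, max_value=0.49))
    @settings(max_examples=60, deadline=None)
    def test_haldane_round_trip(self, theta):
        assert math.isclose(haldane_theta(haldane_cm(theta)), theta, abs_tol=1e-9)

    def test_composite_fraction_closed_form(self):
        # theta across two intervals without interference
        assert math.isclose(haldane_compose(0.1, 0.2), 0.1 * 0.8 + 0.2 * 0.9)
        assert haldane_compose(0.0, 0.3) == 0.3
        assert math.isclose(haldane_compose(0.5, 0.3), 0.5)

    def test_three_locus_order_by_additivity(self):
        # theta_f: AB 0.1, BC 0.1, AC 0.2 -> order A-B-C
        import math as _m

        ests = {}
        from hylaxy.linkage import TwoPointEstimate

        def est(a, b, tf):
            return TwoPointEstimate(a, b, 0.0, tf, 0.0, 0.0, 0.0, 10, 10)

        ests[frozenset(("A", "B"))] = est("A", "B", 0.1)
        ests[frozenset(("B", "C"))] = est("B", "C", 0.1)
        ests[frozenset(("A", "C"))] = est("A", "C", 0.2)
        ds = Dataset(loci=[LocusDef(n) for n in "ABC"])
        m = build_map(ds, ["A", "B", "C"], estimates=ests)
        assert m.loci == ["A", "B", "C"]
        assert math.isclose(
            m.positions_f_cm[-1], haldane_cm(0.1) * 2, rel_tol=1e-12
        )

    def test_capped_interval_flagged(self):
        from hylaxy.linkage import TwoPointEstimate

        ests = {
            frozenset(("A", "B")): TwoPointEstimate("A", "B", 0.0, 0.5, 0, 0, 0, 5, 5),
            frozenset(("B", "C")): TwoPointEstimate("B", "C", 0.0, 0.1, 0, 0, 0, 5, 5),
            frozenset(("A", "C")): TwoPointEstimate("A", "C", 0.0, 0.5, 0, 0, 0, 5, 5),
        }
        ds = Dataset(loci=[LocusDef(n) for n in "ABC"])
        m = build_map(ds, ["A", "B", "C"], estimates=ests)
        assert m.capped_intervals  # somewhere a free interval was capped

    def test_simulated_map_recovery_and_zero_male_length(self):
        # moderate female fractions keep adjacent Haldane sums well
        # separated between orders; recovery degrades as theta -> 0.5
        hits = 0
        for s in range(6):
            cfg = PedigreeSimConfig.default(
                n_loci=6, n_families=100, offspring_per_family=20,
                seed=41 + s, theta_f=[0.25] * 5, theta_m=[0.0] * 5,
            )
            ds, _ = simulate_pedigrees(cfg)
            m = build_map(ds)
            order = m.loci if m.loci[0] == "L1" else m.loci[::-1]
            hits += order == [f"L{i}" for i in range(1, 7)]
            assert m.positions_m_cm[-1] == 0.0
            assert all(t == 0.0 for t in m.interval_theta_m)
        assert hits >= 5
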