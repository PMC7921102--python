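"""Scenario construction, swaps, chemistry, conservation and kinetics."""

import numpy as np
import pytest

from chromemu import lattice, params
from chromemu import _kernels as K
from chromemu.params import EnergyParams, RateParams, ScenarioConfig, Schedule

from conftest import make_state, set_chromatin, set_rna


def chain_lengths(state):
    return [len(c.positions) for c in state.chains]


def assert_chains_connected(state):
    for c in state.chains:
        for (y1, x1), (y2, x2) in zip(c.positions, c.positions[1:]):
            assert max(abs(y1 - y2), abs(x1 - x2)) == 1


class TestBuildScenario:
    def test_uniform_dispersion_layout(self):
        st = lattice.build_scenario(params.scenario("uniform_dispersion"))
        c = st.counts()
        assert (st.width, st.height) == (50, 50)
        assert len(st.chains) == 100
        assert all(n == 5 for n in chain_lengths(st))
        assert c["total_rna"] == 0
        assert c["n_active"] == 0
        assert_chains_connected(st)

    def test_phase_separation_every_rbp_bound(self):
        st = lattice.build_scenario(params.scenario("phase_separation"))
        c = st.counts()
        assert c["n_bound_rbp"] == c["n_rbp"]

    def test_post_mitosis_layout(self):
        st = lattice.build_scenario(params.scenario("post_mitosis_control"))
        assert (st.width, st.height) == (100, 100)
        assert len(st.chains) == 100
        assert all(n == 50 for n in chain_lengths(st))
        assert all(c.state == "permissive" for c in st.chains)
        assert st.padding_species == "inactive_chromatin"
        assert_chains_connected(st)

    def test_onset_scenario_single_central_permissive_chain(self):
        cfg = params.scenario("mir430_onset")
        st = lattice.build_scenario(cfg)
        assert len(st.chains) == 25
        states = [c.state for c in st.chains]
        assert states.count("permissive") == 0  # turned on only at onset time
        assert cfg.permissive_chain == 12
        # chain 12 occupies the central 10x10 box
        ys, xs = zip(*st.chains[12].positions)
        assert 20 <= min(ys) and max(ys) < 30 and 20 <= min(xs) and max(xs) < 30

    def test_layout_overflow_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(name="microphase", width=10, height=10, box=5,
                           chain_length=5, n_chains=100)


class TestAttemptSwap:
    def test_zero_cost_feasible_swap_always_accepted(self, rng):
        st = make_state(6, 6)
        e = EnergyParams(0.0, 0.0, 0.0)
        outcomes = [lattice.attempt_swap(st, e, rng) for _ in range(200)]
        feasible = [o for o in outcomes if o.status != "rejected_padding"]
        assert feasible and all(o.accepted for o in feasible)
        assert all(o.p_swap == 1.0 for o in feasible)

    def test_transcripts_travel_with_the_site(self, rng):
        st = make_state(2, 1)
        set_rna(st, (0, 0), 5)
        e = EnergyParams(0.0, 0.0, 0.0)
        for _ in range(200):
            lattice.attempt_swap(st, e, rng)
        total = st.rna_counts().sum()
        assert total == 5  # swaps never create or destroy transcripts

    def test_tethered_site_never_moves(self, rng):
        st = make_state(4, 4)
        set_chromatin(st, [(1, 1)])
        i = st._flat((1, 1))
        st.tethered[i] = 1
        e = EnergyParams(0.0, 0.0, 0.0)
        for _ in range(500):
            lattice.attempt_swap(st, e, rng)
        assert st.kind[i] == K.KIND_CHROM

    def test_connectivity_breaking_swap_rejected(self, microphase_small, rng):
        e = EnergyParams(0.0, 0.0, 0.0)
        for _ in range(2000):
            out = lattice.attempt_swap(microphase_small, e, rng)
            assert out.status in ("accepted", "rejected_padding",
                                  "rejected_connectivity", "rejected_tethered")
        assert_chains_connected(microphase_small)

    def test_delta_e_matches_local_energy_bookkeeping(self, rng):
        # cross-check the kernel's dE against the Python energy oracle
        e = EnergyParams(1.0, 0.7, 0.3)
        st = lattice.build_scenario(
            params.ScenarioConfig(name="microphase", width=10, height=10,
                                  box=5, chain_length=5, n_chains=4,
                                  padding="rna_rbp"))
        checked = 0
        for trial in range(4000):
            rng2 = np.random.default_rng(trial)
            before = lattice.local_energy(
                st, [(y, x) for y in range(10) for x in range(10)], e)
            out = lattice.attempt_swap(st, e, rng2)
            if not out.accepted:
                continue
            after = lattice.local_energy(
                st, [(y, x) for y in range(10) for x in range(10)], e)
            assert after - before == pytest.approx(out.delta_e, abs=1e-9)
            checked += 1
            if checked >= 50:
                break
        assert checked >= 50


class TestChemicalUpdate:
    def test_all_rates_zero_is_an_error(self):
        st = make_state(4, 4)
        sch = Schedule(1.0, 0)
        with pytest.raises(ValueError):
            lattice.chemical_update(st, RateParams(0, 0, 0, 0, 0, 0, 0), sch)

    def test_production_matches_binomial_band(self):
        # 1000 active chromatin sites at the fastest rate: p = 0.1/interval
        st = make_state(40, 25)
        set_chromatin(st, [(y, x) for y in range(25) for x in range(40)],
                      active=True)
        rates = RateParams(0, 0, 0.1, 0, 0, 0, 0)
        sch = Schedule.from_rates(rates, 40, 25)
        out = lattice.chemical_update(st, rates, sch, seed=77)
        assert sch.conversion_probability(rates.k_rna_prod) == pytest.approx(0.1)
        assert abs(out.productions - 100) <= 3 * np.sqrt(90)

    def test_activation_gated_by_permissive_chain(self):
        cfg = params.ScenarioConfig(name="microphase", width=10, height=10,
                                    box=5, chain_length=5, n_chains=4,
                                    all_chains_permissive=False)
        st = lattice.build_scenario(cfg)
        rates = RateParams(0.1, 0, 0, 0, 0, 0, 0)
        sch = Schedule.from_rates(rates, 10, 10)
        for i in range(50):
            lattice.chemical_update(st, rates, sch, seed=i)
        assert st.counts()["n_active"] == 0
        st.ch_perm[:] = 1
        for i in range(50):
            lattice.chemical_update(st, rates, sch, seed=100 + i)
        assert st.counts()["n_active"] > 0

    def test_decay_suppressed_on_chromatin_when_flagged(self):
        st = make_state(4, 4)
        set_chromatin(st, [(0, 0)])
        set_rna(st, (0, 0), 50)
        rates = RateParams(0, 0, 0, 0, 0.1, 0, 0, rna_decay_on_chromatin=False)
        sch = Schedule.from_rates(rates, 4, 4)
        for i in range(30):
            lattice.chemical_update(st, rates, sch, seed=i)
        assert st.rna_counts().sum() == 50

    def test_transfer_moves_one_transcript_to_rbp_neighbor(self):
        st = make_state(3, 3)
        set_chromatin(st, [(1, 1)])
        set_rna(st, (1, 1), 10)
        rates = RateParams(0, 0, 0, 0.1, 0, 0, 0)
        sch = Schedule.from_rates(rates, 3, 3)
        for i in range(200):
            lattice.chemical_update(st, rates, sch, seed=i)
        i = st._flat((1, 1))
        assert st.rna[i] == 0
        assert st.rna_counts().sum() == 10  # transcripts conserved


class TestInhibitors:
    def test_flavopiridol_zeroes_only_activation(self):
        r = params.default_rates()
        fp = lattice.apply_inhibitor(r, "flavopiridol")
        assert fp.k_chrom_on == 0.0
        assert fp.k_chrom_off == r.k_chrom_off
        assert fp.k_rna_prod == r.k_rna_prod
        assert fp.k_rna_transfer == r.k_rna_transfer
        assert fp.rna_decay_on_chromatin == r.rna_decay_on_chromatin

    def test_actinomycin_freezes_actives_and_retains_their_rna(self):
        r = params.default_rates()
        ad = lattice.apply_inhibitor(r, "actinomycinD")
        assert ad.k_chrom_on == 0.0
        assert ad.k_chrom_off == 0.0
        assert ad.k_rna_prod == 0.0
        assert ad.k_rna_transfer == 0.0
        assert ad.rna_decay_on_chromatin is False
        assert ad.k_rna_decay == r.k_rna_decay  # decay off chromatin continues

    def test_idempotent(self):
        r = params.default_rates()
        once = lattice.apply_inhibitor(r, "flavopiridol")
        assert lattice.apply_inhibitor(once, "flavopiridol") == once

    def test_unknown_inhibitor_rejected(self):
        with pytest.raises(ValueError):
            lattice.apply_inhibitor(params.default_rates(), "puromycin")


class TestRunConservationAndDeterminism:
    def test_species_and_chains_conserved_with_chemistry(self):
        cfg = params.ScenarioConfig(name="microphase", width=20, height=20,
                                    box=5, chain_length=5, n_chains=16)
        st = lattice.build_scenario(cfg)
        before = st.counts()
        lens_before = chain_lengths(st)
        r = params.default_rates()
        sch = Schedule.from_rates(r, 20, 20)
        lattice.run(st, r, params.default_energy(), sch, 300.0, seed=5,
                    keep_snapshots=False)
        after = st.counts()
        assert after["n_chromatin"] == before["n_chromatin"]
        assert after["n_rbp"] == before["n_rbp"]
        assert chain_lengths(st) == lens_before
        assert_chains_connected(st)

    def test_rna_balance_closes(self):
        cfg = params.ScenarioConfig(name="microphase", width=20, height=20,
                                    box=5, chain_length=5, n_chains=16)
        st = lattice.build_scenario(cfg)
        r = params.default_rates()
        sch = Schedule.from_rates(r, 20, 20)
        counts = np.zeros(7, np.int64)
        lattice.seed_rng(st, 9)
        p = sch.conversion_probability
        for _ in range(200):
            K.chem_step(st.kind, st.active, st.rna, st.code, st.chain_id,
                        st.valid, st.ch_perm, st.ch_len, st.offs, st.interior,
                        p(r.k_chrom_on), p(r.k_chrom_off), p(r.k_rna_prod),
                        p(r.k_rna_transfer), p(r.k_rna_decay), 0.0, 0.0, 1,
                        counts, st._rng)
        produced, decayed = counts[2], counts[4]
        assert st.rna_counts().sum() == produced - decayed

    def test_same_seed_reproduces_trajectory_exactly(self):
        cfg = params.scenario("microphase")
        a = lattice.run_scenario(cfg, seed=42, duration=120.0,
                                 keep_snapshots=False)
        b = lattice.run_scenario(cfg, seed=42, duration=120.0,
                                 keep_snapshots=False)
        assert np.array_equal(a.final_state.kind, b.final_state.kind)
        assert np.array_equal(a.final_state.rna, b.final_state.rna)
        assert a.accepted_swaps == b.accepted_swaps
        c = lattice.run_scenario(cfg, seed=43, duration=120.0,
                                 keep_snapshots=False)
        assert not np.array_equal(a.final_state.kind, c.final_state.kind)

    def test_relaxation_phase_executes_no_chemistry(self):
        cfg = params.scenario("mir430_onset")
        traj = lattice.run_scenario(cfg, seed=3, duration=300.0,
                                    keep_snapshots=False)
        # still inside the 600 s relaxation window: no RNA, no active sites
        c = traj.final_state.counts()
        assert c["total_rna"] == 0
        assert c["n_active"] == 0

    def test_boundary_tether_is_permanent(self):
        st = lattice.build_scenario(params.scenario("post_mitosis_control"))
        r = params.default_rates()
        sch = Schedule.from_rates(r, 100, 100)
        lattice.run(st, r, params.default_energy(), sch, 60.0, seed=8,
                    keep_snapshots=False)
        teth = st.tethered.copy()
        lattice.run(st, r, params.default_energy(), sch, 60.0, seed=9,
                    keep_snapshots=False)
        # tethered set never shrinks
        assert np.all(st.tethered[teth == 1] == 1)


class TestKinetics:
    def test_isolated_reaction_survival_matches_exponential(self):
        # deactivation at k = k_max/10 (p = 0.01/interval keeps the
        # first-order discretization bias far below the binomial noise band)
        st = make_state(100, 100)
        set_chromatin(st, [(y, x) for y in range(100) for x in range(100)],
                      active=True)
        k = 0.01
        rates = RateParams(0, k, 0, 0, 0.1, 0, 0)  # decay idles (no RNA)
        sch = Schedule.from_rates(rates, 100, 100)
        lattice.seed_rng(st, 1234)
        n0 = 10_000
        t = 0.0
        for target_kt in (0.25, 0.5, 1.0, 1.5, 2.0):
            while t * k < target_kt - 1e-9:
                lattice.chemical_update(st, rates, sch)
                t += sch.dt_chem
            surv = st.counts()["n_active"] / n0
            expect = np.exp(-k * t)
            se = np.sqrt(expect * (1 - expect) / n0)
            assert abs(surv - expect) <= 3 * se
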