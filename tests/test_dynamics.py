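"""Force laws, the Brownian integrator, switching, and equilibrium checks."""

import numpy as np
import pytest
from scipy.integrate import quad

import polybridge as pb
from polybridge import _kernels
from polybridge.dynamics import (
    ForceField,
    Frame,
    _System,
    compute_forces,
    confinement_radius_for_volume_fraction,
    pair_potential,
    potential_energy,
)
from polybridge.errors import StabilityError


def make_frame(bead_pos, factor_pos, colors, competent=None):
    factor_pos = np.asarray(factor_pos, dtype=float).reshape(-1, 3)
    if competent is None:
        competent = np.ones(len(factor_pos), dtype=bool)
    return Frame(
        time=0.0,
        bead_positions=np.asarray(bead_pos, dtype=float).reshape(-1, 3),
        factor_positions=factor_pos,
        factor_colors=list(colors),
        binding_competent=np.asarray(competent, dtype=bool),
    )


def chain_string(n, colors=()):
    from polybridge.model_core import Bead, GenomeString

    palette = sorted(set(c for c in colors if c)) or ["red"]
    beads = [
        Bead(index=i, colors=frozenset({colors[i]}) if i < len(colors) and colors[i] else frozenset())
        for i in range(n)
    ]
    return GenomeString(beads, palette)


class TestComputeForces:
    def test_bonded_pair_at_rest_length_feels_nothing(self):
        s = chain_string(2)
        fr = make_frame([[0, 0, 0], [30, 0, 0]], np.empty((0, 3)), [])
        f = compute_forces(fr, s, [])
        assert np.abs(f).max() < 1e-12

    def test_factor_in_well_attracted_symmetrically(self):
        s = chain_string(1, ["red"])
        sp = [pb.FactorSpecies("red", 1)]
        fr = make_frame([[0, 0, 0]], [[40.0, 0, 0]], ["red"])
        f = compute_forces(fr, s, sp)
        assert f[1, 0] < -1e-3  # factor pulled toward the bead
        np.testing.assert_allclose(f[0], -f[1], atol=1e-12)
        # incompetent factor feels nothing at this range
        fr2 = make_frame([[0, 0, 0]], [[40.0, 0, 0]], ["red"], [False])
        assert np.abs(compute_forces(fr2, s, sp)).max() < 1e-12
        # non-cognate bead likewise
        fr3 = make_frame([[0, 0, 0]], [[40.0, 0, 0]], ["green"])
        sp3 = [pb.FactorSpecies("green", 1)]
        s3 = chain_string(1, ["red"])
        assert np.abs(compute_forces(fr3, s3, sp3)).max() < 1e-12

    def test_internal_forces_sum_to_zero(self):
        rng = np.random.default_rng(3)
        s = chain_string(20, ["red"] * 10)
        sp = [pb.FactorSpecies("red", 5)]
        fr = make_frame(
            np.cumsum(rng.normal(0, 18, (20, 3)), axis=0),
            rng.uniform(-100, 100, (5, 3)),
            ["red"] * 5,
        )
        f = compute_forces(fr, s, sp)  # no confinement by default
        assert np.abs(f.sum(axis=0)).max() < 1e-9 * max(np.abs(f).max(), 1.0)

    def test_overlapping_particles_finite_forces(self):
        s = chain_string(2)
        fr = make_frame([[0, 0, 0], [0.5, 0, 0]], np.empty((0, 3)), [])
        f = compute_forces(fr, s, [])
        assert np.isfinite(f).all()

    def test_forces_are_gradient_of_potential(self):
        """Central finite differences of the energy, with bending + walls on."""
        rng = np.random.default_rng(8)
        s = chain_string(4, [None, "red", None, "red"])
        sp = [pb.FactorSpecies("red", 2)]
        field = ForceField(bending_rigidity=2.0, confinement_radius_nm=120.0)
        pos = np.array(
            [[0, 0, 0], [28, 5, 0], [55, 10, 8], [80, 0, 0], [40, 20, 10], [105, 5, 0.0]]
        ) + rng.normal(0, 1, (6, 3))
        fr = make_frame(pos[:4], pos[4:], ["red", "red"])
        f = compute_forces(fr, s, sp, field)
        h = 1e-6
        for p in range(6):
            for k in range(3):
                for sign, store in ((1, "up"), (-1, "dn")):
                    q = pos.copy()
                    q[p, k] += sign * h
                    fr2 = make_frame(q[:4], q[4:], ["red", "red"])
                    if sign == 1:
                        up = potential_energy(fr2, s, sp, field)
                    else:
                        dn = potential_energy(fr2, s, sp, field)
                num = -(up - dn) / (2 * h)
                assert f[p, k] == pytest.approx(num, abs=2e-4)


class TestKernelAgreesWithReference:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_forces_match(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 40, 8
        colors = [rng.choice(["red", "green", None]) for _ in range(n)]
        s = chain_string(n, colors)
        sp = [pb.FactorSpecies("red", 4), pb.FactorSpecies("green", 4)]
        field = ForceField(confinement_radius_nm=200.0).resolve(s)
        sys_ = _System(s, sp, field)
        pos = np.vstack(
            [np.cumsum(rng.normal(0, 17, (n, 3)), axis=0), rng.uniform(-80, 80, (m, 3))]
        )
        comp = (rng.random(m) < 0.7).astype(np.uint8)
        cap = 20000
        pi = np.empty(cap, np.int32)
        pj = np.empty(cap, np.int32)
        pc, pq, pe = np.empty(cap), np.empty(cap), np.empty(cap)
        pf = np.empty(cap, np.int32)
        pn = np.empty(cap)
        ka = sys_.kernel_args()
        npairs = _kernels._build_pairs(
            pos, ka["radius"], ka["nb"], ka["bead_mask"], ka["factor_bit"],
            ka["eps_spec"], ka["eps_ns"], ka["attr_w"], 60.0,
            _kernels.SKIN_INNER_NM, pi, pj, pc, pq, pe, pf, pn,
        )
        f = np.zeros_like(pos)
        _kernels._pair_and_bonded_forces(
            pos, ka["radius"], comp, pi, pj, pc, pq, pe, pf, npairs,
            ka["nb"], ka["k_bond"], ka["r0_bond"], ka["e0_rep"], ka["f_cap"],
            ka["attr_w"], ka["kappa"], ka["r_conf"], ka["k_conf"], f,
        )
        fr = make_frame(pos[:n], pos[n:], ["red"] * 4 + ["green"] * 4, comp.astype(bool))
        f_ref = compute_forces(fr, s, sp, field)
        np.testing.assert_allclose(f, f_ref, rtol=1e-9, atol=1e-9)


class TestBdStep:
    def test_dt_zero_is_identity(self):
        s = chain_string(3)
        fr = make_frame(np.random.default_rng(0).normal(0, 20, (3, 3)), np.empty((0, 3)), [])
        out = pb.bd_step(fr, s, [], dt=0.0, rng=np.random.default_rng(1))
        np.testing.assert_array_equal(out.bead_positions, fr.bead_positions)

    def test_same_seed_same_update(self):
        s = chain_string(5)
        fr = make_frame(np.cumsum(np.full((5, 3), 10.0), axis=0), np.empty((0, 3)), [])
        a = pb.bd_step(fr, s, [], dt=0.002, rng=np.random.default_rng(7))
        b = pb.bd_step(fr, s, [], dt=0.002, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.bead_positions, b.bead_positions)

    def test_runaway_drift_raises(self):
        s = chain_string(2)
        fr = make_frame([[0, 0, 0], [600.0, 0, 0]], np.empty((0, 3)), [])
        with pytest.raises(StabilityError):
            pb.bd_step(fr, s, [], dt=0.002)

    def test_steepest_descent_lowers_energy(self):
        """With noise off, repeated updates never raise the potential."""
        rng = np.random.default_rng(5)
        s = chain_string(6, [None, "red", None, "red", None, "red"])
        sp = [pb.FactorSpecies("red", 2)]
        fr = make_frame(
            np.cumsum(rng.normal(0, 12, (6, 3)), axis=0),
            rng.uniform(-60, 60, (2, 3)),
            ["red", "red"],
        )
        energies = [potential_energy(fr, s, sp)]
        for _ in range(60):
            fr = pb.bd_step(fr, s, sp, dt=5e-4, rng=None)
            energies.append(potential_energy(fr, s, sp))
        diffs = np.diff(energies)
        assert (diffs <= 1e-9).all()
        assert energies[-1] < energies[0]


class TestSwitchStates:
    def test_zero_rates_change_nothing(self):
        sp = [pb.FactorSpecies("red", 10, switch_off_rate=0.0, switch_on_rate=0.0)]
        fr = make_frame(
            [[0, 0, 0]], np.zeros((10, 3)), ["red"] * 10,
            np.arange(10) % 2 == 0,
        )
        out = pb.switch_states(fr, sp, dt=0.5, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out.binding_competent, fr.binding_competent)

    def test_equal_rates_relax_to_half(self):
        """Two-state chain with equal rates: stationary competent fraction 1/2."""
        sp = [pb.FactorSpecies("red", 600, switch_off_rate=0.45, switch_on_rate=0.45)]
        fr = make_frame(
            [[0, 0, 0]], np.zeros((600, 3)), ["red"] * 600, np.ones(600, bool)
        )
        rng = np.random.default_rng(13)
        for _ in range(400):
            fr = pb.switch_states(fr, sp, dt=0.2, rng=rng)
        frac = fr.binding_competent.mean()
        se = 0.5 / np.sqrt(600)
        assert abs(frac - 0.5) < 3 * se

    def test_rate_dt_validation(self):
        sp = [pb.FactorSpecies("red", 1, switch_off_rate=10.0, switch_on_rate=10.0)]
        fr = make_frame([[0, 0, 0]], np.zeros((1, 3)), ["red"])
        with pytest.raises(ValueError):
            pb.switch_states(fr, sp, dt=0.2, rng=np.random.default_rng(0))

    def test_physical_rate_mapping(self):
        """1e-5 per Brownian time maps to ~1e-3 per second at tauB = 0.01 s."""
        sp = pb.FactorSpecies("red", 1)
        cfg = pb.SimulationConfig(n_steps=1, seed=0)
        assert sp.switch_off_rate == pytest.approx(1e-5)
        assert cfg.rate_per_second(sp.switch_off_rate) == pytest.approx(1e-3)
        # per-step flip probability at the engine defaults
        assert sp.switch_off_rate * 0.01 == pytest.approx(1e-7)


class TestRunSimulation:
    def test_deterministic_given_seed(self):
        s = chain_string(30, ["red"] * 10)
        sp = [pb.FactorSpecies("red", 3)]
        cfg = pb.SimulationConfig(n_steps=5000, seed=77, frame_interval=1000)
        a = pb.run_simulation(s, sp, None, cfg)
        b = pb.run_simulation(s, sp, None, cfg)
        np.testing.assert_array_equal(
            a.frames[-1].factor_positions, b.frames[-1].factor_positions
        )
        np.testing.assert_array_equal(
            a.frames[-1].bead_positions, b.frames[-1].bead_positions
        )

    def test_stability_abort_names_step(self):
        s = chain_string(2)
        pos = np.array([[0, 0, 0], [600.0, 0, 0], [0, 200.0, 0]])
        with pytest.raises(StabilityError) as e:
            pb.run_simulation(
                s, [pb.FactorSpecies("red", 1)], None,
                pb.SimulationConfig(n_steps=100, seed=0, frame_interval=10),
                initial_positions=pos,
            )
        assert e.value.step is not None

    def test_frame_bookkeeping_and_conservation(self, bridging_traj):
        traj = bridging_traj
        assert traj.n_frames == 40
        times = [f.time for f in traj.frames]
        assert all(b > a for a, b in zip(times, times[1:]))
        spacing = traj.config.frame_interval * traj.config.timestep_tauB
        np.testing.assert_allclose(np.diff(times), spacing)
        for fr in traj.frames[::10]:
            assert fr.n_beads == 200 and fr.n_factors == 20
            assert np.isfinite(fr.bead_positions).all()

    def test_bonds_never_exceed_1p5_rest_length(self, bridging_traj):
        rest = bridging_traj.field.bond_rest_length
        worst = max(
            np.linalg.norm(np.diff(fr.bead_positions, axis=0), axis=1).max()
            for fr in bridging_traj.frames
        )
        assert worst < 1.5 * rest

    def test_confinement_respected(self, bridging_traj, small_field, small_string):
        limit = small_field.confinement_radius_nm + small_string.bead_diameter_nm
        for fr in bridging_traj.frames[::10]:
            assert np.linalg.norm(fr.all_positions(), axis=1).max() < limit

    def test_polymer_internal_distances_grow_with_contour(self, polymer_only_traj):
        """Mean-squared internal distance rises monotonically in log-spaced bins."""
        seps = [1, 2, 4, 8, 16, 32, 64]
        msd = []
        for s in seps:
            vals = []
            for fr in polymer_only_traj.frames:
                d = fr.bead_positions[s:] - fr.bead_positions[:-s]
                vals.append((d**2).sum(axis=1).mean())
            msd.append(np.mean(vals))
        assert all(b > a for a, b in zip(msd, msd[1:]))

    def test_switching_happens_during_run(self):
        sp = [pb.FactorSpecies("red", 20, switch_off_rate=0.05, switch_on_rate=0.05)]
        s = chain_string(20, ["red"] * 5)
        cfg = pb.SimulationConfig(n_steps=40000, seed=3, frame_interval=1000)
        traj = pb.run_simulation(s, sp, None, cfg)
        comp = np.array([fr.binding_competent for fr in traj.frames])
        assert comp.any() and (~comp).any()
        flips = np.abs(np.diff(comp.astype(int), axis=0)).sum()
        assert flips > 10


class TestFreeDiffusion:
    def test_msd_matches_6dt(self):
        """Free factors: MSD = 6 D t within 5% over 2000 walkers."""
        s = chain_string(1)  # one inert bead, pinned
        sp = [pb.FactorSpecies("blue", 2000)]  # color not in palette: never binds
        field = ForceField(excluded_volume_strength=0.0)
        grid = 120.0 * np.indices((13, 13, 13)).reshape(3, -1).T[: 2001]
        cfg = pb.SimulationConfig(n_steps=100, seed=21, frame_interval=100)
        traj = pb.run_simulation(
            s, sp, field, cfg, pinned_beads=[0], initial_positions=grid.astype(float)
        )
        disp = traj.frames[-1].factor_positions - grid[1:]
        t = 100 * cfg.timestep_tauB
        sigma = s.bead_diameter_nm
        D = sigma**2  # nm^2 / tauB for a bead-sized particle
        msd = (disp**2).sum(axis=1).mean()
        assert msd == pytest.approx(6 * D * t, rel=0.05)


class TestTwoParticleEquilibrium:
    def test_bound_fraction_matches_boltzmann_integral(self):
        """One factor + one pinned cognate bead vs the radial Boltzmann weight."""
        s = chain_string(1, ["red"])
        eps = 5.0
        sp = [pb.FactorSpecies("red", 1, specific_affinity_kT=eps)]
        field = ForceField(confinement_radius_nm=240.0).resolve(s)
        cutoff = 30.0 + field.attraction_range_nm

        def u(r):
            pair = pair_potential(
                r, 30.0, field.excluded_volume_strength, field.force_cap_kT_per_nm,
                eps, field.attraction_range_nm,
            )
            lim = field.confinement_radius_nm - 15.0
            wall = 0.5 * field.confinement_spring_constant * np.clip(r - lim, 0, None) ** 2
            return pair + wall

        weight = lambda r: np.exp(-u(r)) * r * r
        num, _ = quad(weight, 0, cutoff, limit=200)
        den = num + quad(weight, cutoff, 400.0, limit=200)[0]
        p_theory = num / den

        p_runs = []
        for seed in range(5):
            cfg = pb.SimulationConfig(
                n_steps=300_000, seed=100 + seed, equilibration_steps=50_000,
                frame_interval=500,
            )
            traj = pb.run_simulation(
                s, sp, field, cfg, pinned_beads=[0],
                initial_positions=np.array([[0.0, 0, 0], [100.0, 0, 0]]),
            )
            d = np.array(
                [np.linalg.norm(fr.factor_positions[0]) for fr in traj.frames]
            )
            p_runs.append((d < cutoff).mean())
        p_hat = np.mean(p_runs)
        se = np.std(p_runs, ddof=1) / np.sqrt(len(p_runs))
        assert abs(p_hat - p_theory) < 3 * max(se, 0.01)


class TestReversibility:
    def test_every_factor_unbinds_after_binding(self):
        """No irreversible trapping: each bound factor is later seen unbound.

        Cognate sites are spaced far apart so binding is single-valent; a
        factor simultaneously bridging several sites in a cluster has an
        effective well of 2-3x the single-site depth and residence times far
        beyond any tractable run — that stability is the bridging phenomenon
        itself, so reversibility is asserted in the single-site regime at a
        moderate affinity.
        """
        from polybridge.model_core import Bead, GenomeString

        beads = [
            Bead(index=i, colors=frozenset({"red"}) if i % 20 == 10 else frozenset())
            for i in range(100)
        ]
        string = GenomeString(beads, ["red"])
        sp = [
            pb.FactorSpecies(
                "red", 5, specific_affinity_kT=5.0,
                switch_off_rate=0.0, switch_on_rate=0.0,
            )
        ]
        radius = confinement_radius_for_volume_fraction(string, sp, 0.02)
        field = ForceField(confinement_radius_nm=radius).resolve(string)
        cfg = pb.SimulationConfig(n_steps=1_200_000, seed=41, frame_interval=2000)
        traj = pb.run_simulation(string, sp, field, cfg)
        from polybridge.observables import bound_factor_flags

        bound = np.array([bound_factor_flags(fr, traj) for fr in traj.frames])
        for k in range(5):
            series = bound[:, k].astype(int)
            assert series.any(), "factor never bound at all"
            # a 1 -> 0 transition exists after the first binding
            assert (np.diff(series) == -1).any()
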