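"""Insertion free-energy maps: pair energies, orientation sets, and the
full map against a naive independent re-implementation."""

import math

import numpy as np
import pytest

from gaspore.constants import COULOMB_K, RT
from gaspore.core import ProbeLigand, ProbeSite, Trajectory
from gaspore.grids import FreeEnergyGrid, GridSpec
from gaspore.ils import (
    E_CAP,
    bulk_reference,
    coulomb_pair,
    field_map,
    ils_map,
    lj_pair,
    orientation_set,
    probe_interaction_energy,
    project_profile,
    reference_grid,
    segment_statistics,
)
from gaspore.potentials import gaussian_barrier
from gaspore.probes import O2, CO2, HostParams, get_probe
from gaspore.synthetic import jittered_host_frames


def one_site_probe(epsilon=0.2, sigma=3.0, charge=0.0):
    return ProbeLigand(
        name="P", sites=(ProbeSite("P", epsilon, sigma, charge, (0.0, 0.0, 0.0)),)
    )


class TestPairEnergies:
    def test_lj_zero_at_sigma(self):
        host = HostParams.uniform(1, epsilon=0.2, sigma=3.0)
        probe = one_site_probe(epsilon=0.2, sigma=3.0)
        # combined sigma = 3.0; inside the switch region the LJ term is bare
        e = probe_interaction_energy(
            np.array([[0.0, 0.0, 0.0]]), host, probe, position=np.array([3.0, 0.0, 0.0])
        )
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_is_minus_epsilon(self):
        host = HostParams.uniform(1, epsilon=0.3, sigma=3.2)
        probe = one_site_probe(epsilon=0.3, sigma=3.2)
        r = 2 ** (1 / 6) * 3.2
        e = probe_interaction_energy(
            np.array([[0.0, 0.0, 0.0]]), host, probe, position=np.array([r, 0.0, 0.0])
        )
        assert e == pytest.approx(-0.3, abs=1e-12)

    def test_coulomb_constant_at_one_angstrom(self):
        assert coulomb_pair(1.0, 1.0, -1.0) == pytest.approx(-332.0636)

    def test_lj_helper_root_and_minimum(self):
        assert lj_pair(3.0, 0.5, 3.0) == pytest.approx(0.0)
        assert lj_pair(2 ** (1 / 6) * 3.0, 0.5, 3.0) == pytest.approx(-0.5)

    def test_overlap_is_capped_not_raised(self):
        host = HostParams.uniform(1, epsilon=0.2, sigma=3.0)
        probe = one_site_probe()
        e = probe_interaction_energy(
            np.array([[0.0, 0.0, 0.0]]), host, probe, position=np.zeros(3)
        )
        assert e == E_CAP

    def test_bundled_probes_are_neutral(self):
        assert get_probe("o2").net_charge == pytest.approx(0.0)
        assert get_probe("co2").net_charge == pytest.approx(0.0)
        assert CO2.sites[0].charge == pytest.approx(0.6)
        assert abs(O2.sites[0].charge) == pytest.approx(0.02)


class TestOrientationSet:
    def test_single_orientation_is_plus_z(self):
        assert np.allclose(orientation_set(1), [[0.0, 0.0, 1.0]])

    def test_deterministic_without_seed(self):
        assert np.array_equal(orientation_set(10), orientation_set(10))

    def test_random_orientations_are_uniform(self):
        v = orientation_set(1000, seed=4)
        assert np.allclose(np.linalg.norm(v, axis=1), 1.0)
        assert np.linalg.norm(v.mean(axis=0)) < 0.1

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            orientation_set(0)


def naive_ils_map(frames, host, probe, spec, temperature):
    """Independent re-implementation of the insertion map with plain Python
    loops: switched LJ + shifted Coulomb, Lorentz-Berthelot, E capped, mean
    Boltzmann factor per cell.  Shares no code with gaspore.ils."""
    rt = 1.987204e-3 * temperature
    cutoff, switch = 12.0, 10.0
    nx, ny, nz = spec.shape
    sub_counts = spec.subsites_per_cell
    n_or = spec.n_orientations
    ors = orientation_set(n_or)
    local = probe.local_positions
    values = np.empty((nx, ny, nz))
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                center = np.array(
                    [
                        spec.origin[0] + (ix + 0.5) * spec.cell_spacing,
                        spec.origin[1] + (iy + 0.5) * spec.cell_spacing,
                        spec.origin[2] + (iz + 0.5) * spec.cell_spacing,
                    ]
                )
                acc = 0.0
                n_terms = 0
                for f in range(frames.n_frames):
                    xyz = frames.frame(f)
                    for sx in range(sub_counts[0]):
                        for sy in range(sub_counts[1]):
                            for sz in range(sub_counts[2]):
                                off = np.array(
                                    [
                                        (sx + 0.5) / sub_counts[0] - 0.5,
                                        (sy + 0.5) / sub_counts[1] - 0.5,
                                        (sz + 0.5) / sub_counts[2] - 0.5,
                                    ]
                                ) * spec.cell_spacing
                                pos = center + off
                                for u in ors:
                                    e = 0.0
                                    R = _rot_to(u)
                                    for si, site in enumerate(probe.sites):
                                        sp = pos + R @ local[si]
                                        for ai in range(host.n_atoms):
                                            d = sp - xyz[ai]
                                            r2 = float(d @ d)
                                            if r2 <= 1e-12:
                                                e += E_CAP
                                                continue
                                            if r2 >= cutoff**2:
                                                continue
                                            r = math.sqrt(r2)
                                            sig = 0.5 * (site.sigma + host.sigma[ai])
                                            eps = math.sqrt(site.epsilon * host.epsilon[ai])
                                            sr6 = (sig**2 / r2) ** 3
                                            if r2 <= switch**2:
                                                sw = 1.0
                                            else:
                                                c2, s2 = cutoff**2, switch**2
                                                sw = ((c2 - r2) ** 2 * (c2 + 2 * r2 - 3 * s2)) / (c2 - s2) ** 3
                                            e += 4 * eps * (sr6 * sr6 - sr6) * sw
                                            e += COULOMB_K * site.charge * host.charge[ai] * (1 / r - 1 / cutoff)
                                    acc += math.exp(-min(e, E_CAP) / rt)
                                    n_terms += 1
                mean = acc / n_terms
                values[ix, iy, iz] = -rt * math.log(max(mean, math.exp(-E_CAP / rt)))
    return values


def _rot_to(u):
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, u))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, u)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


class TestIlsMap:
    def small_spec(self):
        return GridSpec(
            origin=(-1.0, -1.0, -2.0),
            extent=(2.0, 2.0, 4.0),
            cell_spacing=1.0,
            subsites_per_cell=(2, 2, 2),
            n_orientations=3,
        )

    def host_frames(self, trp_structure, sigma=0.2, n=8, seed=2):
        traj = jittered_host_frames(trp_structure, sigma=sigma, n_frames=n, seed=seed)
        host = HostParams.uniform(len(trp_structure), epsilon=0.1, sigma=3.3, charge=0.05)
        host.charge[::2] = -0.05
        return traj, host

    def test_empty_host_gives_zero_map(self):
        frames = Trajectory(positions=np.zeros((2, 0, 3)))
        host = HostParams(epsilon=np.zeros(0), sigma=np.zeros(0), charge=np.zeros(0))
        grid = ils_map(frames, host, O2, self.small_spec())
        assert np.allclose(grid.values, 0.0, atol=1e-12)

    def test_single_frame_single_term_equals_direct_energy(self, trp_structure):
        spec = GridSpec(
            origin=(4.0, 2.0, 2.0),
            extent=(1.0, 1.0, 1.0),
            cell_spacing=1.0,
            subsites_per_cell=(1, 1, 1),
            n_orientations=1,
        )
        probe = one_site_probe()
        frames = Trajectory(positions=trp_structure.positions[None])
        host = HostParams.uniform(len(trp_structure), epsilon=0.15, sigma=3.2, charge=0.0)
        grid = ils_map(frames, host, probe, spec)
        e = probe_interaction_energy(
            trp_structure.positions, host, probe, position=np.array([4.5, 2.5, 2.5])
        )
        assert grid.values[0, 0, 0] == pytest.approx(e, abs=1e-12)

    def test_matches_naive_reimplementation(self, trp_structure):
        frames, host = self.host_frames(trp_structure)
        spec = self.small_spec()
        grid = ils_map(frames, host, O2, spec)
        expected = naive_ils_map(frames, host, O2, spec, 310.0)
        assert np.max(np.abs(grid.values - expected)) < 1e-10

    def test_translation_invariance(self, trp_structure):
        frames, host = self.host_frames(trp_structure, n=3)
        spec = self.small_spec()
        g1 = ils_map(frames, host, O2, spec)
        shift = np.array([7.3, -2.1, 4.9])
        frames2 = Trajectory(positions=frames.positions + shift)
        spec2 = GridSpec(
            origin=tuple(np.array(spec.origin) + shift),
            extent=spec.extent,
            cell_spacing=spec.cell_spacing,
            subsites_per_cell=spec.subsites_per_cell,
            n_orientations=spec.n_orientations,
        )
        g2 = ils_map(frames2, host, O2, spec2)
        assert np.max(np.abs(g1.values - g2.values)) < 1e-10

    def test_polar_probe_warns(self, trp_structure, caplog):
        frames, host = self.host_frames(trp_structure, n=1)
        with caplog.at_level("WARNING"):
            ils_map(frames, host, CO2, self.small_spec())
        assert any("polar" in r.message for r in caplog.records)

    def test_segment_maps_kept(self, trp_structure):
        frames, host = self.host_frames(trp_structure, n=8)
        grid = ils_map(frames, host, O2, self.small_spec(), n_segments=4)
        assert grid.segments.shape == (4, *grid.spec.shape)


class TestBulkReferenceAndProjection:
    def grid_of(self, values):
        values = np.asarray(values, dtype=float)
        spec = GridSpec(
            origin=(0.0, 0.0, 0.0),
            extent=tuple(np.array(values.shape) * 1.0),
            cell_spacing=1.0,
        )
        return FreeEnergyGrid(spec=spec, values=values)

    def test_zero_bulk_gives_zero_reference(self):
        g = self.grid_of(np.zeros((3, 3, 4)))
        ref = bulk_reference(g, ((0, 3), (0, 3), (0, 4)))
        assert ref == pytest.approx(0.0, abs=1e-12)

    def test_constant_bulk_gives_that_constant(self):
        g = self.grid_of(np.full((3, 3, 4), 1.7))
        ref = bulk_reference(g, ((0, 3), (0, 3), (0, 4)))
        assert ref == pytest.approx(1.7)

    def test_empty_bulk_region_errors(self):
        g = self.grid_of(np.zeros((3, 3, 4)))
        with pytest.raises(ValueError, match="no grid cells"):
            bulk_reference(g, ((50, 60), (0, 3), (0, 4)))

    def test_rereferencing_bulk_returns_zero_there(self):
        rng = np.random.default_rng(0)
        g = self.grid_of(rng.normal(1.0, 0.3, size=(4, 4, 6)))
        box = ((0, 4), (0, 4), (4, 6))
        g2 = reference_grid(g, box)
        assert bulk_reference(g2, box) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_grid_projects_to_constant(self):
        g = self.grid_of(np.full((5, 5, 4), 2.5))
        prof = project_profile(g, axis_radius=2.0)
        assert np.allclose(prof.values, 2.5)

    def test_one_deep_cell_dominates_boltzmann_mean(self):
        v = np.full((5, 5, 1), 20.0)
        v[2, 2, 0] = -5.0
        g = self.grid_of(v)
        prof = project_profile(g, axis_radius=10.0)
        # closed form: -RT ln[(e^{5/RT} + 24 e^{-20/RT})/25] ~ -5 + RT ln 25
        rt = RT()
        expected = -rt * np.log((np.exp(5 / rt) + 24 * np.exp(-20 / rt)) / 25)
        assert prof.values[0] == pytest.approx(expected, abs=1e-9)
        assert prof.values[0] == pytest.approx(-5.0 + rt * np.log(25), abs=1e-6)

    def test_axis_radius_smaller_than_cell_errors(self):
        g = self.grid_of(np.zeros((4, 4, 2)))
        with pytest.raises(ValueError, match="axis_radius"):
            project_profile(g, axis_radius=0.2, axis_center=(0.0, 0.0))

    def test_min_mode_takes_layer_minimum(self):
        v = np.full((3, 3, 2), 4.0)
        v[1, 1, 1] = -1.0
        g = self.grid_of(v)
        prof = project_profile(g, axis_radius=5.0, mode="min")
        assert prof.values[1] == pytest.approx(-1.0)

    def test_field_map_matches_potential_bin_average(self):
        pot = gaussian_barrier(3.0, width=1.5, z_range=(-10.0, 10.0), k_radial=0.0, lateral_extent=4.0)
        spec = GridSpec(
            origin=(-1.0, -1.0, -10.0), extent=(2.0, 2.0, 20.0), cell_spacing=0.5
        )
        grid = field_map(pot, spec)
        # center column cell at z in [-0.5, 0): Boltzmann average of U over subsites
        rt = RT()
        zs = grid.spec.axis_centers(2)
        i0 = np.argmin(np.abs(zs - 0.25))
        sub = spec.subsite_offsets()[:, 2] + zs[i0]
        expected = -rt * np.log(np.mean(np.exp(-pot.u_z(sub) / rt)))
        assert grid.values[1, 1, i0] == pytest.approx(expected, abs=1e-10)


class TestSegmentStatistics:
    def test_identical_segments_zero_sd(self):
        segs = np.stack([np.full((2, 2), 1.5)] * 4)
        mean, sd = segment_statistics(segs)
        assert np.allclose(mean, 1.5) and np.allclose(sd, 0.0)

    def test_two_segments_closed_form(self):
        mean, sd = segment_statistics(np.array([[1.0], [3.0]]))
        assert mean[0] == pytest.approx(2.0)
        assert sd[0] == pytest.approx(np.sqrt(2.0))

    def test_single_segment_sd_missing(self):
        mean, sd = segment_statistics(np.array([[1.0, 2.0]]))
        assert sd is None

    def test_eight_noise_segments_recover_sigma(self):
        rng = np.random.default_rng(12)
        segs = rng.normal(0.0, 1.0, size=(8, 500))
        _, sd = segment_statistics(segs)
        assert np.mean(sd) == pytest.approx(1.0, rel=0.25)
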