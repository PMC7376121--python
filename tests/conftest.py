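"""Shared fixtures: synthetic geometries, traces and generated PDB files."""

import numpy as np
import pytest

import pentaspin as ps


def format_pdb_atom(serial, name, resname, chain, resnum, xyz, occupancy=1.0, altloc=" ",
                    element=None):
    """One ATOM record (coordinates in Å)."""
    element = element or name[0]
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}  0.00          {element:>2s}"
    )


def write_pdb(path, records):
    path.write_text("\n".join(records) + "\nEND\n")


def make_residue_records(chain, resnum, origin_a, serial0=1, resname="CYS"):
    """N/CA/CB backbone stub at ``origin_a`` (Å), CB 1.5 Å along +x."""
    o = np.asarray(origin_a, dtype=float)
    return [
        format_pdb_atom(serial0, "N", resname, chain, resnum, o + [0.0, 1.4, 0.0]),
        format_pdb_atom(serial0 + 1, "CA", resname, chain, resnum, o),
        format_pdb_atom(serial0 + 2, "CB", resname, chain, resnum, o + [1.5, 0.0, 0.0]),
    ]


@pytest.fixture
def pentamer_geometry():
    return ps.make_cn_geometry(5, 2.2)


@pytest.fixture
def pentamer_truth(pentamer_geometry):
    r_grid = ps.deer.default_r_grid()
    return ps.geometry_to_distribution(pentamer_geometry, r_grid, width_sd=0.08)


@pytest.fixture
def noiseless_deer_trace(pentamer_truth):
    params = ps.DeerParameters(
        mod_depth=0.3, bg_rate=0.15, noise_sd=0.0, time_axis=np.arange(0, 3.0, 0.012)
    )
    return ps.simulate_deer(pentamer_truth, params, seed=0)


@pytest.fixture
def eseem_factory():
    """Factory for 3pESEEM traces with 2H + 1H couplings at X-band."""
    freq, g = 9.5, 2.006
    nu_h = ps.larmor_frequency("1H", freq, g)
    nu_d = ps.larmor_frequency("2H", freq, g)
    tau_blind = ps.blind_spot_tau(freq, g)

    def make(k2h=0.3, k1h=0.3, tau=None, noise_sd=0.01, seed=0):
        params = ps.EseemParameters(
            tau=tau_blind if tau is None else tau,
            couplings=[
                ps.NuclearCoupling("2H", k2h, nu_d),
                ps.NuclearCoupling("1H", k1h, nu_h),
            ],
            noise_sd=noise_sd,
            freq_GHz=freq,
            g_value=g,
        )
        return ps.simulate_3peseem(params, seed=seed)

    make.nu_h = nu_h
    make.nu_d = nu_d
    make.tau_blind = tau_blind
    return make


@pytest.fixture
def mini_pdb(tmp_path):
    """Three isolated residues on one chain, far apart."""
    records = []
    for i, x in enumerate((0.0, 30.0, 60.0)):
        records += make_residue_records("A", i + 1, [x, 0.0, 0.0], serial0=3 * i + 1)
    path = tmp_path / "mini.pdb"
    write_pdb(path, records)
    return path


@pytest.fixture
def pentamer_pdb(tmp_path):
    """Five chains, one residue each, CA/CB on a C5 ring of radius 22 Å."""
    records = []
    serial = 1
    for i, chain in enumerate("ABCDE"):
        ang = 2 * np.pi * i / 5
        origin = 22.0 * np.array([np.cos(ang), np.sin(ang), 0.0])
        records += make_residue_records(chain, 10, origin, serial0=serial)
        serial += 3
    path = tmp_path / "pentamer.pdb"
    write_pdb(path, records)
    return path
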