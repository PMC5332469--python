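import numpy as np
import pandas as pd
import pytest

import lipidshell as ls
from lipidshell.core_io import TOPOLOGY_COLUMNS, TopologyTable, Trajectory


def make_topology(rows):
    return TopologyTable(pd.DataFrame(rows, columns=TOPOLOGY_COLUMNS))


def point_atoms(n, role="headgroup_other", element="C", charge=0.0,
                sigma=0.3, eps=0.1, residue_start=1):
    """n single-atom residues of one role, for constructed configurations."""
    return make_topology(
        [[i, "X", residue_start + i, "TST", element, role, "", -1, charge, sigma, eps]
         for i in range(n)]
    )


@pytest.fixture(scope="session")
def flat_bilayer():
    """Noise-free flat bilayer: exact thickness / S_CD test bed."""
    spec = ls.SyntheticBilayerSpec(
        n_lipids_per_leaflet=36, n_frames=2, seed=1,
        positional_noise_sigma=0.0, site_jitter_sigma=0.0, chain_order_s=1.0,
    )
    traj, topo, gt = ls.generate_bilayer(spec)
    return traj, topo, gt


@pytest.fixture(scope="session")
def noisy_bilayer():
    """Fluid bilayer with positional noise, 200 frames."""
    spec = ls.SyntheticBilayerSpec(
        n_lipids_per_leaflet=64, n_frames=200, seed=2,
        positional_noise_sigma=0.05,
    )
    traj, topo, gt = ls.generate_bilayer(spec)
    return traj, topo, gt


@pytest.fixture(scope="session")
def inclusion_system():
    """Static C4 inclusion, no enhancement: annular-null test bed."""
    spec = ls.SyntheticBilayerSpec(
        n_lipids_per_leaflet=64, n_frames=20, seed=3,
        inclusion=ls.InclusionSpec(radius=1.2, static=True),
    )
    return ls.generate_inclusion_system(spec)
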