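"""Shared fixtures and independent oracles.

The brute-force superposition oracle deliberately goes through
scipy's rotation machinery and a generic multi-start minimiser — a route
entirely independent of the quaternion-eigenvalue implementation it
checks.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ncsx.harness import SyntheticSpec, generate_synthetic_multimer, _mixed_coil_subunit
from ncsx.model_io import AtomRecord, CaFragment, PartialModel, Residue


def brute_force_min_rmsd(moving, fixed, n_starts: int = 12, seed: int = 0) -> float:
    """Global minimum r.m.s.d. by multi-start search over rotation vectors.

    The optimal translation for any rotation matches the centroids, so the
    search space is the 3-parameter rotation vector; several random starts
    plus local refinement find the global optimum for small point sets.
    """
    mov = np.asarray(moving, float)
    fix = np.asarray(fixed, float)
    x = mov - mov.mean(axis=0)
    y = fix - fix.mean(axis=0)
    n = len(x)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = x @ R.T - y
        return np.sqrt(np.sum(d * d) / n)

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(3)]
    for _ in range(n_starts):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        starts.append(axis * rng.uniform(0, np.pi))
    for s in starts:
        res = minimize(cost, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, res.fun)
    return float(best)


def coil(n: int, seed: int = 0) -> np.ndarray:
    """Protein-like random-coil Ca trace."""
    return _mixed_coil_subunit(n, np.random.default_rng(seed))


def make_fragment(coords, fragment_id: int = 0, chain_id: str = "A",
                  start_index: int = 1, docked: bool = True) -> CaFragment:
    """Ca-only fragment from an (n, 3) coordinate array."""
    residues = []
    for i, ca in enumerate(np.asarray(coords, float)):
        idx = start_index + i
        atom = AtomRecord(chain_id, idx, "ALA", "CA", ca, True)
        residues.append(Residue(idx, "ALA", ca, [atom]))
    return CaFragment(fragment_id, chain_id, residues, docked_to_sequence=docked)


def make_model(*fragments, **kwargs) -> PartialModel:
    return PartialModel(fragments=list(fragments), **kwargs)


@pytest.fixture(scope="session")
def pentamer():
    """Noise-free proper 5-mer, 69 residues per subunit, with truth operators."""
    return generate_synthetic_multimer(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def pentamer_model(pentamer):
    return pentamer[0]
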