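"""Generators with the statistical structure the analysis assumes.

Two kinds of ground-truth inputs:

* abstract field matrices whose response is a planted linear function of a
  small set of signal columns plus Gaussian noise, for recovery tests of
  the regression/cross-validation stack;
* toy congeneric 3D series built from a scaffold and a substituent set of
  known nominal bulk, whose activity is a pure function of that bulk, for
  end-to-end pipeline recovery tests.

Every generator is a pure function of its seed and parameters
(``numpy.random.default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .conformer_alignment import Molecule3D, assign_gasteiger_charges, embed_3d
from .qsar_pls import PLSError, loo_cross_validate

__all__ = [
    "SyntheticFieldDataset",
    "SyntheticSeriesSpec",
    "DEFAULT_SCAFFOLD",
    "DEFAULT_SUBSTITUENTS",
    "simulate_field_dataset",
    "simulate_congeneric_series",
    "permutation_null",
]

#: dihydropyrazole scaffold with one open para position ([*:1]) on the
#: C5 aryl ring; matches the pipeline's default core pattern.
DEFAULT_SCAFFOLD = "CC(=O)N1N=C(c2ccccc2)CC1c1ccc([*:1])cc1"

#: substituent SMILES -> nominal bulk volume in A^3 (documented constants,
#: not computed volumes: keeps the planted ground truth exact)
DEFAULT_SUBSTITUENTS: dict[str, float] = {
    "[H]": 5.0,
    "F": 9.0,
    "Cl": 20.0,
    "Br": 26.0,
    "C": 24.0,
    "CC": 41.0,
    "CCC": 58.0,
    "C(C)C": 58.0,
    "C(C)(C)C": 75.0,
    "OC": 31.0,
}


@dataclass
class SyntheticFieldDataset:
    X: np.ndarray
    y: np.ndarray
    signal_columns: np.ndarray
    true_coefficients: np.ndarray
    noise_sd: float
    seed: int


@dataclass
class SyntheticSeriesSpec:
    scaffold: str = DEFAULT_SCAFFOLD
    substituents: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SUBSTITUENTS))
    slope: float = 0.02  # activity units per A^3
    intercept: float = -1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.substituents) < 6:
            raise ValueError("need at least 6 substituents")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")


def simulate_field_dataset(
    n: int,
    p: int,
    k_signal: int,
    beta: float,
    noise_sd: float,
    seed: int,
) -> SyntheticFieldDataset:
    """Energy-like matrix with ``k_signal`` columns carrying coefficient beta."""
    if n < 8:
        raise ValueError("need n >= 8 rows")
    if not 1 <= k_signal <= p:
        raise ValueError("need p >= k_signal >= 1")
    rng = np.random.default_rng(seed)
    # columns with heterogeneous, energy-like spread (a few kcal/mol wide);
    # signal columns sit in the high-variance stratum, mirroring the lattice
    # region where a congeneric series actually varies
    col_sd = rng.uniform(1.0, 8.0, size=p)
    signal = rng.choice(p, size=k_signal, replace=False)
    col_sd[signal] = rng.uniform(6.0, 8.0, size=k_signal)
    X = rng.normal(0.0, 1.0, size=(n, p)) * col_sd
    coef = np.zeros(p)
    coef[signal] = beta
    y = X @ coef + rng.normal(0.0, noise_sd, size=n)
    return SyntheticFieldDataset(
        X=X,
        y=y,
        signal_columns=np.sort(signal),
        true_coefficients=coef,
        noise_sd=noise_sd,
        seed=seed,
    )


def _attach(scaffold: str, substituent: str) -> str:
    """Replace the [*:1] attachment point with a substituent fragment."""
    mol = Chem.MolFromSmiles(scaffold)
    if mol is None:
        raise ValueError(f"invalid scaffold {scaffold!r}")
    if substituent == "[H]":
        frag_smiles = scaffold.replace("([*:1])", "").replace("[*:1]", "[H]")
        out = Chem.MolFromSmiles(frag_smiles)
    else:
        frag = Chem.MolFromSmiles(f"[*:2]{substituent}")
        if frag is None:
            raise ValueError(f"unattachable substituent {substituent!r}")
        # join at the dummy atoms: bond the two attachment neighbours,
        # then drop both dummies
        combo = Chem.RWMol(Chem.CombineMols(mol, frag))
        dummies = [a.GetIdx() for a in combo.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 2:
            raise ValueError(f"unattachable substituent {substituent!r}")
        nbrs = [combo.GetAtomWithIdx(d).GetNeighbors()[0].GetIdx() for d in dummies]
        combo.AddBond(nbrs[0], nbrs[1], Chem.BondType.SINGLE)
        for d in sorted(dummies, reverse=True):
            combo.RemoveAtom(d)
        out = combo.GetMol()
        Chem.SanitizeMol(out)
    if out is None:
        raise ValueError(f"unattachable substituent {substituent!r}")
    return Chem.MolToSmiles(out)


def simulate_congeneric_series(
    spec: SyntheticSeriesSpec,
) -> tuple[list[Molecule3D], np.ndarray]:
    """One embedded, charged molecule per substituent plus planted activities."""
    rng = np.random.default_rng(spec.seed)
    molecules: list[Molecule3D] = []
    activities = []
    for idx, (sub, volume) in enumerate(sorted(spec.substituents.items())):
        smiles = _attach(spec.scaffold, sub)
        mol = embed_3d(smiles, seed=spec.seed, compound_id=f"S{idx + 1}")
        molecules.append(assign_gasteiger_charges(mol))
        activities.append(
            spec.intercept + spec.slope * volume + rng.normal(0.0, spec.noise_sd)
        )
    return molecules, np.array(activities)


def permutation_null(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int,
    seed: int,
    n_components: int = 2,
) -> np.ndarray:
    """LOO q2 distribution under seeded permutations of the response."""
    if n_perm < 10:
        raise ValueError("need n_perm >= 10")
    y = np.asarray(y, dtype=float).ravel()
    if np.var(y) == 0:
        raise PLSError("zero-variance response")
    rng = np.random.default_rng(seed)
    q2 = np.empty(n_perm)
    for i in range(n_perm):
        q2[i] = loo_cross_validate(X, rng.permutation(y), n_components).q2
    return q2
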