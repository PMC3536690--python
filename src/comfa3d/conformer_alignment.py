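"""3D embedding, charge assignment and rigid core-based superposition.

One seeded, force-field-relaxed conformer per molecule replaces ensemble
conformational analysis: determinism is a contract here (identical SMILES +
seed give identical coordinates). Molecules are superposed on a reference
compound by a proper-rotation least-squares fit (Kabsch) of a shared
dihydropyrazole core.

Pharmacophore feature perception is a deliberately small rule set:

* HBA        - N or O bearing no hydrogen, non-positive formal charge,
               excluding nitrogens whose lone pair is delocalized into an
               adjacent C=O / C=S (amide- and thioamide-type N);
* HYDROPHOBE - centroid of each connected cluster of non-polar aliphatic
               carbons and halogens (clusters are merged when closer than
               3.0 A in space), and the centroid of each all-carbon
               aromatic ring;
* AROMATIC_RING - centroid of every aromatic ring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .compound_library import FormulaParseError
from .params import vdw_for

__all__ = [
    "Molecule3D",
    "CoreMatch",
    "Feature",
    "PharmacophoreHypothesis",
    "DEFAULT_CORE_SMARTS",
    "EmbeddingError",
    "CoreMatchError",
    "DegenerateGeometryError",
    "embed_3d",
    "assign_gasteiger_charges",
    "find_core",
    "kabsch_superpose",
    "align_series",
    "perceive_features",
    "map_to_hypothesis",
    "build_hypothesis",
    "molecules_to_sdf",
]

#: 4,5-dihydro-1H-pyrazole ring + C3/C5 aryl attachment atoms + N1 exocyclic
#: carbon; 8 atoms in query order (exoC, N1, N2, C3, Ar3-c, C4, C5, Ar5-c).
DEFAULT_CORE_SMARTS = "[#6][N]1[N]=[C](-[c])[CH2][CH]1-[c]"

HBA = "HBA"
HYDROPHOBE = "HYDROPHOBE"
AROMATIC_RING = "AROMATIC_RING"

_HALOGENS = {"F", "Cl", "Br", "I"}
_HYDROPHOBE_MERGE_DISTANCE = 3.0  # A


class EmbeddingError(RuntimeError):
    pass


class CoreMatchError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class Molecule3D:
    """Embedded, charged, force-field-parameterized 3D structure."""

    compound_id: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) in A
    bonds: list[tuple[int, int, float]]
    embed_seed: int
    charges: np.ndarray | None = None  # partial charges, e
    vdw_radius: np.ndarray | None = None  # A
    well_depth: np.ndarray | None = None  # kcal/mol
    core_rmsd: float | None = None
    rdkit_mol: Chem.Mol = field(default=None, repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def with_coords(self, coords: np.ndarray, **extra) -> "Molecule3D":
        return replace(self, coords=np.asarray(coords, dtype=float), **extra)


def _mol_to_molecule3d(mol: Chem.Mol, compound_id: str, seed: int) -> Molecule3D:
    conf = mol.GetConformer()
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array(conf.GetPositions(), dtype=float)
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    params = np.array([vdw_for(e) for e in elements])
    return Molecule3D(
        compound_id=compound_id,
        elements=elements,
        coords=coords,
        bonds=bonds,
        embed_seed=seed,
        vdw_radius=params[:, 0],
        well_depth=params[:, 1],
        rdkit_mol=mol,
    )


def embed_3d(smiles: str, seed: int, compound_id: str = "", max_attempts: int = 5) -> Molecule3D:
    """Seeded distance-geometry embedding followed by MMFF relaxation."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormulaParseError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    ok = -1
    for attempt in range(max_attempts):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + attempt
        ok = AllChem.EmbedMolecule(mol, params)
        if ok == 0:
            break
    if ok != 0:
        raise EmbeddingError(
            f"embedding failed for compound {compound_id or smiles!r} "
            f"after {max_attempts} attempts"
        )
    if AllChem.MMFFHasAllMoleculeParams(mol):
        AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    else:  # pragma: no cover - packaged series is fully MMFF-typed
        AllChem.UFFOptimizeMolecule(mol, maxIters=2000)
    out = _mol_to_molecule3d(mol, compound_id, int(seed))
    _check_bond_lengths(out)
    return out


def _check_bond_lengths(mol: Molecule3D) -> None:
    for i, j, _ in mol.bonds:
        d = float(np.linalg.norm(mol.coords[i] - mol.coords[j]))
        if not 0.7 <= d <= 2.2:
            raise EmbeddingError(
                f"bond {i}-{j} of {mol.compound_id!r} has unphysical length {d:.3f} A"
            )


def assign_gasteiger_charges(mol: Molecule3D) -> Molecule3D:
    """Populate iterative partial-equalization (Gasteiger) charges."""
    rd = Chem.Mol(mol.rdkit_mol)
    Chem.rdPartialCharges.ComputeGasteigerCharges(rd, throwOnParamFailure=True)
    charges = np.array(
        [a.GetDoubleProp("_GasteigerCharge") for a in rd.GetAtoms()], dtype=float
    )
    if not np.all(np.isfinite(charges)):
        raise ValueError(f"non-finite Gasteiger charges for {mol.compound_id!r}")
    formal = float(sum(a.GetFormalCharge() for a in rd.GetAtoms()))
    if abs(charges.sum() - formal) > 1e-3:
        raise ValueError(
            f"Gasteiger charges of {mol.compound_id!r} sum to {charges.sum():.5f}, "
            f"expected {formal:.1f}"
        )
    return replace(mol, charges=charges, rdkit_mol=rd)


@dataclass(frozen=True)
class CoreMatch:
    """Ordered atom-index pairs (mobile_i, template_i) for a shared core."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 3:
            raise CoreMatchError("core match needs at least 3 atom pairs")
        mob = [p[0] for p in self.pairs]
        tem = [p[1] for p in self.pairs]
        if len(set(mob)) != len(mob) or len(set(tem)) != len(tem):
            raise CoreMatchError("core match indices must be unique")

    @property
    def mobile_indices(self) -> list[int]:
        return [p[0] for p in self.pairs]

    @property
    def template_indices(self) -> list[int]:
        return [p[1] for p in self.pairs]


def find_core(mol: Molecule3D, core_pattern: str | Molecule3D = DEFAULT_CORE_SMARTS) -> CoreMatch:
    """Match a core pattern; deterministic lowest-index tie-break.

    ``core_pattern`` may be a SMARTS expression or another
    :class:`Molecule3D` used as a literal query (matching a molecule
    against itself yields the identity mapping).
    """
    if isinstance(core_pattern, Molecule3D):
        query = Chem.RemoveHs(Chem.Mol(core_pattern.rdkit_mol))
    else:
        query = Chem.MolFromSmarts(core_pattern)
        if query is None:
            raise CoreMatchError(f"core pattern does not compile: {core_pattern!r}")
    matches = mol.rdkit_mol.GetSubstructMatches(query, uniquify=True, maxMatches=256)
    if not matches:
        raise CoreMatchError(f"core absent in {mol.compound_id or 'molecule'!r}")
    best = min(matches)
    return CoreMatch(pairs=tuple((mol_i, q_i) for q_i, mol_i in enumerate(best)))


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal proper rotation R and translation t.

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` mapping mobile points onto
    the target frame; reflections are disallowed (det(R) = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DegenerateGeometryError("point sets must share shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    a, b = mobile - mc, target - tc
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise DegenerateGeometryError("collinear point set")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tc - rot @ mc
    rmsd = float(np.sqrt(np.mean(np.sum(((mobile @ rot.T + trans) - target) ** 2, axis=1))))
    return rot, trans, rmsd


def align_series(
    compounds: list[Molecule3D],
    template_id: str = "D5",
    core_pattern: str = DEFAULT_CORE_SMARTS,
) -> list[Molecule3D]:
    """Rigid-transform every molecule so its core best fits the template core."""
    by_id = {m.compound_id: m for m in compounds}
    if template_id not in by_id:
        raise CoreMatchError(f"template {template_id!r} not in series")
    template = by_id[template_id]
    t_core = find_core(template, core_pattern)
    t_points = template.coords[t_core.mobile_indices]

    failures = []
    aligned: list[Molecule3D] = []
    for mol in compounds:
        if mol.compound_id == template_id:
            aligned.append(mol.with_coords(mol.coords, core_rmsd=0.0))
            continue
        try:
            m_core = find_core(mol, core_pattern)
        except CoreMatchError:
            failures.append(mol.compound_id)
            continue
        rot, trans, rmsd = kabsch_superpose(mol.coords[m_core.mobile_indices], t_points)
        aligned.append(mol.with_coords(mol.coords @ rot.T + trans, core_rmsd=rmsd))
    if failures:
        raise CoreMatchError(f"core absent in compounds: {failures}")
    return aligned


@dataclass(frozen=True)
class Feature:
    kind: str
    center: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.array(self.center)


@dataclass(frozen=True)
class PharmacophoreHypothesis:
    """Fixed feature arrangement to map molecules against."""

    features: tuple[tuple[str, tuple[float, float, float], float], ...]

    def __post_init__(self) -> None:
        if any(tol <= 0 for _, _, tol in self.features):
            raise ValueError("feature tolerance must be positive")


def _is_hba(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() not in ("N", "O"):
        return False
    if atom.GetTotalNumHs() > 0 or atom.GetFormalCharge() > 0:
        return False
    if atom.GetSymbol() == "N":
        # exclude amide/thioamide-type N (lone pair delocalized into C=O/C=S)
        for nbr in atom.GetNeighbors():
            if nbr.GetSymbol() == "C":
                for bond in nbr.GetBonds():
                    other = bond.GetOtherAtom(nbr)
                    if (
                        bond.GetBondTypeAsDouble() == 2.0
                        and other.GetIdx() != atom.GetIdx()
                        and other.GetSymbol() in ("O", "S")
                    ):
                        return False
    return True


def _hydrophobic_atoms(mol: Chem.Mol) -> list[int]:
    out = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in _HALOGENS:
            out.append(atom.GetIdx())
        elif sym == "C" and not atom.GetIsAromatic() and atom.GetTotalDegree() == 4:
            nbrs = {n.GetSymbol() for n in atom.GetNeighbors()}
            if nbrs <= ({"C", "H"} | _HALOGENS):
                out.append(atom.GetIdx())
    return out


def perceive_features(mol: Molecule3D) -> list[Feature]:
    """Perceive HBA / HYDROPHOBE / AROMATIC_RING features (order-independent)."""
    rd = mol.rdkit_mol
    coords = mol.coords
    feats: list[Feature] = []

    for atom in rd.GetAtoms():
        if _is_hba(atom):
            feats.append(Feature(HBA, tuple(coords[atom.GetIdx()])))

    ring_info = rd.GetRingInfo()
    for ring in ring_info.AtomRings():
        atoms = [rd.GetAtomWithIdx(i) for i in ring]
        if all(a.GetIsAromatic() for a in atoms):
            center = tuple(coords[list(ring)].mean(axis=0))
            feats.append(Feature(AROMATIC_RING, center))
            if all(a.GetSymbol() == "C" for a in atoms):
                feats.append(Feature(HYDROPHOBE, center))

    hydro = _hydrophobic_atoms(rd)
    if hydro:
        # single-linkage clusters: bonded or within the merge distance
        parent = {i: i for i in hydro}

        def root(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(hydro, 2):
            bonded = rd.GetBondBetweenAtoms(i, j) is not None
            if bonded or np.linalg.norm(coords[i] - coords[j]) <= _HYDROPHOBE_MERGE_DISTANCE:
                parent[root(i)] = root(j)
        clusters: dict[int, list[int]] = {}
        for i in hydro:
            clusters.setdefault(root(i), []).append(i)
        for members in clusters.values():
            # a cluster must be a proper substituent: at least one member
            # bonded to a heavy atom outside the cluster (methane-like
            # whole-molecule clusters carry no positional information)
            member_set = set(members)
            attached = any(
                nbr.GetAtomicNum() > 1 and nbr.GetIdx() not in member_set
                for i in members
                for nbr in rd.GetAtomWithIdx(i).GetNeighbors()
            )
            if attached:
                feats.append(Feature(HYDROPHOBE, tuple(coords[members].mean(axis=0))))

    return sorted(feats, key=lambda f: (f.kind, tuple(np.round(f.center, 6))))


def _hydrophobe_cluster_sizes(mol: Molecule3D) -> dict[tuple[float, ...], int]:
    """Feature center -> cluster weight, for hypothesis ranking."""
    rd = mol.rdkit_mol
    coords = mol.coords
    sizes: dict[tuple[float, ...], int] = {}
    for ring in rd.GetRingInfo().AtomRings():
        atoms = [rd.GetAtomWithIdx(i) for i in ring]
        if all(a.GetIsAromatic() and a.GetSymbol() == "C" for a in atoms):
            sizes[tuple(np.round(coords[list(ring)].mean(axis=0), 6))] = len(ring)
    hydro = _hydrophobic_atoms(rd)
    feats = [f for f in perceive_features(mol) if f.kind == HYDROPHOBE]
    for f in feats:
        key = tuple(np.round(f.center, 6))
        if key not in sizes:
            members = [
                i for i in hydro if np.linalg.norm(coords[i] - f.xyz) <= _HYDROPHOBE_MERGE_DISTANCE
            ]
            sizes[key] = max(len(members), 1)
    return sizes


def build_hypothesis(reference: Molecule3D, tolerance: float = 1.6) -> PharmacophoreHypothesis:
    """Derive the packaged 2-HBA + 3-HYDROPHOBE hypothesis from a reference.

    The three hydrophobes retained are the largest perceived clusters
    (ties broken by coordinates, for reproducibility).
    """
    feats = perceive_features(reference)
    hbas = [f for f in feats if f.kind == HBA]
    hydros = [f for f in feats if f.kind == HYDROPHOBE]
    if len(hbas) != 2:
        raise ValueError(f"reference yields {len(hbas)} HBA features, expected 2")
    sizes = _hydrophobe_cluster_sizes(reference)
    hydros.sort(key=lambda f: (-sizes.get(tuple(np.round(f.center, 6)), 1), f.center))
    if len(hydros) < 3:
        raise ValueError("reference yields fewer than 3 hydrophobic clusters")
    chosen = hbas + hydros[:3]
    return PharmacophoreHypothesis(
        features=tuple((f.kind, f.center, tolerance) for f in chosen)
    )


def map_to_hypothesis(
    features: list[Feature], hypothesis: PharmacophoreHypothesis
) -> tuple[list[tuple[int, int]], float] | None:
    """Optimal one-to-one assignment of kind-compatible features.

    Returns ``(pairs, fit_rmsd)`` with pairs of (hypothesis index, feature
    index), or ``None`` when some hypothesis feature cannot be matched
    within its tolerance. The search is an exact minimum over one-to-one
    assignments (feature counts are small).
    """
    if not hypothesis.features:
        raise ValueError("empty hypothesis")
    by_kind: dict[str, list[int]] = {}
    for idx, f in enumerate(features):
        by_kind.setdefault(f.kind, []).append(idx)

    groups: list[tuple[list[int], list[int]]] = []  # (hypothesis idxs, candidate idxs)
    for kind in sorted({k for k, _, _ in hypothesis.features}):
        h_idx = [i for i, (k, _, _) in enumerate(hypothesis.features) if k == kind]
        cands = by_kind.get(kind, [])
        if len(cands) < len(h_idx):
            return None
        groups.append((h_idx, cands))

    best: tuple[float, list[tuple[int, int]]] | None = None
    per_group_options = []
    for h_idx, cands in groups:
        options = []
        for combo in itertools.permutations(cands, len(h_idx)):
            sq = 0.0
            ok = True
            for hi, fi in zip(h_idx, combo):
                _, center, tol = hypothesis.features[hi]
                d = float(np.linalg.norm(features[fi].xyz - np.array(center)))
                if d > tol:
                    ok = False
                    break
                sq += d * d
            if ok:
                options.append((sq, list(zip(h_idx, combo))))
        if not options:
            return None
        per_group_options.append(options)

    for combo in itertools.product(*per_group_options):
        sq = sum(c[0] for c in combo)
        pairs = [p for c in combo for p in c[1]]
        if best is None or sq < best[0]:
            best = (sq, pairs)
    assert best is not None
    rmsd = float(np.sqrt(best[0] / len(hypothesis.features)))
    return sorted(best[1]), rmsd


def molecules_to_sdf(molecules: list[Molecule3D], path) -> None:
    """Write aligned structures as multi-record SDF (V2000) with metadata."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for mol in molecules:
            rd = Chem.Mol(mol.rdkit_mol)
            conf = rd.GetConformer()
            for i, xyz in enumerate(mol.coords):
                conf.SetAtomPosition(i, [float(v) for v in xyz])
            rd.SetProp("_Name", mol.compound_id)
            rd.SetProp("embed_seed", str(mol.embed_seed))
            if mol.core_rmsd is not None:
                rd.SetProp("core_rmsd", f"{mol.core_rmsd:.6f}")
            if mol.charges is not None:
                rd.SetProp("partial_charges", " ".join(f"{q:.6f}" for q in mol.charges))
            writer.write(rd)
    finally:
        writer.close()
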