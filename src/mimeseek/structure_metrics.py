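"""Geometry metrics for TCR-pHLA coordinate models.

Implements the comparisons used to characterise TCR-pHLA complexes:
least-squares superposition RMSD (Kabsch), Shrake-Rupley solvent
accessible surface area and the buried surface area derived from it,
typed interatomic contact lists, and the TCR crossing angle over the
HLA peptide-binding groove.

All distances are in Angstrom, areas in Angstrom^2, angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

#: Bondi-type van der Waals radii (Angstrom); hydrogens are excluded
#: because crystal structures generally lack them.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

#: Chain roles recognised by role-dependent operations.
ROLES = ("HLA", "B2M", "PEPTIDE", "TCRA", "TCRB")

#: Default HLA class I groove helix ranges (alpha1 and alpha2 helices),
#: residue numbering of the mature heavy chain.
DEFAULT_GROOVE_HELICES = ((50, 85), (138, 180))


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_seq, self.icode)


@dataclass
class StructureModel:
    """A parsed coordinate model: a flat atom list plus chain roles.

    ``entity_map`` assigns each chain a role from :data:`ROLES`; it must
    be populated (via :meth:`assign_roles`) before role-dependent
    operations such as BSA or the crossing angle.
    """

    atoms: list[Atom]
    entity_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("StructureModel requires at least one atom")
        coords = self.coords()
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in model")

    def coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        pool = self.atoms if atoms is None else atoms
        return np.array([[a.x, a.y, a.z] for a in pool], dtype=float)

    def assign_roles(self, mapping: dict[str, str]) -> None:
        for chain, role in mapping.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
        self.entity_map = dict(mapping)

    def chains_with_role(self, roles: Iterable[str]) -> set[str]:
        wanted = set(roles)
        return {c for c, r in self.entity_map.items() if r in wanted}

    def select(
        self,
        chains: Iterable[str] | None = None,
        residue_range: tuple[int, int] | None = None,
        atom_names: Iterable[str] | None = None,
        predicate: Callable[[Atom], bool] | None = None,
    ) -> list[Atom]:
        """Deterministic, ordered atom selection (file order preserved)."""
        chain_set = set(chains) if chains is not None else None
        name_set = set(atom_names) if atom_names is not None else None
        out = []
        for a in self.atoms:
            if chain_set is not None and a.chain not in chain_set:
                continue
            if residue_range is not None and not (
                residue_range[0] <= a.res_seq <= residue_range[1]
            ):
                continue
            if name_set is not None and a.atom_name not in name_set:
                continue
            if predicate is not None and not predicate(a):
                continue
            out.append(a)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with ``x' = R x + t`` applied to every atom."""
        new_atoms = []
        for a in self.atoms:
            p = rotation @ a.pos + translation
            new_atoms.append(
                Atom(a.chain, a.res_seq, a.icode, a.res_name, a.atom_name,
                     a.element, float(p[0]), float(p[1]), float(p[2]), a.occupancy)
            )
        return StructureModel(atoms=new_atoms, entity_map=dict(self.entity_map))


@dataclass(frozen=True)
class ContactRecord:
    atom_a: Atom
    atom_b: Atom
    distance: float
    kind: str  # "polar" | "nonpolar"


# ---------------------------------------------------------------------------
# Superposition

def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired coordinate sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ mobile[i] + translation`` best matches ``target[i]`` in
    the least-squares sense. The rotation is proper (reflections are
    corrected via the determinant sign of the SVD solution).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(
            f"coordinate count mismatch: {mobile.shape} vs {target.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 paired 3-D points")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    x, y = mobile - cm, target - ct
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ct - rotation @ cm
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rotation, translation, rmsd


def _pair_atoms(
    model_a: StructureModel,
    model_b: StructureModel,
    chains: Iterable[str] | None,
    residue_range: tuple[int, int] | None,
    mode: str,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str]]]:
    if mode not in ("ca", "all"):
        raise ValueError("mode must be 'ca' or 'all'")
    names = {"CA"} if mode == "ca" else None

    def index(model: StructureModel) -> dict:
        sel = model.select(chains=chains, residue_range=residue_range, atom_names=names)
        idx: dict[tuple, Atom] = {}
        for a in sel:
            if mode == "all" and a.element == "H":
                continue
            idx[(a.chain, a.res_seq, a.icode, a.atom_name)] = a
        return idx

    ia, ib = index(model_a), index(model_b)
    common = [k for k in ia if k in ib]
    dropped = sorted({(k[0], k[1], k[2]) for k in set(ia) ^ set(ib)})
    if not common:
        raise ValueError("no pairable atoms between models")
    xa = np.array([ia[k].pos for k in common])
    xb = np.array([ib[k].pos for k in common])
    return xa, xb, dropped


def rmsd_between(
    model_a: StructureModel,
    model_b: StructureModel,
    chains: Iterable[str] | None = None,
    residue_range: tuple[int, int] | None = None,
    mode: str = "ca",
) -> float:
    """Superposition RMSD between two models on pairable atoms.

    Atoms are paired by (chain, residue number, insertion code, atom
    name); unpairable atoms are dropped. ``mode='ca'`` restricts to
    C-alpha atoms, ``'all'`` uses all non-hydrogen atoms.
    """
    xa, xb, _ = _pair_atoms(model_a, model_b, chains, residue_range, mode)
    _, _, rmsd = kabsch_superpose(xa, xb)
    return rmsd


# ---------------------------------------------------------------------------
# Surface area

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    atoms: Sequence[Atom] | None = None,
) -> np.ndarray:
    """Per-atom solvent accessible surface area (Shrake-Rupley).

    Each atom's van der Waals sphere is inflated by the probe radius and
    sampled with a deterministic golden-spiral point set; points inside
    any neighbour's inflated sphere are buried. Hydrogens are skipped
    (area 0). Unknown heavy elements raise ``ValueError``.
    """
    radii = VDW_RADII if radii is None else radii
    pool = list(model.atoms if atoms is None else atoms)
    coords = np.array([[a.x, a.y, a.z] for a in pool])
    r = np.empty(len(pool))
    for i, a in enumerate(pool):
        if a.element == "H":
            r[i] = np.nan
            continue
        if a.element not in radii:
            raise ValueError(f"no van der Waals radius for element {a.element!r}")
        r[i] = radii[a.element] + probe
    heavy = ~np.isnan(r)
    sphere = _sphere_points(n_points)
    areas = np.zeros(len(pool))
    hidx = np.where(heavy)[0]
    hcoords = coords[hidx]
    hr = r[hidx]
    tree = cKDTree(hcoords)
    max_r = hr.max() if len(hr) else 0.0
    for j, i in enumerate(hidx):
        pts = hcoords[j] + hr[j] * sphere
        neigh = [k for k in tree.query_ball_point(hcoords[j], hr[j] + max_r) if k != j]
        accessible = np.ones(n_points, dtype=bool)
        for k in neigh:
            d2 = np.sum((pts - hcoords[k]) ** 2, axis=1)
            accessible &= d2 > hr[k] ** 2
        areas[i] = 4.0 * math.pi * hr[j] ** 2 * accessible.mean()
    return areas


def buried_surface_area(
    model: StructureModel,
    entity: str,
    partner_group: Iterable[str],
    context: Iterable[str] | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Buried surface area on ``entity`` due to ``partner_group`` chains.

    BSA(entity | partners) = SASA(entity in its context with the
    partners removed) - SASA(entity in the full complex). ``context``
    defaults to every assigned role except the partners, so a peptide is
    evaluated in its pHLA context by default.
    """
    partners = set(partner_group)
    if entity in partners:
        raise ValueError("entity role cannot also be a partner role")
    if context is None:
        context = set(model.entity_map.values()) - partners
    context = set(context) | {entity}
    if context & partners:
        raise ValueError("context and partner role sets overlap")

    entity_chains = model.chains_with_role([entity])
    if not entity_chains:
        raise ValueError(f"no chains with role {entity!r}")
    ctx_atoms = [a for a in model.atoms
                 if model.entity_map.get(a.chain) in context]
    full_atoms = [a for a in model.atoms
                  if model.entity_map.get(a.chain) in (context | partners)]

    def entity_total(pool: list[Atom]) -> float:
        sub = StructureModel(atoms=pool, entity_map=dict(model.entity_map))
        areas = shrake_rupley_sasa(sub, probe=probe, n_points=n_points)
        mask = np.array([a.chain in entity_chains for a in pool])
        return float(areas[mask].sum())

    return entity_total(ctx_atoms) - entity_total(full_atoms)


# ---------------------------------------------------------------------------
# Contacts

_POLAR_ELEMENTS = frozenset({"N", "O", "S"})


def find_contacts(
    model: StructureModel,
    group_a: Iterable[str],
    group_b: Iterable[str],
    polar_cutoff: float = 3.5,
    nonpolar_cutoff: float = 4.0,
) -> list[ContactRecord]:
    """Typed interatomic contacts between two disjoint role groups.

    All inter-group heavy-atom pairs within ``nonpolar_cutoff`` are
    reported; pairs where both atoms are N/O/S and the distance is
    within ``polar_cutoff`` are classified polar. Sorted by chain,
    residue, then distance.
    """
    ga, gb = set(group_a), set(group_b)
    if ga & gb:
        raise ValueError("contact groups must be disjoint")
    atoms_a = [a for a in model.atoms if model.entity_map.get(a.chain) in ga]
    atoms_b = [a for a in model.atoms if model.entity_map.get(a.chain) in gb]
    records: list[ContactRecord] = []
    if not atoms_a or not atoms_b:
        return records
    ca = np.array([[a.x, a.y, a.z] for a in atoms_a])
    cb = np.array([[a.x, a.y, a.z] for a in atoms_b])
    tree = cKDTree(cb)
    for i, a in enumerate(atoms_a):
        if a.element == "H":
            continue
        for j in tree.query_ball_point(ca[i], nonpolar_cutoff):
            b = atoms_b[j]
            if b.element == "H":
                continue
            dist = float(np.linalg.norm(ca[i] - cb[j]))
            if dist > nonpolar_cutoff:
                continue
            polar = (
                a.element in _POLAR_ELEMENTS
                and b.element in _POLAR_ELEMENTS
                and dist <= polar_cutoff
            )
            records.append(
                ContactRecord(a, b, dist, "polar" if polar else "nonpolar")
            )
    records.sort(
        key=lambda r: (r.atom_a.chain, r.atom_a.res_seq, r.atom_a.icode,
                       r.distance, r.atom_b.chain, r.atom_b.res_seq)
    )
    return records


# ---------------------------------------------------------------------------
# Crossing angle

def _cystine_midpoint(model: StructureModel, chain: str,
                      residue_pair: tuple[int, int]) -> np.ndarray:
    sg = []
    missing = []
    for res in residue_pair:
        hits = model.select(chains=[chain], residue_range=(res, res),
                            atom_names=["SG"])
        if not hits:
            missing.append(f"{chain}:{res}:SG")
        else:
            sg.append(hits[0].pos)
    if missing:
        raise ValueError(f"missing S-gamma atoms: {missing}")
    return (sg[0] + sg[1]) / 2.0


def crossing_angle(
    model: StructureModel,
    va_cystine: tuple[int, int],
    vb_cystine: tuple[int, int],
    groove_helices: Sequence[tuple[int, int]] = DEFAULT_GROOVE_HELICES,
) -> float:
    """TCR crossing angle over the HLA groove, in degrees.

    The TCR vector runs from the midpoint of the V-beta intradomain
    cystine S-gamma pair to the V-alpha cystine midpoint. The groove
    axis is the first principal axis of the C-alpha atoms of the HLA
    alpha1/alpha2 helix ranges, oriented along the peptide N-to-C
    direction. Returns the angle between the two vectors in [0, 180].
    """
    tcra = model.chains_with_role(["TCRA"])
    tcrb = model.chains_with_role(["TCRB"])
    hla = model.chains_with_role(["HLA"])
    pep = model.chains_with_role(["PEPTIDE"])
    if not (tcra and tcrb and hla and pep):
        raise ValueError("roles TCRA, TCRB, HLA and PEPTIDE must all be assigned")
    va_mid = _cystine_midpoint(model, next(iter(tcra)), va_cystine)
    vb_mid = _cystine_midpoint(model, next(iter(tcrb)), vb_cystine)
    tcr_vec = va_mid - vb_mid

    helix_ca = []
    for lo, hi in groove_helices:
        helix_ca.extend(
            model.select(chains=hla, residue_range=(lo, hi), atom_names=["CA"])
        )
    if len(helix_ca) < 3:
        raise ValueError("too few groove helix C-alpha atoms")
    coords = np.array([a.pos for a in helix_ca])
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]

    pep_ca = model.select(chains=pep, atom_names=["CA"])
    if len(pep_ca) < 2:
        raise ValueError("peptide needs >= 2 C-alpha atoms to orient the groove")
    n_to_c = pep_ca[-1].pos - pep_ca[0].pos
    if np.dot(axis, n_to_c) < 0:
        axis = -axis

    cosang = np.dot(tcr_vec, axis) / (np.linalg.norm(tcr_vec) * np.linalg.norm(axis))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
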