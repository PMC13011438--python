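"""Atomic physicochemical and topological descriptors.

Ten physicochemical slots and four topological slots per heavy atom.
Each physicochemical slot is filled by a named provider; the default
registry uses pure reference implementations for degree, valence, PEOE
charges/electronegativities, polarizabilities, VSEPR geometry, inductive
effect, and pi electronegativity, and an MMFF94-parameterized provider for
the partial-charge slot.  Any slot can be disabled, which removes exactly
that named column from the feature schema.

Reference forms
---------------
* PEOE: the Gasteiger–Marsili partial equalization of orbital
  electronegativities, chi(q) = a + b q + c q^2 with per-cycle damping 0.5
  over 6 cycles.  Implicit hydrogens participate as pseudo-atoms and their
  converged charges are folded into the parent heavy atom, so the reported
  per-heavy-atom charges sum exactly to the molecular formal charge.
* Hybrid polarizability: per-(element, hybridization) lookup of atomic
  hybrid polarizabilities (Å^3).
* Effective polarizability: the hybrid value plus distance-damped
  contributions of all topologically reachable atoms,
  alpha_eff(i) = sum_j 0.5^d(i,j) * alpha(j).
* Inductive effect: electronegativity-difference sum attenuated by the
  squared bond distance, iota(i) = sum_j (chi_j - chi_i) / d(i,j)^2,
  with implicit hydrogens contributing at distance 1 (Pauling scale).
* Pi electronegativity: per-element lookup for atoms engaged in a pi
  system (double/triple/aromatic bonds), 0 otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_core import Hybridization, MoleculeRecord, SomkitError, UNREACHABLE

log = logging.getLogger(__name__)

PHYSCHEM_SLOTS: tuple[str, ...] = (
    "atom_degree",
    "formal_valence",
    "hybrid_polarizability",
    "vsepr_geometry",
    "effective_polarizability",
    "inductive_effect",
    "peoe_sigma_charge",
    "peoe_sigma_electronegativity",
    "pi_electronegativity",
    "mmff94_charge",
)

TOPO_SLOTS: tuple[str, ...] = (
    "longest_max_top_dist_in_molecule",
    "highest_max_top_dist_in_row",
    "dist_difference",
    "dist_ratio",
)


class DescriptorError(SomkitError):
    pass


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

# Pauling electronegativities.
PAULING_EN: dict[str, float] = {
    "H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98, "Si": 1.90,
    "P": 2.19, "S": 2.58, "Cl": 3.16, "Br": 2.96, "I": 2.66,
}

# Atomic hybrid polarizabilities (Å^3), keyed by (element, hybridization
# class).  Values follow published atomic hybrid polarizability tables;
# the exact source table is a documented reference choice.
_HYBRID_POLARIZABILITY: dict[tuple[str, str], float] = {
    ("C", "sp"): 1.283, ("C", "sp2"): 1.352, ("C", "sp3"): 1.061,
    ("C", "ar"): 1.352,
    ("N", "sp"): 0.956, ("N", "sp2"): 1.030, ("N", "sp3"): 0.964,
    ("N", "ar"): 1.030,
    ("O", "sp2"): 0.569, ("O", "sp3"): 0.637, ("O", "ar"): 0.569,
    ("S", "sp2"): 3.000, ("S", "sp3"): 3.000, ("S", "ar"): 3.000,
    ("P", "sp3"): 1.538,
    ("F", "sp3"): 0.296, ("Cl", "sp3"): 2.315, ("Br", "sp3"): 3.013,
    ("I", "sp3"): 5.415,
    ("Si", "sp3"): 2.700,
    ("H", "sp3"): 0.387,
}

# Gasteiger–Marsili orbital electronegativity coefficients (a, b, c),
# chi(q) = a + b q + c q^2, by (element, hybridization class).
_PEOE_PARAMS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("H", "s"): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", "sp3"): (14.66, 13.85, 2.31),
    ("Cl", "sp3"): (11.00, 9.69, 1.35),
    ("Br", "sp3"): (10.08, 8.47, 1.16),
    ("I", "sp3"): (9.90, 7.96, 0.96),
    ("S", "sp3"): (10.14, 9.13, 1.38),
    ("S", "sp2"): (10.14, 9.13, 1.38),
    ("P", "sp3"): (8.90, 8.24, 0.96),
}

# Cation electronegativity of hydrogen, the special divisor of the
# original scheme.
_H_PLUS_EN = 20.02

# Pi-orbital electronegativity lookup (eV scale) for atoms in pi systems.
_PI_EN: dict[tuple[str, str], float] = {
    ("C", "pi"): 5.60, ("C", "pi2"): 7.00,
    ("N", "pi"): 7.95, ("N", "pi2"): 9.00,
    ("O", "pi"): 10.09,
    ("S", "pi"): 6.22,
}

# Valence electron counts for lone-pair estimation.
_VALENCE_ELECTRONS: dict[str, int] = {
    "H": 1, "C": 4, "Si": 4, "N": 5, "P": 5, "O": 6, "S": 6,
    "F": 7, "Cl": 7, "Br": 7, "I": 7,
}

#: VSEPR coordination geometry codes (stable across versions).
VSEPR_CODES = {
    "linear": 0,
    "trigonal_planar": 1,
    "bent": 2,
    "tetrahedral": 3,
    "trigonal_pyramidal": 4,
    "trigonal_bipyramidal": 5,
    "octahedral": 6,
    "other": 7,
}


# ---------------------------------------------------------------------------
# topological descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopoVector:
    longest_max_top_dist_in_molecule: int
    highest_max_top_dist_in_row: int
    dist_difference: int
    dist_ratio: float

    def as_tuple(self) -> tuple[int, int, int, float]:
        return (
            self.longest_max_top_dist_in_molecule,
            self.highest_max_top_dist_in_row,
            self.dist_difference,
            self.dist_ratio,
        )


def topo_descriptors(dm: np.ndarray, atom: int) -> TopoVector:
    """Four topological quantities for one atom.

    ``longest``: molecular diameter (max bond distance between any two
    atoms); ``row_max``: eccentricity of the atom; plus their difference
    and ratio.  A single-atom molecule yields (0, 0, 0, 1.0): its only atom
    trivially attains the molecular maximum.
    """
    finite = dm[dm < UNREACHABLE]
    longest = int(finite.max()) if finite.size else 0
    row = dm[atom]
    row_finite = row[row < UNREACHABLE]
    row_max = int(row_finite.max()) if row_finite.size else 0
    diff = longest - row_max
    ratio = (row_max / longest) if longest > 0 else 1.0
    return TopoVector(longest, row_max, diff, ratio)


# ---------------------------------------------------------------------------
# reference physicochemical implementations
# ---------------------------------------------------------------------------

def atom_degree(mol: MoleculeRecord, atom: int) -> int:
    """Number of heavy-atom neighbors."""
    return len(mol.neighbors(atom))


def formal_valence(mol: MoleculeRecord, atom: int) -> int:
    """Sum of Kekulé bond orders to all neighbors, implicit hydrogens included."""
    return sum(order for _, order, _ in mol.neighbors(atom)) + mol.atoms[atom].implicit_h_count


def _lone_pairs(mol: MoleculeRecord, atom: int) -> int:
    a = mol.atoms[atom]
    ve = _VALENCE_ELECTRONS.get(a.element)
    if ve is None:
        return 0
    return max(0, (ve - a.formal_charge - formal_valence(mol, atom)) // 2)


def vsepr_geometry(mol: MoleculeRecord, atom: int) -> int:
    """VSEPR coordination geometry as a stable small-integer code."""
    a = mol.atoms[atom]
    sigma = len(mol.neighbors(atom)) + a.implicit_h_count
    lp = _lone_pairs(mol, atom)
    steric = sigma + lp
    if steric <= 2:
        name = "linear"
    elif steric == 3:
        name = "trigonal_planar" if lp == 0 else "bent"
    elif steric == 4:
        name = {0: "tetrahedral", 1: "trigonal_pyramidal"}.get(lp, "bent")
    elif steric == 5:
        name = "trigonal_bipyramidal"
    elif steric == 6:
        name = "octahedral"
    else:
        name = "other"
    return VSEPR_CODES[name]


def _polar_key(element: str, hyb: Hybridization, aromatic: bool) -> tuple[str, str]:
    if aromatic:
        return (element, "ar")
    if hyb == Hybridization.SP:
        return (element, "sp")
    if hyb == Hybridization.SP2:
        return (element, "sp2")
    return (element, "sp3")


def hybrid_polarizability(mol: MoleculeRecord, atom: int) -> float:
    a = mol.atoms[atom]
    key = _polar_key(a.element, a.hybridization, a.aromatic)
    try:
        return _HYBRID_POLARIZABILITY[key]
    except KeyError:
        # fall back to the sp3 entry of the element before rejecting
        alt = (a.element, "sp3")
        if alt in _HYBRID_POLARIZABILITY:
            return _HYBRID_POLARIZABILITY[alt]
        raise DescriptorError(
            f"molecule {mol.mol_id}: no polarizability entry for {key}"
        )


def effective_polarizability(mol: MoleculeRecord, atom: int, decay: float = 0.5) -> float:
    """Hybrid polarizability plus distance-damped neighbor contributions.

    Implicit hydrogens contribute at one bond beyond their parent atom.
    """
    dm = mol.distances()
    total = 0.0
    for j in range(mol.n_atoms):
        d = dm[atom, j]
        if d >= UNREACHABLE:
            continue
        total += (decay ** int(d)) * hybrid_polarizability(mol, j)
        h = mol.atoms[j].implicit_h_count
        if h:
            total += (decay ** (int(d) + 1)) * h * _HYBRID_POLARIZABILITY[("H", "sp3")]
    return total


def polarizabilities(mol: MoleculeRecord, atom: int) -> tuple[float, float]:
    return hybrid_polarizability(mol, atom), effective_polarizability(mol, atom)


def inductive_effect(mol: MoleculeRecord, atom: int) -> float:
    a = mol.atoms[atom]
    chi_i = PAULING_EN.get(a.element)
    if chi_i is None:
        raise DescriptorError(f"molecule {mol.mol_id}: no electronegativity for {a.element}")
    dm = mol.distances()
    total = 0.0
    for j in range(mol.n_atoms):
        d = int(dm[atom, j])
        if j == atom or d >= UNREACHABLE:
            continue
        chi_j = PAULING_EN.get(mol.atoms[j].element)
        if chi_j is None:
            raise DescriptorError(
                f"molecule {mol.mol_id}: no electronegativity for {mol.atoms[j].element}"
            )
        total += (chi_j - chi_i) / (d * d)
        h = mol.atoms[j].implicit_h_count
        if h:
            total += h * (PAULING_EN["H"] - chi_i) / ((d + 1) * (d + 1))
    total += a.implicit_h_count * (PAULING_EN["H"] - chi_i)
    return total


def _has_pi_bond(mol: MoleculeRecord, atom: int) -> tuple[bool, bool]:
    """(any pi participation, triple-bond participation)."""
    a = mol.atoms[atom]
    triple = any(order == 3 for _, order, _ in mol.neighbors(atom))
    pi = a.aromatic or triple or any(order == 2 for _, order, _ in mol.neighbors(atom))
    return pi, triple


def pi_electronegativity(mol: MoleculeRecord, atom: int) -> float:
    """Pi-orbital electronegativity; 0 for atoms outside any pi system."""
    pi, triple = _has_pi_bond(mol, atom)
    if not pi:
        return 0.0
    el = mol.atoms[atom].element
    if triple and (el, "pi2") in _PI_EN:
        return _PI_EN[(el, "pi2")]
    return _PI_EN.get((el, "pi"), 0.0)


def _peoe_key(element: str, hyb: Hybridization, aromatic: bool) -> tuple[str, str]:
    if element == "H":
        return ("H", "s")
    if aromatic:
        return (element, "sp2") if (element, "sp2") in _PEOE_PARAMS else (element, "sp3")
    if hyb == Hybridization.SP and (element, "sp") in _PEOE_PARAMS:
        return (element, "sp")
    if hyb == Hybridization.SP2 and (element, "sp2") in _PEOE_PARAMS:
        return (element, "sp2")
    return (element, "sp3")


def peoe_charges(
    mol: MoleculeRecord, n_iterations: int = 6, damping: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Converged PEOE sigma charges and sigma electronegativities.

    Returns (charges, electronegativities), one entry per heavy atom.
    Charge transferred across a bond in cycle ``n`` is
    ``(chi_j - chi_i) / chi^+ * damping**n`` where ``chi^+`` is the cation
    electronegativity (a + b + c) of the less electronegative partner
    (20.02 for hydrogen).  Transfers are antisymmetric, so total charge is
    conserved exactly.
    """
    # expand implicit hydrogens into pseudo-atoms
    params: list[tuple[float, float, float]] = []
    parent: list[int] = []  # heavy parent index for every participant
    bonds: list[tuple[int, int]] = []
    for i, a in enumerate(mol.atoms):
        key = _peoe_key(a.element, a.hybridization, a.aromatic)
        if key not in _PEOE_PARAMS:
            raise DescriptorError(
                f"molecule {mol.mol_id}: no PEOE parameters for {key}"
            )
        params.append(_PEOE_PARAMS[key])
        parent.append(i)
    for b in mol.bonds:
        bonds.append((b.i, b.j))
    for i, a in enumerate(mol.atoms):
        for _ in range(a.implicit_h_count):
            params.append(_PEOE_PARAMS[("H", "s")])
            parent.append(i)
            bonds.append((i, len(params) - 1))

    n = len(params)
    abc = np.asarray(params, dtype=float)
    q = np.zeros(n)
    for i, a in enumerate(mol.atoms):
        q[i] = float(a.formal_charge)
    is_h = np.array([k >= mol.n_atoms for k in range(n)], dtype=bool)
    chi_plus = abc.sum(axis=1)
    chi_plus[is_h] = _H_PLUS_EN

    for cycle in range(1, n_iterations + 1):
        chi = abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q * q
        factor = damping ** cycle
        dq = np.zeros(n)
        for i, j in bonds:
            if chi[j] > chi[i]:
                t = (chi[j] - chi[i]) / chi_plus[i] * factor
                dq[i] += t
                dq[j] -= t
            elif chi[i] > chi[j]:
                t = (chi[i] - chi[j]) / chi_plus[j] * factor
                dq[j] += t
                dq[i] -= t
        q += dq

    chi_final = abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q * q
    charges = np.zeros(mol.n_atoms)
    for k in range(n):
        charges[parent[k]] += q[k]
    return charges, chi_final[: mol.n_atoms].copy()


def mmff94_charges(mol: MoleculeRecord) -> np.ndarray:
    """MMFF94 partial charges per heavy atom (RDKit force-field backend)."""
    if mol.rdmol is None:
        raise DescriptorError(
            f"molecule {mol.mol_id}: no structure object for MMFF94 charges"
        )
    molh = Chem.AddHs(Chem.Mol(mol.rdmol))
    props = AllChem.MMFFGetMoleculeProperties(molh)
    if props is None:
        raise DescriptorError(
            f"molecule {mol.mol_id}: MMFF94 parameterization failed"
        )
    return np.array(
        [props.GetMMFFPartialCharge(i) for i in range(mol.n_atoms)], dtype=float
    )


# ---------------------------------------------------------------------------
# provider registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorProvider:
    """A named backend filling a subset of the physicochemical slots.

    ``compute(mol)`` returns ``{slot: per-atom float array}`` covering every
    declared slot for every heavy atom — partial fills are a contract
    violation.
    """

    name: str
    provides: tuple[str, ...]
    compute: Callable[[MoleculeRecord], dict[str, np.ndarray]]


def _reference_compute(mol: MoleculeRecord) -> dict[str, np.ndarray]:
    n = mol.n_atoms
    charges, electronegativities = peoe_charges(mol)
    out = {
        "atom_degree": np.array([atom_degree(mol, i) for i in range(n)], dtype=float),
        "formal_valence": np.array([formal_valence(mol, i) for i in range(n)], dtype=float),
        "hybrid_polarizability": np.array(
            [hybrid_polarizability(mol, i) for i in range(n)]
        ),
        "vsepr_geometry": np.array([vsepr_geometry(mol, i) for i in range(n)], dtype=float),
        "effective_polarizability": np.array(
            [effective_polarizability(mol, i) for i in range(n)]
        ),
        "inductive_effect": np.array([inductive_effect(mol, i) for i in range(n)]),
        "peoe_sigma_charge": charges,
        "peoe_sigma_electronegativity": electronegativities,
        "pi_electronegativity": np.array(
            [pi_electronegativity(mol, i) for i in range(n)]
        ),
    }
    return out


REFERENCE_PROVIDER = DescriptorProvider(
    name="reference",
    provides=tuple(s for s in PHYSCHEM_SLOTS if s != "mmff94_charge"),
    compute=_reference_compute,
)

MMFF94_PROVIDER = DescriptorProvider(
    name="rdkit_mmff94",
    provides=("mmff94_charge",),
    compute=lambda mol: {"mmff94_charge": mmff94_charges(mol)},
)

DEFAULT_PROVIDERS: tuple[DescriptorProvider, ...] = (REFERENCE_PROVIDER, MMFF94_PROVIDER)


def resolve_providers(
    enabled_slots: Iterable[str],
    providers: Optional[Iterable[DescriptorProvider]] = None,
) -> list[DescriptorProvider]:
    """Check at configuration time that every enabled slot has a provider."""
    enabled = list(enabled_slots)
    unknown = [s for s in enabled if s not in PHYSCHEM_SLOTS]
    if unknown:
        raise DescriptorError(f"unknown descriptor slots: {unknown}")
    pool = list(providers) if providers is not None else list(DEFAULT_PROVIDERS)
    chosen = []
    covered: set[str] = set()
    for prov in pool:
        wanted = [s for s in prov.provides if s in enabled and s not in covered]
        if wanted:
            chosen.append(prov)
            covered.update(wanted)
    missing = [s for s in enabled if s not in covered]
    if missing:
        raise DescriptorError(
            f"no registered provider for enabled descriptor slots: {missing}"
        )
    return chosen


def physchem_matrix(
    mol: MoleculeRecord,
    enabled_slots: Iterable[str],
    providers: Optional[Iterable[DescriptorProvider]] = None,
) -> np.ndarray:
    """(n_atoms, n_enabled_slots) matrix, columns in PHYSCHEM_SLOTS order."""
    enabled = [s for s in PHYSCHEM_SLOTS if s in set(enabled_slots)]
    chosen = resolve_providers(enabled, providers)
    values: dict[str, np.ndarray] = {}
    for prov in chosen:
        result = prov.compute(mol)
        for slot in prov.provides:
            if slot not in enabled or slot in values:
                continue
            col = np.asarray(result[slot], dtype=float)
            if col.shape != (mol.n_atoms,) or not np.all(np.isfinite(col)):
                raise DescriptorError(
                    f"provider {prov.name} returned invalid values for {slot}"
                )
            values[slot] = col
    return np.column_stack([values[s] for s in enabled]) if enabled else \
        np.zeros((mol.n_atoms, 0))


def topo_matrix(mol: MoleculeRecord) -> np.ndarray:
    dm = mol.distances()
    rows = [topo_descriptors(dm, i).as_tuple() for i in range(mol.n_atoms)]
    return np.asarray(rows, dtype=float)
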