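"""Geometric contact analysis of metal-cluster crystal structures.

Rules tailored to DNA-stabilized silver nanoclusters:

* **Argentophilic (Ag-Ag) interactions** — unordered Ag pairs closer than
  the sum of two silver van der Waals radii, 3.44 A.
* **Nucleotide-Ag coordination bonds** — per aromatic ring nitrogen at most
  one bond, to the nearest Ag within the search radius (3.0 A default); per
  carbonyl or phosphate oxygen up to two bonds, to the two nearest Ag.
  Genuine coordination bonds in deposited structures fall in 2.2-2.8 A.
* **Occupancy partitioning** — full versus low-occupancy (mobile) Ag sites.
* **Sugar pucker** — furanose conformation classified from the
  pseudorotation phase of the five endocyclic torsions.

Structures are read from PDB or mmCIF via gemmi; contact detection itself is
implemented here and is exactly equivalent to brute-force all-pairs
enumeration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ContactSet",
    "SugarPucker",
    "load_structure",
    "write_structure",
    "ag_ag_interactions",
    "coordination_bonds",
    "occupancy_partition",
    "distance_histogram",
    "sugar_pucker",
    "classify_sugar_puckers",
    "pseudorotation_phase",
    "AG_AG_CUTOFF",
    "COORDINATION_WINDOW",
    "SEARCH_RADIUS",
]

logger = logging.getLogger(__name__)

#: Sum of two silver van der Waals radii (A) — the Ag-Ag interaction cutoff.
AG_AG_CUTOFF = 3.44
#: Observed range of nucleotide-Ag coordination bonds (A), used as the
#: validation window for deposited structures.
COORDINATION_WINDOW = (2.2, 2.8)
#: Candidate search radius for coordination bonds (A); covers the observed
#: 2.2-2.8 A window with margin.
SEARCH_RADIUS = 3.0


def _donor_table() -> dict:
    with resources.files("agnckit.data").joinpath("donors.json").open() as fh:
        table = json.load(fh)
    table.pop("_comment", None)
    return table


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element, identity, coordinates (A) and occupancy."""

    element: str
    name: str
    residue_name: str
    residue_number: int
    chain_id: str
    altloc: str
    position: tuple[float, float, float]
    occupancy: float
    serial: int

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise ValueError("coordinates must be finite")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class StructureModel:
    """Atom list with optional subunit labelling.

    ``subunit_map`` maps chain ids to subunit labels (e.g. the two
    DNA-strand pairs of an asymmetric unit); unmapped chains form their own
    subunit.
    """

    atoms: list[AtomRecord]
    source: str = ""
    subunit_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure model must contain atoms")

    def subunit_of(self, atom: AtomRecord) -> str:
        return self.subunit_map.get(atom.chain_id, atom.chain_id)

    def select(self, element: str | None = None) -> list[AtomRecord]:
        if element is None:
            return list(self.atoms)
        return [a for a in self.atoms if a.element.capitalize() == element.capitalize()]

    def coordinates(self, atoms: list[AtomRecord] | None = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        return np.array([a.position for a in atoms], dtype=float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Rigidly rotated + translated copy (contact sets are invariant)."""
        rot = np.asarray(rotation, float)
        tr = np.asarray(translation, float)
        new_atoms = [
            AtomRecord(element=a.element, name=a.name, residue_name=a.residue_name,
                       residue_number=a.residue_number, chain_id=a.chain_id,
                       altloc=a.altloc, position=tuple(rot @ a.xyz + tr),
                       occupancy=a.occupancy, serial=a.serial)
            for a in self.atoms
        ]
        return StructureModel(atoms=new_atoms, source=self.source,
                              subunit_map=dict(self.subunit_map))

    def residues(self):
        """Iterate (chain_id, residue_number, residue_name, [atoms])."""
        groups: dict[tuple, list[AtomRecord]] = {}
        for a in self.atoms:
            groups.setdefault((a.chain_id, a.residue_number, a.residue_name), []).append(a)
        for (chain, num, name), atoms in groups.items():
            yield chain, num, name, atoms


@dataclass
class ContactSet:
    """Classified Ag-Ag and donor-Ag contact lists (deduplicated)."""

    ag_ag: list[tuple[AtomRecord, AtomRecord, float]]
    coordination: list[tuple[AtomRecord, str, AtomRecord, float]]
    ag_ag_cutoff: float = AG_AG_CUTOFF
    search_radius: float = SEARCH_RADIUS

    @property
    def ag_ag_distances(self) -> np.ndarray:
        return np.array([d for _, _, d in self.ag_ag])

    @property
    def coordination_distances(self) -> np.ndarray:
        return np.array([d for _, _, _, d in self.coordination])

    def ag_ag_pairs(self) -> set[tuple[int, int]]:
        """Unordered Ag-Ag pairs as sorted serial tuples (for set comparison)."""
        return {tuple(sorted((a.serial, b.serial))) for a, b, _ in self.ag_ag}

    def coordination_triples(self) -> set[tuple[int, str, int]]:
        return {(d.serial, cls, ag.serial) for d, cls, ag, _ in self.coordination}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"donor_chain": d.chain_id, "donor_res": d.residue_number,
             "donor_atom": d.name, "donor_class": cls, "ag_serial": ag.serial,
             "distance_A": round(dist, 2)}
            for d, cls, ag, dist in self.coordination
        ]
        return pd.DataFrame(rows, columns=["donor_chain", "donor_res", "donor_atom",
                                           "donor_class", "ag_serial", "distance_A"])

    def summary(self) -> dict:
        return {
            "n_ag_ag": len(self.ag_ag),
            "n_coordination": len(self.coordination),
            "ag_ag_cutoff_A": self.ag_ag_cutoff,
            "search_radius_A": self.search_radius,
            "ag_ag_range_A": ([round(float(self.ag_ag_distances.min()), 2),
                               round(float(self.ag_ag_distances.max()), 2)]
                              if self.ag_ag else None),
            "coordination_range_A": ([round(float(self.coordination_distances.min()), 2),
                                      round(float(self.coordination_distances.max()), 2)]
                                     if self.coordination else None),
        }


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------
def load_structure(path: str | Path, fmt: str | None = None,
                   altloc_policy: str = "highest_occupancy",
                   symmetry_mates: bool = False,
                   subunit_map: dict[str, str] | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``altloc_policy``: ``"highest_occupancy"`` (default) keeps the
    best-populated alternative location of each atom (ties go to the earlier
    altloc letter); ``"all"`` keeps every altloc. ``symmetry_mates=True``
    additionally applies the deposited crystallographic symmetry operators,
    which is needed for inter-asymmetric-unit contacts.
    """
    path = Path(path)
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            fmt_map = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}
            st = gemmi.read_structure(str(path), format=fmt_map[fmt.lower()])
    except Exception as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    if symmetry_mates:
        how = gemmi.HowToNameCopiedChain.AddNumber
        st.transform_to_assembly("unit_cell", how)

    atoms: list[AtomRecord] = []
    serial = 0
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                serial += 1
                atoms.append(AtomRecord(
                    element=atom.element.name, name=atom.name,
                    residue_name=res.name, residue_number=res.seqid.num,
                    chain_id=chain.name, altloc=atom.altloc or "",
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=float(min(max(atom.occ, 0.0), 1.0)),
                    serial=serial,
                ))
    if altloc_policy == "highest_occupancy":
        atoms = _pick_altlocs(atoms)
    elif altloc_policy != "all":
        raise ValueError("altloc_policy must be 'highest_occupancy' or 'all'")
    return StructureModel(atoms=atoms, source=str(path),
                          subunit_map=subunit_map or {})


def _pick_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.residue_name, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, -ord(a.altloc or "A")) > (b.occupancy, -ord(b.altloc or "A")):
                best[key] = a
    return [best[k] for k in order]


def write_structure(model: StructureModel, path: str | Path,
                    fmt: str | None = None) -> None:
    """Write a model as PDB or mmCIF (format inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = gemmi.Structure()
    st.name = model.source or "model"
    st.cell = gemmi.UnitCell(100, 100, 100, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    gmodel = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in model.atoms:
        chain = chains.setdefault(a.chain_id, gemmi.Chain(a.chain_id))
        res = None
        for r in chain:
            if r.seqid.num == a.residue_number and r.name == a.residue_name:
                res = r
                break
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            chain.add_residue(res)
            res = chain[-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.position)
        atom.occ = a.occupancy
        atom.altloc = a.altloc or "\0"
        res.add_atom(atom)
    for chain in chains.values():
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# --------------------------------------------------------------------------
# contacts
# --------------------------------------------------------------------------
def ag_ag_interactions(model: StructureModel, cutoff: float = AG_AG_CUTOFF
                       ) -> ContactSet:
    """All unordered Ag-Ag pairs strictly below ``cutoff`` (A).

    Equivalent to brute-force all-pairs enumeration; an empty result is a
    valid outcome.
    """
    silvers = model.select("Ag")
    pairs: list[tuple[AtomRecord, AtomRecord, float]] = []
    if len(silvers) >= 2:
        coords = model.coordinates(silvers)
        tree = cKDTree(coords)
        for i, j in sorted(tree.query_pairs(r=cutoff)):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d < cutoff:
                a, b = silvers[i], silvers[j]
                if b.serial < a.serial:
                    a, b = b, a
                pairs.append((a, b, d))
    pairs.sort(key=lambda p: (p[0].serial, p[1].serial))
    return ContactSet(ag_ag=pairs, coordination=[], ag_ag_cutoff=cutoff)


def coordination_bonds(model: StructureModel,
                       search_radius: float = SEARCH_RADIUS,
                       include_bridging: bool = False,
                       donor_table: dict | None = None) -> ContactSet:
    """Nucleotide-donor to silver coordination bonds.

    Per aromatic nitrogen: at most one bond, to the nearest Ag within
    ``search_radius``. Per carbonyl or phosphate oxygen: up to two bonds, to
    the two nearest Ag. Exactly equal distances are broken by the lower Ag
    serial. Bridging phosphate-ester oxygens (O3'/O5') are excluded unless
    ``include_bridging``. Donor atoms of residues absent from the donor
    table are skipped with a warning.
    """
    table = donor_table if donor_table is not None else _donor_table()
    silvers = model.select("Ag")
    contacts: list[tuple[AtomRecord, str, AtomRecord, float]] = []
    if not silvers:
        return ContactSet(ag_ag=[], coordination=[], search_radius=search_radius)
    ag_coords = model.coordinates(silvers)
    tree = cKDTree(ag_coords)

    warned: set[str] = set()
    for atom in model.atoms:
        if atom.element.capitalize() == "Ag":
            continue
        res_entry = table.get(atom.residue_name)
        if res_entry is None:
            if atom.residue_name not in warned and atom.element in ("N", "O"):
                logger.warning("coordination_bonds: residue %r not in donor "
                               "table; its atoms are skipped", atom.residue_name)
                warned.add(atom.residue_name)
            continue
        name = atom.name.replace("*", "'")
        donor_class = None
        for cls in ("aromatic_N", "carbonyl_O", "phosphate_O"):
            if name in res_entry.get(cls, ()):
                donor_class = cls
                break
        if donor_class is None and include_bridging and \
                name in res_entry.get("phosphate_bridging", ()):
            donor_class = "phosphate_O"
        if donor_class is None:
            continue
        n_max = 1 if donor_class == "aromatic_N" else 2
        idx = tree.query_ball_point(atom.xyz, r=search_radius)
        dists = [(float(np.linalg.norm(ag_coords[i] - atom.xyz)),
                  silvers[i].serial, i) for i in idx]
        dists = [(d, s, i) for d, s, i in dists if d < search_radius]
        dists.sort()  # ties broken by the lower serial
        for d, _, i in dists[:n_max]:
            contacts.append((atom, donor_class, silvers[i], d))
    contacts.sort(key=lambda c: (c[0].serial, c[3]))
    return ContactSet(ag_ag=[], coordination=contacts, search_radius=search_radius)


def occupancy_partition(model: StructureModel, threshold: float = 0.99
                        ) -> tuple[list[AtomRecord], list[AtomRecord], dict]:
    """Split Ag sites into full (occ >= threshold) and low-occupancy lists.

    Returns ``(full, low, per_subunit)`` where ``per_subunit`` maps each
    subunit label to its ``(n_full, n_low)`` counts.
    """
    silvers = model.select("Ag")
    if not silvers:
        raise ValueError("structure contains no Ag atoms")
    full = [a for a in silvers if a.occupancy >= threshold]
    low = [a for a in silvers if a.occupancy < threshold]
    per_subunit: dict[str, tuple[int, int]] = {}
    for label in sorted({model.subunit_of(a) for a in silvers}):
        nf = sum(1 for a in full if model.subunit_of(a) == label)
        nl = sum(1 for a in low if model.subunit_of(a) == label)
        per_subunit[label] = (nf, nl)
    return full, low, per_subunit


def distance_histogram(contacts: ContactSet, bin_width: float = 0.1,
                       which: str = "all", start: float | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of contact distances with half-open bins [lo, hi).

    Returns ``(edges, counts)`` with ``len(edges) == len(counts) + 1``; the
    total count always equals the number of contacts.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if which == "ag_ag":
        d = contacts.ag_ag_distances
    elif which == "coordination":
        d = contacts.coordination_distances
    elif which == "all":
        d = np.concatenate([contacts.ag_ag_distances,
                            contacts.coordination_distances])
    else:
        raise ValueError("which must be 'ag_ag', 'coordination' or 'all'")
    if d.size == 0:
        lo = start if start is not None else 0.0
        return np.array([lo, lo + bin_width]), np.zeros(1, dtype=int)
    lo = start if start is not None else np.floor(d.min() / bin_width) * bin_width
    idx = np.floor((d - lo) / bin_width).astype(int)
    if np.any(idx < 0):
        raise ValueError("start lies above the smallest distance")
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    edges = lo + bin_width * np.arange(n_bins + 1)
    return edges, counts


# --------------------------------------------------------------------------
# sugar pucker
# --------------------------------------------------------------------------
_RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")
# endocyclic torsions nu0..nu4 as atom-name quadruples
_TORSIONS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def pseudorotation_phase(coords: dict[str, np.ndarray]) -> tuple[float, float]:
    """Pseudorotation phase P (deg, [0, 360)) and amplitude tau_m.

    Altona-Sundaralingam formalism from the five endocyclic torsions:
    ``tan P = [(nu4 + nu1) - (nu3 + nu0)] / [2 nu2 (sin 36 + sin 72)]``.
    """
    nu = [dihedral(*(coords[n] for n in quad)) for quad in _TORSIONS]
    denom = 2.0 * nu[2] * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))
    p = np.degrees(np.arctan2((nu[4] + nu[1]) - (nu[3] + nu[0]), denom))
    if p < 0:
        p += 360.0
    tau_m = nu[2] / np.cos(np.radians(p)) if np.cos(np.radians(p)) != 0 else np.nan
    return float(p), float(tau_m)


@dataclass
class SugarPucker:
    """Furanose pucker classification for one residue."""

    conformation: str  # "C3'-endo", "C2'-endo", "other" or "incomplete"
    phase: float  # deg, NaN when incomplete
    amplitude: float  # deg


def sugar_pucker(residue_atoms) -> SugarPucker:
    """Classify a furanose ring from its five ring atoms.

    Accepts a mapping of atom name to coordinates or a sequence of
    :class:`AtomRecord`. Classification: C3'-endo for P in [0, 36) deg,
    C2'-endo for P in [144, 180) deg, otherwise "other"; boundary values go
    to the lower-index class. Missing ring atoms give "incomplete".
    """
    if isinstance(residue_atoms, dict):
        coords = {k.replace("*", "'"): np.asarray(v, float)
                  for k, v in residue_atoms.items()}
    else:
        coords = {a.name.replace("*", "'"): a.xyz for a in residue_atoms}
    if not all(name in coords for name in _RING_ATOMS):
        return SugarPucker(conformation="incomplete", phase=float("nan"),
                           amplitude=float("nan"))
    p, tau_m = pseudorotation_phase(coords)
    if 0.0 <= p < 36.0:
        conf = "C3'-endo"
    elif 144.0 <= p < 180.0:
        conf = "C2'-endo"
    else:
        conf = "other"
    return SugarPucker(conformation=conf, phase=p, amplitude=tau_m)


def classify_sugar_puckers(model: StructureModel) -> pd.DataFrame:
    """Sugar-pucker table for every residue that carries a furanose ring."""
    rows = []
    for chain, num, name, atoms in model.residues():
        names = {a.name.replace("*", "'") for a in atoms}
        if not names & set(_RING_ATOMS):
            continue
        pucker = sugar_pucker(atoms)
        rows.append((chain, num, name, pucker.conformation,
                     round(pucker.phase, 1) if np.isfinite(pucker.phase) else np.nan))
    return pd.DataFrame(rows, columns=["chain", "residue_number", "residue_name",
                                       "conformation", "phase_deg"])
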