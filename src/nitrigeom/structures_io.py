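"""Read, clean and select atoms from PDB structures and multi-model trajectories.

This module turns PDB-format coordinate files into the labelled in-memory
objects the geometry layer consumes: flat :class:`AtomRecord` lists, complete
:class:`ActiveSite` objects (the T2Cu ion, its three coordinating histidine
nitrogens, the nitrite ion, and named auxiliary residues), and mass-weighted
sidechain centres of mass.  Parsing is delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "AtomGroup",
    "ActiveSite",
    "SidechainCOM",
    "SiteConfig",
    "read_structure",
    "clean_altlocs",
    "extract_active_site",
    "sidechain_com",
    "active_site_table",
    "write_sites_pdb",
    "load_site_config",
]

# Atom names that belong to the peptide backbone; everything else in a residue
# is treated as sidechain (the Cb onward, per the COM definition used here).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})

_TOL = 1e-9


@functools.lru_cache(maxsize=None)
def atomic_mass(element: str) -> float:
    """Standard atomic mass (u) for an element symbol, via gemmi's tables."""
    el = gemmi.Element(element.capitalize() if len(element) > 1 else element.upper())
    if el.name == "X":
        raise ValueError(f"unknown element symbol {element!r}")
    return float(el.weight)


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record from a (possibly multi-model) PDB file."""

    chain_id: str
    residue_name: str
    residue_number: int
    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    model_index: int = 1

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class AtomGroup:
    """A named set of atoms (e.g. one residue's sidechain)."""

    names: list[str]
    elements: list[str]
    positions: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if len(self.names) != len(self.elements) or len(self.names) != len(self.positions):
            raise ValueError("AtomGroup fields must have equal lengths")

    def __len__(self) -> int:
        return len(self.names)

    def select(self, names: Iterable[str]) -> "AtomGroup":
        wanted = set(names)
        idx = [i for i, n in enumerate(self.names) if n in wanted]
        return AtomGroup(
            [self.names[i] for i in idx],
            [self.elements[i] for i in idx],
            self.positions[idx] if idx else np.zeros((0, 3)),
        )

    def com(self, include_hydrogens: bool = False) -> np.ndarray:
        """Mass-weighted centre of mass of the group."""
        idx = [
            i
            for i, el in enumerate(self.elements)
            if include_hydrogens or el.upper() not in ("H", "D")
        ]
        if not idx:
            raise ValueError("no atoms left for centre of mass")
        masses = np.array([atomic_mass(self.elements[i]) for i in idx])
        return masses @ self.positions[idx] / masses.sum()


@dataclass(frozen=True)
class HisNitrogen:
    """The coordinating sidechain nitrogen of one histidine ligand."""

    residue_number: int
    atom_name: str  # ND1 or NE2
    position: np.ndarray

    @property
    def label(self) -> str:
        return f"His{self.residue_number}"


@dataclass
class ActiveSite:
    """T2Cu centre, three His ligand nitrogens, nitrite, and auxiliary residues.

    All coordinates are Angstrom vectors from a single model/frame.
    ``aux`` maps a role label (e.g. ``"Tyr323"``) to the residue's atoms.
    """

    cu: np.ndarray
    his_n: list[HisNitrogen]
    nitrite_n: np.ndarray
    nitrite_o1: np.ndarray
    nitrite_o2: np.ndarray
    aux: dict[str, AtomGroup] = field(default_factory=dict)
    chain_id: str = "A"
    frame_index: int = 1
    missing_aux: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("cu", "nitrite_n", "nitrite_o1", "nitrite_o2"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            setattr(self, name, v)
        if len(self.his_n) != 3:
            raise ValueError(f"expected exactly 3 His nitrogens, got {len(self.his_n)}")
        for bond_atom in (self.nitrite_o1, self.nitrite_o2):
            if np.linalg.norm(bond_atom - self.nitrite_n) <= _TOL:
                raise ValueError("nitrite N-O distance must be > 0")
        if np.linalg.norm(self.nitrite_o1 - self.nitrite_o2) <= _TOL:
            raise ValueError("nitrite O1 and O2 coincide")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ActiveSite":
        """Return a copy with ``x -> R x + t`` applied to every coordinate."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        move = lambda v: R @ v + t
        return ActiveSite(
            cu=move(self.cu),
            his_n=[
                HisNitrogen(h.residue_number, h.atom_name, move(h.position)) for h in self.his_n
            ],
            nitrite_n=move(self.nitrite_n),
            nitrite_o1=move(self.nitrite_o1),
            nitrite_o2=move(self.nitrite_o2),
            aux={
                role: AtomGroup(list(g.names), list(g.elements), g.positions @ R.T + t)
                for role, g in self.aux.items()
            },
            chain_id=self.chain_id,
            frame_index=self.frame_index,
            missing_aux=list(self.missing_aux),
        )

    def with_swapped_oxygens(self) -> "ActiveSite":
        """Return a copy with the (arbitrary) O1/O2 labels exchanged."""
        out = ActiveSite(
            cu=self.cu,
            his_n=list(self.his_n),
            nitrite_n=self.nitrite_n,
            nitrite_o1=self.nitrite_o2,
            nitrite_o2=self.nitrite_o1,
            aux=dict(self.aux),
            chain_id=self.chain_id,
            frame_index=self.frame_index,
            missing_aux=list(self.missing_aux),
        )
        return out


@dataclass(frozen=True)
class SidechainCOM:
    """Mass-weighted centre of mass of one residue sidechain."""

    residue_id: tuple[str, int, str]  # (chain, number, name)
    com: np.ndarray
    atom_count: int


@dataclass
class SiteConfig:
    """Which residues make up the active site in a given structure.

    Defaults follow the RpNiR numbering: His99/His134/His289 coordinate the
    T2Cu, with Asp97 (Asn97 in the D97N mutant), His240, Ile242 and Tyr323 as
    the mechanistically relevant neighbours.
    """

    chain: str = "A"
    cu_residue: str | int = "CU"
    his_residues: tuple[int, int, int] = (99, 134, 289)
    nitrite_residue: str | int = "NO2"
    aux_residues: Mapping[str, int] = field(
        default_factory=lambda: {"Asp97": 97, "His240": 240, "Ile242": 242, "Tyr323": 323}
    )


def read_structure(path: str | Path, model_policy: str = "all") -> list[AtomRecord]:
    """Parse a PDB file into a flat list of :class:`AtomRecord`.

    Parameters
    ----------
    path:
        PDB-format file; multi-model (MODEL/ENDMDL) files are supported.
    model_policy:
        ``"all"`` returns every model (``model_index`` starts at 1);
        ``"first"`` returns only the first model.
    """
    if model_policy not in ("all", "first"):
        raise ValueError(f"model_policy must be 'all' or 'first', got {model_policy!r}")
    path = Path(path)
    _precheck_pdb_text(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi names the line
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    records: list[AtomRecord] = []
    for m_idx, model in enumerate(structure, start=1):
        if model_policy == "first" and m_idx > 1:
            break
        for chain in model:
            for residue in chain:
                for atom in residue:
                    records.append(
                        AtomRecord(
                            chain_id=chain.name,
                            residue_name=residue.name,
                            residue_number=residue.seqid.num,
                            atom_name=atom.name,
                            element=atom.element.name,
                            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            occupancy=float(min(max(atom.occ, 0.0), 1.0)),
                            b_factor=float(atom.b_iso),
                            altloc="" if atom.altloc == "\0" else atom.altloc,
                            model_index=m_idx,
                        )
                    )
    if not records:
        raise ValueError(f"no atoms found in {path}")
    return records


def _precheck_pdb_text(path: Path) -> None:
    """Fail early, naming the offending line, on malformed coordinate records."""
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except (ValueError, IndexError):
                    raise ValueError(
                        f"cannot parse PDB file {path}: bad coordinates on line {lineno}"
                    ) from None


def clean_altlocs(
    atoms: Sequence[AtomRecord], remove_partial_waters: bool = False
) -> list[AtomRecord]:
    """Resolve alternate locations, keeping one atom per site.

    For every (model, chain, residue, atom name) group with more than one
    altloc, the survivor is the copy with the highest occupancy; occupancy
    ties are broken by the lowest B-factor, then by altloc character order.
    With ``remove_partial_waters=True``, water molecules whose atoms retain
    occupancy < 1 after altloc resolution are dropped as well.

    Idempotent: reapplying the function changes nothing.
    """
    groups: dict[tuple, list[int]] = {}
    for i, a in enumerate(atoms):
        key = (a.model_index, a.chain_id, a.residue_number, a.residue_name, a.atom_name)
        groups.setdefault(key, []).append(i)

    keep: set[int] = set()
    for idxs in groups.values():
        if len(idxs) == 1:
            keep.add(idxs[0])
        else:
            best = min(idxs, key=lambda i: (-atoms[i].occupancy, atoms[i].b_factor, atoms[i].altloc))
            keep.add(best)

    survivors = [atoms[i] for i in sorted(keep)]
    if remove_partial_waters:
        partial_waters = {
            (a.model_index, a.chain_id, a.residue_number)
            for a in survivors
            if a.residue_name in WATER_NAMES and a.occupancy < 1.0
        }
        survivors = [
            a
            for a in survivors
            if (a.model_index, a.chain_id, a.residue_number) not in partial_waters
        ]
    return survivors


def _residue_atoms(
    atoms: Sequence[AtomRecord], chain: str, model_index: int, key: str | int
) -> list[AtomRecord]:
    if isinstance(key, int):
        match = lambda a: a.residue_number == key
    else:
        match = lambda a: a.residue_name == key
    return [
        a
        for a in atoms
        if a.chain_id == chain and a.model_index == model_index and match(a)
    ]


def _group_from(atoms: Sequence[AtomRecord]) -> AtomGroup:
    return AtomGroup(
        [a.atom_name for a in atoms],
        [a.element for a in atoms],
        np.array([a.position for a in atoms]) if atoms else np.zeros((0, 3)),
    )


def extract_active_site(
    atoms: Sequence[AtomRecord],
    chain: str | None = None,
    config: SiteConfig | None = None,
    model_index: int = 1,
) -> ActiveSite:
    """Select the T2Cu site atoms from a parsed structure.

    The coordinating nitrogen of each histidine is whichever of ND1/NE2 lies
    closer to the Cu ion (robust to tautomer naming conventions).  Nitrite
    atoms are mapped by element: exactly one N and two O are required.
    Auxiliary residues named in the config are attached when present;
    absent roles are recorded in ``missing_aux`` rather than raising.
    """
    config = config or SiteConfig()
    chain = chain if chain is not None else config.chain

    cu_atoms = _residue_atoms(atoms, chain, model_index, config.cu_residue)
    cu_atoms = [a for a in cu_atoms if a.element.upper() == "CU"] or cu_atoms
    if not cu_atoms:
        raise ValueError(
            f"no Cu atom found (chain {chain}, model {model_index}, residue {config.cu_residue!r})"
        )
    cu = cu_atoms[0].position

    his_n: list[HisNitrogen] = []
    for resnum in config.his_residues:
        res = _residue_atoms(atoms, chain, model_index, resnum)
        candidates = [a for a in res if a.atom_name in ("ND1", "NE2")]
        if not candidates:
            raise ValueError(
                f"His{resnum}: no sidechain nitrogen (ND1/NE2) in chain {chain}, "
                f"model {model_index}"
            )
        nearest = min(candidates, key=lambda a: np.linalg.norm(a.position - cu))
        his_n.append(HisNitrogen(resnum, nearest.atom_name, nearest.position))

    nit = _residue_atoms(atoms, chain, model_index, config.nitrite_residue)
    n_atoms = [a for a in nit if a.element.upper() == "N"]
    o_atoms = [a for a in nit if a.element.upper() == "O"]
    if len(n_atoms) != 1 or len(o_atoms) != 2:
        raise ValueError(
            f"nitrite residue {config.nitrite_residue!r} (chain {chain}): expected 1 N and 2 O, "
            f"found {len(n_atoms)} N and {len(o_atoms)} O"
        )

    aux: dict[str, AtomGroup] = {}
    missing: list[str] = []
    for role, resnum in config.aux_residues.items():
        res = _residue_atoms(atoms, chain, model_index, resnum)
        if res:
            aux[role] = _group_from(res)
        else:
            missing.append(role)

    return ActiveSite(
        cu=cu,
        his_n=his_n,
        nitrite_n=n_atoms[0].position,
        nitrite_o1=o_atoms[0].position,
        nitrite_o2=o_atoms[1].position,
        aux=aux,
        chain_id=chain,
        frame_index=model_index,
        missing_aux=missing,
    )


def sidechain_com(
    atoms: Sequence[AtomRecord],
    residue_id: tuple[str, int],
    model_index: int = 1,
    include_hydrogens: bool = False,
) -> SidechainCOM:
    """Mass-weighted centre of mass of a residue sidechain.

    The sidechain is every atom from Cb onward: backbone N, CA, C, O (and
    OXT) are excluded, as are hydrogens unless ``include_hydrogens`` is set —
    so crystal structures (no H) and MD snapshots give comparable values.
    """
    chain, resnum = residue_id
    res = _residue_atoms(atoms, chain, model_index, resnum)
    if not res:
        raise ValueError(f"residue {chain}/{resnum} not found in model {model_index}")
    side = [
        a
        for a in res
        if a.atom_name not in BACKBONE_ATOMS
        and (include_hydrogens or a.element.upper() not in ("H", "D"))
    ]
    if not side:
        raise ValueError(
            f"residue {chain}/{resnum} ({res[0].residue_name}) has no sidechain atoms"
        )
    masses = np.array([atomic_mass(a.element) for a in side])
    com = masses @ np.array([a.position for a in side]) / masses.sum()
    return SidechainCOM(
        residue_id=(chain, resnum, res[0].residue_name),
        com=com,
        atom_count=len(side),
    )


def active_site_table(site: ActiveSite) -> pd.DataFrame:
    """Flatten an ActiveSite to a (role, chain, resnum, atom, x, y, z) table."""
    rows = []

    def add(role: str, resnum, atom: str, pos: np.ndarray) -> None:
        rows.append(
            {
                "role": role,
                "chain": site.chain_id,
                "resnum": resnum,
                "atom": atom,
                "x": pos[0],
                "y": pos[1],
                "z": pos[2],
            }
        )

    add("Cu", "", "CU", site.cu)
    for h in site.his_n:
        add(h.label, h.residue_number, h.atom_name, h.position)
    add("nitrite", "", "N", site.nitrite_n)
    add("nitrite", "", "O1", site.nitrite_o1)
    add("nitrite", "", "O2", site.nitrite_o2)
    for role, group in site.aux.items():
        for name, pos in zip(group.names, group.positions):
            add(role, "", name, pos)
    return pd.DataFrame(rows)


_ROLE_RESNAMES = {"ASP": "ASP", "ASN": "ASN", "TYR": "TYR", "HIS": "HIS", "ILE": "ILE"}


def _role_to_residue(role: str) -> tuple[str, int]:
    """Map a role label like 'Tyr323' to a (residue name, number) pair."""
    head = "".join(c for c in role if c.isalpha())
    digits = "".join(c for c in role if c.isdigit())
    resname = _ROLE_RESNAMES.get(head[:3].upper(), head[:3].upper() or "UNK")
    return resname, int(digits) if digits else 0


def write_sites_pdb(
    sites: Sequence[ActiveSite],
    path: str | Path,
    cu_resnum: int = 500,
    nitrite_resnum: int = 501,
    decoy_his_nitrogen: bool = True,
) -> None:
    """Write one or more ActiveSites as a (multi-model) PDB file.

    Each site becomes one MODEL.  Histidines are written minimally: the
    coordinating nitrogen at its exact position plus (optionally) the other
    sidechain nitrogen as a decoy placed 1.4 A further from Cu along the
    same direction, so re-extraction exercises the nearer-atom rule and
    still recovers the original coordinates.
    """
    structure = gemmi.Structure()
    structure.name = "nitrigeom synthetic site"

    def new_residue(name: str, num: int) -> gemmi.Residue:
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(num, " ")
        res.het_flag = "H" if name in ("CU", "NO2", "HOH") else "A"
        return res

    def add_atom(res: gemmi.Residue, name: str, element: str, pos: np.ndarray) -> None:
        atom = gemmi.Atom()
        atom.name = name
        atom.element = gemmi.Element(element)
        atom.pos = gemmi.Position(*map(float, pos))
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)

    for m_idx, site in enumerate(sites, start=1):
        model = gemmi.Model(str(m_idx))
        chain = gemmi.Chain(site.chain_id or "A")

        for h in site.his_n:
            res = new_residue("HIS", h.residue_number)
            add_atom(res, h.atom_name, "N", h.position)
            if decoy_his_nitrogen:
                direction = h.position - site.cu
                direction = direction / np.linalg.norm(direction)
                other = "ND1" if h.atom_name == "NE2" else "NE2"
                add_atom(res, other, "N", h.position + 1.4 * direction)
            chain.add_residue(res)

        for role, group in site.aux.items():
            resname, resnum = _role_to_residue(role)
            res = new_residue(resname, resnum)
            for name, element, pos in zip(group.names, group.elements, group.positions):
                add_atom(res, name, element, pos)
            chain.add_residue(res)

        cu_res = new_residue("CU", cu_resnum)
        add_atom(cu_res, "CU", "Cu", site.cu)
        chain.add_residue(cu_res)

        nit = new_residue("NO2", nitrite_resnum)
        add_atom(nit, "N", "N", site.nitrite_n)
        add_atom(nit, "O1", "O", site.nitrite_o1)
        add_atom(nit, "O2", "O", site.nitrite_o2)
        chain.add_residue(nit)

        model.add_chain(chain)
        structure.add_model(model)

    structure.setup_entities()
    with open(path, "w") as fh:
        fh.write(structure.make_pdb_string())


def load_site_config(path: str | Path) -> SiteConfig:
    """Read a SiteConfig from a plain key-value (YAML) file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "chain" in raw:
        kwargs["chain"] = str(raw["chain"])
    if "cu" in raw:
        kwargs["cu_residue"] = raw["cu"]
    if "his" in raw:
        his = tuple(int(x) for x in raw["his"])
        if len(his) != 3:
            raise ValueError("site config: 'his' must list exactly 3 residue numbers")
        kwargs["his_residues"] = his
    if "nitrite" in raw:
        kwargs["nitrite_residue"] = raw["nitrite"]
    if "aux" in raw:
        kwargs["aux_residues"] = {str(k): int(v) for k, v in raw["aux"].items()}
    return SiteConfig(**kwargs)
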