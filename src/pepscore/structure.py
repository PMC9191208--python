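"""Peptide-protein complex structures: parsing, validation, writing.

A *peptide-protein complex* pairs a receptor chain of at least 50 residues
with a peptide chain of at most 25 residues that buries at least 200 A^2 of
contact surface against the receptor.  :func:`select_peptide_complexes`
applies exactly these filters.

PDB input/output is delegated to gemmi; only the first model and the first
alternate location of each atom are kept, and HETATM records (co-factors,
solvent) are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: residue-count bounds and buried-area threshold for complex eligibility
MIN_RECEPTOR_LEN = 50
MAX_PEPTIDE_LEN = 25
MIN_CONTACT_SURFACE = 200.0  # A^2

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class PDBParseError(ValueError):
    """Raised when a PDB text stream cannot be interpreted."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name!r}")


@dataclass
class Residue:
    name3: str
    one_letter: str
    chain_id: str
    author_seq: int
    index: int
    atoms: dict[str, Atom] = field(default_factory=dict)
    icode: str = ""

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"].coord

    def heavy_coords(self) -> np.ndarray:
        return np.array(
            [a.coord for a in self.atoms.values() if a.element != "H"]
        )


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def backbone_coords(self, atom_names=("N", "CA", "C", "O")) -> np.ndarray:
        """Coordinates of the requested backbone atoms, in residue order.

        Atoms missing from a residue are silently skipped, so the caller
        must use matching residues when comparing two chains (see
        :func:`pepscore.metrics.paired_backbone`).
        """
        coords = [
            r.atoms[n].coord for r in self.residues for n in atom_names
            if n in r.atoms
        ]
        return np.array(coords)


@dataclass
class PepComplex:
    """Receptor + peptide chain pair, the unit all operations act on."""

    receptor: Chain
    peptide: Chain
    is_validated: bool = False

    def copy(self) -> "PepComplex":
        import copy as _copy

        return _copy.deepcopy(self)


def _convert_residue(res: gemmi.Residue, chain_id: str, index: int) -> Residue | None:
    atoms: dict[str, Atom] = {}
    for atom in res:
        if atom.name in atoms:  # later altloc of an atom already seen
            continue
        atoms[atom.name] = Atom(
            name=atom.name,
            element=atom.element.name,
            coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
        )
    if "CA" not in atoms:
        logger.warning(
            "residue %s %s%d has no CA atom; skipped", res.name, chain_id, res.seqid.num
        )
        return None
    name3 = res.name
    return Residue(
        name3=name3,
        one_letter=THREE_TO_ONE.get(name3, "X"),
        chain_id=chain_id,
        author_seq=res.seqid.num,
        index=index,
        atoms=atoms,
        icode=res.seqid.icode.strip(),
    )


def parse_pdb(text: str) -> list[Chain]:
    """Parse PDB-format text into chains of standard residues.

    Only MODEL 1 is read; HETATM records and residues lacking a CA are
    dropped, the first alternate location wins, and chains left with fewer
    than two residues are discarded.
    """
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        raise PDBParseError("no ATOM records found in input")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line number
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("no models in input")
    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.het_flag == "H":
                continue
            converted = _convert_residue(gres, gchain.name, len(residues))
            if converted is not None:
                residues.append(converted)
        if len(residues) < 2:
            if residues:
                logger.warning("chain %s has <2 usable residues; dropped", gchain.name)
            continue
        chains.append(Chain(id=gchain.name, residues=residues))
    return chains


def write_pdb(complex_: PepComplex) -> str:
    """Serialize a complex to PDB text (fixed-width, 3-decimal coordinates)."""
    for chain in (complex_.receptor, complex_.peptide):
        if len(chain) == 0:
            raise ValueError(f"chain {chain.id!r} is empty")
    st = gemmi.Structure()
    st.name = "pepscore"
    model = gemmi.Model(1)
    for chain in (complex_.receptor, complex_.peptide):
        gchain = gemmi.Chain(chain.id)
        for res in chain:
            gres = gemmi.Residue()
            gres.name = res.name3
            gres.seqid = gemmi.SeqId(res.author_seq, res.icode or " ")
            gres.het_flag = "A"
            for atom in res.atoms.values():
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.coord)
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))


def select_peptide_complexes(chains: list[Chain]) -> list[PepComplex]:
    """All ordered (receptor, peptide) pairs passing the eligibility filters.

    Receptor >= 50 residues, peptide <= 25 residues, buried contact surface
    >= 200 A^2.  Fewer than two chains yields an empty list.
    """
    from .metrics import contact_surface

    out: list[PepComplex] = []
    for rec in chains:
        if len(rec) < MIN_RECEPTOR_LEN:
            continue
        for pep in chains:
            if pep is rec or len(pep) > MAX_PEPTIDE_LEN or len(pep) < 2:
                continue
            if contact_surface(rec, pep) >= MIN_CONTACT_SURFACE:
                out.append(PepComplex(receptor=rec, peptide=pep, is_validated=True))
    return out
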