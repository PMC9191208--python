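"""Geometric and interface-quality metrics.

LRMSD is the RMSD of peptide backbone atoms after least-squares
superposition of the model receptor onto the native receptor; the training
target is its S-score normalization ``1 / (1 + (LRMSD/d0)^2)`` with
``d0 = 8 A``, which maps any RMSD onto (0, 1] with 0.5 at 8 A.

DockQ combines the fraction of preserved native cross-interface contacts
(Fnat, heavy atoms < 5 A), interface RMSD (iRMSD, backbone of residues with
any heavy atom < 10 A of the partner chain) and LRMSD:

    DockQ = (Fnat + 1/(1+(LRMSD/8.5)^2) + 1/(1+(iRMSD/1.5)^2)) / 3

with quality classes Incorrect < 0.23 <= Acceptable < 0.49 <= Medium
< 0.80 <= High (boundary membership goes to the higher class).

Contact surface is the per-side buried area (dSASA/2) from Shrake-Rupley
solvent-accessible surface areas (960 sphere points per atom, probe 1.4 A,
single-atom van der Waals radii), computed with biotite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure import Chain, PepComplex

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# DockQ constants (contact / interface cutoffs and scaling distances)
FNAT_CUTOFF = 5.0       # A, heavy-atom contact distance
INTERFACE_CUTOFF = 10.0  # A, interface-residue definition
DOCKQ_D1 = 8.5          # A, LRMSD scaling
DOCKQ_D2 = 1.5          # A, iRMSD scaling
CAPRI_BOUNDS = (0.23, 0.49, 0.80)

SASA_POINTS = 960
SASA_PROBE = 1.4  # A


@dataclass
class SuperpositionResult:
    rotation: np.ndarray    # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class QualityReport:
    lrmsd: float
    lrmsd_norm: float
    fnat: float
    irmsd: float
    dockq: float
    capri_class: str

    def as_dict(self) -> dict:
        return {
            "lrmsd": self.lrmsd,
            "lrmsd_norm": self.lrmsd_norm,
            "fnat": self.fnat,
            "irmsd": self.irmsd,
            "dockq": self.dockq,
            "capri_class": self.capri_class,
        }


def superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (Kabsch).

    Reflections are excluded: the returned rotation always has det = +1.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape:
        raise ValueError(f"point counts differ: {mobile.shape} vs {target.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    mob_c = mobile.mean(axis=0)
    tgt_c = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tgt_c, mobile - mob_c)
    R = rot.as_matrix()
    t = tgt_c - R @ mob_c
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def check_correspondence(model: PepComplex, native: PepComplex) -> None:
    for attr in ("receptor", "peptide"):
        m: Chain = getattr(model, attr)
        n: Chain = getattr(native, attr)
        if len(m) != len(n):
            raise ValueError(
                f"{attr} length mismatch: model {len(m)} vs native {len(n)}"
            )
        for rm, rn in zip(m, n):
            if rm.name3 != rn.name3:
                raise ValueError(
                    f"first differing residue: {attr} index {rm.index} "
                    f"({rm.name3} vs {rn.name3})"
                )


def paired_backbone(
    a: Chain, b: Chain, atom_names=BACKBONE_ATOMS
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of backbone atoms present in both chains, residue-paired."""
    ca, cb = [], []
    for ra, rb in zip(a, b):
        for name in atom_names:
            if name in ra.atoms and name in rb.atoms:
                ca.append(ra.atoms[name].coord)
                cb.append(rb.atoms[name].coord)
    return np.array(ca), np.array(cb)


def receptor_superposition(
    model: PepComplex, native: PepComplex
) -> SuperpositionResult:
    mob, tgt = paired_backbone(model.receptor, native.receptor)
    return superpose(mob, tgt)


def lrmsd(
    model: PepComplex,
    native: PepComplex,
    atom_names=BACKBONE_ATOMS,
) -> float:
    """Peptide backbone RMSD after superposing receptors.

    ``atom_names`` defaults to N, CA, C, O; pass ``("CA",)`` for CA-only.
    """
    check_correspondence(model, native)
    sup = receptor_superposition(model, native)
    mob, tgt = paired_backbone(model.peptide, native.peptide, atom_names)
    fitted = sup.apply(mob)
    return float(np.sqrt(np.mean(np.sum((fitted - tgt) ** 2, axis=1))))


def lrmsd_norm(value: float, d0: float = 8.0) -> float:
    """S-score normalization of an RMSD: 1 / (1 + (value/d0)^2)."""
    if value < 0:
        raise ValueError("RMSD cannot be negative")
    return 1.0 / (1.0 + (value / d0) ** 2)


def _residue_heavy(chain: Chain) -> list[np.ndarray]:
    return [r.heavy_coords() for r in chain]


def _native_contacts(native: PepComplex) -> list[tuple[int, int]]:
    rec = _residue_heavy(native.receptor)
    pep = _residue_heavy(native.peptide)
    contacts = []
    for i, rc in enumerate(rec):
        for j, pc in enumerate(pep):
            if cdist(rc, pc).min() < FNAT_CUTOFF:
                contacts.append((i, j))
    return contacts


def _interface_residues(native: PepComplex) -> tuple[list[int], list[int]]:
    rec = _residue_heavy(native.receptor)
    pep = _residue_heavy(native.peptide)
    rec_all = np.vstack(rec)
    pep_all = np.vstack(pep)
    rec_if = [i for i, rc in enumerate(rec) if cdist(rc, pep_all).min() < INTERFACE_CUTOFF]
    pep_if = [j for j, pc in enumerate(pep) if cdist(pc, rec_all).min() < INTERFACE_CUTOFF]
    return rec_if, pep_if


def dockq(model: PepComplex, native: PepComplex) -> QualityReport:
    """Full DockQ quality report of a model against its native complex."""
    check_correspondence(model, native)
    contacts = _native_contacts(native)
    if not contacts:
        raise ValueError("native complex has no cross-interface contacts")

    m_rec = _residue_heavy(model.receptor)
    m_pep = _residue_heavy(model.peptide)
    preserved = sum(
        1 for i, j in contacts if cdist(m_rec[i], m_pep[j]).min() < FNAT_CUTOFF
    )
    fnat = preserved / len(contacts)

    rec_if, pep_if = _interface_residues(native)
    mob, tgt = [], []
    for attr, idxs in (("receptor", rec_if), ("peptide", pep_if)):
        m_chain: Chain = getattr(model, attr)
        n_chain: Chain = getattr(native, attr)
        for idx in idxs:
            rm, rn = m_chain.residues[idx], n_chain.residues[idx]
            for name in BACKBONE_ATOMS:
                if name in rm.atoms and name in rn.atoms:
                    mob.append(rm.atoms[name].coord)
                    tgt.append(rn.atoms[name].coord)
    irmsd = superpose(np.array(mob), np.array(tgt)).rmsd

    lr = lrmsd(model, native)
    score = (
        fnat
        + 1.0 / (1.0 + (lr / DOCKQ_D1) ** 2)
        + 1.0 / (1.0 + (irmsd / DOCKQ_D2) ** 2)
    ) / 3.0
    return QualityReport(
        lrmsd=lr,
        lrmsd_norm=lrmsd_norm(lr),
        fnat=fnat,
        irmsd=irmsd,
        dockq=score,
        capri_class=capri_class(score),
    )


def capri_class(dockq_value: float) -> str:
    """CAPRI-style quality class of a DockQ value.

    Boundary membership goes to the higher class (0.49 -> Medium).
    """
    if not 0.0 <= dockq_value <= 1.0:
        raise ValueError(f"DockQ value out of range: {dockq_value}")
    acceptable, medium, high = CAPRI_BOUNDS
    if dockq_value >= high:
        return "High"
    if dockq_value >= medium:
        return "Medium"
    if dockq_value >= acceptable:
        return "Acceptable"
    return "Incorrect"


def _chain_atoms(chains: list[Chain]) -> "object":
    """Assemble a biotite AtomArray of the heavy atoms of the given chains."""
    import biotite.structure as struc

    records = [
        (c.id, r.author_seq, r.name3, a.name, a.element, a.coord)
        for c in chains
        for r in c
        for a in r.atoms.values()
        if a.element != "H"
    ]
    if not records:
        raise ValueError("no heavy atoms in chain(s)")
    arr = struc.AtomArray(len(records))
    arr.chain_id = np.array([r[0] for r in records])
    arr.res_id = np.array([r[1] for r in records])
    arr.res_name = np.array([r[2] for r in records])
    arr.atom_name = np.array([r[3] for r in records])
    arr.element = np.array([r[4].upper() for r in records])
    arr.coord = np.array([r[5] for r in records], dtype=np.float32)
    arr.hetero = np.zeros(len(records), dtype=bool)
    return arr


def total_sasa(chains: list[Chain]) -> float:
    """Shrake-Rupley solvent-accessible surface area of the chains, in A^2."""
    import biotite.structure as struc

    arr = _chain_atoms(chains)
    values = struc.sasa(
        arr,
        probe_radius=SASA_PROBE,
        point_number=SASA_POINTS,
        vdw_radii="Single",
    )
    return float(np.nansum(values))


def contact_surface(receptor: Chain, peptide: Chain) -> float:
    """Per-side buried interface area: (SASA_r + SASA_p - SASA_complex) / 2."""
    s_r = total_sasa([receptor])
    s_p = total_sasa([peptide])
    s_c = total_sasa([receptor, peptide])
    return max(0.0, (s_r + s_p - s_c) / 2.0)
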