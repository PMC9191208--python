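"""Synthetic complexes and native-perturbation decoy generation.

:func:`make_fixture_complex` builds a geometrically idealized peptide-
protein complex: the receptor is a two-strand groove (CA trace at 3.8 A
spacing joined by a half-circle turn) and the peptide an extended strand
lying in the groove, burying well over the 200 A^2 eligibility threshold.
It stands in for experimentally determined complexes wherever training or
benchmarking data are needed.

Decoys are made by perturbing the native peptide with a rigid rotation, a
rigid translation and per-residue backbone pivot noise.  A decoy is
*salvageable* when its whole-peptide LRMSD is below 5.5 A, or some
contiguous stretch of at least half the peptide (minimum 5 residues) has a
window LRMSD below 4.0 A in the same receptor frame.
:func:`assemble_balanced_set` draws decoys with an adaptive move magnitude
(scales grow after salvageable draws and shrink otherwise) and rejection-
samples until exactly half the set is salvageable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from . import metrics
from .structure import Atom, Chain, PepComplex, Residue, ONE_TO_THREE

SALVAGE_GLOBAL_LRMSD = 5.5  # A, whole-peptide criterion
SALVAGE_WINDOW_LRMSD = 4.0  # A, contiguous-stretch criterion
SALVAGE_MIN_WINDOW = 5      # residues

CA_SPACING = 3.8  # A, consecutive CA-CA distance of the idealized trace

#: decoy generation scheme labels; only native perturbation is generated
#: in-package, the docking schemes are reserved for externally produced sets
SCHEMES = ("native_perturbation", "rigid_body_docking", "template_based_docking")


@dataclass
class PerturbationParams:
    translation_scale: float = 4.0   # A; translation magnitude per draw
    rotation_scale: float = 20.0     # degrees; rigid rotation angle per draw
    internal_scale: float = 5.0      # degrees; per-joint backbone pivot sd
    adapt_factor: float = 1.1        # multiplicative magnitude adaptation

    def __post_init__(self):
        if min(self.translation_scale, self.rotation_scale, self.internal_scale) <= 0:
            raise ValueError("all perturbation scales must be positive")
        if self.adapt_factor <= 1.0:
            raise ValueError("adapt_factor must exceed 1")

    def scaled(self, factor: float) -> "PerturbationParams":
        return replace(
            self,
            translation_scale=self.translation_scale * factor,
            rotation_scale=self.rotation_scale * factor,
            internal_scale=self.internal_scale * factor,
        )


@dataclass
class DecoyRecord:
    complex: PepComplex
    lrmsd_to_native: float
    target: float
    salvageable: bool
    scheme: str = "native_perturbation"
    seed_state: dict | None = None


def _residue(
    name1: str, chain_id: str, index: int, ca: np.ndarray,
    direction: np.ndarray, side: np.ndarray, author_seq: int,
) -> Residue:
    """Idealized backbone around a CA position.

    N and C sit along the chain direction, O off the carbonyl, and a
    pseudo-C-beta 1.5 A along ``side``; good enough geometry for distance
    based featurization and surface burial, not for stereochemistry.
    """
    up = np.cross(direction, side)
    n_up = up / (np.linalg.norm(up) + 1e-12)
    atoms = {
        "N": Atom("N", "N", ca - 1.25 * direction + 0.45 * n_up),
        "CA": Atom("CA", "C", ca),
        "C": Atom("C", "C", ca + 1.25 * direction + 0.45 * n_up),
        "O": Atom("O", "O", ca + 1.25 * direction + 1.65 * n_up),
    }
    name3 = ONE_TO_THREE[name1]
    if name1 != "G":
        atoms["CB"] = Atom("CB", "C", ca + 1.5 * side)
    return Residue(
        name3=name3, one_letter=name1, chain_id=chain_id,
        author_seq=author_seq, index=index, atoms=atoms,
    )


def _chain_from_trace(
    chain_id: str, sequence: str, trace: np.ndarray, sides: np.ndarray
) -> Chain:
    residues = []
    for i, (aa, ca) in enumerate(zip(sequence, trace)):
        if i < len(trace) - 1:
            d = trace[i + 1] - ca
        else:
            d = ca - trace[i - 1]
        d = d / np.linalg.norm(d)
        residues.append(_residue(aa, chain_id, i, ca, d, sides[i], i + 1))
    return Chain(id=chain_id, residues=residues)


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    aas = "ARNDCQEGHILKMFPSTWYV"
    return "".join(aas[i] for i in rng.integers(0, len(aas), n))


def make_fixture_complex(
    seed: int = 0, receptor_len: int = 60, peptide_len: int = 12
) -> PepComplex:
    """Deterministic synthetic groove complex passing all eligibility filters."""
    if receptor_len < 50:
        raise ValueError("receptor_len must be >= 50")
    if not 2 <= peptide_len <= 25:
        raise ValueError("peptide_len must be in [2, 25]")
    rng = np.random.default_rng(seed)

    groove_width = 12.0
    half = groove_width / 2.0
    # Turn: circular arc out of the strand plane joining (cx, 0, 0) to
    # (cx, groove_width, 0) in m chords of exactly CA_SPACING; the arc
    # radius solving 2 R sin(asin(half/R)/m) = CA_SPACING is found
    # numerically (m = 4 is the smallest count with a solution >= half).
    from scipy.optimize import brentq

    m = 4
    radius = brentq(
        lambda r: 2.0 * r * np.sin(np.arcsin(half / r) / m) - CA_SPACING,
        half + 1e-9,
        10.0 * half,
    )
    n_turn = m  # m - 1 interior arc points + the far-strand entry point
    n1 = (receptor_len - n_turn + 1) // 2
    n2 = receptor_len - n_turn - n1

    trace = []
    sides = []
    # strand 1 along +x at y=0; side chains point into the groove (+y)
    for i in range(n1):
        trace.append([i * CA_SPACING, 0.0, 0.0])
        sides.append([0.0, 1.0, 0.0])
    # turn arc in the x = cx plane, bulging in +z
    cx = (n1 - 1) * CA_SPACING
    height = np.sqrt(radius**2 - half**2)
    center = np.array([cx, half, -height])
    v0 = np.array([cx, 0.0, 0.0]) - center
    v1 = np.array([cx, groove_width, 0.0]) - center
    phi = 2.0 * np.arcsin(half / radius)
    for k in range(1, m + 1):
        t = k / m
        point = center + (
            np.sin((1.0 - t) * phi) * v0 + np.sin(t * phi) * v1
        ) / np.sin(phi)
        trace.append(point)
        sides.append([1.0, 0.0, 0.0])
    # strand 2 along -x at y=groove_width; side chains point into the groove
    for i in range(n2):
        trace.append([cx - (i + 1) * CA_SPACING, groove_width, 0.0])
        sides.append([0.0, -1.0, 0.0])
    trace = np.array(trace)
    trace += rng.uniform(-0.02, 0.02, trace.shape)  # break exact symmetry

    receptor = _chain_from_trace(
        "R", _random_sequence(rng, receptor_len), trace, np.array(sides)
    )

    # peptide: extended strand centred in the groove, slightly above plane
    pep_trace = []
    pep_sides = []
    overlap = min(n1, n2) * CA_SPACING
    x0 = cx - (overlap + peptide_len * CA_SPACING) / 2.0 + CA_SPACING
    for i in range(peptide_len):
        pep_trace.append([x0 + i * CA_SPACING, groove_width / 2.0, 0.8])
        pep_sides.append([0.0, 1.0 if i % 2 else -1.0, 0.0])
    pep_trace = np.array(pep_trace)
    pep_trace += rng.uniform(-0.05, 0.05, pep_trace.shape)

    peptide = _chain_from_trace(
        "P", _random_sequence(rng, peptide_len), pep_trace, np.array(pep_sides)
    )
    return PepComplex(receptor=receptor, peptide=peptide, is_validated=True)


def _peptide_atom_coords(complex_: PepComplex) -> tuple[list[tuple[int, str]], np.ndarray]:
    keys, coords = [], []
    for res in complex_.peptide:
        for name, atom in res.atoms.items():
            keys.append((res.index, name))
            coords.append(atom.coord)
    return keys, np.array(coords)


def _set_peptide_coords(
    complex_: PepComplex, keys: list[tuple[int, str]], coords: np.ndarray
) -> None:
    for (idx, name), xyz in zip(keys, coords):
        complex_.peptide.residues[idx].atoms[name].coord = xyz


def propose_move(
    complex_: PepComplex,
    params: PerturbationParams,
    rng: np.random.Generator,
) -> PepComplex:
    """Perturbed copy of the peptide pose; the receptor is never touched.

    Moves, in order: per-residue backbone pivot noise (angle ~ N(0,
    internal_scale) about each CA-CA axis, rotating everything downstream),
    a rigid rotation by exactly ``rotation_scale`` degrees about a random
    axis through the peptide centroid, and a rigid translation of exactly
    ``translation_scale`` A in a random direction.
    """
    decoy = complex_.copy()
    keys, coords = _peptide_atom_coords(decoy)
    ca_pos = np.array([r.ca for r in decoy.peptide])
    n_res = len(decoy.peptide)

    if params.internal_scale > 0 and n_res > 1:
        angles = np.deg2rad(rng.normal(0.0, params.internal_scale, n_res - 1))
        for j in range(1, n_res):
            axis = ca_pos[j] - ca_pos[j - 1]
            axis = axis / (np.linalg.norm(axis) + 1e-12)
            rot = Rotation.from_rotvec(axis * angles[j - 1])
            pivot = ca_pos[j]
            downstream = np.array([k[0] >= j for k in keys])
            coords[downstream] = rot.apply(coords[downstream] - pivot) + pivot
            ca_pos[j:] = rot.apply(ca_pos[j:] - pivot) + pivot

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(axis * np.deg2rad(params.rotation_scale))
    centroid = coords.mean(axis=0)
    coords = rot.apply(coords - centroid) + centroid

    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    coords = coords + params.translation_scale * direction

    _set_peptide_coords(decoy, keys, coords)
    return decoy


def perturb_native(
    native: PepComplex,
    params: PerturbationParams,
    rng: np.random.Generator,
) -> DecoyRecord:
    """One decoy from the native pose, with its LRMSD, target and flag."""
    decoy = propose_move(native, params, rng)
    lr = metrics.lrmsd(decoy, native)
    salv, _ = is_salvageable(decoy, native)
    return DecoyRecord(
        complex=decoy,
        lrmsd_to_native=lr,
        target=metrics.lrmsd_norm(lr),
        salvageable=salv,
        scheme="native_perturbation",
    )


def is_salvageable(
    decoy: PepComplex, native: PepComplex
) -> tuple[bool, dict]:
    """Salvageability flag plus diagnostics (global LRMSD, best window).

    True when the whole-peptide LRMSD is below 5.5 A, or any contiguous
    window of >= max(ceil(L/2), 5) residues has a window LRMSD below 4.0 A
    in the whole-receptor superposition frame (no per-window refit).
    """
    metrics.check_correspondence(decoy, native)
    n_res = len(decoy.peptide)
    if n_res < 2:
        raise ValueError("peptide must have at least 2 residues")
    sup = metrics.receptor_superposition(decoy, native)

    sq_by_res: list[np.ndarray] = []
    for rm, rn in zip(decoy.peptide, native.peptide):
        devs = [
            np.sum((sup.apply(rm.atoms[n].coord) - rn.atoms[n].coord) ** 2)
            for n in metrics.BACKBONE_ATOMS
            if n in rm.atoms and n in rn.atoms
        ]
        sq_by_res.append(np.array(devs))

    all_sq = np.concatenate(sq_by_res)
    global_lrmsd = float(np.sqrt(all_sq.mean()))

    min_window = max(int(np.ceil(n_res / 2.0)), SALVAGE_MIN_WINDOW)
    best = {"start": 0, "length": n_res, "window_lrmsd": global_lrmsd}
    window_hit = False
    for length in range(min(min_window, n_res), n_res + 1):
        for start in range(0, n_res - length + 1):
            chunk = np.concatenate(sq_by_res[start : start + length])
            w_rmsd = float(np.sqrt(chunk.mean()))
            if w_rmsd < best["window_lrmsd"]:
                best = {"start": start, "length": length, "window_lrmsd": w_rmsd}
            if length >= min_window and w_rmsd < SALVAGE_WINDOW_LRMSD:
                window_hit = True
    flag = global_lrmsd < SALVAGE_GLOBAL_LRMSD or window_hit
    diag = {"lrmsd": global_lrmsd, "min_window": min_window, **best}
    return flag, diag


def assemble_balanced_set(
    native: PepComplex,
    n: int,
    params: PerturbationParams | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int | None = None,
) -> list[DecoyRecord]:
    """Exactly n/2 salvageable and n/2 unsalvageable decoys of one native.

    After every draw all move scales are multiplied by ``adapt_factor`` if
    the draw was salvageable and divided by it otherwise, steering the
    generator toward the salvageability boundary; draws in an already full
    category are discarded.
    """
    if n < 2 or n % 2:
        raise ValueError("n must be an even number >= 2")
    params = params or PerturbationParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    max_attempts = max_attempts or 200 * n

    quota = n // 2
    kept: dict[bool, list[DecoyRecord]] = {True: [], False: []}
    current = params
    for attempt in range(max_attempts):
        record = perturb_native(native, current, rng)
        factor = current.adapt_factor if record.salvageable else 1.0 / current.adapt_factor
        current = current.scaled(factor)
        bucket = kept[record.salvageable]
        if len(bucket) < quota:
            bucket.append(record)
        if len(kept[True]) == quota and len(kept[False]) == quota:
            out = kept[True] + kept[False]
            order = rng.permutation(n)
            return [out[i] for i in order]
    raise RuntimeError(
        f"balanced set unreachable in {max_attempts} attempts "
        f"(salvageable {len(kept[True])}/{quota}, "
        f"unsalvageable {len(kept[False])}/{quota})"
    )


def make_quality_range_set(
    native: PepComplex,
    n: int,
    rng: np.random.Generator,
    translation_range: tuple[float, float] = (0.3, 8.0),
    rotation_range: tuple[float, float] = (1.0, 40.0),
    internal_range: tuple[float, float] = (0.5, 10.0),
) -> list[DecoyRecord]:
    """Decoys spanning the whole quality range, for evaluation.

    Unlike the adaptive balanced generator, which concentrates draws near
    the salvageability boundary, each decoy here gets fixed move scales
    drawn uniformly from wide ranges, giving LRMSDs spread from near-native
    to clearly incorrect — the appropriate test bed for rank correlation
    between a score and true quality.
    """
    out = []
    for _ in range(n):
        params = PerturbationParams(
            translation_scale=float(rng.uniform(*translation_range)),
            rotation_scale=float(rng.uniform(*rotation_range)),
            internal_scale=float(rng.uniform(*internal_range)),
        )
        out.append(perturb_native(native, params, rng))
    return out


def write_decoy_set(records: list[DecoyRecord], directory) -> "object":
    """Serialize decoys as PDB files plus a tab-separated manifest."""
    import os

    from .structure import write_pdb

    os.makedirs(directory, exist_ok=True)
    manifest_path = os.path.join(directory, "manifest.tsv")
    tmp = manifest_path + ".tmp"
    with open(tmp, "w") as fh:
        fh.write("file\tscheme\tlrmsd\ttarget\tsalvageable\n")
        for i, rec in enumerate(records):
            name = f"decoy_{i:04d}.pdb"
            pdb_tmp = os.path.join(directory, name + ".tmp")
            with open(pdb_tmp, "w") as pf:
                pf.write(write_pdb(rec.complex))
            os.replace(pdb_tmp, os.path.join(directory, name))
            fh.write(
                f"{name}\t{rec.scheme}\t{rec.lrmsd_to_native:.3f}"
                f"\t{rec.target:.4f}\t{int(rec.salvageable)}\n"
            )
    os.replace(tmp, manifest_path)
    return manifest_path
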