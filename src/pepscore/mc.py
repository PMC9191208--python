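"""Metropolis Monte-Carlo refinement of a peptide pose.

The energy is a simple residue-level base term (soft-sphere clash penalty
plus a capped contact reward across the interface) optionally combined
with the learned quality score as an additional term ``-w * score``, so
higher predicted quality lowers the energy.  There is deliberately no
gradient minimization stage anywhere in the loop.  An *oracle* mode
replaces the learned term with ``-w * lrmsd_norm(true LRMSD)`` against a
known native, used to validate that a perfect score term steers sampling
toward the native pose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import metrics
from .decoys import PerturbationParams, propose_move
from .gnn import ModelParams, forward
from .graph import build_graph, reference_point
from .structure import PepComplex

logger = logging.getLogger(__name__)

CLASH_DISTANCE = 3.0   # A, reference-point distance below which pairs clash
CLASH_WEIGHT = 25.0    # energy units per squared A of overlap
CONTACT_DISTANCE = 8.0  # A, reference-point contact reward distance
CONTACT_CAP = 4        # max rewarded contacts per peptide residue


@dataclass
class EnergyTerms:
    base_energy: float
    learned_term: float
    weight: float

    @property
    def total(self) -> float:
        return self.base_energy + self.learned_term


@dataclass
class MCConfig:
    n_steps: int = 200
    kT: float = 1.0
    move_scales: PerturbationParams = field(
        default_factory=lambda: PerturbationParams(
            translation_scale=0.5, rotation_scale=5.0, internal_scale=2.0
        )
    )
    weight: float = 1.0
    seed: int = 0
    snapshot_stride: int = 5
    oracle_native: PepComplex | None = None

    def __post_init__(self):
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


@dataclass
class Snapshot:
    complex: PepComplex
    energy: EnergyTerms
    accepted: bool
    step: int


@dataclass
class MCTrajectory:
    snapshots: list[Snapshot]
    n_accepted: int
    n_steps: int
    final: Snapshot

    @property
    def best(self) -> Snapshot:
        return min(self.snapshots, key=lambda s: (s.energy.total, s.step))


def base_energy(complex_: PepComplex) -> float:
    """Soft-sphere clash penalty minus capped cross-chain contact reward."""
    rec = np.array([reference_point(r) for r in complex_.receptor])
    pep = np.array([reference_point(r) for r in complex_.peptide])
    d = cdist(pep, rec)
    clash = CLASH_WEIGHT * np.sum(np.clip(CLASH_DISTANCE - d, 0.0, None) ** 2)
    contacts_per_pep = np.sum(d <= CONTACT_DISTANCE, axis=1)
    reward = np.sum(np.minimum(contacts_per_pep, CONTACT_CAP))
    return float(clash - reward)


def _learned_term(
    complex_: PepComplex,
    params: ModelParams | None,
    config: MCConfig,
) -> float:
    if config.oracle_native is not None:
        lr = metrics.lrmsd(complex_, config.oracle_native)
        return -config.weight * metrics.lrmsd_norm(lr)
    if params is None or config.weight == 0.0:
        return 0.0
    return -config.weight * forward(build_graph(complex_), params).score


def energy_of(
    complex_: PepComplex, params: ModelParams | None, config: MCConfig
) -> EnergyTerms:
    return EnergyTerms(
        base_energy=base_energy(complex_),
        learned_term=_learned_term(complex_, params, config),
        weight=config.weight,
    )


def metropolis_step(
    current_total: float,
    proposal_total: float,
    kT: float,
    rng: np.random.Generator,
) -> bool:
    """Standard Metropolis acceptance on the total energy difference."""
    if not np.isfinite(proposal_total):
        logger.warning("non-finite proposal energy; rejected")
        return False
    delta = proposal_total - current_total
    if delta <= 0:
        return True
    return bool(rng.random() < np.exp(-delta / kT))


def refine(
    start: PepComplex,
    params: ModelParams | None,
    config: MCConfig,
) -> MCTrajectory:
    """Metropolis refinement of the peptide pose; the receptor never moves.

    Snapshots (including rejected proposals) are recorded every
    ``snapshot_stride`` steps; the start and final states are always kept.
    """
    rng = np.random.default_rng(config.seed)
    state = start.copy()
    state_energy = energy_of(state, params, config)
    snapshots = [Snapshot(state.copy(), state_energy, True, 0)]
    n_accepted = 0
    for step in range(1, config.n_steps + 1):
        proposal = propose_move(state, config.move_scales, rng)
        prop_energy = energy_of(proposal, params, config)
        accepted = metropolis_step(
            state_energy.total, prop_energy.total, config.kT, rng
        )
        if accepted:
            state, state_energy = proposal, prop_energy
            n_accepted += 1
        if step % config.snapshot_stride == 0:
            snapshots.append(Snapshot(proposal, prop_energy, accepted, step))
    final = Snapshot(state, state_energy, True, config.n_steps)
    return MCTrajectory(
        snapshots=snapshots,
        n_accepted=n_accepted,
        n_steps=config.n_steps,
        final=final,
    )


def select_models(trajectories: list[MCTrajectory], k: int) -> list[Snapshot]:
    """Top-k snapshots by total energy across trajectories.

    Ties break by earlier step, then by trajectory order.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    ranked = sorted(
        (
            (snap.energy.total, snap.step, ti, si, snap)
            for ti, traj in enumerate(trajectories)
            for si, snap in enumerate(traj.snapshots)
        ),
        key=lambda t: t[:4],
    )
    if k > len(ranked):
        logger.warning("requested %d models but only %d available", k, len(ranked))
    return [r[4] for r in ranked[:k]]
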