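"""Polymer system definition, interaction tables, schedules and chain
initialisation.

The model represents a chromatin segment as a FENE-bonded bead chain with
per-bead chromatin-state labels.  Nonbonded interactions are state-pair
12-6 Lennard-Jones terms (truncated and shifted); Hi-C loop anchors are
tethered by stiff harmonic restraints; a cubic box with repulsive walls
confines the chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..exceptions import InitializationError, ValidationError
from .potentials import WCA_CUTOFF

__all__ = [
    "PolymerParams",
    "PolymerSystem",
    "Phase",
    "SimulationSchedule",
    "build_system",
    "interaction_table",
    "reference_schedule",
    "desk_schedule",
    "init_conformation",
]


@dataclass
class PolymerParams:
    """Scalar model parameters in reduced units.

    Defaults follow the published chromatin model: FENE K_S = 30 eps/sigma^2
    with R_0 = 1.6 sigma; loop restraints K_L = 300 eps/sigma^2 with
    R0L = 1.2 sigma; wall strength eps_W = 1; uniform equilibration strength
    eps_G = 1; cubic box of side L = 35 sigma; Langevin damping gamma = 1/tau
    at temperature T = 1.
    """

    k_s: float = 30.0
    r0: float = 1.6
    k_l: float = 300.0
    r0l: float = 1.2
    eps_w: float = 1.0
    eps_g: float = 1.0
    box: float = 35.0
    gamma: float = 1.0
    temperature: float = 1.0
    sigma: float = 1.0


@dataclass
class PolymerSystem:
    """A bead chain with chromatin states, loops and interaction tables."""

    states: np.ndarray              # (n,) int state codes
    state_names: List[str]
    loops: np.ndarray               # (L, 2) int anchor pairs
    eps_table: np.ndarray           # (S, S) pair interaction strengths
    cutoff_table: np.ndarray        # (S, S) pair cutoffs (sigma)
    params: PolymerParams = field(default_factory=PolymerParams)

    @property
    def n_beads(self) -> int:
        return len(self.states)

    def uniform_tables(self) -> Tuple[np.ndarray, np.ndarray]:
        """Purely repulsive uniform-strength tables for equilibration."""
        s = len(self.state_names)
        return (np.full((s, s), self.params.eps_g),
                np.full((s, s), WCA_CUTOFF))


def interaction_table(
    state_names: Sequence[str],
    pairs: Optional[Dict[Tuple[str, str], Tuple[float, float]]] = None,
    default_eps: float = 1.0,
    default_cutoff: float = WCA_CUTOFF,
) -> Tuple[np.ndarray, np.ndarray]:
    """Build symmetric (eps, cutoff) tables from a sparse pair mapping.

    Unlisted pairs default to purely repulsive WCA (eps=1, cutoff=2^(1/6));
    attractive pairs conventionally use a 2.5 sigma cutoff.
    """
    s = len(state_names)
    idx = {name: i for i, name in enumerate(state_names)}
    eps = np.full((s, s), default_eps)
    cut = np.full((s, s), default_cutoff)
    for (a, b), (e, rc) in (pairs or {}).items():
        i, j = idx[a], idx[b]
        eps[i, j] = eps[j, i] = e
        cut[i, j] = cut[j, i] = rc
    return eps, cut


def build_system(
    states: Sequence,
    loops: Optional[Sequence[Tuple[int, int]]] = None,
    eps_table: Optional[np.ndarray] = None,
    cutoff_table: Optional[np.ndarray] = None,
    pair_interactions: Optional[Dict] = None,
    params: Optional[PolymerParams] = None,
    state_names: Optional[Sequence[str]] = None,
    **overrides,
) -> PolymerSystem:
    """Validate and assemble a PolymerSystem.

    ``states`` is a sequence of chromatin-state labels, one per bead.
    Interactions come either as dense ``eps_table``/``cutoff_table`` arrays
    over the sorted unique states, or as a ``pair_interactions`` mapping
    {(state_a, state_b): (eps, cutoff)}.  ``state_names`` fixes the state
    space explicitly so that systems differing only in their per-bead
    annotations share one interaction table.  Scalar parameters may be
    overridden by keyword (e.g. ``box=20.0``).
    """
    states = list(states)
    if len(states) < 2:
        raise ValidationError("need at least 2 beads")
    if state_names is None:
        state_names = sorted({str(s) for s in states})
    else:
        state_names = [str(s) for s in state_names]
        missing = {str(s) for s in states} - set(state_names)
        if missing:
            raise ValidationError(f"states {sorted(missing)} not in state_names")
    codes = np.array([state_names.index(str(s)) for s in states], dtype=np.int64)

    n = len(states)
    loop_arr = np.asarray(list(loops or []), dtype=np.int64).reshape(-1, 2)
    for i, j in loop_arr:
        if not (0 <= i < n and 0 <= j < n):
            raise ValidationError(f"loop anchor ({i}, {j}) out of range for {n} beads")
        if i == j:
            raise ValidationError(f"loop anchors must be distinct, got ({i}, {j})")
    if len(loop_arr):
        canon = np.sort(loop_arr, axis=1)
        uniq, idx = np.unique(canon, axis=0, return_index=True)
        if len(uniq) < len(loop_arr):
            warnings.warn("duplicate loop anchors removed", UserWarning)
        loop_arr = canon[np.sort(idx)]

    s = len(state_names)
    if eps_table is not None:
        eps = np.asarray(eps_table, dtype=float)
        cut = (np.asarray(cutoff_table, dtype=float) if cutoff_table is not None
               else np.full((s, s), WCA_CUTOFF))
        if eps.shape != (s, s) or cut.shape != (s, s):
            raise ValidationError(f"interaction tables must be {s}x{s}")
        if not np.allclose(eps, eps.T) or not np.allclose(cut, cut.T):
            raise ValidationError("interaction tables must be symmetric in the two states")
    else:
        eps, cut = interaction_table(state_names, pair_interactions)
    if (eps < 0).any():
        raise ValidationError("interaction strengths must be >= 0")

    p = params or PolymerParams()
    if overrides:
        p = replace(p, **overrides)
    return PolymerSystem(states=codes, state_names=state_names, loops=loop_arr,
                         eps_table=eps, cutoff_table=cut, params=p)


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

@dataclass
class Phase:
    """One stage of the simulation protocol.

    mode: "soft" (cosine push-off, prefactor ramped a_start -> a_end),
    "uniform" (state-blind repulsive LJ at eps_G) or "state" (state-pair LJ
    plus loop restraints).  Frames are recorded only in phases with
    ``save=True``.
    """

    mode: str
    n_steps: int
    dt: float
    a_start: float = 0.0
    a_end: float = 100.0
    save: bool = False

    def __post_init__(self):
        if self.mode not in ("soft", "uniform", "state"):
            raise ValidationError(f"unknown phase mode {self.mode!r}")
        if self.n_steps < 0 or self.dt <= 0:
            raise ValidationError("need n_steps >= 0 and dt > 0")


@dataclass
class SimulationSchedule:
    phases: List[Phase]
    save_interval: int = 1000

    def __post_init__(self):
        if self.save_interval < 1:
            raise ValidationError("save_interval must be >= 1")


def reference_schedule() -> SimulationSchedule:
    """The full published protocol: soft push-off (4e5 steps, dt=0.01,
    A ramped 0->100), three uniform-LJ equilibration stages (4e5, 5e5, 5e5
    steps at dt = 1e-6, 1e-4, 1e-2), a slow state-potential stage (1e6 steps
    at dt = 1e-6) and a 2e6-step production run at dt = 0.01 saved every
    1000 steps.  Intended for cluster use; see desk_schedule for tests.
    """
    return SimulationSchedule(
        phases=[
            Phase("soft", 400_000, 0.01, 0.0, 100.0),
            Phase("uniform", 400_000, 1e-6),
            Phase("uniform", 500_000, 1e-4),
            Phase("uniform", 500_000, 1e-2),
            Phase("state", 1_000_000, 1e-6),
            Phase("state", 2_000_000, 1e-2, save=True),
        ],
        save_interval=1000,
    )


def desk_schedule(production_steps: int = 50_000,
                  save_interval: int = 1000) -> SimulationSchedule:
    """Reduced-scale protocol with the same phase structure, sized for a
    single CPU (hundreds of beads, minutes of wall time)."""
    return SimulationSchedule(
        phases=[
            Phase("soft", 4_000, 0.01, 0.0, 100.0),
            Phase("uniform", 1_000, 1e-5),
            Phase("uniform", 2_000, 1e-3),
            Phase("uniform", 3_000, 1e-2),
            Phase("state", 2_000, 1e-3),
            Phase("state", production_steps, 1e-2, save=True),
        ],
        save_interval=save_interval,
    )


# ---------------------------------------------------------------------------
# initial conformation
# ---------------------------------------------------------------------------

def init_conformation(n_beads: int, seed: Optional[int] = None,
                      box: float = 35.0, bond_low: float = 0.9,
                      bond_high: float = 1.1, min_sep: float = 0.7,
                      wall_margin: float = 1.5,
                      max_restarts: int = 50) -> np.ndarray:
    """Self-avoiding worm-like chain inside the box.

    Consecutive beads are separated by a bond length drawn uniformly from
    (bond_low, bond_high); no two beads approach closer than ``min_sep`` and
    every bead keeps ``wall_margin`` clear of the walls.  Deterministic for a
    given seed.
    """
    rng = np.random.default_rng(seed)
    half = box / 2.0 - wall_margin
    if half <= 0:
        raise InitializationError("box too small for the wall margin")
    for _ in range(max_restarts):
        pts = np.empty((n_beads, 3))
        pts[0] = rng.uniform(-half / 2, half / 2, size=3)
        ok = True
        for i in range(1, n_beads):
            placed = False
            for _attempt in range(100):
                vec = rng.standard_normal(3)
                vec /= np.linalg.norm(vec)
                cand = pts[i - 1] + vec * rng.uniform(bond_low, bond_high)
                if np.abs(cand).max() > half:
                    continue
                d2 = ((pts[:i] - cand) ** 2).sum(axis=1)
                # self-avoidance against all but the immediate predecessor
                if i >= 2 and d2[:i - 1].min() < min_sep ** 2:
                    continue
                pts[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    raise InitializationError(
        f"could not place a {n_beads}-bead self-avoiding chain in a box of {box} sigma; "
        "try a larger box")
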