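"""Stochastic 2D lattice model of euchromatin as an active microemulsion.

Chromatin is represented by linearly connected chains of lattice sites
(transcriptionally inactive or active) immersed in RNA-binding proteins
(RBPs) that are unbound or RNA-bound.  Dynamics interleave two processes:

* **Neighbor swaps** (Kawasaki exchange): a uniformly random Chebyshev-
  adjacent pair is proposed; swaps that would break chain connectivity or
  move a tethered site are rejected outright; otherwise the swap is accepted
  with probability ``min(1, exp(-dE))`` (Metropolis, default) or
  ``min(1, exp(delta_e_min - dE))`` (normalized variant), where ``dE`` sums
  mismatch costs over the 8-neighborhoods involved.  Transcripts resident on
  a site travel with it.
* **Chemical conversions** on a fixed clock ``dt_chem = 0.1 / k_max``:
  chromatin activation (on permissive chains only) / deactivation, transcript
  production on active chromatin, transcript hand-off to a neighboring RBP,
  per-transcript decay, and permissive/restrictive chain switching.

Scenario builders reproduce the named experiments: exploratory uniform
dispersion / phase separation / microphase setups (50x50, 100 chains of 5),
the post-mitosis inhibitor experiments (100x100, 100 chains of 50, boundary
tethering), and transcription onset at a single central locus.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels as K
from .params import EnergyParams, RateParams, Schedule, ScenarioConfig

__all__ = [
    "SimulationState",
    "ChromatinChain",
    "SwapOutcome",
    "ConversionCounts",
    "Trajectory",
    "build_scenario",
    "local_energy",
    "compute_delta_e_min",
    "attempt_swap",
    "chemical_update",
    "apply_inhibitor",
    "run",
    "run_scenario",
    "seed_rng",
    "swap_acceptance_probability",
    "cost_matrix",
]

_STATUS_NAMES = {
    K.REJ_PADDING: "rejected_padding",
    K.REJ_TETHER: "rejected_tethered",
    K.REJ_CONNECTIVITY: "rejected_connectivity",
    K.REJ_ENERGY: "rejected_energy",
    K.ACCEPTED: "accepted",
}

_PAD_CODE = {"rna_rbp": 0, "inactive_chromatin": 1, "none": 2}


def seed_rng(state: "SimulationState", seed: int) -> None:
    """Seed the state's kernel RNG stream (``run`` does this itself)."""
    state._rng[0] = np.uint64(seed)


def cost_matrix(energy: EnergyParams) -> np.ndarray:
    """5x5 symmetric pair-cost matrix over species codes (index 4 = inert)."""
    w = np.zeros((5, 5))
    w[2, 1] = w[1, 2] = energy.w_inactive_boundRBP
    w[2, 3] = w[3, 2] = energy.w_inactive_active
    w[3, 3] = energy.w_active_active
    return w


def _cost_diff_matrix(energy: EnergyParams) -> np.ndarray:
    """Flattened difference table dmat[(ca*5+cb)*5+cn] = w[cb,cn]-w[ca,cn]."""
    w = cost_matrix(energy)
    d = np.zeros(125)
    for ca in range(5):
        for cb in range(5):
            for cn in range(5):
                d[(ca * 5 + cb) * 5 + cn] = w[cb, cn] - w[ca, cn]
    return d


def _exp_lookup(energy: EnergyParams):
    """(1/q, table) for tabulated Metropolis factors when every cost is an
    integer multiple of a common quantum q; (0.0, tiny array) otherwise."""
    costs = [c for c in (energy.w_inactive_boundRBP, energy.w_inactive_active,
                         energy.w_active_active) if c > 0]
    if not costs:
        return 0.0, np.zeros(1)
    q = min(costs)
    for c in costs:
        if abs(c / q - round(c / q)) > 1e-9:
            return 0.0, np.zeros(1)
    kmax = int(round(14 * max(costs) / q)) + 2
    table = np.exp(-q * np.arange(kmax + 1))
    return 1.0 / q, table


@dataclass
class ChromatinChain:
    """Ordered chain of chromatin sites; consecutive members are Chebyshev
    neighbors.  ``state`` is ``"permissive"`` or ``"restrictive"``."""

    positions: List[Tuple[int, int]]
    state: str


@dataclass
class SwapOutcome:
    a: Tuple[int, int]
    b: Optional[Tuple[int, int]]
    delta_e: float
    p_swap: float
    accepted: bool
    status: str


@dataclass
class ConversionCounts:
    activations: int = 0
    deactivations: int = 0
    productions: int = 0
    transfers: int = 0
    decays: int = 0
    chain_on: int = 0
    chain_off: int = 0

    @classmethod
    def from_array(cls, arr) -> "ConversionCounts":
        return cls(*(int(x) for x in arr))


class SimulationState:
    """Lattice occupancy, chains, transcript counts and the simulation clock.

    Internally the grid is padded by one ring of static sites; all public
    coordinates are 0-based interior ``(y, x)`` pairs.
    """

    def __init__(self, width: int, height: int, padding: str = "rna_rbp",
                 config: Optional[ScenarioConfig] = None):
        if padding not in _PAD_CODE:
            raise ValueError(f"unknown padding species {padding!r}")
        self.width = int(width)
        self.height = int(height)
        self.padding_species = padding
        self.config = config
        self.time = 0.0
        Wp, Hp = self.width + 2, self.height + 2
        M = Wp * Hp
        self._Wp = Wp
        self._rng = np.zeros(1, np.uint64)
        self.kind = np.zeros(M, np.uint8)
        self.code = np.zeros(M, np.uint8)
        self.active = np.zeros(M, np.uint8)
        self.rna = np.zeros(M, np.int32)
        self.chain_id = np.full(M, -1, np.int32)
        self.chain_index = np.full(M, -1, np.int32)
        self.tethered = np.zeros(M, np.uint8)
        self.valid = np.zeros(M, np.uint8)
        self.boundary_ring = np.zeros(M, np.uint8)
        self.ch_sites = np.zeros((0, 0), np.int32)
        self.ch_len = np.zeros(0, np.int32)
        self.ch_perm = np.zeros(0, np.uint8)

        yy, xx = np.mgrid[0:Hp, 0:Wp]
        interior2d = (yy >= 1) & (yy <= self.height) & (xx >= 1) & (xx <= self.width)
        self.valid[interior2d.ravel()] = 1
        ring = interior2d & (
            (yy == 1) | (yy == self.height) | (xx == 1) | (xx == self.width)
        )
        self.boundary_ring[ring.ravel()] = 1
        self.interior = np.flatnonzero(self.valid).astype(np.int64)
        idx = np.arange(M, dtype=np.int64)
        self.ycoord = (idx // Wp).astype(np.int32)
        self.xcoord = (idx % Wp).astype(np.int32)
        steps = K.NEIGHBOR_STEPS
        self.offs = (steps[:, 0] * Wp + steps[:, 1]).astype(np.int64)
        # padding occupancy
        pad = ~interior2d
        padf = pad.ravel()
        if padding == "rna_rbp":
            self.kind[padf] = K.KIND_RBP
            self.rna[padf] = 1
        elif padding == "inactive_chromatin":
            self.kind[padf] = K.KIND_CHROM
        else:
            self.kind[padf] = K.KIND_INERT
        self.tethered[padf] = 1
        self.refresh_code()

    def refresh_code(self) -> None:
        """Recompute the cached species-code array from the raw fields."""
        code = np.zeros_like(self.kind)
        rbp = self.kind == K.KIND_RBP
        code[rbp & (self.rna > 0)] = 1
        chrom = self.kind == K.KIND_CHROM
        code[chrom] = 2 + self.active[chrom]
        code[self.kind == K.KIND_INERT] = 4
        self.code = code

    # -- coordinate helpers -------------------------------------------------
    def _flat(self, pos: Tuple[int, int]) -> int:
        y, x = pos
        if not (0 <= y < self.height and 0 <= x < self.width):
            raise IndexError(f"position {pos} outside lattice")
        return (y + 1) * self._Wp + (x + 1)

    def _pos(self, i: int) -> Tuple[int, int]:
        return i // self._Wp - 1, i % self._Wp - 1

    # -- views --------------------------------------------------------------
    def _interior2d(self, arr) -> np.ndarray:
        return arr.reshape(self.height + 2, self._Wp)[1:-1, 1:-1]

    def chromatin_mask(self) -> np.ndarray:
        return self._interior2d(self.kind) == K.KIND_CHROM

    def active_mask(self) -> np.ndarray:
        return (self._interior2d(self.kind) == K.KIND_CHROM) & (
            self._interior2d(self.active) == 1
        )

    def rna_counts(self) -> np.ndarray:
        return self._interior2d(self.rna).astype(np.int64)

    @property
    def chains(self) -> List[ChromatinChain]:
        out = []
        for c in range(self.ch_len.shape[0]):
            n = int(self.ch_len[c])
            pos = [self._pos(int(self.ch_sites[c, j])) for j in range(n)]
            out.append(
                ChromatinChain(pos, "permissive" if self.ch_perm[c] else "restrictive")
            )
        return out

    def counts(self) -> dict:
        kin = self._interior2d(self.kind)
        act = self._interior2d(self.active)
        rna = self._interior2d(self.rna)
        chrom = kin == K.KIND_CHROM
        rbp = kin == K.KIND_RBP
        return {
            "time": self.time,
            "n_chromatin": int(chrom.sum()),
            "n_active": int((chrom & (act == 1)).sum()),
            "n_rbp": int(rbp.sum()),
            "n_bound_rbp": int((rbp & (rna > 0)).sum()),
            "total_rna": int(rna.sum()),
        }

    def copy(self) -> "SimulationState":
        st = SimulationState.__new__(SimulationState)
        st.__dict__.update(self.__dict__)
        for name in ("kind", "code", "active", "rna", "chain_id",
                     "chain_index", "tethered", "ch_sites", "ch_len",
                     "ch_perm", "_rng"):
            setattr(st, name, getattr(self, name).copy())
        return st

    # -- persistence ----------------------------------------------------------
    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            width=self.width, height=self.height,
            padding=_PAD_CODE[self.padding_species], time=self.time,
            kind=self.kind, active=self.active, rna=self.rna,
            chain_id=self.chain_id, chain_index=self.chain_index,
            tethered=self.tethered, ch_sites=self.ch_sites,
            ch_len=self.ch_len, ch_perm=self.ch_perm,
        )

    @classmethod
    def from_npz(cls, path) -> "SimulationState":
        with np.load(path) as z:
            pad = [k for k, v in _PAD_CODE.items() if v == int(z["padding"])][0]
            st = cls(int(z["width"]), int(z["height"]), pad)
            st.time = float(z["time"])
            for name in ("kind", "active", "rna", "chain_id", "chain_index",
                         "tethered"):
                getattr(st, name)[:] = z[name]
            st.ch_sites = z["ch_sites"].astype(np.int32)
            st.ch_len = z["ch_len"].astype(np.int32)
            st.ch_perm = z["ch_perm"].astype(np.uint8)
        st.refresh_code()
        return st

    def _kernel_args(self):
        return (self.kind, self.active, self.rna, self.code, self.chain_id,
                self.chain_index, self.tethered, self.valid,
                self.boundary_ring, self.ch_sites, self.ch_len)


# ---------------------------------------------------------------------------
# scenario construction


def build_scenario(config: ScenarioConfig, seed: Optional[int] = None) -> SimulationState:
    """Construct the initial lattice for a named scenario.

    Chains are laid out serpentine-wise, centered in a regular grid of
    ``box x box`` site boxes; the remaining interior is unbound RBP.  The
    padding ring, RNA pre-binding, chain permissive states and boundary
    tethering follow the scenario definition.  Placement is deterministic;
    ``seed`` is accepted for interface symmetry.
    """
    st = SimulationState(config.width, config.height, config.padding, config)
    nbx = config.width // config.box
    nby = config.height // config.box
    if config.n_chains > nbx * nby:
        raise ValueError("chain layout overflows the lattice")
    L = config.chain_length
    rows = -(-L // config.box)  # ceil
    row0 = (config.box - rows) // 2
    n = config.n_chains
    st.ch_sites = np.zeros((n, L), np.int32)
    st.ch_len = np.full(n, L, np.int32)
    st.ch_perm = np.ones(n, np.uint8) if config.all_chains_permissive else np.zeros(n, np.uint8)

    for c in range(n):
        by, bx = divmod(c, nbx)
        oy, ox = by * config.box, bx * config.box
        placed = 0
        for r in range(rows):
            y = oy + row0 + r
            xs = range(config.box) if r % 2 == 0 else range(config.box - 1, -1, -1)
            for x in xs:
                if placed >= L:
                    break
                pos = (y, ox + x)
                i = st._flat(pos)
                st.kind[i] = K.KIND_CHROM
                st.rna[i] = 0
                st.chain_id[i] = c
                st.chain_index[i] = placed
                st.ch_sites[c, placed] = i
                placed += 1
    if config.prebind_rna:
        rbp = (st.kind == K.KIND_RBP) & (st.valid == 1)
        st.rna[rbp] = 1
    st.refresh_code()
    if config.tether_boundary:
        chrom_ring = (st.kind == K.KIND_CHROM) & (st.boundary_ring == 1)
        st.tethered[chrom_ring] = 1
    st.time = 0.0
    return st


# ---------------------------------------------------------------------------
# energies


def local_energy(state: SimulationState, positions: Iterable[Tuple[int, int]],
                 energy: EnergyParams) -> float:
    """Sum of mismatch costs over all unordered 8-neighborhood pairs touching
    the given interior positions (each pair counted once; the padding ring
    counts as neighbors)."""
    w = cost_matrix(energy)
    seen = set()
    total = 0.0
    for pos in positions:
        a = state._flat(pos)
        for off in state.offs:
            b = a + int(off)
            pair = (a, b) if a < b else (b, a)
            if pair in seen:
                continue
            seen.add(pair)
            total += w[state.code[a], state.code[b]]
    return float(total)


def compute_delta_e_min(energy: EnergyParams) -> float:
    """Largest possible energy drop of any swap (a value <= 0).

    Enumerates the species of the two swapped sites and, independently, the
    species filling each of their 7 non-partner neighbor slots (the partner
    pair itself is unchanged by the swap).  Because the energy is additive
    over slots, minimizing each slot independently is an exhaustive search
    over all local configurations.
    """
    w = cost_matrix(energy)
    species = range(4)
    best = 0.0
    for ca in species:
        for cb in species:
            da = min(w[cb, n] - w[ca, n] for n in species)
            db = min(w[ca, n] - w[cb, n] for n in species)
            best = min(best, 7 * da + 7 * db)
    return float(best)


def swap_acceptance_probability(delta_e: float, energy: EnergyParams) -> float:
    """Acceptance probability for an energy change under the configured rule."""
    rule = 0 if energy.acceptance == "metropolis" else 1
    return float(K._p_accept(delta_e, rule, energy.delta_e_min))


# ---------------------------------------------------------------------------
# single-step operations


def attempt_swap(state: SimulationState, energy: EnergyParams,
                 rng: np.random.Generator) -> SwapOutcome:
    """Propose and (probabilistically) execute one neighbor swap.

    The proposal is a uniformly random (interior site, 8-neighbor direction)
    pair.  This Python-level path draws the proposal index and one acceptance
    uniform from ``rng`` per call; it shares its feasibility/energy/swap code
    with the batched kernel.
    """
    rule = 0 if energy.acceptance == "metropolis" else 1
    dEmin = energy.delta_e_min
    r = int(rng.integers(0, state.interior.shape[0] * 8))
    a = int(state.interior[r >> 3])
    b = a + int(state.offs[r & 7])
    u = float(rng.random())
    status, dE, p = K.attempt_once(
        *state._kernel_args(), _cost_diff_matrix(energy), state.offs,
        state.ycoord, state.xcoord,
        1 if (state.config is not None and state.config.tether_boundary) else 0,
        rule, dEmin, a, b, u,
    )
    bpos = state._pos(b) if state.valid[b] == 1 else None
    return SwapOutcome(
        a=state._pos(a), b=bpos, delta_e=float(dE), p_swap=float(p),
        accepted=status == K.ACCEPTED, status=_STATUS_NAMES[int(status)],
    )


def chemical_update(state: SimulationState, rates: RateParams,
                    schedule: Schedule, seed: Optional[int] = None) -> ConversionCounts:
    """Execute one chemical interval on every interior site.

    Raises if every rate is zero (the chemical clock is undefined; skip
    chemistry instead).  Uses the kernel RNG stream; pass ``seed`` or call
    :func:`seed_rng` beforehand for reproducibility.
    """
    if rates.k_max == 0:
        raise ValueError("all rates are zero: dt_chem undefined; skip chemistry")
    if seed is not None:
        seed_rng(state, seed)
    p = schedule.conversion_probability
    counts = np.zeros(7, np.int64)
    K.chem_step(
        state.kind, state.active, state.rna, state.code, state.chain_id,
        state.valid, state.ch_perm, state.ch_len, state.offs, state.interior,
        p(rates.k_chrom_on), p(rates.k_chrom_off), p(rates.k_rna_prod),
        p(rates.k_rna_transfer), p(rates.k_rna_decay), p(rates.k_chain_on),
        p(rates.k_chain_off), 1 if rates.rna_decay_on_chromatin else 0, counts,
        state._rng,
    )
    state.time += schedule.dt_chem
    return ConversionCounts.from_array(counts)


def apply_inhibitor(rates: RateParams, kind: str) -> RateParams:
    """Transcription-inhibitor mimics.

    * ``flavopiridol``: chromatin can no longer become transcriptionally
      active (``k_chrom_on = 0``); everything else unchanged (amphiphile
      removal -- active sites decay away, nuclear RNA remains).
    * ``actinomycinD``: activation, deactivation, production and transfer all
      stop and transcripts on chromatin no longer decay (amphiphile
      retention -- arrested polymerases keep their transcripts tethered).
    """
    if kind == "flavopiridol":
        return rates.replace(k_chrom_on=0.0)
    if kind == "actinomycinD":
        return rates.replace(
            k_chrom_on=0.0, k_chrom_off=0.0, k_rna_prod=0.0,
            k_rna_transfer=0.0, rna_decay_on_chromatin=False,
        )
    raise ValueError(f"unknown inhibitor {kind!r}")


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Snapshots plus a per-snapshot species/RNA manifest.

    ``final_state`` is the live end-of-run state (also the last snapshot
    when snapshots are kept).
    """

    times: List[float]
    snapshots: List[SimulationState]
    counts: pd.DataFrame
    accepted_swaps: int = 0
    final_state: Optional[SimulationState] = None

    def save(self, outdir) -> None:
        """Write compressed snapshot arrays plus a CSV manifest."""
        import os

        os.makedirs(outdir, exist_ok=True)
        for t, snap in zip(self.times, self.snapshots):
            snap.to_npz(os.path.join(outdir, f"snapshot_{t:010.1f}s.npz"))
        self.counts.to_csv(os.path.join(outdir, "manifest.csv"), index=False)


def _effective_rates(config: ScenarioConfig, rates: RateParams) -> RateParams:
    if not config.chemistry:
        return rates.zeroed()
    if not config.chain_switching:
        return rates.replace(k_chain_on=0.0, k_chain_off=0.0)
    return rates


def run(state: SimulationState, rates: RateParams, energy: EnergyParams,
        schedule: Schedule, duration: float, seed: int,
        snapshot_every: Optional[float] = None,
        keep_snapshots: bool = True) -> Trajectory:
    """Advance ``state`` in place for ``duration`` seconds of simulated time.

    Honors the scenario attached to the state: an initial relaxation phase
    (all reactions off), timed onset of the single permissive chain, timed
    inhibitor application, boundary tethering.  Swap attempts continue at
    ``schedule.swap_attempts_per_chem_interval`` per interval throughout
    (including relaxation).  ``dt_chem`` stays fixed for the whole run even
    when an inhibitor later reduces the fastest rate.  Deterministic for a
    given seed.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    cfg = state.config
    seed_rng(state, seed)
    rule = 0 if energy.acceptance == "metropolis" else 1
    dEmin = energy.delta_e_min
    cost = _cost_diff_matrix(energy)
    qinv, etable = _exp_lookup(energy)
    dt = schedule.dt_chem
    # steps are counted in absolute simulated time so a run can be resumed
    # (e.g. inhibitor branches off a shared pre-treatment trajectory)
    start = int(round(state.time / dt))
    nsteps = start + int(round(duration / dt))
    relax_steps = 0
    onset_step = None
    inhibit_step = None
    if cfg is not None:
        relax_steps = int(round(cfg.relaxation_time / dt))
        if cfg.onset_time is not None and cfg.permissive_chain is not None:
            onset_step = int(round(cfg.onset_time / dt))
        if cfg.inhibitor is not None and cfg.inhibitor_application_time is not None:
            inhibit_step = int(round(cfg.inhibitor_application_time / dt))
    snap_steps = (
        max(1, int(round(snapshot_every / dt))) if snapshot_every else None
    )
    base_rates = _effective_rates(cfg, rates) if cfg is not None else rates
    tether = 1 if (cfg is not None and cfg.tether_boundary) else 0

    times: List[float] = [state.time]
    snaps: List[SimulationState] = [state.copy()] if keep_snapshots else []
    rows = [state.counts()]
    accepted = 0
    counts = np.zeros(7, np.int64)

    step = start
    while step < nsteps:
        # next event boundary
        nxt = nsteps
        for ev in (relax_steps, onset_step, inhibit_step):
            if ev is not None and step < ev < nxt:
                nxt = ev
        if snap_steps is not None:
            k = ((step // snap_steps) + 1) * snap_steps
            if k < nxt:
                nxt = k
        if onset_step is not None and step >= onset_step:
            state.ch_perm[cfg.permissive_chain] = 1
        cur = base_rates
        if inhibit_step is not None and step >= inhibit_step:
            cur = apply_inhibitor(base_rates, cfg.inhibitor)
        chem_on = step >= relax_steps and cur.k_max > 0
        p = schedule.conversion_probability
        accepted += K.run_chunk(
            *state._kernel_args(), state.ch_perm, cost, state.offs,
            state.interior, state.ycoord, state.xcoord, tether, rule, dEmin,
            nxt - step, schedule.swap_attempts_per_chem_interval,
            1 if chem_on else 0,
            p(cur.k_chrom_on), p(cur.k_chrom_off), p(cur.k_rna_prod),
            p(cur.k_rna_transfer), p(cur.k_rna_decay), p(cur.k_chain_on),
            p(cur.k_chain_off), 1 if cur.rna_decay_on_chromatin else 0,
            counts, state._rng, qinv, etable,
        )
        step = nxt
        state.time = step * dt
        at_snap = snap_steps is not None and step % snap_steps == 0
        if at_snap or step == nsteps:
            times.append(state.time)
            if keep_snapshots:
                snaps.append(state.copy())
            rows.append(state.counts())
    return Trajectory(times, snaps, pd.DataFrame(rows), accepted, state)


def run_scenario(config: ScenarioConfig, rates: Optional[RateParams] = None,
                 energy: Optional[EnergyParams] = None, *, seed: int,
                 duration: Optional[float] = None,
                 snapshot_every: Optional[float] = None,
                 sweeps_per_interval: Optional[float] = None,
                 keep_snapshots: bool = True) -> Trajectory:
    """Build a scenario and run it with the default (or given) parameters."""
    from .params import _defaults, default_energy, default_rates

    if sweeps_per_interval is None:
        sweeps_per_interval = float(_defaults()[2].get("sweeps_per_interval", 10.0))
    rates = rates if rates is not None else default_rates()
    energy = energy if energy is not None else default_energy()
    state = build_scenario(config)
    eff = _effective_rates(config, rates)
    schedule = Schedule.from_rates(eff, config.width, config.height,
                                   sweeps_per_interval)
    return run(state, rates, energy, schedule,
               duration if duration is not None else config.duration,
               seed, snapshot_every, keep_snapshots)
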