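"""Kinetic, energetic and scenario parameters for the lattice model.

The model describes euchromatin as an active microemulsion on a 2D lattice:
chromatin chains (transcriptionally inactive or active sites) mixed with
RNA-binding proteins (RBPs, unbound or RNA-bound).  Chemical conversions are
first-order reactions executed on a fixed clock ``dt_chem = 0.1 / k_max`` with
per-interval probability ``P_chem = dt_chem * k``; spatial rearrangement
happens through energy-biased neighbor swaps (see :mod:`chromemu.lattice`).

The numeric rate and mismatch-cost defaults shipped in
``chromemu/data/default_params.yaml`` are calibration surrogates: they were
chosen so that the model reproduces the three reference regimes (uniform
dispersion, phase separation, microphase separation) at the lattice scales
used throughout, and can be overridden from any YAML/JSON config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

__all__ = [
    "RateParams",
    "EnergyParams",
    "Schedule",
    "ScenarioConfig",
    "scenario",
    "default_rates",
    "default_energy",
    "load_params",
    "save_params",
    "SCENARIO_NAMES",
]


@dataclass(frozen=True)
class RateParams:
    """First-order conversion rates, all in 1/s.

    ``rna_decay_on_chromatin=False`` suppresses transcript decay on chromatin
    sites only (used by the actinomycin D mimic, where arrested polymerases
    retain their transcripts).
    """

    k_chrom_on: float = 0.02
    k_chrom_off: float = 0.02
    k_rna_prod: float = 0.1
    k_rna_transfer: float = 0.1
    k_rna_decay: float = 0.0002
    k_chain_on: float = 0.005
    k_chain_off: float = 0.005
    rna_decay_on_chromatin: bool = True

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "rna_decay_on_chromatin":
                continue
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"rate {f.name} must be >= 0, got {v}")

    @property
    def k_max(self) -> float:
        """Fastest nonzero conversion rate (0.0 if all rates vanish)."""
        return max(
            self.k_chrom_on,
            self.k_chrom_off,
            self.k_rna_prod,
            self.k_rna_transfer,
            self.k_rna_decay,
            self.k_chain_on,
            self.k_chain_off,
        )

    def replace(self, **kw) -> "RateParams":
        return dataclasses.replace(self, **kw)

    def zeroed(self) -> "RateParams":
        """All conversion rates set to zero (pure swap dynamics)."""
        return RateParams(0, 0, 0, 0, 0, 0, 0, self.rna_decay_on_chromatin)


#: acceptance rules for neighbor swaps
ACCEPTANCE_RULES = ("metropolis", "normalized")


@dataclass(frozen=True)
class EnergyParams:
    """Mismatch costs in units of thermal energy k_BT.

    Only three neighbor pair classes carry a cost: inactive chromatin next to
    an RNA-bound RBP, inactive next to active chromatin, and active next to
    active chromatin.  All other neighbor pairs are neutral, which is what
    lets unbound RBPs mix freely and lets active chromatin (the amphiphile)
    sit inside the RNA-RBP phase.

    ``acceptance`` selects the swap acceptance rule:

    * ``"metropolis"`` (default): ``P = min(1, exp(-dE))`` -- the standard
      Kawasaki exchange rule.
    * ``"normalized"``: ``P = min(1, exp(delta_e_min - dE))`` -- acceptance
      proportional to ``exp(-dE)``, normalized so the largest possible energy
      drop is accepted with probability 1.  This variant suppresses even
      neutral swaps by ``exp(delta_e_min)`` and is provided for comparison;
      it is impractically slow for any cost large enough to drive
      segregation.
    """

    w_inactive_boundRBP: float = 1.0
    w_inactive_active: float = 1.0
    w_active_active: float = 1.0
    acceptance: str = "metropolis"

    def __post_init__(self) -> None:
        for name in ("w_inactive_boundRBP", "w_inactive_active", "w_active_active"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.acceptance not in ACCEPTANCE_RULES:
            raise ValueError(f"acceptance must be one of {ACCEPTANCE_RULES}")

    @property
    def delta_e_min(self) -> float:
        """Largest possible energy drop of any swap (cached, <= 0).

        Computed by the slot-enumeration convention of
        :func:`chromemu.lattice.compute_delta_e_min`.
        """
        from .lattice import compute_delta_e_min

        cached = self.__dict__.get("_delta_e_min")
        if cached is None:
            cached = compute_delta_e_min(self)
            object.__setattr__(self, "_delta_e_min", cached)
        return cached

    def replace(self, **kw) -> "EnergyParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class Schedule:
    """Interleaving of chemistry and swap attempts.

    ``dt_chem`` is the chemical clock (0.1 / k_max so that no per-interval
    conversion probability exceeds 0.1); ``swap_attempts_per_chem_interval``
    is the number of swap proposals executed between consecutive chemical
    updates.  One "sweep" equals width*height attempts; the default is 10
    sweeps per interval, which calibrates diffusion relative to chemistry.
    """

    dt_chem: float
    swap_attempts_per_chem_interval: int

    def __post_init__(self) -> None:
        if self.dt_chem <= 0:
            raise ValueError("dt_chem must be > 0")
        if self.swap_attempts_per_chem_interval < 0:
            raise ValueError("swap attempts must be >= 0")

    @classmethod
    def from_rates(
        cls,
        rates: RateParams,
        width: int,
        height: int,
        sweeps_per_interval: float = 10.0,
        fallback_dt: float = 1.0,
    ) -> "Schedule":
        """Build the schedule from rates and lattice size.

        If every rate is zero there is no chemical clock; ``fallback_dt``
        then sets the bookkeeping interval for the swap-only dynamics.
        """
        kmax = rates.k_max
        dt = 0.1 / kmax if kmax > 0 else fallback_dt
        return cls(dt, int(round(sweeps_per_interval * width * height)))

    def conversion_probability(self, k: float) -> float:
        """Per-interval conversion probability ``P_chem = dt_chem * k``."""
        p = self.dt_chem * k
        if p > 0.1 + 1e-12:
            raise ValueError(
                f"P_chem = {p:.4f} > 0.1; dt_chem inconsistent with rates"
            )
        return p


SCENARIO_NAMES = (
    "uniform_dispersion",
    "phase_separation",
    "microphase",
    "post_mitosis_control",
    "post_mitosis_flavopiridol",
    "post_mitosis_actinomycinD",
    "mir430_onset",
)

PADDING_SPECIES = ("rna_rbp", "inactive_chromatin", "none")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one named in-silico experiment.

    ``rate_mask`` flags which groups of reactions run at all: the exploratory
    uniform-dispersion and phase-separation setups execute no chemistry, the
    microphase and miR-430 setups run with chain switching disabled (chains
    hold a fixed permissive/restrictive state).
    """

    name: str
    width: int = 50
    height: int = 50
    box: int = 5
    chain_length: int = 5
    n_chains: int = 100
    padding: str = "rna_rbp"
    tether_boundary: bool = False
    relaxation_time: float = 0.0
    inhibitor: Optional[str] = None
    inhibitor_application_time: Optional[float] = None
    duration: float = 1800.0
    all_chains_permissive: bool = True
    permissive_chain: Optional[int] = None  # single permissive chain id
    onset_time: Optional[float] = None  # time at which that chain turns on
    prebind_rna: bool = False  # start with every RBP carrying one transcript
    chemistry: bool = True
    chain_switching: bool = True

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.padding not in PADDING_SPECIES:
            raise ValueError(f"unknown padding species {self.padding!r}")
        nbx = self.width // self.box
        nby = self.height // self.box
        if self.n_chains > nbx * nby:
            raise ValueError("chain layout overflows the lattice")
        if self.chain_length > self.box * self.box:
            raise ValueError("chain does not fit its box")


def scenario(name: str, **overrides) -> ScenarioConfig:
    """Preset :class:`ScenarioConfig` for each named experiment."""
    presets = {
        # exploratory setups: 100 chains of length 5 in 5x5 boxes, 50x50
        "uniform_dispersion": dict(
            padding="rna_rbp", chemistry=False, chain_switching=False
        ),
        "phase_separation": dict(
            padding="rna_rbp", chemistry=False, chain_switching=False, prebind_rna=True
        ),
        "microphase": dict(padding="rna_rbp", chemistry=True, chain_switching=False),
        # post-mitosis setups: 100 chains of length 50 in 10x10 boxes, 100x100
        # all chains stay permissive for transcription (no switching)
        "post_mitosis_control": dict(
            width=100,
            height=100,
            box=10,
            chain_length=50,
            padding="inactive_chromatin",
            tether_boundary=True,
            relaxation_time=600.0,
            duration=2700.0,
            chain_switching=False,
        ),
        # transcription onset at a single central locus: 25 chains of length
        # 20 in 10x10 boxes on a 50x50 lattice, only the central chain is
        # ever permissive, turned on after relaxation
        "mir430_onset": dict(
            box=10,
            chain_length=20,
            n_chains=25,
            padding="inactive_chromatin",
            relaxation_time=600.0,
            all_chains_permissive=False,
            permissive_chain=12,
            onset_time=600.0,
            chain_switching=False,
            duration=1800.0,
        ),
    }
    presets["post_mitosis_flavopiridol"] = dict(
        presets["post_mitosis_control"], inhibitor="flavopiridol",
        inhibitor_application_time=900.0,
    )
    presets["post_mitosis_actinomycinD"] = dict(
        presets["post_mitosis_control"], inhibitor="actinomycinD",
        inhibitor_application_time=900.0,
    )
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}")
    kw = dict(presets[name])
    kw.update(overrides)
    return ScenarioConfig(name=name, **kw)


# ---------------------------------------------------------------------------
# YAML round trip


def default_rates() -> RateParams:
    return _defaults()[0]


def default_energy() -> EnergyParams:
    return _defaults()[1]


def _defaults():
    text = resources.files("chromemu").joinpath("data/default_params.yaml").read_text()
    doc = yaml.safe_load(text)
    return (
        RateParams(**doc.get("rates", {})),
        EnergyParams(**doc.get("energy", {})),
        doc.get("schedule", {}),
    )


def load_params(path: str):
    """Read ``(RateParams, EnergyParams, schedule_kwargs)`` from a YAML file.

    Missing sections fall back to the shipped defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    d_rates, d_energy, d_sched = _defaults()
    rates = d_rates.replace(**doc.get("rates", {}))
    energy = d_energy.replace(**doc.get("energy", {}))
    sched = dict(d_sched)
    sched.update(doc.get("schedule", {}))
    return rates, energy, sched


def save_params(path: str, rates: RateParams, energy: EnergyParams, schedule_kwargs=None) -> None:
    doc = {
        "rates": dataclasses.asdict(rates),
        "energy": {
            k: v
            for k, v in dataclasses.asdict(energy).items()
        },
        "schedule": dict(schedule_kwargs or {}),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
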