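"""End-to-end in-silico experiments: simulate -> render -> quantify -> test.

``reproduce_inhibitor_experiment`` runs the post-mitosis control /
flavopiridol / actinomycin D conditions, renders the final chromatin
profiles, quantifies DNA image contrast (C_DNA) and correlation length
(L_corr) per run, and compares each inhibitor against control with
permutation tests (Bonferroni m = 2).  ``reproduce_onset_experiment`` runs
the single-locus transcription-onset scenario repeatedly and averages the
radial ring analysis around the activated chain, aligned at onset.

All randomness descends from one base seed; re-running with the same seed
reproduces every number in the reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import lattice
from .image import (
    AlignedRadialProfile,
    RadialTimeProfile,
    align_average_profiles,
    fit_correlation_length,
    image_contrast,
    radial_correlation,
    radial_ring_profile,
)
from .params import (
    EnergyParams,
    RateParams,
    ScenarioConfig,
    Schedule,
    default_energy,
    default_rates,
    scenario,
)
from .render import RenderConfig, render_profile
from .stats import PermutationResult, permutation_test

__all__ = [
    "ExperimentReport",
    "OnsetReport",
    "reproduce_inhibitor_experiment",
    "reproduce_onset_experiment",
    "quantify_snapshot",
    "quantify_trajectory",
]

INHIBITOR_CONDITIONS = ("control", "flavopiridol", "actinomycinD")


def _defaults_sweeps() -> float:
    from .params import _defaults

    return float(_defaults()[2].get("sweeps_per_interval", 10.0))


def _params_hash(rates: RateParams, energy: EnergyParams) -> str:
    doc = yaml.safe_dump(
        {"rates": dataclasses.asdict(rates), "energy": dataclasses.asdict(energy)},
        sort_keys=True,
    )
    return hashlib.sha256(doc.encode()).hexdigest()[:12]


@dataclass
class ExperimentReport:
    """Per-condition C_DNA / L_corr table plus permutation test results."""

    table: pd.DataFrame
    tests: Dict[Tuple[str, str], PermutationResult]
    condition_means: pd.DataFrame
    underpowered: bool
    metadata: dict

    def p_corrected(self, condition: str, metric: str) -> float:
        return self.tests[(condition, metric)].p_corrected


@dataclass
class OnsetReport:
    """Averaged radial-time maps around the activated locus."""

    aligned: AlignedRadialProfile
    onset_rel_index: int
    n_runs: int
    metadata: dict

    def ring_mean(self, channel: str, rings=range(4)) -> np.ndarray:
        """Mean over the given rings per aligned frame."""
        sel = np.asarray(list(rings))
        return np.nanmean(self.aligned.mean[channel][:, sel], axis=1)

    def delta_after_onset(self, channel: str, rings=range(4)) -> float:
        """Post-onset minus pre-onset window mean of the ring signal.

        Averages the aligned series over all frames after onset (excluding
        the onset frame itself) and over all frames before it; individual
        frames are too noisy for a single-frame comparison.
        """
        series = self.ring_mean(channel, rings)
        i0 = int(np.searchsorted(self.aligned.rel_frames, 0))
        pre = series[:i0] if i0 > 0 else series[i0:i0 + 1]
        post = series[i0 + 1:] if i0 + 1 < series.size else series[-1:]
        return float(np.nanmean(post) - np.nanmean(pre))


def quantify_snapshot(state: lattice.SimulationState, blur_sigma_nm: float = 120.0,
                      max_lag_px: Optional[int] = None) -> Tuple[float, float]:
    """Render a snapshot and return (C_DNA, L_corr) of the DNA profile."""
    img = render_profile(state, RenderConfig(blur_sigma_nm=blur_sigma_nm))
    dna = img["dna"]
    mask = img.mask
    c = image_contrast(dna, mask).c_dna
    if max_lag_px is None:
        max_lag_px = min(36, min(dna.shape) - 1)
    curve = radial_correlation(dna, mask, img.pixel_size_nm, max_lag_px=max_lag_px)
    fit = fit_correlation_length(curve)
    return float(c), float(fit.l_corr_um)


def quantify_trajectory(traj: lattice.Trajectory, blur_sigma_nm: float = 120.0,
                        n_avg: int = 3) -> Tuple[float, float]:
    """Mean (C_DNA, L_corr) over the last ``n_avg`` snapshots of a run.

    Time-averaging late snapshots reduces the configuration-to-configuration
    noise of both statistics for (quasi-)steady patterns.
    """
    snaps = traj.snapshots[-n_avg:] if traj.snapshots else [traj.final_state]
    vals = np.array([quantify_snapshot(s, blur_sigma_nm) for s in snaps])
    return float(vals[:, 0].mean()), float(vals[:, 1].mean())


def reproduce_inhibitor_experiment(
    rates: Optional[RateParams] = None,
    energy: Optional[EnergyParams] = None,
    n_per_condition: int = 20,
    base_seed: int = 0,
    normal_phase_s: float = 1800.0,
    inhibitor_duration_s: float = 1800.0,
    sweeps_per_interval: Optional[float] = None,
    blur_sigma_nm: float = 120.0,
    n_resamples: int = 100_000,
    lattice_size: int = 100,
) -> ExperimentReport:
    """Post-mitosis inhibitor experiment.

    Each seed runs one shared pre-treatment trajectory (10 min relaxation
    with all reactions off, then ``normal_phase_s`` of free transcription,
    long enough for the microphase pattern to mature) and then branches
    into control / flavopiridol / actinomycin D for
    ``inhibitor_duration_s`` of simulated time.  Each branch is rendered
    (sigma 120 nm) and quantified as the time-average over its last three
    snapshots.  ``lattice_size`` selects the full-scale 100x100 layout or
    the scaled-down 50x50 variant (same box/chain structure).
    """
    if n_per_condition < 2:
        raise ValueError("need at least 2 runs per condition")
    rates = rates if rates is not None else default_rates()
    energy = energy if energy is not None else default_energy()
    seed_rng = np.random.default_rng(base_seed)
    seeds = seed_rng.integers(2**31, size=(n_per_condition, 4))
    boxes = (lattice_size // 10) ** 2
    cfg = scenario("post_mitosis_control", width=lattice_size,
                   height=lattice_size, n_chains=boxes)
    if sweeps_per_interval is None:
        sweeps_per_interval = _defaults_sweeps()
    schedule = Schedule.from_rates(rates, cfg.width, cfg.height, sweeps_per_interval)
    rows = []
    for i in range(n_per_condition):
        state = lattice.build_scenario(cfg)
        lattice.run(state, rates, energy, schedule,
                    cfg.relaxation_time + normal_phase_s, int(seeds[i, 0]),
                    keep_snapshots=False)
        for j, cond in enumerate(INHIBITOR_CONDITIONS):
            branch = state.copy()
            r = rates if cond == "control" else lattice.apply_inhibitor(rates, cond)
            traj = lattice.run(branch, r, energy, schedule, inhibitor_duration_s,
                               int(seeds[i, 1 + j]),
                               snapshot_every=inhibitor_duration_s / 12.0)
            c, l = quantify_trajectory(traj, blur_sigma_nm)
            rows.append({"condition": cond, "seed": int(seeds[i, 0]),
                         "branch_seed": int(seeds[i, 1 + j]),
                         "c_dna": c, "l_corr_um": l})
    table = pd.DataFrame(rows)
    tests: Dict[Tuple[str, str], PermutationResult] = {}
    test_rng = np.random.default_rng(int(seed_rng.integers(2**31)))
    ctrl = table[table.condition == "control"]
    for cond in ("flavopiridol", "actinomycinD"):
        sub = table[table.condition == cond]
        for metric in ("c_dna", "l_corr_um"):
            res = permutation_test(sub[metric].values, ctrl[metric].values,
                                   n_resamples, test_rng, m_comparisons=2)
            tests[(cond, metric)] = res
    means = table.groupby("condition")[["c_dna", "l_corr_um"]].agg(["mean", "std"])
    return ExperimentReport(
        table=table,
        tests=tests,
        condition_means=means,
        underpowered=n_per_condition < 5,
        metadata={
            "base_seed": base_seed,
            "n_per_condition": n_per_condition,
            "params_hash": _params_hash(rates, energy),
            "normal_phase_s": normal_phase_s,
            "inhibitor_duration_s": inhibitor_duration_s,
            "blur_sigma_nm": blur_sigma_nm,
        },
    )


def reproduce_onset_experiment(
    rates: Optional[RateParams] = None,
    energy: Optional[EnergyParams] = None,
    n_runs: int = 12,
    base_seed: int = 0,
    snapshot_every_s: float = 60.0,
    duration_s: Optional[float] = None,
    max_ring: int = 10,
    blur_sigma_nm: float = 150.0,
    sweeps_per_interval: Optional[float] = None,
) -> OnsetReport:
    """Transcription onset at the single central permissive chain.

    Runs the onset scenario ``n_runs`` times, renders every snapshot with a
    live-cell-like blur, computes Chebyshev-ring profiles around the
    activated chain's centroid per frame, aligns the profiles at onset and
    averages them.
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    rates = rates if rates is not None else default_rates()
    energy = energy if energy is not None else default_energy()
    if sweeps_per_interval is None:
        sweeps_per_interval = _defaults_sweeps()
    seeds = np.random.default_rng(base_seed).integers(2**31, size=n_runs)
    cfg = scenario("mir430_onset")
    if duration_s is None:
        duration_s = cfg.duration
    profiles: List[RadialTimeProfile] = []
    for i in range(n_runs):
        traj = lattice.run_scenario(
            cfg, rates, energy, seed=int(seeds[i]), duration=duration_s,
            snapshot_every=snapshot_every_s,
            sweeps_per_interval=sweeps_per_interval,
        )
        data = {c: np.zeros((len(traj.snapshots), max_ring + 1))
                for c in ("dna", "rna", "ser2phos")}
        cents = []
        t0_index = None
        for f, snap in enumerate(traj.snapshots):
            img = render_profile(snap, RenderConfig(blur_sigma_nm=blur_sigma_nm))
            chain = snap.chains[cfg.permissive_chain]
            pos = np.asarray(chain.positions, float)
            centroid = pos.mean(axis=0)
            cents.append(tuple(centroid))
            prof = radial_ring_profile(img, centroid, max_ring)
            for c in data:
                data[c][f] = prof.means[c]
            if t0_index is None and traj.times[f] >= (cfg.onset_time or 0.0):
                t0_index = f
        profiles.append(RadialTimeProfile(
            rings=np.arange(max_ring + 1), data=data, centroids=cents,
            t0_index=t0_index, frame_interval_s=snapshot_every_s,
        ))
    aligned = align_average_profiles(profiles)
    onset_rel = int(np.searchsorted(aligned.rel_frames, 0))
    return OnsetReport(
        aligned=aligned, onset_rel_index=onset_rel, n_runs=n_runs,
        metadata={
            "base_seed": base_seed,
            "params_hash": _params_hash(rates, energy),
            "snapshot_every_s": snapshot_every_s,
            "duration_s": duration_s,
            "blur_sigma_nm": blur_sigma_nm,
        },
    )
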