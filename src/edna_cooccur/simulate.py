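"""Synthetic pond-occupancy and qPCR observation simulator.

Latent layer: each species occupies each pond in month 1 with probability
psi0; thereafter an empty site is colonized with per-month probability
gamma and an occupied site goes extinct with probability epsilon.  A
predator->prey interaction multiplies the prey's colonization (theta_col)
and extinction (theta_ext) probabilities when at least one predator
occupied the site in the preceding month, and the predators' colonization
(phi_pred) when at least one prey was present; multipliers of 1 give fully
independent dynamics.  Effective probabilities are clipped to [0, 1] with
a capping counter rather than an error.

Observation layer: each sampled site-month yields n_bio water samples,
each run in n_tech qPCR replicates.  Given true presence a replicate
amplifies with probability p_rep at a lognormal relative DNA amount; given
absence it amplifies with probability p_fp at half the assay's LOD (a trace
signal that the LOD rule screens out).  Amplifying replicates receive
Cq = curve(x) + Gaussian noise; predicted Cq beyond the 50-cycle protocol
is recorded as no amplification.  Site-months in months 2+ may be missing
completely at random; month 1 is always sampled.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DetectionMatrix, SpeciesSpec
from .qpcr import (
    MAX_CYCLES,
    WELL_COLUMNS,
    StandardCurve,
    default_standard_curve,
    predict_cq,
)

#: The study system: two amphibian prey and two invasive predatory fish.
DEFAULT_SPECIES: tuple[SpeciesSpec, ...] = (
    SpeciesSpec("A1", "prey", "Pelobates fuscus (garlic toad)"),
    SpeciesSpec("A2", "prey", "Triturus cristatus (crested newt)"),
    SpeciesSpec("F1", "predator", "Lepomis gibbosus (pumpkinseed)"),
    SpeciesSpec("F2", "predator", "Pseudorasbora parva (topmouth gudgeon)"),
)

PRESETS = ("null_model", "strong_avoidance", "paper_like")


def _per_species(value, species: Sequence[SpeciesSpec]) -> np.ndarray:
    """Broadcast a scalar or per-species mapping to an array."""
    if isinstance(value, Mapping):
        missing = [s.species_id for s in species if s.species_id not in value]
        if missing:
            raise ValueError(f"per-species parameter missing for {missing}")
        return np.array([float(value[s.species_id]) for s in species])
    return np.full(len(species), float(value))


def _check_prob(name: str, arr: np.ndarray) -> None:
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"{name} must lie in [0, 1]; got {arr}")


@dataclass(frozen=True)
class OccupancyParams:
    """Latent occupancy dynamics.

    psi0, gamma, epsilon may be scalars or per-species-id mappings.
    Interaction multipliers act on the prey's (theta_*) or predators'
    (phi_pred) probabilities; 1 means no interaction.  interaction_timing
    conditions on the other guild's state in the preceding month
    ("previous", default) or the month being decided ("same", predators
    updated first).
    """

    psi0: float | Mapping[str, float] = 0.5
    gamma: float | Mapping[str, float] = 0.2
    epsilon: float | Mapping[str, float] = 0.2
    theta_col: float = 1.0
    theta_ext: float = 1.0
    phi_pred: float = 1.0
    interaction_timing: str = "previous"

    def __post_init__(self) -> None:
        for name in ("theta_col", "theta_ext", "phi_pred"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.interaction_timing not in ("previous", "same"):
            raise ValueError(
                f"unknown interaction_timing {self.interaction_timing!r}"
            )


@dataclass(frozen=True)
class ObservationParams:
    """qPCR observation layer (replicate design, noise, missingness)."""

    n_bio: int = 3
    n_tech: int = 3
    p_rep: float = 0.8
    p_fp: float = 0.002
    conc_mu: float = 0.0
    conc_sigma: float = 1.0
    cq_sd: float = 0.3
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("n_bio and n_tech must be >= 1")
        for name in ("p_rep", "p_fp", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.conc_sigma < 0 or self.cq_sd < 0:
            raise ValueError("scale parameters must be >= 0")


@dataclass
class SyntheticDataset:
    """One simulated survey: latent truth, replicate wells, provenance."""

    truth: DetectionMatrix
    wells: pd.DataFrame
    seed: int
    params: dict
    species: tuple[SpeciesSpec, ...]
    curve: StandardCurve


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_occupancy(
    species: Sequence[SpeciesSpec],
    params: OccupancyParams,
    n_sites: int,
    n_months: int,
    seed,
    site_ids: Sequence[str] | None = None,
) -> DetectionMatrix:
    """Simulate the latent presence/absence trajectories (no missingness)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_months < 2:
        raise ValueError("n_months must be >= 2")
    if not species:
        raise ValueError("at least one species is required")
    ids = [s.species_id for s in species]
    if len(set(ids)) != len(ids):
        raise ValueError("species_id values must be unique")
    rng = _as_rng(seed)

    psi0 = _per_species(params.psi0, species)
    gamma = _per_species(params.gamma, species)
    epsilon = _per_species(params.epsilon, species)
    _check_prob("psi0", psi0)
    _check_prob("gamma", gamma)
    _check_prob("epsilon", epsilon)

    is_prey = np.array([s.role == "prey" for s in species])
    is_pred = ~is_prey
    n_sp = len(species)
    state = np.zeros((n_sp, n_sites, n_months))
    state[:, :, 0] = rng.random((n_sp, n_sites)) < psi0[:, None]
    n_capped = 0

    def effective(base, mult, active):
        """Per-site effective probability with capping count."""
        nonlocal n_capped
        eff = np.where(active, base * mult, base)
        n_capped += int(np.sum(eff > 1.0)) + int(np.sum(eff < 0.0))
        return np.clip(eff, 0.0, 1.0)

    for t in range(1, n_months):
        prev = state[:, :, t - 1]
        pred_prev = prev[is_pred].any(axis=0) if is_pred.any() else (
            np.zeros(n_sites, dtype=bool))
        prey_prev = prev[is_prey].any(axis=0) if is_prey.any() else (
            np.zeros(n_sites, dtype=bool))
        u = rng.random((n_sp, n_sites))
        new = np.empty((n_sp, n_sites))

        def step(i, pred_cue, prey_cue):
            if is_prey[i]:
                g = effective(gamma[i], params.theta_col, pred_cue)
                e = effective(epsilon[i], params.theta_ext, pred_cue)
            else:
                g = effective(gamma[i], params.phi_pred, prey_cue)
                e = np.full(n_sites, epsilon[i])
            occupied = prev[i] == 1
            return np.where(occupied, u[i] >= e, u[i] < g).astype(float)

        if params.interaction_timing == "previous":
            for i in range(n_sp):
                new[i] = step(i, pred_prev, prey_prev)
        else:  # "same": predators move first, prey see predators at month t
            for i in np.flatnonzero(is_pred):
                new[i] = step(i, pred_prev, prey_prev)
            pred_now = new[is_pred].any(axis=0) if is_pred.any() else (
                np.zeros(n_sites, dtype=bool))
            for i in np.flatnonzero(is_prey):
                new[i] = step(i, pred_now, prey_prev)
        state[:, :, t] = new

    if site_ids is None:
        width = len(str(n_sites))
        site_ids = [f"P{k + 1:0{width}d}" for k in range(n_sites)]
    matrix = DetectionMatrix(
        ids, list(site_ids), list(range(1, n_months + 1)), state,
        meta={"n_capped": n_capped},
    )
    return matrix


def apply_missingness(
    truth: DetectionMatrix, missing_rate: float, seed
) -> DetectionMatrix:
    """Mark site-months in months 2+ missing completely at random.

    Month 1 is never missing; missingness hits all species of a site-month.
    """
    rng = _as_rng(seed)
    out = truth.copy()
    n_sites = len(out.site_ids)
    n_months = len(out.months)
    drop = rng.random((n_sites, n_months)) < missing_rate
    drop[:, 0] = False
    out.state[:, drop] = np.nan
    out.meta["missing_rate"] = missing_rate
    return out


def simulate_wells(
    truth: DetectionMatrix,
    obs: ObservationParams,
    curve: StandardCurve | Mapping[str, StandardCurve],
    seed,
) -> pd.DataFrame:
    """Overlay the qPCR observation layer on a latent truth matrix.

    Returns the canonical wells frame (site_id, month, species_id, bio_rep,
    tech_rep, cq); cq is NaN for non-amplifying replicates.  Missing
    site-months emit no wells.
    """
    rng = _as_rng(seed)
    if isinstance(curve, Mapping):
        curves = {sp: curve[sp] for sp in truth.species_ids}
    else:
        curves = {sp: curve for sp in truth.species_ids}
    for sp, c in curves.items():
        if not np.isfinite(c.slope_ln) or not np.isfinite(c.intercept):
            raise ValueError(f"curve for {sp!r} has non-finite coefficients")

    n_sp = len(truth.species_ids)
    n_sites = len(truth.site_ids)
    n_months = len(truth.months)
    reps = obs.n_bio * obs.n_tech

    # replicate-level grids, species-major then site, month, bio, tech
    sp_idx, site_idx, mon_idx, bio, tech = np.meshgrid(
        np.arange(n_sp), np.arange(n_sites), np.arange(n_months),
        np.arange(1, obs.n_bio + 1), np.arange(1, obs.n_tech + 1),
        indexing="ij",
    )
    flat = lambda a: a.reshape(-1)
    sp_idx, site_idx, mon_idx = flat(sp_idx), flat(site_idx), flat(mon_idx)
    bio, tech = flat(bio), flat(tech)

    present = truth.state[sp_idx, site_idx, mon_idx]  # 0/1/NaN
    sampled = ~np.isnan(present)

    # one uniform/lognormal/normal draw per replicate, in fixed order, so the
    # stream is deterministic regardless of which replicates survive masks
    n_total = present.size
    u = rng.random(n_total)
    conc_present = rng.lognormal(obs.conc_mu, obs.conc_sigma, n_total)
    noise = rng.normal(0.0, obs.cq_sd, n_total) if obs.cq_sd > 0 else (
        np.zeros(n_total))

    p_amp = np.where(present == 1, obs.p_rep, obs.p_fp)
    amplified = sampled & (u < p_amp)

    lod = np.array([
        curves[truth.species_ids[i]].lod or 1e-3 for i in range(n_sp)
    ])
    conc = np.where(present == 1, conc_present, lod[sp_idx] / 2.0)
    cq = np.full(n_total, np.nan)
    if amplified.any():
        slopes = np.array([curves[truth.species_ids[i]].slope_ln
                           for i in range(n_sp)])
        intercepts = np.array([curves[truth.species_ids[i]].intercept
                               for i in range(n_sp)])
        cq_pred = slopes[sp_idx] * np.log(conc) + intercepts[sp_idx]
        cq = np.where(amplified, cq_pred + noise, np.nan)
        # beyond the 50-cycle protocol: recorded as no amplification
        cq = np.where(cq > MAX_CYCLES, np.nan, cq)
        cq = np.where(cq <= 0, np.nan, cq)

    site_ids = np.asarray(truth.site_ids, dtype=object)
    species_ids = np.asarray(truth.species_ids, dtype=object)
    months = np.asarray(truth.months)
    df = pd.DataFrame(
        {
            "site_id": site_ids[site_idx[sampled]],
            "month": months[mon_idx[sampled]],
            "species_id": species_ids[sp_idx[sampled]],
            "bio_rep": bio[sampled],
            "tech_rep": tech[sampled],
            "cq": cq[sampled],
        },
        columns=WELL_COLUMNS,
    )
    df = df.sort_values(
        ["site_id", "month", "species_id", "bio_rep", "tech_rep"],
        kind="stable",
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

#: Base rates shared by the presets.  The survey found any-prey at ~45% of
#: sites and any-fish at ~63%; with two roughly exchangeable species per
#: guild, per-species initial occupancy is 1 - sqrt(1 - guild fraction).
#: Turnover rates reflect one breeding season: amphibians move between
#: breeding ponds (higher gamma/epsilon); invasive fish persist once
#: established (low epsilon) while still spreading (moderate gamma).
BASE_PSI0 = {"A1": 0.258, "A2": 0.258, "F1": 0.392, "F2": 0.392}
BASE_GAMMA = {"A1": 0.3, "A2": 0.3, "F1": 0.15, "F2": 0.15}
BASE_EPSILON = {"A1": 0.3, "A2": 0.3, "F1": 0.05, "F2": 0.05}

_AVOIDANCE = dict(theta_col=0.1, theta_ext=5.0, phi_pred=2.0)


def scenario_params(name: str) -> tuple[OccupancyParams, ObservationParams, int, int]:
    """(occupancy, observation, n_sites, n_months) for a named preset."""
    base = dict(psi0=BASE_PSI0, gamma=BASE_GAMMA, epsilon=BASE_EPSILON)
    if name == "null_model":
        return (
            OccupancyParams(**base),
            ObservationParams(missing_rate=0.0),
            31, 3,
        )
    if name == "strong_avoidance":
        return (
            OccupancyParams(**base, **_AVOIDANCE),
            ObservationParams(missing_rate=0.0),
            60, 3,
        )
    if name == "paper_like":
        return (
            OccupancyParams(**base, **_AVOIDANCE),
            ObservationParams(missing_rate=0.15),
            31, 3,
        )
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESETS}")


def make_scenario(
    name: str,
    seed: int,
    *,
    n_sites: int | None = None,
    n_months: int | None = None,
    species: Sequence[SpeciesSpec] = DEFAULT_SPECIES,
    curve: StandardCurve | None = None,
) -> SyntheticDataset:
    """Generate a full synthetic survey from a named preset.

    One seed drives three child streams (occupancy, missingness, wells) via
    numpy's SeedSequence, so regeneration with the same (preset, seed) is
    bit-identical.
    """
    occ, obs, default_sites, default_months = scenario_params(name)
    n_sites = default_sites if n_sites is None else n_sites
    n_months = default_months if n_months is None else n_months
    curve = curve or default_standard_curve()

    ss = np.random.SeedSequence(seed)
    rng_occ, rng_miss, rng_wells = (np.random.default_rng(c) for c in ss.spawn(3))
    truth = simulate_occupancy(species, occ, n_sites, n_months, rng_occ)
    truth = apply_missingness(truth, obs.missing_rate, rng_miss)
    wells = simulate_wells(truth, obs, curve, rng_wells)
    truth.meta["seed"] = seed
    truth.meta["preset"] = name

    params = {
        "preset": name,
        "n_sites": n_sites,
        "n_months": n_months,
        "occupancy": asdict(occ),
        "observation": asdict(obs),
        "curve": asdict(curve),
        "species": [asdict(s) for s in species],
    }
    return SyntheticDataset(
        truth=truth, wells=wells, seed=seed, params=params,
        species=tuple(species), curve=curve,
    )
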