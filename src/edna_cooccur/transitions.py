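"""Month-to-month occupancy transitions and the co-occurrence matrix.

Between two consecutive months a species at a site shows one of four
transition states:

    ``--``  stay zero   (absent, absent)
    ``++``  persist     (present, present)
    ``-+``  enter       (absent, present)
    ``+-``  disappear   (present, absent)

The co-occurrence matrix is row-conditional: cell (r, c) is the number of
sites where the row event r (one species in one state) was accompanied by
the column event c, divided by the number of sites showing r.  If half of
the sites where species A persisted also had species B disappearing, cell
(A:++, B:+-) is 0.5.  Rows with zero occurrences are undefined (NaN),
never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DetectionMatrix, month_pair_label

STAY_ZERO = "--"
PERSIST = "++"
ENTER = "-+"
DISAPPEAR = "+-"
STATES: tuple[str, ...] = (STAY_ZERO, PERSIST, ENTER, DISAPPEAR)
_STATE_CODE = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)


def transition_state(before: int, after: int) -> str:
    """Map a (presence@t, presence@t+1) pair to its transition code."""
    pair = (int(before), int(after))
    try:
        return {(0, 0): STAY_ZERO, (1, 1): PERSIST,
                (0, 1): ENTER, (1, 0): DISAPPEAR}[pair]
    except KeyError:
        raise ValueError(f"presence values must be 0/1; got {pair}") from None


@dataclass
class TransitionTable:
    """Per-site, per-species transition states for one consecutive month pair.

    ``states`` is a site x species frame of transition codes.  Sites where
    either month was unsampled are absent from the frame for *all* species
    (complete-pair analysis), so every species shares one site set.
    """

    month_pair: tuple[int, int]
    states: pd.DataFrame

    def __post_init__(self) -> None:
        self.month_pair = (int(self.month_pair[0]), int(self.month_pair[1]))
        bad = ~self.states.isin(STATES).all(axis=None)
        if bad:
            raise ValueError(f"transition states must be among {STATES}")

    @property
    def site_ids(self) -> list[str]:
        return [str(s) for s in self.states.index]

    @property
    def species_ids(self) -> list[str]:
        return [str(s) for s in self.states.columns]

    @property
    def n_sites(self) -> int:
        return len(self.states)

    @property
    def label(self) -> str:
        return month_pair_label(self.month_pair)

    def to_codes(self) -> np.ndarray:
        """Integer (n_sites, n_species) array with states coded 0..3."""
        arr = self.states.to_numpy(dtype=object)
        return np.vectorize(_STATE_CODE.__getitem__, otypes=[np.int64])(arr)

    @classmethod
    def from_codes(
        cls,
        month_pair: tuple[int, int],
        codes: np.ndarray,
        site_ids: Sequence[str],
        species_ids: Sequence[str],
    ) -> "TransitionTable":
        frame = pd.DataFrame(
            np.asarray(STATES, dtype=object)[codes],
            index=list(site_ids),
            columns=list(species_ids),
        )
        return cls(month_pair, frame)


def encode_transitions(
    matrix: DetectionMatrix, month_pair: tuple[int, int]
) -> TransitionTable:
    """Encode every site's transition between two consecutive months.

    A site with either month unsampled is dropped for all species.
    """
    t0, t1 = int(month_pair[0]), int(month_pair[1])
    if t1 != t0 + 1:
        raise ValueError(
            f"month pair must be consecutive; got ({t0}, {t1})"
        )
    if t0 not in matrix.months or t1 not in matrix.months:
        raise ValueError(f"months {month_pair} not both present in matrix")
    k0, k1 = matrix.month_index(t0), matrix.month_index(t1)
    before = matrix.state[:, :, k0]  # (species, sites)
    after = matrix.state[:, :, k1]
    keep = ~(np.isnan(before).any(axis=0) | np.isnan(after).any(axis=0))
    codes = np.empty((int(keep.sum()), len(matrix.species_ids)), dtype=np.int64)
    b = before[:, keep].astype(int).T  # (sites, species)
    a = after[:, keep].astype(int).T
    # (0,0)->0 --, (1,1)->1 ++, (0,1)->2 -+, (1,0)->3 +-
    codes[(b == 0) & (a == 0)] = _STATE_CODE[STAY_ZERO]
    codes[(b == 1) & (a == 1)] = _STATE_CODE[PERSIST]
    codes[(b == 0) & (a == 1)] = _STATE_CODE[ENTER]
    codes[(b == 1) & (a == 0)] = _STATE_CODE[DISAPPEAR]
    sites = [s for s, k in zip(matrix.site_ids, keep) if k]
    return TransitionTable.from_codes((t0, t1), codes, sites, matrix.species_ids)


# ---------------------------------------------------------------------------
# Co-occurrence matrix
# ---------------------------------------------------------------------------

def event_labels(species_ids: Sequence[str]) -> list[str]:
    """Event universe in species-major order: 'SP:--', 'SP:++', ..."""
    return [f"{sp}:{st}" for sp in species_ids for st in STATES]


def one_hot_events(codes: np.ndarray) -> np.ndarray:
    """(n_sites, n_species*4) indicator of each site's events."""
    n_sites, n_species = codes.shape
    ind = (codes[:, :, None] == np.arange(N_STATES)[None, None, :])
    return ind.reshape(n_sites, n_species * N_STATES).astype(float)


def joint_counts(codes: np.ndarray) -> np.ndarray:
    """Event x event co-occurrence counts over sites."""
    ind = one_hot_events(codes)
    return ind.T @ ind


@dataclass
class CooccurrenceMatrix:
    """Row-conditional co-occurrence proportions with raw counts.

    ``proportions.loc[r, c]`` = P(column event c | row event r), NaN when
    the row event never occurred.
    """

    proportions: pd.DataFrame
    joint_counts: pd.DataFrame
    row_counts: pd.Series

    @property
    def event_keys(self) -> list[str]:
        return list(self.proportions.index)

    def cell(self, row_species: str, row_state: str,
             col_species: str, col_state: str) -> float:
        return float(
            self.proportions.loc[f"{row_species}:{row_state}",
                                 f"{col_species}:{col_state}"]
        )


def cooccurrence_matrix(table: TransitionTable) -> CooccurrenceMatrix:
    """Build the row-conditional co-occurrence matrix for one month pair."""
    if table.n_sites == 0:
        raise ValueError("transition table has no sites")
    codes = table.to_codes()
    joint = joint_counts(codes)
    rows = np.diag(joint).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        props = np.where(rows[:, None] > 0, joint / rows[:, None], np.nan)
    labels = event_labels(table.species_ids)
    return CooccurrenceMatrix(
        proportions=pd.DataFrame(props, index=labels, columns=labels),
        joint_counts=pd.DataFrame(joint.astype(int), index=labels, columns=labels),
        row_counts=pd.Series(rows.astype(int), index=labels),
    )


# ---------------------------------------------------------------------------
# Site summaries (Results-style fractions)
# ---------------------------------------------------------------------------

@dataclass
class SiteSummary:
    """Month-pooled site occupancy fractions by trophic guild.

    A site counts as prey-positive (fish-positive) if any prey (predator)
    species was detected there in any sampled month; "only" means the other
    guild was never detected at that site.  Sample-level positivity counts
    field samples (site-month biological replicates) with at least one
    positive replicate for any target species; None when wells were not
    supplied.
    """

    n_sites: int
    fraction_sites_any_target: float
    fraction_prey_any: float
    fraction_prey_only: float
    fraction_fish_any: float
    fraction_fish_only: float
    fraction_cooccur: float
    n_samples: int | None = None
    n_samples_positive: int | None = None

    def __post_init__(self) -> None:
        f = [
            self.fraction_sites_any_target, self.fraction_prey_any,
            self.fraction_prey_only, self.fraction_fish_any,
            self.fraction_fish_only, self.fraction_cooccur,
        ]
        if any(not (0.0 <= v <= 1.0) for v in f):
            raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_prey_only > self.fraction_prey_any + 1e-12:
            raise ValueError("prey_only cannot exceed prey_any")
        if self.fraction_fish_only > self.fraction_fish_any + 1e-12:
            raise ValueError("fish_only cannot exceed fish_any")
        if self.fraction_cooccur > min(
            self.fraction_prey_any, self.fraction_fish_any
        ) + 1e-12:
            raise ValueError("cooccur cannot exceed min(prey_any, fish_any)")

    @property
    def fraction_samples_positive(self) -> float | None:
        if self.n_samples in (None, 0):
            return None
        return self.n_samples_positive / self.n_samples


def summarize_sites(
    matrix: DetectionMatrix, roles: Mapping[str, str]
) -> SiteSummary:
    """Month-pooled per-site guild flags and their fractions over all sites."""
    unknown = [sp for sp in matrix.species_ids if sp not in roles]
    if unknown:
        raise ValueError(f"roles missing for species {unknown}")
    present_any = np.nansum(matrix.state, axis=2) > 0  # (species, sites)
    # sites with no sampled month at all contribute False everywhere
    is_prey = np.array([roles[sp] == "prey" for sp in matrix.species_ids])
    is_pred = np.array([roles[sp] == "predator" for sp in matrix.species_ids])
    prey_any = present_any[is_prey].any(axis=0) if is_prey.any() else (
        np.zeros(len(matrix.site_ids), dtype=bool))
    fish_any = present_any[is_pred].any(axis=0) if is_pred.any() else (
        np.zeros(len(matrix.site_ids), dtype=bool))
    any_target = prey_any | fish_any
    n = len(matrix.site_ids)
    return SiteSummary(
        n_sites=n,
        fraction_sites_any_target=float(any_target.mean()) if n else 0.0,
        fraction_prey_any=float(prey_any.mean()) if n else 0.0,
        fraction_prey_only=float((prey_any & ~fish_any).mean()) if n else 0.0,
        fraction_fish_any=float(fish_any.mean()) if n else 0.0,
        fraction_fish_only=float((fish_any & ~prey_any).mean()) if n else 0.0,
        fraction_cooccur=float((prey_any & fish_any).mean()) if n else 0.0,
    )
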