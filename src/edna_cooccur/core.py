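"""Shared containers for eDNA pond-occupancy surveys.

A survey records, for each target species, pond (site) and month, whether
the species' DNA was detected.  Months are consecutive within one field
season.  Some site-months may be unsampled (dried ponds, disturbance by
protected birds); those are explicitly *missing*, never coerced to absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Default field-season month labels; month ordinals are 1-based.
MONTH_NAMES: dict[int, str] = {1: "May", 2: "June", 3: "July"}
MONTH_ORDINALS: dict[str, int] = {v: k for k, v in MONTH_NAMES.items()}

ROLES = ("predator", "prey")


def month_ordinal(token: int | str) -> int:
    """Accept a month as an ordinal or a name (May/June/July)."""
    if isinstance(token, (int, np.integer)):
        return int(token)
    token = str(token).strip()
    if token in MONTH_ORDINALS:
        return MONTH_ORDINALS[token]
    try:
        return int(token)
    except ValueError:
        raise ValueError(f"unknown month token: {token!r}") from None


def month_label(m: int) -> str:
    return MONTH_NAMES.get(int(m), f"M{int(m)}")


def month_pair_label(pair: tuple[int, int]) -> str:
    return f"{month_label(pair[0])}-{month_label(pair[1])}"


@dataclass(frozen=True)
class SpeciesSpec:
    """One target species: a short id (A1, F2, ...), its trophic role and a
    human-readable name."""

    species_id: str
    role: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(
                f"unknown role {self.role!r} for {self.species_id}; "
                f"expected one of {ROLES}"
            )
        if not self.species_id:
            raise ValueError("species_id must be non-empty")


@dataclass(eq=False)
class DetectionMatrix:
    """Species x site x month presence/absence with an explicit missing mask.

    ``state`` is a float array of shape (n_species, n_sites, n_months) with
    values 1.0 (present/detected), 0.0 (absent/not detected) and NaN
    (site-month not sampled).  Missingness applies to a whole site-month:
    either all species are NaN there or none are.
    """

    species_ids: list[str]
    site_ids: list[str]
    months: list[int]
    state: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species_ids = [str(s) for s in self.species_ids]
        self.site_ids = [str(s) for s in self.site_ids]
        self.months = [int(m) for m in self.months]
        self.state = np.asarray(self.state, dtype=float)
        expected = (len(self.species_ids), len(self.site_ids), len(self.months))
        if self.state.shape != expected:
            raise ValueError(
                f"state shape {self.state.shape} != (species, sites, months) "
                f"{expected}"
            )
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species_ids")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site_ids")
        if self.months != sorted(self.months):
            raise ValueError("months must be strictly increasing")
        finite = self.state[~np.isnan(self.state)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("state values must be 0, 1 or NaN")

    # -- indexing helpers -------------------------------------------------
    def species_index(self, species_id: str) -> int:
        return self.species_ids.index(species_id)

    def month_index(self, month: int) -> int:
        return self.months.index(int(month))

    def sampled_mask(self) -> np.ndarray:
        """(n_sites, n_months) boolean: True where the site-month was sampled."""
        return ~np.isnan(self.state).all(axis=0)

    # -- tidy-frame round trip --------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with columns species_id, site_id, month, state
        (state one of '0', '1', 'NA')."""
        rows = []
        for i, sp in enumerate(self.species_ids):
            for j, site in enumerate(self.site_ids):
                for k, m in enumerate(self.months):
                    v = self.state[i, j, k]
                    tok = "NA" if np.isnan(v) else str(int(v))
                    rows.append((sp, site, m, tok))
        return pd.DataFrame(rows, columns=["species_id", "site_id", "month", "state"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DetectionMatrix":
        required = ["species_id", "site_id", "month", "state"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"detection matrix frame missing columns {missing}")
        df = df.copy()
        df["month"] = df["month"].map(month_ordinal)
        keys = df[["species_id", "site_id", "month"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (species_id, site_id, month) key: {dup}")

        def parse_state(tok, row_idx):
            s = str(tok).strip()
            if s in ("NA", "", "nan"):
                return np.nan
            if s in ("0", "0.0"):
                return 0.0
            if s in ("1", "1.0"):
                return 1.0
            raise ValueError(f"row {row_idx}: unknown state token {tok!r}")

        df["value"] = [parse_state(t, i) for i, t in zip(df.index, df["state"])]
        species = list(dict.fromkeys(df["species_id"].astype(str)))
        sites = sorted(df["site_id"].astype(str).unique())
        months = sorted(df["month"].unique())
        state = np.full((len(species), len(sites), len(months)), np.nan)
        si = {s: i for i, s in enumerate(species)}
        ti = {s: i for i, s in enumerate(sites)}
        mi = {m: i for i, m in enumerate(months)}
        for sp, site, m, v in zip(
            df["species_id"].astype(str), df["site_id"].astype(str),
            df["month"], df["value"],
        ):
            state[si[sp], ti[site], mi[m]] = v
        return cls(species, sites, [int(m) for m in months], state)

    def equals(self, other: "DetectionMatrix") -> bool:
        return (
            self.species_ids == other.species_ids
            and self.site_ids == other.site_ids
            and self.months == other.months
            and np.array_equal(self.state, other.state, equal_nan=True)
        )

    def copy(self) -> "DetectionMatrix":
        return DetectionMatrix(
            list(self.species_ids), list(self.site_ids), list(self.months),
            self.state.copy(), dict(self.meta),
        )


def roles_from_species(species: Iterable[SpeciesSpec]) -> dict[str, str]:
    return {s.species_id: s.role for s in species}
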