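"""Monte-Carlo permutation test for transition co-occurrence.

The null model permutes each species' transition states across sites
independently, preserving every species' transition-type frequencies (and
hence each site's temporal autocorrelation structure) while breaking any
cross-species association.  Repeating the permutation builds a null
distribution for every co-occurrence cell; the empirical cell is then
classified as occurring more or less often than expected by chance.

P-values use the add-one (finite-permutation) correction
p = (1 + #{null >= empirical}) / (1 + B), so they are never zero, and ties
count toward the tail.  Two-sided p doubles the smaller tail, capped at 1.
Because each species' state frequencies are preserved, the row counts of
the co-occurrence matrix are permutation-invariant and tail comparisons
can be made on integer joint counts, avoiding float ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .core import month_pair_label
from .transitions import (
    N_STATES,
    STATES,
    CooccurrenceMatrix,
    TransitionTable,
    cooccurrence_matrix,
    joint_counts,
)

logger = logging.getLogger(__name__)

DIRECTION_MORE = "more_than_expected"
DIRECTION_LESS = "less_than_expected"
DIRECTION_NONE = "none"

SUMMARY_COLUMNS = [
    "month_pair", "row_species", "row_state", "col_species", "col_state",
    "empirical", "null_mean", "null_sd", "p_upper", "p_lower",
    "p_two_sided", "direction",
]


@dataclass(frozen=True)
class MonteCarloConfig:
    """Test configuration.

    scope
        ``cross_species_only`` (default) restricts significance calls to
        cells whose row and column species differ; same-species blocks are
        still reported descriptively.  ``all_cells`` tests everything.
    tail
        ``two_sided`` (default), ``one_sided_upper`` or ``one_sided_lower``.
    adjust
        None (default, per-cell chance statements) or ``"bh"`` for a
        Benjamini-Hochberg correction across tested cells.
    check_null_conservation
        Assert on every permutation that each species' state frequencies
        are unchanged (test mode; costs a little time).
    """

    n_permutations: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    scope: str = "cross_species_only"
    tail: str = "two_sided"
    adjust: str | None = None
    check_null_conservation: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.scope not in ("cross_species_only", "all_cells"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.tail not in ("two_sided", "one_sided_upper", "one_sided_lower"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.adjust not in (None, "bh"):
            raise ValueError(f"unknown adjust {self.adjust!r}")


@dataclass
class NullCellSummary:
    """Permutation-null summary for one co-occurrence cell."""

    null_mean: float
    null_sd: float
    p_upper: float
    p_lower: float
    p_two_sided: float
    direction: str


@dataclass
class MonteCarloResult:
    month_pair: tuple[int, int]
    empirical: CooccurrenceMatrix
    summary: pd.DataFrame  # tidy, one row per ordered event pair
    config: MonteCarloConfig

    @property
    def label(self) -> str:
        return month_pair_label(self.month_pair)

    def cell(self, row_species: str, row_state: str,
             col_species: str, col_state: str) -> pd.Series:
        s = self.summary
        m = (
            (s["row_species"] == row_species) & (s["row_state"] == row_state)
            & (s["col_species"] == col_species) & (s["col_state"] == col_state)
        )
        hit = s[m]
        if hit.empty:
            raise KeyError(
                f"no cell ({row_species}:{row_state}, {col_species}:{col_state})"
            )
        return hit.iloc[0]


def permute_table(
    table: TransitionTable, rng: np.random.Generator
) -> TransitionTable:
    """Permute each species' transition states across sites independently."""
    codes = table.to_codes()
    permuted = np.empty_like(codes)
    n_sites = codes.shape[0]
    for j in range(codes.shape[1]):
        permuted[:, j] = codes[rng.permutation(n_sites), j]
    return TransitionTable.from_codes(
        table.month_pair, permuted, table.site_ids, table.species_ids
    )


def _permuted_codes(
    codes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = np.empty_like(codes)
    n_sites = codes.shape[0]
    for j in range(codes.shape[1]):
        out[:, j] = codes[rng.permutation(n_sites), j]
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def run_test(table: TransitionTable, config: MonteCarloConfig) -> MonteCarloResult:
    """Run the permutation test on one month pair's transition table."""
    if len(table.species_ids) < 2:
        raise ValueError("test needs >=2 species")
    if table.n_sites < 2:
        raise ValueError("test needs >=2 sites")

    codes = table.to_codes()
    emp = cooccurrence_matrix(table)
    emp_joint = emp.joint_counts.to_numpy(dtype=float)
    rows = emp.row_counts.to_numpy(dtype=float)
    n_events = emp_joint.shape[0]

    rng = np.random.default_rng(config.seed)
    B = config.n_permutations
    ge = np.zeros((n_events, n_events), dtype=np.int64)
    le = np.zeros((n_events, n_events), dtype=np.int64)
    s1 = np.zeros((n_events, n_events))
    s2 = np.zeros((n_events, n_events))
    state_freq = None
    if config.check_null_conservation:
        state_freq = np.stack(
            [np.bincount(codes[:, j], minlength=N_STATES)
             for j in range(codes.shape[1])]
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(rows > 0, rows, np.nan)[:, None]
        for _ in range(B):
            perm = _permuted_codes(codes, rng)
            if state_freq is not None:
                freq = np.stack(
                    [np.bincount(perm[:, j], minlength=N_STATES)
                     for j in range(perm.shape[1])]
                )
                assert np.array_equal(freq, state_freq), (
                    "permutation altered a species' state frequencies"
                )
            joint = joint_counts(perm)
            ge += joint >= emp_joint
            le += joint <= emp_joint
            prop = joint / denom
            s1 += np.nan_to_num(prop)
            s2 += np.nan_to_num(prop) ** 2

    null_mean = np.where(rows[:, None] > 0, s1 / B, np.nan)
    null_var = np.where(rows[:, None] > 0, s2 / B - (s1 / B) ** 2, np.nan)
    null_sd = np.sqrt(np.clip(null_var, 0.0, None))
    p_upper = (1.0 + ge) / (1.0 + B)
    p_lower = (1.0 + le) / (1.0 + B)
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_upper, p_lower))

    species_of_event = [sp for sp in table.species_ids for _ in STATES]
    state_of_event = [st for _ in table.species_ids for st in STATES]
    label = table.label

    records = []
    tested_mask = []
    for r in range(n_events):
        for c in range(n_events):
            cross = species_of_event[r] != species_of_event[c]
            defined = rows[r] > 0
            # same-species blocks stay descriptive unless scope=all_cells
            tested = defined and (cross or config.scope == "all_cells")
            if not defined:
                logger.debug(
                    "%s: row event %s:%s absent empirically; cell skipped",
                    label, species_of_event[r], state_of_event[r],
                )
            if config.tail == "two_sided":
                p_sel = p_two[r, c]
            elif config.tail == "one_sided_upper":
                p_sel = p_upper[r, c]
            else:
                p_sel = p_lower[r, c]
            records.append(
                (
                    label,
                    species_of_event[r], state_of_event[r],
                    species_of_event[c], state_of_event[c],
                    emp.proportions.iat[r, c] if defined else np.nan,
                    null_mean[r, c], null_sd[r, c],
                    p_upper[r, c] if defined else np.nan,
                    p_lower[r, c] if defined else np.nan,
                    p_sel if defined else np.nan,
                    DIRECTION_NONE,
                )
            )
            tested_mask.append(tested)

    summary = pd.DataFrame(records, columns=SUMMARY_COLUMNS)
    summary["tested"] = tested_mask

    # significance thresholding (optionally BH-adjusted across tested cells)
    tested_idx = summary.index[summary["tested"]]
    p_for_call = summary.loc[tested_idx, "p_two_sided"].to_numpy()
    if config.adjust == "bh" and len(tested_idx):
        p_for_call = _benjamini_hochberg(p_for_call)
        summary.loc[tested_idx, "p_adjusted"] = p_for_call
    sig = p_for_call <= config.alpha
    pu = summary.loc[tested_idx, "p_upper"].to_numpy()
    pl = summary.loc[tested_idx, "p_lower"].to_numpy()
    if config.tail == "one_sided_upper":
        direction = np.where(sig, DIRECTION_MORE, DIRECTION_NONE)
    elif config.tail == "one_sided_lower":
        direction = np.where(sig, DIRECTION_LESS, DIRECTION_NONE)
    else:
        direction = np.where(
            sig & (pu < pl), DIRECTION_MORE,
            np.where(sig & (pl < pu), DIRECTION_LESS, DIRECTION_NONE),
        )
    summary.loc[tested_idx, "direction"] = direction

    return MonteCarloResult(table.month_pair, emp, summary, config)


def report(
    result: MonteCarloResult,
    tsv_path=None,
    fig_path=None,
    header_lines: Iterable[str] = (),
) -> pd.DataFrame:
    """Emit the tidy cell summary as TSV and, optionally, a dot-matrix
    figure (blue = more than expected by chance, red = less)."""
    out = result.summary[SUMMARY_COLUMNS].copy()
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            out.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    if fig_path is not None:
        _dot_matrix_figure(result, fig_path)
    return out


def _dot_matrix_figure(result: MonteCarloResult, fig_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = result.empirical.event_keys
    n = len(labels)
    props = result.empirical.proportions.to_numpy()
    colors = {DIRECTION_MORE: "#1f77b4", DIRECTION_LESS: "#d62728",
              DIRECTION_NONE: "#bbbbbb"}
    dir_map = {
        (f"{r.row_species}:{r.row_state}", f"{r.col_species}:{r.col_state}"):
        r.direction
        for r in result.summary.itertuples()
    }
    fig, ax = plt.subplots(figsize=(0.45 * n + 2, 0.45 * n + 2))
    for i, rl in enumerate(labels):
        for j, cl in enumerate(labels):
            v = props[i, j]
            if np.isnan(v):
                continue
            ax.scatter(
                j, n - 1 - i, s=30 + 320 * v,
                color=colors[dir_map.get((rl, cl), DIRECTION_NONE)],
                edgecolors="black", linewidths=0.3,
            )
    ax.set_xticks(range(n), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(n), labels[::-1], fontsize=7)
    ax.set_xlim(-0.7, n - 0.3)
    ax.set_ylim(-0.7, n - 0.3)
    ax.set_title(
        f"Transition co-occurrence, {result.label} "
        "(blue: more than chance, red: less)"
    )
    fig.tight_layout()
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
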