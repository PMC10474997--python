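"""Readers/writers for the survey schemas, the pipeline driver and the
Results-style study summary.

All on-disk formats are plain CSV/TSV.  Pipeline artifacts carry `#`
provenance comment lines (config hash, seed, package version); every
reader skips such lines.

Schemas
-------
wells.csv            site_id,month,species_id,bio_rep,tech_rep,cq
                     (empty cq = no amplification)
dilution CSV         concentration,rep,cq
detection matrix CSV species_id,site_id,month,state   (state in {0,1,NA})
detections CSV       site_id,month,species_id,detected,n_positive_replicates,basis
transitions CSV      month_pair,site_id,species_id,state
co-occurrence TSV    square matrix, SPECIES:STATE row/column headers
MC results TSV       tidy cell summary (see montecarlo.SUMMARY_COLUMNS)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    DetectionMatrix,
    SpeciesSpec,
    month_ordinal,
    month_pair_label,
    roles_from_species,
)
from .montecarlo import MonteCarloConfig, MonteCarloResult, report, run_test
from .qpcr import (
    WELL_COLUMNS,
    DilutionSeries,
    StandardCurve,
    as_wells_frame,
    call_detections,
    calls_to_frame,
    fit_standard_curve,
)
from .simulate import DEFAULT_SPECIES, SyntheticDataset, make_scenario
from .transitions import (
    CooccurrenceMatrix,
    SiteSummary,
    TransitionTable,
    cooccurrence_matrix,
    encode_transitions,
    summarize_sites,
)

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Malformed input file; message names the file and offending content."""


def _read_csv(path, sep=",") -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _write_with_header(
    df: pd.DataFrame, path, sep: str, header_lines: Iterable[str]
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Wells / dilution series / detections
# ---------------------------------------------------------------------------

def read_wells(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, WELL_COLUMNS, path)
    try:
        return as_wells_frame(df[WELL_COLUMNS])
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def write_wells(wells, path, header_lines: Iterable[str] = ()) -> None:
    df = as_wells_frame(wells)
    _write_with_header(df, path, ",", header_lines)


def read_dilution_series(path) -> DilutionSeries:
    df = _read_csv(path)
    _require_columns(df, ["concentration", "rep", "cq"], path)
    try:
        return DilutionSeries.from_frame(df)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def write_dilution_series(
    series: DilutionSeries, path, header_lines: Iterable[str] = ()
) -> None:
    _write_with_header(series.to_frame(), path, ",", header_lines)


def write_detections(calls, path, header_lines: Iterable[str] = ()) -> None:
    _write_with_header(calls_to_frame(calls), path, ",", header_lines)


# ---------------------------------------------------------------------------
# Detection matrix
# ---------------------------------------------------------------------------

def read_detection_matrix(path) -> DetectionMatrix:
    df = _read_csv(path)
    _require_columns(df, ["species_id", "site_id", "month", "state"], path)
    try:
        return DetectionMatrix.from_frame(df)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def write_detection_matrix(
    matrix: DetectionMatrix, path, header_lines: Iterable[str] = ()
) -> None:
    _write_with_header(matrix.to_frame(), path, ",", header_lines)


# ---------------------------------------------------------------------------
# Transitions / co-occurrence / MC results
# ---------------------------------------------------------------------------

def write_transitions(
    tables: Sequence[TransitionTable], path, header_lines: Iterable[str] = ()
) -> None:
    rows = []
    for table in tables:
        label = table.label
        for site in table.site_ids:
            for sp in table.species_ids:
                rows.append((label, site, sp, table.states.at[site, sp]))
    df = pd.DataFrame(rows, columns=["month_pair", "site_id", "species_id", "state"])
    _write_with_header(df, path, ",", header_lines)


def read_transitions(path) -> list[TransitionTable]:
    """Rebuild one TransitionTable per month_pair label found in the file."""
    df = _read_csv(path)
    _require_columns(df, ["month_pair", "site_id", "species_id", "state"], path)

    def parse_pair(label: str) -> tuple[int, int]:
        a, _, b = str(label).partition("-")
        try:
            return (month_ordinal(a), month_ordinal(b))
        except ValueError:
            raise SchemaError(f"{path}: bad month_pair label {label!r}") from None

    tables = []
    for label, grp in df.groupby("month_pair", sort=False):
        pivot = grp.pivot(index="site_id", columns="species_id", values="state")
        if pivot.isna().any(axis=None):
            raise SchemaError(
                f"{path}: month_pair {label!r} is not complete over "
                "site x species"
            )
        try:
            tables.append(TransitionTable(parse_pair(label), pivot))
        except ValueError as exc:
            raise SchemaError(f"{path}: {exc}") from None
    tables.sort(key=lambda t: t.month_pair)
    return tables


def write_cooccurrence(
    matrix: CooccurrenceMatrix, path, header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        matrix.proportions.to_csv(
            fh, sep="\t", index=True, index_label="event", float_format="%.10g",
            na_rep="NA",
        )


def write_mc_result(
    result: MonteCarloResult, path, fig_path=None,
    header_lines: Iterable[str] = (),
) -> None:
    report(result, tsv_path=path, fig_path=fig_path, header_lines=header_lines)


# ---------------------------------------------------------------------------
# Study summary
# ---------------------------------------------------------------------------

def summarize_study(
    matrix: DetectionMatrix,
    roles: Mapping[str, str],
    wells=None,
    curves: Mapping[str, StandardCurve] | StandardCurve | None = None,
) -> SiteSummary:
    """Site-level guild fractions plus, when wells and curves are supplied,
    the fraction of field samples (site-month biological replicates) with at
    least one positive replicate for any target species."""
    summary = summarize_sites(matrix, roles)
    if wells is None:
        return summary
    if curves is None:
        raise ValueError("curves are required to score sample positivity")
    df = as_wells_frame(wells)
    if isinstance(curves, StandardCurve):
        curves = {sp: curves for sp in df["species_id"].unique()}
    from .qpcr import quantify_cq

    df = df.reset_index(drop=True)
    positive = np.zeros(len(df), dtype=bool)
    for sp, grp in df.groupby("species_id"):
        curve = curves[sp]
        if curve.lod is None:
            raise ValueError(f"curve for {sp!r} has no defined LOD")
        cq = grp["cq"].to_numpy(dtype=float)
        q = quantify_cq(curve, cq)  # NaN cq -> NaN quantity
        with np.errstate(invalid="ignore"):
            positive[grp.index] = ~np.isnan(cq) & (q > curve.lod)
    df = df.assign(_pos=positive)
    samples = df.groupby(["site_id", "month", "bio_rep"])["_pos"].any()
    return dataclasses.replace(
        summary,
        n_samples=int(len(samples)),
        n_samples_positive=int(samples.sum()),
    )


def summary_to_dict(summary: SiteSummary) -> dict:
    out = dataclasses.asdict(summary)
    out["fraction_samples_positive"] = summary.fraction_samples_positive
    out["percent"] = {
        k: round(100.0 * v)
        for k, v in out.items()
        if k.startswith("fraction_") and v is not None
    }
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either ``preset`` (simulate a survey) or ``wells_path``/``matrix_path``
    (analyze shipped data) must be set.  Standard curves come from
    ``curve_paths`` (dilution CSV per species) or fall back to the reference
    assay curve for simulated data.
    """

    out_dir: str | Path
    preset: str | None = "paper_like"
    seed: int = 1
    wells_path: str | Path | None = None
    matrix_path: str | Path | None = None
    curve_paths: dict[str, str] = field(default_factory=dict)
    species: tuple[SpeciesSpec, ...] = DEFAULT_SPECIES
    mc: MonteCarloConfig = field(default_factory=MonteCarloConfig)
    make_figures: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["wells_path"] = str(self.wells_path) if self.wells_path else None
        d["matrix_path"] = str(self.matrix_path) if self.matrix_path else None
        return d

    def config_hash(self) -> str:
        # hash the analytic configuration only: the same analysis written
        # to a different directory is the same run
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def provenance_lines(config: PipelineConfig) -> list[str]:
    return [
        f"edna-cooccur {__version__}",
        f"config_hash={config.config_hash()}",
        f"seed={config.seed}",
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain and write every artifact under ``config.out_dir``.

    Returns a dict of in-memory results: wells, matrix, tables, mc_results,
    summary, and the artifact paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = provenance_lines(config)
    roles = roles_from_species(config.species)
    curves: Mapping[str, StandardCurve] | StandardCurve

    dataset: SyntheticDataset | None = None
    truth = None
    if config.wells_path is not None:
        wells = read_wells(config.wells_path)
        if config.curve_paths:
            curves = {
                sp: fit_standard_curve(read_dilution_series(p))
                for sp, p in config.curve_paths.items()
            }
        else:
            from .qpcr import default_standard_curve
            curves = default_standard_curve()
    elif config.preset is not None:
        dataset = make_scenario(config.preset, config.seed)
        wells = dataset.wells
        truth = dataset.truth
        curves = dataset.curve
        write_detection_matrix(truth, out / "truth_matrix.csv", header)
    elif config.matrix_path is None:
        raise ValueError("config needs a preset, wells_path or matrix_path")

    if config.matrix_path is not None:
        matrix = read_detection_matrix(config.matrix_path)
        wells = None
        curves = None
        calls = []
    else:
        write_wells(wells, out / "wells.csv", header)
        calls, matrix = call_detections(wells, curves)
        write_detections(calls, out / "detections.csv", header)
    write_detection_matrix(matrix, out / "detection_matrix.csv", header)

    tables = [
        encode_transitions(matrix, (m, m + 1))
        for m in matrix.months[:-1]
    ]
    write_transitions(tables, out / "transitions.csv", header)

    mc_results = []
    paths = {}
    for table in tables:
        label = table.label
        co = cooccurrence_matrix(table)
        write_cooccurrence(co, out / f"cooccurrence_{label}.tsv", header)
        result = run_test(table, config.mc)
        fig = out / f"mc_{label}.png" if config.make_figures else None
        write_mc_result(result, out / f"mc_{label}.tsv", fig, header)
        mc_results.append(result)
        paths[label] = out / f"mc_{label}.tsv"
        logger.info(
            "%s: %d cells flagged at alpha=%g", label,
            int((result.summary["direction"] != "none").sum()),
            config.mc.alpha,
        )

    summary = summarize_study(
        matrix, roles,
        wells=wells if config.matrix_path is None else None,
        curves=curves if config.matrix_path is None else None,
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_to_dict(summary), fh, indent=2)
        fh.write("\n")

    with open(out / "provenance.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "config": config.to_dict(),
            },
            fh, indent=2, default=str,
        )
        fh.write("\n")

    return {
        "wells": wells,
        "matrix": matrix,
        "truth": truth,
        "tables": tables,
        "mc_results": mc_results,
        "summary": summary,
        "out_dir": out,
        "mc_paths": paths,
    }
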