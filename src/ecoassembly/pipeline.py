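"""End-to-end orchestration: preprocess, pair, null models, partition.

``run_pipeline`` takes aligned in-memory inputs (or use
:func:`run_from_paths` for files), applies the configured preprocessing,
builds the constrained pair set, runs the betaNTI and RC_Bray null
models, classifies every pair and aggregates per-group process
fractions. All randomness is derived from the single ``seed``, so a
rerun with the same inputs and seed reproduces every output byte for
byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import AlignmentReport, CommunityTable, align_inputs
from .io import read_count_table, read_loads, read_metadata, read_tree
from .pairs import PairConstraints, PairSet, select_pairs
from .partition import (
    AssemblyProfile,
    DriverRegression,
    ProcessLabel,
    aggregate_profile,
    classify_pair,
    driver_regression,
)
from .phylo import beta_nti_batch, patristic_matrix
from .preprocess import prevalence_filter, rarefy, to_absolute
from .raupcrick import metacommunity_pools, rc_bray

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_from_paths"]


@dataclass
class RunConfig:
    """Everything the pipeline needs beyond the input files.

    abundance_mode : {"rarefied", "absolute"}
        Whether null models run on rarefied integer counts (default) or
        on load-scaled absolute abundances (requires per-sample loads).
    pool_scope : {"group", "cohort"}
        Metacommunity pool for RC_Bray: the samples of each comparison
        group (default) or the whole analyzed table.
    """

    abundance_mode: str = "rarefied"
    rarefaction_depth: int = 4000
    min_prevalence: int = 3
    n_null_bnti: int = 999
    n_null_rc: int = 999
    weighted_bmntd: bool = True
    pool_scope: str = "group"
    constraints: PairConstraints = field(
        default_factory=lambda: PairConstraints(
            patient_relation="different",
            ward_relation="same",
            time_matching="same_calendar_week",
        )
    )
    driver_covariates: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.abundance_mode not in ("rarefied", "absolute"):
            raise ValueError(f"bad abundance_mode: {self.abundance_mode!r}")
        if self.pool_scope not in ("group", "cohort"):
            raise ValueError(f"bad pool_scope: {self.pool_scope!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "constraints" in raw:
            c = raw["constraints"]
            for key in ("ward_relation", "time_matching"):
                if isinstance(c.get(key), list):
                    c[key] = tuple(c[key])
            raw["constraints"] = PairConstraints(**c)
        return cls(**raw)

    def describe(self) -> str:
        return "\n".join(f"{k} = {v}" for k, v in sorted(vars(self).items()))


@dataclass
class PipelineResult:
    """All pipeline outputs plus the processed table they were computed on."""

    pair_results: pd.DataFrame
    profiles: list[AssemblyProfile]
    regressions: dict[str, DriverRegression]
    table: CommunityTable
    alignment: AlignmentReport
    dropped_low_depth: list[str]
    config: RunConfig
    seed: int

    def profiles_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            row = {"group": p.group_label, "n_pairs": p.n_pairs, "n_degenerate": p.n_degenerate}
            row.update({lab.value: p.fractions[lab] for lab in ProcessLabel})
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.pair_results.to_csv(
            os.path.join(outdir, "pair_results.tsv"), sep="\t", index=False
        )
        self.profiles_frame().to_csv(
            os.path.join(outdir, "process_fractions.tsv"), sep="\t", index=False
        )
        reg_rows = [vars(r) for r in self.regressions.values()]
        pd.DataFrame(reg_rows).to_csv(
            os.path.join(outdir, "driver_regression.tsv"), sep="\t", index=False
        )
        with open(os.path.join(outdir, "qc_report.txt"), "w") as fh:
            fh.write(self.qc_text())
        with open(os.path.join(outdir, "run_log.txt"), "w") as fh:
            fh.write(f"seed = {self.seed}\n{self.config.describe()}\n")

    def qc_text(self) -> str:
        degen = int(self.pair_results["degenerate"].sum())
        return (
            f"alignment: {self.alignment.summary()}\n"
            f"samples dropped below rarefaction depth: {self.dropped_low_depth}\n"
            f"degenerate pairs excluded from fractions: {degen}\n"
            f"pairs analyzed: {len(self.pair_results)}\n"
        )


def _rc_for_pairs(
    pairs: PairSet,
    table: CommunityTable,
    config: RunConfig,
    seed: int,
) -> list:
    """RC_Bray per pair with group- or cohort-scoped pools."""
    if config.pool_scope == "cohort":
        pools = {g: metacommunity_pools(table) for g in set(pairs.groups)}
    else:
        pools = {}
        for g in set(pairs.groups):
            members = sorted(
                {s for p, pg in zip(pairs.pairs, pairs.groups) if pg == g for s in p}
            )
            pools[g] = metacommunity_pools(table, members)
    return [
        rc_bray(p, table, pools[g], n_null=config.n_null_rc, seed=seed)
        for p, g in zip(pairs.pairs, pairs.groups)
    ]


def run_pipeline(
    table: CommunityTable,
    tree,
    meta: pd.DataFrame,
    config: RunConfig,
    seed: int,
    loads: dict[str, float] | None = None,
    copy_numbers: dict[str, float] | None = None,
) -> PipelineResult:
    table, tree, meta, report = align_inputs(table, tree, meta)

    table, dropped = rarefy(table, config.rarefaction_depth, seed)
    table = prevalence_filter(table, config.min_prevalence)
    if table.n_taxa == 0:
        raise ValueError("no taxa survive preprocessing")
    if config.abundance_mode == "absolute":
        if loads is None:
            raise ValueError("absolute abundance mode requires per-sample loads")
        table = to_absolute(table, loads, copy_numbers)
    # re-align so the tree matches the filtered taxon set
    table, tree, meta, _ = align_inputs(table, tree, meta)

    pairs = select_pairs(meta, config.constraints)
    if len(pairs) == 0:
        raise ValueError("constraints admit no sample pairs")

    dmat = patristic_matrix(tree)
    dmat = dmat.filter(table.taxon_ids)

    bnti_results = beta_nti_batch(
        pairs, table, dmat, n_null=config.n_null_bnti, seed=seed,
        weighted=config.weighted_bmntd,
    )

    # RC runs on integer counts; in absolute mode totals are rounded
    # because the null is an individual-based draw
    rc_table = table
    if config.abundance_mode == "absolute":
        rc_data = table.data.round().astype(np.int64)
        rc_table = CommunityTable(data=rc_data, is_absolute=False)
    rc_results = _rc_for_pairs(pairs, rc_table, config, seed)

    rows = []
    for (a, b), g, bres, rres in zip(pairs.pairs, pairs.groups, bnti_results, rc_results):
        label = ""
        if not bres.degenerate:
            label = classify_pair(bres.bnti, rres.rc).value
        rows.append(
            dict(
                sample_a=a, sample_b=b, group=g,
                bmntd=bres.bmntd_observed, null_mean=bres.null_mean,
                null_sd=bres.null_sd, bnti=bres.bnti, degenerate=bres.degenerate,
                bc_observed=rres.bc_observed, frac_below=rres.frac_below,
                rc=rres.rc, process=label,
            )
        )
    pair_results = pd.DataFrame(rows)

    profiles = aggregate_profile(pair_results, grouping="group")

    regressions = {}
    for cov in config.driver_covariates:
        try:
            regressions[cov] = driver_regression(pair_results, meta, cov)
        except ValueError as exc:
            warnings.warn(f"driver regression on {cov!r} skipped: {exc}", stacklevel=2)

    return PipelineResult(
        pair_results=pair_results,
        profiles=profiles,
        regressions=regressions,
        table=table,
        alignment=report,
        dropped_low_depth=dropped,
        config=config,
        seed=seed,
    )


def run_from_paths(
    counts_path,
    tree_path,
    meta_path,
    config: RunConfig,
    seed: int,
    loads_path=None,
    orientation: str = "samples_as_rows",
) -> PipelineResult:
    """File-based entry point used by the command-line interface."""
    table = read_count_table(counts_path, orientation=orientation)
    tree = read_tree(tree_path)
    meta = read_metadata(meta_path)
    loads = read_loads(loads_path) if loads_path else None
    return run_pipeline(table, tree, meta, config, seed, loads=loads)
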