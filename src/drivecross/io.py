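"""File schemas, run configuration and report generation.

Count tables and sequenced subsets travel as long-format CSV with documented
headers; loaders reject unknown schemas. Reference phenotype-count fixtures
transcribing the published F1/F2 tables ship with the package (the counts
are printed in full in the source tables) and carry the percentages and
denominators as printed, so reports can be checked against them cell by cell.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .cross_simulator import COUNT_COLUMNS, SUBSET_COLUMNS, SimParams
from .genetics_core import CrossSpec, Lineage
from .target_site_caller import DEFAULT_TARGET_SITE, TargetSiteRef

logger = logging.getLogger("drivecross")

SCHEMA_VERSION = "1"

FIXTURE_COLUMNS = [
    "background",
    "lineage",
    "eye",
    "cfp",
    "count",
    "printed_pct",
    "printed_denominator",
]


def _validate_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    if list(df.columns) != expected:
        raise ValueError(
            f"unrecognised {what} schema (version {SCHEMA_VERSION}): expected "
            f"columns {expected}, got {list(df.columns)}"
        )


def load_count_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate_columns(df, COUNT_COLUMNS, "count-table")
    return df


def save_count_table(df: pd.DataFrame, path: str | Path) -> None:
    _validate_columns(df, COUNT_COLUMNS, "count-table")
    df.to_csv(path, index=False)


def load_subset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate_columns(df, SUBSET_COLUMNS, "sequenced-subset")
    return df


def save_subset(df: pd.DataFrame, path: str | Path) -> None:
    _validate_columns(df, SUBSET_COLUMNS, "sequenced-subset")
    df.to_csv(path, index=False)


def _load_fixture(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("drivecross.data").joinpath(name)
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p)
    return df


def _warn_denominators(df: pd.DataFrame, table: str) -> pd.DataFrame:
    """Flag printed denominators that disagree with the row-count sums.

    The published F1 table prints one cell denominator (the female-lineage
    NDOKAYO cardinal cell) that is inconsistent with the rest of its row;
    the count sum is authoritative and the mismatch is warned about, never
    silently corrected.
    """
    totals = df.groupby(["background", "lineage"])["count"].transform("sum")
    bad = df.index[df["printed_denominator"] != totals]
    for i in bad:
        row = df.loc[i]
        logger.warning(
            "%s: printed denominator %d for %s/%s %s/%s disagrees with the "
            "row count sum %d; using the count sum",
            table,
            int(row["printed_denominator"]),
            row["background"],
            row["lineage"],
            row["eye"],
            row["cfp"],
            int(totals.loc[i]),
        )
    return df


def load_f1_reference_counts() -> pd.DataFrame:
    """Pooled F1 phenotype counts of the ten reference crosses (fixture)."""
    df = _load_fixture("table1_f1_phenotypes.csv")
    _validate_columns(df, FIXTURE_COLUMNS, "reference-count")
    return _warn_denominators(df, "F1 reference table")


def load_f2_reference_counts() -> pd.DataFrame:
    """Pooled F2 phenotype counts of the eight productive intercrosses (fixture)."""
    df = _load_fixture("table2_f2_phenotypes.csv")
    _validate_columns(df, FIXTURE_COLUMNS, "reference-count")
    return _warn_denominators(df, "F2 reference table")


def load_sequenced_nhej_reference() -> pd.DataFrame:
    """Published per-class NHEJ carrier percentages among sequenced F1 (fixture)."""
    df = _load_fixture("table3_sequenced_nhej.csv")
    _validate_columns(
        df, ["background", "blk_nhej_pct", "cd_nhej_pct"], "sequenced-NHEJ"
    )
    return df


def fixture_to_count_table(df: pd.DataFrame, generation: str) -> pd.DataFrame:
    """Reshape a reference fixture into the standard count-table schema.

    Fixture counts are three-replicate pools, recorded as a single
    pseudo-replicate 0.
    """
    out = df.copy()
    out["cross_id"] = out["background"] + "_" + out["lineage"]
    out["generation"] = generation
    out["replicate"] = 0
    return out[COUNT_COLUMNS]


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Validated end-to-end run configuration.

    Mirrors the simulation parameters, the cross list, sequencing-subsample
    sizes and the target-site reference; unknown keys anywhere raise a named
    error rather than being ignored.
    """

    params: SimParams = field(default_factory=SimParams)
    crosses: tuple[CrossSpec, ...] = ()
    n_sequence_per_class: int = 40
    target_site: TargetSiteRef = DEFAULT_TARGET_SITE
    output_dir: str = "out"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"simulation", "crosses", "estimation", "target_site", "output_dir", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        seed = int(d.get("seed", 0))
        sim = dict(d.get("simulation", {}))
        sim_fields = {f.name for f in fields(SimParams)}
        bad = set(sim) - sim_fields
        if bad:
            raise ValueError(f"unknown simulation keys: {sorted(bad)}")
        for key in ("dep_outcome", "g_germ"):
            if key in sim:
                sim[key] = tuple(sim[key])
        sim.setdefault("seed", seed)
        params = SimParams(**sim)
        crosses = []
        for c in d.get("crosses", []):
            bad = set(c) - {"background", "lineage", "hybrid_male_sterile", "snp_freq"}
            if bad:
                raise ValueError(f"unknown cross keys: {sorted(bad)}")
            crosses.append(
                CrossSpec(
                    background=c["background"],
                    lineage=Lineage(c["lineage"]),
                    hybrid_male_sterile=bool(c.get("hybrid_male_sterile", False)),
                    snp_freq=float(c.get("snp_freq", 0.0)),
                )
            )
        est = dict(d.get("estimation", {}))
        bad = set(est) - {"n_sequence_per_class"}
        if bad:
            raise ValueError(f"unknown estimation keys: {sorted(bad)}")
        ts = d.get("target_site")
        if ts is not None:
            bad = set(ts) - {"protospacer", "pam", "flank_left", "flank_right", "snp_defs"}
            if bad:
                raise ValueError(f"unknown target_site keys: {sorted(bad)}")
            target = TargetSiteRef(
                protospacer=ts["protospacer"],
                pam=ts["pam"],
                flank_left=ts["flank_left"],
                flank_right=ts["flank_right"],
                snp_defs=tuple(tuple(s) for s in ts.get("snp_defs", ())),
            )
        else:
            target = DEFAULT_TARGET_SITE
        return cls(
            params=params,
            crosses=tuple(crosses),
            n_sequence_per_class=int(est.get("n_sequence_per_class", 40)),
            target_site=target,
            output_dir=str(d.get("output_dir", "out")),
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Human-readable report


def _fmt_cell(count: int, total: int) -> str:
    return f"{100 * count / total:.1f}%({count}/{total})"


def phenotype_report(df: pd.DataFrame, title: str) -> str:
    """Printed-table-style report: percentages at 1 d.p. with counts in parens.

    Accepts either the standard count-table schema or a reference fixture.
    """
    lines = [title]
    for (background, lineage), grp in df.groupby(["background", "lineage"], sort=False):
        total = int(grp["count"].sum())
        cells = ", ".join(
            f"{row.eye}/{row.cfp} {_fmt_cell(int(row.count_), total)}"
            for row in grp.rename(columns={"count": "count_"}).itertuples(index=False)
        )
        lines.append(f"  {background} ({lineage}): {cells}  [n={total}]")
    return "\n".join(lines)
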