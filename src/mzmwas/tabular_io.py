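"""Readers/writers for the pipeline's tabular formats, plus packaged fixtures.

Feature tables follow the shape emitted by untargeted LC-MS peak-extraction
software: one row per m/z feature with columns ``mz``, ``rt`` and one
intensity column per sample.  Such software typically writes 0 for a
feature not detected in a sample, so the default dialect coerces zeros to
missing; pass ``zero_as_missing=False`` for data with true zeros.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .annotation import monoisotopic_mass
from .containers import (
    FeatureTable,
    MetaboliteRecord,
    ValidationError,
    make_feature_id,
    validate_samples,
)

_RT_ALIASES = ("rt", "time", "retention_time")


@dataclass
class TableDialect:
    """How to interpret a feature-table file."""

    zero_as_missing: bool = True  # peak extractors emit 0 for "not detected"
    sep: str = "\t"


def read_feature_table(
    path: Union[str, Path], dialect: Optional[TableDialect] = None
) -> FeatureTable:
    """Read a TSV/CSV feature table (columns: mz, rt/time, then samples)."""
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=dialect.sep)
    cols = {c.lower(): c for c in df.columns}
    if "mz" not in cols:
        raise ValidationError(f"{path}: missing required column 'mz'")
    rt_col = next((cols[a] for a in _RT_ALIASES if a in cols), None)
    if rt_col is None:
        raise ValidationError(f"{path}: missing retention-time column (rt/time)")
    mz = df[cols["mz"]].astype(float)
    rt = df[rt_col].astype(float)
    sample_cols = [c for c in df.columns if c not in (cols["mz"], rt_col)]
    if not sample_cols:
        raise ValidationError(f"{path}: no sample intensity columns found")
    data = df[sample_cols].astype(float)
    neg = data.lt(0).any(axis=1)
    if neg.any():
        raise ValidationError(
            f"{path}: negative intensity in row {int(np.nonzero(neg.to_numpy())[0][0])}"
        )
    if dialect.zero_as_missing:
        data = data.where(data != 0)
    fids = [make_feature_id(m, r) for m, r in zip(mz, rt)]
    data.index = fids
    mz.index = fids
    rt.index = fids
    return FeatureTable(data=data, mz=mz, rt=rt)


def write_feature_table(
    table: FeatureTable,
    path: Union[str, Path],
    dialect: Optional[TableDialect] = None,
) -> None:
    """Write a feature table; missing values are written as 0 when the
    dialect treats zeros as missing, otherwise as empty fields."""
    dialect = dialect or TableDialect()
    out = pd.DataFrame({"mz": table.mz, "rt": table.rt})
    data = table.data
    if dialect.zero_as_missing:
        data = data.fillna(0.0)
    out = pd.concat([out, data], axis=1)
    out.to_csv(path, sep=dialect.sep, index=False)


def read_metabolite_db(path: Union[str, Path]) -> list[MetaboliteRecord]:
    """Read a metabolite database TSV (id, name, formula, mass[, pathway]).

    Masses are filled from formulas when absent; when both are given they
    must agree within 1e-4 Da.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "name": str})
    if df.empty:
        return []
    required = {"id", "name"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        formula = row.get("formula")
        formula = None if pd.isna(formula) or formula == "" else str(formula)
        mass = row.get("mass")
        mass = None if pd.isna(mass) else float(mass)
        pathway = row.get("pathway")
        pathway = None if pd.isna(pathway) or pathway == "" else str(pathway)
        records.append(
            make_record(
                record_id=str(row["id"]),
                name=str(row["name"]),
                formula=formula,
                mass=mass,
                pathway_tag=pathway,
                context=f"{path} row {i}",
            )
        )
    return records


def make_record(
    record_id: str,
    name: str,
    formula: Optional[str] = None,
    mass: Optional[float] = None,
    source_tag: str = "",
    pathway_tag: Optional[str] = None,
    context: str = "",
) -> MetaboliteRecord:
    """Build a validated record, deriving the mass from the formula if needed."""
    where = f" ({context})" if context else ""
    if formula is None and mass is None:
        raise ValidationError(
            f"record {record_id!r}{where}: needs a formula or a mass"
        )
    if formula is not None:
        computed = monoisotopic_mass(formula)
        if mass is not None and abs(mass - computed) > 1e-4:
            raise ValidationError(
                f"record {record_id!r}{where}: mass {mass} disagrees with "
                f"formula-derived {computed:.6f} by more than 1e-4 Da"
            )
        mass = computed if mass is None else mass
    return MetaboliteRecord(
        record_id=record_id,
        name=name,
        monoisotopic_mass=float(mass),
        formula=formula,
        source_tag=source_tag,
        pathway_tag=pathway_tag,
    )


def write_metabolite_db(
    records: Iterable[MetaboliteRecord], path: Union[str, Path]
) -> None:
    rows = [
        {
            "id": r.record_id,
            "name": r.name,
            "formula": r.formula or "",
            "mass": r.monoisotopic_mass,
            "pathway": r.pathway_tag or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["id", "name", "formula", "mass", "pathway"]).to_csv(
        path, sep="\t", index=False
    )


def read_samples(path: Union[str, Path]) -> pd.DataFrame:
    """Read sample metadata TSV (columns: sample_id, group, covariates...)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    return validate_samples(df)


def write_samples(samples: pd.DataFrame, path: Union[str, Path]) -> None:
    samples.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures (transcribed printed tables, used for count/format tests)
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return importlib.resources.files("mzmwas").joinpath("data", name)


def load_table1_fixture() -> pd.DataFrame:
    """Seed features of the printed cluster table.

    21 rows: ``cluster`` label (1-4 or ``Independent``), seed ``mz`` at the
    printed 3-decimal precision (kept as strings, never re-rounded), and the
    printed comma-separated list of correlated features at r > 0.81.
    """
    with importlib.resources.as_file(_fixture_path("table1_clusters.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    df["correlated_features"] = df["correlated_features"].map(
        lambda s: [x.strip() for x in s.split(",")]
    )
    return df


def load_table2_fixture() -> pd.DataFrame:
    """Printed annotation table of the 17 clustered seed features."""
    with importlib.resources.as_file(_fixture_path("table2_annotations.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def load_demographics_fixture() -> pd.DataFrame:
    """Cohort balance counts reconstructed from the printed percentages
    (n = 26 cases / 19 controls), with the printed p-values alongside."""
    with importlib.resources.as_file(_fixture_path("demographics.tsv")) as p:
        return pd.read_csv(p, sep="\t")
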