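"""Readers and writers for the on-disk formats.

Intensity matrices travel as TSV/CSV with a header row of sample IDs,
metabolite IDs in the first column and an optional ``kegg_id`` second
column; missing cells are empty or the literal ``NA``.  Sample metadata
is a two-column table (sample, condition).  Pathways use the GMT
dialect (name, description, members, tab-separated).  Isotopologue
tables are long TSV (metabolite, kegg_id, mass_shift, sample, area).

All writers round-trip losslessly: values are serialized with
shortest-round-trip float representation, missingness as ``NA``, and
row/column order is preserved.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import AnalysisConfig, IntensityMatrix, IsotopologueTable, PathwaySet

logger = logging.getLogger(__name__)

#: cell contents interpreted as missing
MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan"})

KEGG_COLUMN = "kegg_id"


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_metadata(path: str | Path) -> pd.Series:
    """Read a two-column (sample, condition) table into a Series."""
    meta = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    cols = [c.lower() for c in meta.columns]
    if "sample" in cols and "condition" in cols:
        meta.columns = cols
    else:  # headerless two-column file
        meta = pd.read_csv(path, sep=_sep_for(path), dtype=str, header=None,
                           names=["sample", "condition"])
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample {dup!r} in metadata {path}")
    return pd.Series(meta["condition"].values, index=meta["sample"].values,
                     name="condition")


def read_intensity_matrix(path: str | Path, metadata_path: str | Path,
                          scale: str = "raw") -> IntensityMatrix:
    """Parse a metabolite x sample intensity table plus its metadata.

    ``scale`` declares the scale state of the values on disk
    (``"raw"`` for fresh peak areas; ``"log"``/``"log10"``/
    ``"median_centered"`` when re-reading preprocessed output).

    Raises
    ------
    ValueError
        If a sample column is absent from the metadata, or a
        non-missing cell fails to parse as a number (the error names
        the offending metabolite/sample cell).
    """
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected metabolite column plus >=1 sample column")
    met_col = raw.columns[0]
    metabolites = raw[met_col].astype(str)
    kegg = None
    body = raw.drop(columns=[met_col])
    if body.columns.size and body.columns[0] == KEGG_COLUMN:
        kegg_raw = body[KEGG_COLUMN].astype(str)
        kegg = pd.Series(
            [None if v in MISSING_TOKENS else v for v in kegg_raw],
            index=metabolites.values, name=KEGG_COLUMN,
        )
        body = body.drop(columns=[KEGG_COLUMN])

    condition = read_metadata(metadata_path)
    absent = [s for s in body.columns if s not in condition.index]
    if absent:
        raise ValueError(
            f"sample(s) {', '.join(absent)} in {path} absent from metadata "
            f"{metadata_path}"
        )

    values = np.empty(body.shape, dtype=float)
    for j, sample in enumerate(body.columns):
        col = body[sample].to_numpy()
        for i, cell in enumerate(col):
            if cell in MISSING_TOKENS:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric value {cell!r} at metabolite "
                        f"{metabolites.iloc[i]!r}, sample {sample!r} in {path}"
                    ) from None

    df = pd.DataFrame(values, index=pd.Index(metabolites.values, name=met_col),
                      columns=list(body.columns))
    matrix = IntensityMatrix(
        values=df,
        condition=condition.reindex(body.columns),
        kegg_ids=kegg,
        scale=scale,
    )
    matrix.log(f"read {df.shape[0]} metabolites x {df.shape[1]} samples from {path}")
    return matrix


def _fmt(value: float) -> str:
    """Lossless shortest float representation; NA for missing."""
    if isinstance(value, float) and np.isnan(value):
        return "NA"
    return repr(float(value))


def write_intensity_matrix(matrix: IntensityMatrix, path: str | Path,
                           metadata_path: str | Path | None = None) -> None:
    """Write a matrix (and optionally its metadata) back to disk."""
    sep = _sep_for(path)
    with open(path, "w") as fh:
        header = ["metabolite"]
        if matrix.kegg_ids is not None:
            header.append(KEGG_COLUMN)
        header.extend(str(s) for s in matrix.sample_ids)
        fh.write(sep.join(header) + "\n")
        for met in matrix.metabolite_ids:
            row = [str(met)]
            if matrix.kegg_ids is not None:
                kid = matrix.kegg_ids.loc[met]
                row.append("" if kid is None or (isinstance(kid, float) and np.isnan(kid)) else str(kid))
            row.extend(_fmt(v) for v in matrix.values.loc[met])
            fh.write(sep.join(row) + "\n")
    if metadata_path is not None:
        write_metadata(matrix.condition, metadata_path)


def write_metadata(condition: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcondition\n")
        for sample, cond in condition.items():
            fh.write(f"{sample}\t{cond}\n")


def read_kegg_map(path: str | Path) -> pd.Series:
    """Read a two-column (metabolite, kegg_id) mapping table."""
    tab = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    cols = [c.lower() for c in tab.columns]
    if "metabolite" in cols and KEGG_COLUMN in cols:
        tab.columns = cols
    else:
        tab = pd.read_csv(path, sep=_sep_for(path), dtype=str, header=None,
                          names=["metabolite", KEGG_COLUMN])
    return pd.Series(tab[KEGG_COLUMN].values, index=tab["metabolite"].values,
                     name=KEGG_COLUMN)


def write_kegg_map(mapping: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metabolite\tkegg_id\n")
        for met, kid in mapping.items():
            fh.write(f"{met}\t{kid}\n")


def read_pathways_gmt(path: str | Path) -> list[PathwaySet]:
    """Parse a GMT file: one pathway per line, tab-separated
    ``name<TAB>description<TAB>member1<TAB>member2...``.

    Pathways with zero members are skipped with a warning; a line with
    fewer than two fields raises with its line number.
    """
    pathways: list[PathwaySet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (need name + description)")
            name = fields[0]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                logger.warning("%s:%d: pathway %r has no members; skipped", path, lineno, name)
                continue
            pathways.append(PathwaySet(name=name, members=members))
    if not pathways:
        logger.warning("%s: no pathways read", path)
    return pathways


def write_pathways_gmt(pathways: list[PathwaySet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.name, "na", *sorted(pw.members)]) + "\n")


def read_isotopologue_table(path: str | Path, metadata_path: str | Path,
                            n_max: dict[str, int] | None = None) -> IsotopologueTable:
    """Read a long-format isotopologue TSV.

    When ``n_max`` is not supplied the carbon capacity of each
    metabolite is inferred as the largest mass shift present for it.
    """
    data = pd.read_csv(path, sep=_sep_for(path),
                       dtype={"metabolite": str, "kegg_id": str, "sample": str})
    data["mass_shift"] = data["mass_shift"].astype(int)
    data["area"] = data["area"].astype(float)
    condition = read_metadata(metadata_path)
    if n_max is None:
        n_max = {str(m): int(g["mass_shift"].max())
                 for m, g in data.groupby("metabolite", sort=False)}
    return IsotopologueTable(data=data, condition=condition, n_max=n_max)


def write_isotopologue_table(table: IsotopologueTable, path: str | Path,
                             metadata_path: str | Path | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("metabolite\tkegg_id\tmass_shift\tsample\tarea\n")
        for row in table.data.itertuples(index=False):
            fh.write(f"{row.metabolite}\t{row.kegg_id}\t{int(row.mass_shift)}\t"
                     f"{row.sample}\t{_fmt(float(row.area))}\n")
    if metadata_path is not None:
        write_metadata(table.condition, metadata_path)


def read_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a flat YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key/value mapping")
    known = AnalysisConfig.__dataclass_fields__.keys()
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**raw)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {k: getattr(config, k) for k in AnalysisConfig.__dataclass_fields__},
            fh, sort_keys=True,
        )


def sig12(x: float) -> float:
    """Round to 12 significant digits (report serialization convention)."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return x
    return float(f"{x:.12g}")


def write_table(df: pd.DataFrame, path: str | Path, *, index_label: str | None = None) -> None:
    """Write a result table as TSV with 12-significant-digit floats."""
    df.to_csv(path, sep="\t", float_format="%.12g",
              index_label=index_label if index_label else None,
              index=index_label is not None)
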