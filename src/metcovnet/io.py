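"""Tabular readers/writers and BrainNet Viewer export formats.

Subject metadata and SUVR matrices travel as delimited text (CSV/TSV).
Networks are exported in the two plain-text formats BrainNet Viewer
consumes: a ``.node`` file (one row per region: x y z color size label) and
a ``.edge`` file (square whitespace-separated weight matrix).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasSpec
from .datatypes import SubjectRecord, SUVRTable

__all__ = [
    "DEFAULT_SEX_MAP",
    "read_subject_table",
    "write_subject_table",
    "read_suvr_table",
    "write_suvr_table",
    "write_brainnet_node",
    "read_brainnet_node",
    "write_brainnet_edge",
    "read_brainnet_edge",
]

log = logging.getLogger(__name__)

# male=1 / female=0: sex enters the analyses as a numeric covariate
DEFAULT_SEX_MAP = {
    "m": 1, "male": 1, "1": 1,
    "f": 0, "female": 0, "0": 0,
}

_META_COLUMNS = ("subject_id", "group", "age", "sex", "bmi")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_subject_table(
    path: str | Path,
    sex_map: dict[str, int] | None = None,
) -> list[SubjectRecord]:
    """Read subject metadata and biomarkers from a delimited text file.

    Required columns: ``subject_id``, ``group``, ``age``, ``sex``. Optional:
    ``bmi`` plus any number of biomarker columns. Empty biomarker cells are
    preserved as missing (NaN), never imputed.

    Raises
    ------
    ValueError
        On duplicate subject ids or a sex value absent from ``sex_map``.
    """
    sex_map = DEFAULT_SEX_MAP if sex_map is None else sex_map
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"subject_id": str})
    missing = [c for c in ("subject_id", "group", "age", "sex") if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing required columns: {missing}")
    if df.empty:
        log.warning("subject table %s has a header but no data rows", path)
        return []
    dupes = df["subject_id"][df["subject_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate subject_id values: {dupes}")

    biomarker_cols = [c for c in df.columns if c not in _META_COLUMNS]
    records: list[SubjectRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        raw_sex = str(getattr(row, "sex")).strip().lower()
        if raw_sex not in sex_map:
            raise ValueError(
                f"row {row_no} (subject {row.subject_id}): "
                f"unmappable sex value {raw_sex!r}"
            )
        bmi = float(getattr(row, "bmi")) if "bmi" in df.columns else None
        if bmi is not None and np.isnan(bmi):
            bmi = None
        biomarkers = {c: float(getattr(row, c)) for c in biomarker_cols}
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                age=float(row.age),
                sex=sex_map[raw_sex],
                bmi=bmi,
                biomarkers=biomarkers,
            )
        )
    assert len(records) == len(df)
    return records


def write_subject_table(records: list[SubjectRecord], path: str | Path) -> None:
    """Write records to delimited text, one row per subject."""
    biomarker_names: list[str] = []
    for r in records:
        for b in r.biomarkers:
            if b not in biomarker_names:
                biomarker_names.append(b)
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "bmi": r.bmi if r.bmi is not None else np.nan,
        }
        row.update({b: r.biomarkers.get(b, np.nan) for b in biomarker_names})
        rows.append(row)
    cols = list(_META_COLUMNS) + biomarker_names
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_sep_for(path), index=False, float_format="%.10g")


def write_suvr_table(table: SUVRTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.insert(0, "subject_id", table.subject_ids)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.10g")


def read_suvr_table(path: str | Path, atlas: AtlasSpec, kind: str = "suvr") -> SUVRTable:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"subject_id": str})
    names = atlas.analysis_names
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValueError(f"SUVR table missing region columns: {missing[:5]}...")
    return SUVRTable(df["subject_id"].tolist(), atlas, df[names].to_numpy(float), kind)


def write_brainnet_node(
    atlas: AtlasSpec,
    colors: np.ndarray,
    sizes: np.ndarray,
    path: str | Path,
) -> None:
    """Write a BrainNet Viewer ``.node`` file for the analysis regions.

    Six whitespace-separated columns per row: x y z color size label, in
    atlas order. ``colors`` conventionally carries the group-difference
    direction (+1/-1/0) and ``sizes`` an effect magnitude.
    """
    colors = np.asarray(colors, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    n = atlas.n_analysis
    if colors.shape != (n,) or sizes.shape != (n,):
        raise ValueError(
            f"need one color and one size per analysis region ({n}); "
            f"got {colors.shape} and {sizes.shape}"
        )
    centers = atlas.centers()
    lines = []
    for i, region in enumerate(atlas.analysis_regions):
        x, y, z = centers[i]
        lines.append(
            f"{x:.6g}\t{y:.6g}\t{z:.6g}\t{colors[i]:.6g}\t{sizes[i]:.6g}\t{region.name}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_brainnet_node(path: str | Path) -> pd.DataFrame:
    """Parse a ``.node`` file back into a DataFrame (x, y, z, color, size, label)."""
    text = Path(path).read_text().strip()
    if not text:
        return pd.DataFrame(columns=["x", "y", "z", "color", "size", "label"])
    rows = []
    for line in text.splitlines():
        parts = line.split()
        rows.append(
            dict(
                x=float(parts[0]), y=float(parts[1]), z=float(parts[2]),
                color=float(parts[3]), size=float(parts[4]), label=parts[5],
            )
        )
    return pd.DataFrame(rows)


def write_brainnet_edge(matrix: np.ndarray, path: str | Path) -> None:
    """Write a square symmetric matrix as a BrainNet Viewer ``.edge`` file.

    Values are formatted at 6 significant digits; the diagonal is written
    as zero.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"edge matrix must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("edge matrix must be symmetric")
    m = m.copy()
    np.fill_diagonal(m, 0.0)
    lines = ["\t".join(f"{v:.6g}" for v in row) for row in m]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_brainnet_edge(path: str | Path) -> np.ndarray:
    rows = [
        [float(v) for v in line.split()]
        for line in Path(path).read_text().strip().splitlines()
        if line.strip()
    ]
    m = np.asarray(rows, dtype=float)
    if m.size and m.shape[0] != m.shape[1]:
        raise ValueError(f"edge file is not square: {m.shape}")
    return m
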