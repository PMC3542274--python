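"""TSV/YAML readers and writers.

All tabular formats are UTF-8 tab-separated files with '#' comment lines;
genotype calls are written 1 (retained), 0 (lost), NA (missing).  Writers
prepend a header comment recording the package version and, where relevant,
the seed and scenario parameters, so every output is self-describing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype import GenotypeMatrix
from .mapping import FrameworkMap
from .markers import MarkerDef, MarkerMap
from .simulate import PanelScenario, TruthRecord

_CALL_SYMBOLS = {"1", "0", "NA"}


def _header(params: Mapping[str, object] | None = None) -> str:
    parts = [f"# rhpanel v{__version__}"]
    if params:
        parts.append(
            "# " + " ".join(f"{k}={v}" for k, v in params.items())
        )
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a matrix TSV: line_id [family_id] then one column per marker."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.columns[0] != "line_id":
        raise ValueError(
            f"{path}: first column must be 'line_id', got {df.columns[0]!r}"
        )
    has_family = len(df.columns) > 1 and df.columns[1] == "family_id"
    marker_cols = list(df.columns[2 if has_family else 1 :])
    if not marker_cols:
        raise ValueError(f"{path}: no marker columns")
    line_ids = df["line_id"].tolist()
    if len(set(line_ids)) != len(line_ids):
        raise ValueError(f"{path}: duplicate line ids")
    if len(set(marker_cols)) != len(marker_cols):
        raise ValueError(f"{path}: duplicate marker columns")
    grid = np.empty((len(line_ids), len(marker_cols)))
    for j, col in enumerate(marker_cols):
        for i, v in enumerate(df[col].astype(str)):
            if v == "1":
                grid[i, j] = 1.0
            elif v == "0":
                grid[i, j] = 0.0
            elif v in ("NA", "nan"):
                grid[i, j] = np.nan
            else:
                raise ValueError(
                    f"{path}: invalid call {v!r} at line "
                    f"{line_ids[i]!r}, marker {col!r}"
                )
    family_of = (
        dict(zip(line_ids, df["family_id"].tolist())) if has_family else None
    )
    return GenotypeMatrix(grid, line_ids, marker_cols, family_of)


def write_genotype_matrix(
    matrix: GenotypeMatrix,
    path: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(params))
        cols = ["line_id"]
        if matrix.family_of:
            cols.append("family_id")
        fh.write("\t".join(cols + matrix.marker_ids) + "\n")
        for i, line in enumerate(matrix.line_ids):
            row = [line]
            if matrix.family_of:
                row.append(matrix.family_of.get(line, "NA"))
            for v in matrix.calls[i, :]:
                row.append("NA" if np.isnan(v) else str(int(v)))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ("marker_id", "chromosome", "bin_label", "pos_bp", "pos_cM", "system")


def read_marker_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("marker_id", "chromosome"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    lengths: dict[str, int] = {}
    centromeres: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("# chrom_length_bp"):
                _, _, rest = raw.partition("chrom_length_bp")
                for tok in rest.split():
                    c, _, v = tok.partition("=")
                    lengths[c] = int(v)
            elif raw.startswith("# centromere_bp"):
                _, _, rest = raw.partition("centromere_bp")
                for tok in rest.split():
                    c, _, v = tok.partition("=")
                    centromeres[c] = int(v)
    markers = []
    for _, row in df.iterrows():
        def opt(col: str):
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) or v == "NA" else v

        pos_bp = opt("pos_bp")
        pos_cm = opt("pos_cM")
        markers.append(
            MarkerDef(
                marker_id=row["marker_id"],
                chromosome=row["chromosome"],
                bin_label=opt("bin_label"),
                pos_bp=int(pos_bp) if pos_bp is not None else None,
                pos_cM=float(pos_cm) if pos_cm is not None else None,
                system=opt("system"),
            )
        )
    return MarkerMap(
        markers=markers, chrom_length_bp=lengths, centromere_bp=centromeres
    )


def write_marker_map(
    marker_map: MarkerMap,
    path: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(params))
        if marker_map.chrom_length_bp:
            fh.write(
                "# chrom_length_bp "
                + " ".join(
                    f"{c}={v}" for c, v in marker_map.chrom_length_bp.items()
                )
                + "\n"
            )
        if marker_map.centromere_bp:
            fh.write(
                "# centromere_bp "
                + " ".join(
                    f"{c}={v}" for c, v in marker_map.centromere_bp.items()
                )
                + "\n"
            )
        fh.write("\t".join(_MAP_COLUMNS) + "\n")
        for m in marker_map.markers:
            fh.write(
                "\t".join(
                    [
                        m.marker_id,
                        m.chromosome,
                        m.bin_label or "NA",
                        str(m.pos_bp) if m.pos_bp is not None else "NA",
                        str(m.pos_cM) if m.pos_cM is not None else "NA",
                        m.system or "NA",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# family table, truth record, framework map
# ---------------------------------------------------------------------------


def write_family_table(
    family_of: Mapping[str, str],
    path: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(params))
        fh.write("line_id\tfamily_id\n")
        for line, fam in family_of.items():
            fh.write(f"{line}\t{fam}\n")


def read_family_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return dict(zip(df["line_id"], df["family_id"]))


def write_truth_record(
    truth: TruthRecord,
    path: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    """True per-line deletion intervals (line_id, chromosome, homolog,
    start_bp, end_bp); the header also records the true G."""
    merged = dict(params or {})
    merged["true_G"] = truth.G
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(merged))
        fh.write("line_id\tchromosome\thomolog\tstart_bp\tend_bp\n")
        for line, dels in truth.line_deletions.items():
            hom = truth.line_source[line][2]
            for chrom, s, e in dels:
                fh.write(f"{line}\t{chrom}\t{hom}\t{s}\t{e}\n")


def write_framework_map(
    framework: FrameworkMap,
    path: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(params))
        fh.write("marker_id\tposition_cR\tbin_id\n")
        for p in framework.positions:
            fh.write(f"{p.marker_id}\t{p.position_cR:.4f}\t{p.bin_id}\n")


def write_graphical_genotype(
    grid: pd.DataFrame,
    path: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(params))
        grid.to_csv(fh, sep="\t", index_label="line_id")


def read_graphical_genotype(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", dtype=str, index_col="line_id",
        keep_default_na=False,
    )


# ---------------------------------------------------------------------------
# scenario config
# ---------------------------------------------------------------------------


def load_scenario(path: str | Path, **overrides) -> PanelScenario:
    """Read a PanelScenario from a flat YAML mapping; kwargs override."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario YAML must be a mapping")
    known = {f.name for f in dataclasses.fields(PanelScenario)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown scenario keys {sorted(unknown)}")
    raw.update(overrides)
    return PanelScenario(**raw)


def save_scenario(scenario: PanelScenario, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(scenario), fh, sort_keys=False)
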