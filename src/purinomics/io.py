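"""Tabular I/O for metabolomics and calorimetry data, plus analysis configuration.

Delimited-text readers and writers for the sample x metabolite peak-area
(AUC) tables, metabolite -> pathway maps, and interval-level indirect
calorimetry traces.  CSV vs TSV is auto-detected from the file extension.
Samples are rows and metabolites are columns; a ``transpose`` flag accepts
the other dialect.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .physiology import CalorimetryTrace

logger = logging.getLogger(__name__)

#: Pathway assigned to metabolites missing from the pathway map.
UNMAPPED = "Unmapped"

_CALORIMETRY_COLUMNS = ["animal", "group", "start_min", "vo2", "vco2", "beam_breaks"]


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt", ".tab")) else ","


@dataclass
class MetaboliteMatrix:
    """Sample x metabolite AUC table with group labels and a pathway map.

    Attributes
    ----------
    auc : pandas.DataFrame
        Positive peak areas, samples as rows, metabolites as columns.
    groups : pandas.Series
        Group label per sample (index-aligned with ``auc``); opaque strings,
        e.g. ``saline`` / ``ATP_30min``.  The control group is only ever
        identified by name, never by position.
    pathways : pandas.Series
        Pathway name per metabolite (index = metabolite names).
    sex : pandas.Series or None
        Optional per-sample sex labels.
    """

    auc: pd.DataFrame
    groups: pd.Series
    pathways: pd.Series
    sex: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.auc.index.duplicated().any():
            dup = self.auc.index[self.auc.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.auc.columns.duplicated().any():
            dup = self.auc.columns[self.auc.columns.duplicated()][0]
            raise ValueError(f"duplicate metabolite id: {dup!r}")
        values = self.auc.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("AUC table contains non-numeric values")
        bad = ~(values > 0) | ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-positive or missing AUC for sample {self.auc.index[i]!r}, "
                f"metabolite {self.auc.columns[j]!r}: {values[i, j]!r}"
            )
        missing_group = self.auc.index.difference(self.groups.index)
        if len(missing_group):
            raise ValueError(f"sample {missing_group[0]!r} has no group label")
        self.groups = self.groups.reindex(self.auc.index)
        missing_path = self.auc.columns.difference(self.pathways.index)
        if len(missing_path):
            raise ValueError(f"metabolite {missing_path[0]!r} has no pathway")
        self.pathways = self.pathways.reindex(self.auc.columns)
        if self.sex is not None:
            self.sex = self.sex.reindex(self.auc.index)

    @property
    def samples(self) -> pd.Index:
        return self.auc.index

    @property
    def metabolites(self) -> pd.Index:
        return self.auc.columns

    def subset_groups(self, groups: list[str]) -> "MetaboliteMatrix":
        """Restrict to samples belonging to the named groups."""
        keep = self.groups.isin(groups)
        return MetaboliteMatrix(
            auc=self.auc.loc[keep],
            groups=self.groups.loc[keep],
            pathways=self.pathways,
            sex=None if self.sex is None else self.sex.loc[keep],
        )


def read_metabolite_table(
    path: str | Path,
    pathway_map_path: str | Path,
    group_column: str = "group",
    sex_column: str | None = None,
    transpose: bool = False,
) -> MetaboliteMatrix:
    """Read a delimited AUC table plus a metabolite -> pathway map.

    The table must have a header row, sample ids in the first column, a
    ``group_column``, and one numeric column per metabolite.  Metabolites
    absent from the pathway map are assigned the pathway ``"Unmapped"``
    with a logged warning.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if transpose:
        df = df.T
    if group_column not in df.columns:
        raise ValueError(f"missing group column {group_column!r} in {path}")
    groups = df[group_column].astype(str)
    meta_cols = [group_column] + ([sex_column] if sex_column else [])
    sex = df[sex_column].astype(str) if sex_column else None
    auc = df.drop(columns=meta_cols)
    # Coerce and point at the first offending cell, not just "bad table".
    for col in auc.columns:
        vals = pd.to_numeric(auc[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            sample = auc.index[bad.to_numpy()][0]
            raise ValueError(
                f"non-numeric or non-positive AUC at sample {sample!r}, "
                f"metabolite {col!r}: {auc.loc[sample, col]!r}"
            )
        auc[col] = vals
    pmap = pd.read_csv(pathway_map_path, sep=_sep_for(pathway_map_path))
    pathways = pd.Series(
        pmap.iloc[:, 1].astype(str).to_numpy(), index=pmap.iloc[:, 0].astype(str)
    )
    unmapped = auc.columns.difference(pathways.index)
    if len(unmapped):
        logger.warning(
            "%d metabolites missing from pathway map assigned %r: %s",
            len(unmapped), UNMAPPED, list(unmapped[:5]),
        )
        pathways = pd.concat(
            [pathways, pd.Series(UNMAPPED, index=unmapped)]
        )
    pathways = pathways.reindex(auc.columns)
    auc.index.name = None
    auc.columns.name = None
    groups.name = "group"
    return MetaboliteMatrix(auc=auc, groups=groups, pathways=pathways, sex=sex)


def write_metabolite_table(
    matrix: MetaboliteMatrix,
    path: str | Path,
    pathway_map_path: str | Path | None = None,
    group_column: str = "group",
) -> None:
    """Write a MetaboliteMatrix in the layout ``read_metabolite_table`` accepts."""
    df = matrix.auc.copy()
    df.insert(0, group_column, matrix.groups)
    df.index.name = "sample"
    df.to_csv(path, sep=_sep_for(path))
    if pathway_map_path is not None:
        pd.DataFrame(
            {"metabolite": matrix.pathways.index, "pathway": matrix.pathways.to_numpy()}
        ).to_csv(pathway_map_path, sep=_sep_for(pathway_map_path), index=False)


def read_calorimetry(path: str | Path) -> list[CalorimetryTrace]:
    """Read interval-level calorimetry rows into one trace per animal.

    Expected columns: animal, group, start_min, vo2, vco2, beam_breaks.
    Intervals are sorted by start time per animal; duplicate timestamps for
    one animal are an error.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in _CALORIMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calorimetry file {path} missing column(s): {missing}")
    traces = []
    for animal, sub in df.groupby("animal", sort=True):
        sub = sub.sort_values("start_min")
        if sub["start_min"].duplicated().any():
            t = sub.loc[sub["start_min"].duplicated(), "start_min"].iloc[0]
            raise ValueError(f"duplicate interval start {t} for animal {animal!r}")
        traces.append(
            CalorimetryTrace(
                animal=str(animal),
                group=str(sub["group"].iloc[0]),
                intervals=sub[["start_min", "vo2", "vco2", "beam_breaks"]].reset_index(
                    drop=True
                ),
            )
        )
    return traces


def write_calorimetry(traces: list[CalorimetryTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        sub = tr.intervals.copy()
        sub.insert(0, "group", tr.group)
        sub.insert(0, "animal", tr.animal)
        rows.append(sub)
    pd.concat(rows, ignore_index=True).to_csv(path, sep=_sep_for(path), index=False)


@dataclass
class AnalysisConfig:
    """Thresholds, component counts and seeds for a metabolomics run.

    ``fdr_max``, ``vip_min`` and ``p_max`` reproduce the headline
    significance filter (FDR < 0.05, VIP >= 0.9, t-test p < 0.05);
    ``cluster_vip_threshold`` gates which members count toward supercluster
    impact (1.0 for the acute 30-min tables, 1.5 for the 4-hour tables).
    """

    control_group: str = "saline"
    fdr_max: float = 0.05
    vip_min: float = 0.9
    p_max: float = 0.05
    cluster_vip_threshold: float = 1.0
    n_components: int = 2
    n_clusters: int = 10
    knn_k: int = 10
    n_trees: int = 200
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("fdr_max", "p_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.vip_min < 0:
            raise ValueError(f"vip_min must be >= 0, got {self.vip_min}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
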