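"""Control-referenced z-scoring of log2 peak areas.

Raw AUCs are log2-transformed and each metabolite is standardized against
the mean and sample SD of the designated control group, so downstream
effect sizes are in control-SD units.  A generalized log transform
``glog2(y) = log2(y + 1)`` is provided for cytokine-like concentrations
that can fall between 0 and 1 pg/ml.  Missing values are a hard error
throughout: no imputation path exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MetaboliteMatrix


@dataclass
class ZScoreMatrix:
    """Control-referenced z-scores with their standardization parameters.

    ``z`` is samples x metabolites, dimensionless (control-SD units);
    ``control_mean``/``control_sd`` are the per-metabolite log2-scale
    parameters used; ``excluded`` lists metabolites dropped for zero
    control SD.
    """

    z: pd.DataFrame
    groups: pd.Series
    control_group: str
    control_mean: pd.Series
    control_sd: pd.Series
    excluded: list = field(default_factory=list)
    source: MetaboliteMatrix | None = None

    @property
    def metabolites(self) -> pd.Index:
        return self.z.columns

    def treated_mask(self) -> pd.Series:
        return self.groups != self.control_group

    def mean_treated_z(self) -> pd.Series:
        """Per-metabolite mean z over all non-control samples."""
        return self.z.loc[self.treated_mask()].mean(axis=0)


def log2_transform(matrix: MetaboliteMatrix | pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2 of a positive AUC table."""
    df = matrix.auc if isinstance(matrix, MetaboliteMatrix) else matrix
    values = df.to_numpy(dtype=float)
    if np.any(~(values > 0)):
        i, j = np.argwhere(~(values > 0))[0]
        raise ValueError(
            f"non-positive AUC at sample {df.index[i]!r}, metabolite "
            f"{df.columns[j]!r}; cannot log2-transform"
        )
    return pd.DataFrame(np.log2(values), index=df.index, columns=df.columns)


def control_zscore(
    matrix: MetaboliteMatrix | pd.DataFrame,
    control_group: str,
    groups: pd.Series | None = None,
) -> ZScoreMatrix:
    """Standardize log2 AUCs against the control group's mean and sample SD.

    z_ij = (log2 x_ij - mu_ctrl_j) / sigma_ctrl_j with sigma the control
    sample SD (denominator n-1).  Metabolites with zero control SD are
    excluded with a warning.  The control group must have >= 3 samples.
    """
    if isinstance(matrix, MetaboliteMatrix):
        groups = matrix.groups
        log2 = log2_transform(matrix)
        source = matrix
    else:
        if groups is None:
            raise ValueError("groups required when passing a bare log2 table")
        log2 = matrix
        source = None
    is_ctrl = groups == control_group
    n_ctrl = int(is_ctrl.sum())
    if n_ctrl < 3:
        raise ValueError(
            f"control group {control_group!r} has {n_ctrl} samples; need >= 3"
        )
    ctrl = log2.loc[is_ctrl]
    mu = ctrl.mean(axis=0)
    sigma = ctrl.std(axis=0, ddof=1)
    degenerate = sigma <= 0
    excluded = list(log2.columns[degenerate])
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} metabolite(s) with zero control SD: "
            f"{excluded[:5]}",
            stacklevel=2,
        )
    keep = log2.columns[~degenerate]
    z = (log2[keep] - mu[keep]) / sigma[keep]
    return ZScoreMatrix(
        z=z,
        groups=groups,
        control_group=control_group,
        control_mean=mu[keep],
        control_sd=sigma[keep],
        excluded=excluded,
        source=source,
    )


def glog2(y):
    """Generalized log transform glog2(y) = log2(y + 1) for y >= 0.

    Keeps fractional concentrations between 0 and 1 pg/ml non-negative on
    the transformed scale.
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0):
        raise ValueError("glog2 requires non-negative input")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def export_control_stats(zmat: ZScoreMatrix, path) -> None:
    """Audit export of per-metabolite control mean and SD (TSV)."""
    pd.DataFrame(
        {
            "metabolite": zmat.control_mean.index,
            "control_log2_mean": zmat.control_mean.to_numpy(),
            "control_log2_sd": zmat.control_sd.to_numpy(),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
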