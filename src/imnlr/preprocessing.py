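"""Quality control and value-scale transforms for methylation matrices.

The container is a CpG x sample matrix of beta values (methylation
fractions in [0, 1]) with an optional matched matrix of detection
p-values.  QC drops CpGs failing detection in a sizable fraction of
samples; the beta/M transforms move between the bounded fraction scale
and the variance-stabilized log2-ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_P_THRESHOLD = 1e-5
DEFAULT_SAMPLE_FRACTION = 0.25
DEFAULT_EPSILON = 1e-3


@dataclass
class BetaMatrix:
    """CpG x sample beta values with optional matched detection p-values."""

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise ValueError("CpG and sample ids must be unique")
        arr = v.to_numpy()
        if np.isnan(arr).any():
            raise ValueError("beta matrix contains missing values")
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.detection_p is not None:
            p = self.detection_p
            if not (p.index.equals(v.index) and p.columns.equals(v.columns)):
                raise ValueError(
                    "detection_p must match the beta matrix shape and ordering"
                )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cpgs(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)


def filter_detection_p(
    beta: BetaMatrix,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    sample_fraction: float = DEFAULT_SAMPLE_FRACTION,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Drop CpGs whose detection-failure fraction strictly exceeds the cut.

    A probe call fails when detection p > ``p_threshold``; the CpG is
    removed when the fraction of failing samples is strictly greater than
    ``sample_fraction`` (a probe failing in exactly that fraction is kept).
    Returns the filtered matrix and a removal log with one row per CpG
    (``failure_fraction``, ``removed``).  Column order and surviving row
    order are preserved.
    """
    if beta.detection_p is None:
        raise ValueError(
            "detection p-values are required for QC; skip this step explicitly "
            "if the data carry none"
        )
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    if not 0 < sample_fraction < 1:
        raise ValueError("sample_fraction must be in (0, 1)")

    frac = (beta.detection_p.to_numpy() > p_threshold).mean(axis=1)
    removed = frac > sample_fraction
    log = pd.DataFrame(
        {"failure_fraction": frac, "removed": removed}, index=beta.cpg_ids
    )
    keep = ~removed
    filtered = BetaMatrix(
        values=beta.values.loc[keep],
        detection_p=beta.detection_p.loc[keep],
    )
    return filtered, log


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """Logit2 transform: M = log2(b / (1 - b)) with clipping at epsilon.

    Betas are clipped into [epsilon, 1 - epsilon] first, so M is finite
    everywhere and strictly increasing on the clipped range.  Accepts
    scalars, arrays, Series or DataFrames and preserves the input type.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    if isinstance(beta, (pd.DataFrame, pd.Series)):
        clipped = beta.clip(epsilon, 1.0 - epsilon)
        return np.log2(clipped / (1.0 - clipped))
    arr = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    out = np.log2(arr / (1.0 - arr))
    return out.item() if np.isscalar(beta) or out.ndim == 0 else out

def m_to_beta(m):
    """Inverse logit2: b = 2^M / (1 + 2^M), the exact inverse of unclipped M."""
    if isinstance(m, (pd.DataFrame, pd.Series)):
        return 1.0 / (1.0 + 2.0 ** (-m))
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + 2.0 ** (-arr))
    return out.item() if np.isscalar(m) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Delimited-text I/O (first column CpG id, header row sample ids)
# ---------------------------------------------------------------------------


def read_beta_csv(
    beta_path: str | Path, detection_path: str | Path | None = None
) -> BetaMatrix:
    values = pd.read_csv(beta_path, index_col=0)
    detection = (
        pd.read_csv(detection_path, index_col=0) if detection_path is not None else None
    )
    return BetaMatrix(values=values, detection_p=detection)


def write_beta_csv(
    beta: BetaMatrix, beta_path: str | Path, detection_path: str | Path | None = None
) -> None:
    beta.values.to_csv(beta_path, float_format="%.6g")
    if detection_path is not None and beta.detection_p is not None:
        beta.detection_p.to_csv(detection_path, float_format="%.6g")


def write_removal_log(log: pd.DataFrame, path: str | Path) -> None:
    out = log.copy()
    out.index.name = "cpg_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
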