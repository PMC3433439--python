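"""Variance stabilization and removal of fixed technical effects.

Two-channel intensities are put on a common scale with a robust
affine-arsinh (generalized-log) transform, then a per-gene fixed-effect
linear model strips dye, block, batch and person effects; the residuals
are the expression traits handed to QTL mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_FACTORS = ("dye", "block", "batch", "person")


def glog_normalize(
    intensities: pd.DataFrame, samplesheet: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Calibrate channels to a common scale and arsinh-transform.

    Each channel c is matched to the first (reference) channel by a robust
    affine calibration ``(x - a_c) / b_c`` with ``b_c = MAD_c / MAD_ref``
    and ``a_c = median_c - b_c * median_ref``, then transformed with
    ``h = asinh`` of the calibrated value.  One calibration is run jointly
    across all channels of the experiment (a single normalization of all
    columns), and the arsinh damps the variance of multiplicatively noisy
    intensities so the per-stratum SD is roughly flat in the mean.
    """
    if intensities.shape[1] < 2:
        raise ValueError("need at least two channels to normalize")
    if (intensities.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    med = intensities.median(axis=0)
    mad = (intensities - med).abs().median(axis=0)
    zero = mad[mad == 0.0]
    if not zero.empty:
        raise ValueError(f"channel(s) with zero MAD: {list(zero.index)}")
    ref = intensities.columns[0]
    b = mad / mad[ref]
    a = med - b * med[ref]
    calibrated = (intensities - a) / b
    return np.arcsinh(calibrated)


@dataclass
class TechnicalModel:
    """Per-gene fixed-effect fit: h_i = mu + dye + block + batch + person + e.

    ``residuals`` is the individuals x transcripts residual matrix used as
    expression traits downstream; ``channel_residuals`` keeps the same
    residuals indexed by channel.
    """

    mu: pd.Series
    coefficients: pd.DataFrame  # terms x genes, sum-to-zero contrasts
    channel_residuals: pd.DataFrame  # channels x genes
    residuals: pd.DataFrame  # individuals x genes
    design_columns: list[str]
    dropped_columns: list[str]


def _design_matrix(samplesheet: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Sum-to-zero design with deterministic aliased-column dropping.

    Columns are added factor by factor in sample-sheet column order; a
    contrast column is kept only if it increases the design rank.  A
    multi-level factor whose every contrast is dropped is completely
    confounded and reported as an error.
    """
    n = len(samplesheet)
    cols = [np.ones(n)]
    names = ["mu"]
    dropped: list[str] = []
    confounded: list[str] = []
    for factor in [f for f in samplesheet.columns if f in _FACTORS]:
        levels = list(pd.unique(samplesheet[factor]))
        if len(levels) < 2:
            continue
        kept_any = False
        for lev in levels[:-1]:  # sum-to-zero: last level is the negative reference
            col = (samplesheet[factor] == lev).to_numpy(dtype=float) - (
                samplesheet[factor] == levels[-1]
            ).to_numpy(dtype=float)
            trial = np.column_stack(cols + [col])
            if np.linalg.matrix_rank(trial) > len(cols):
                cols.append(col)
                names.append(f"{factor}[{lev}]")
                kept_any = True
            else:
                dropped.append(f"{factor}[{lev}]")
        if not kept_any:
            confounded.append(factor)
    if confounded:
        raise ValueError(
            "design rank-deficient: factor(s) completely confounded "
            f"with earlier terms: {confounded}"
        )
    return np.column_stack(cols), names, dropped


def remove_technical_effects(
    normalized: pd.DataFrame, samplesheet: pd.DataFrame
) -> TechnicalModel:
    """Fit the per-gene technical model and return residual expression.

    ``normalized`` is genes x channels; ``samplesheet`` is indexed by
    channel with factor columns among dye/block/batch/person plus an
    ``individual`` column mapping each channel to the profiled tree.
    All four technical factors are fitted per gene with sum-to-zero
    contrasts and the least-squares residuals are returned.
    """
    missing = set(normalized.columns) - set(samplesheet.index)
    if missing:
        raise ValueError(f"channels absent from sample sheet: {sorted(missing)}")
    sheet = samplesheet.loc[list(normalized.columns)]
    X, names, dropped = _design_matrix(sheet)
    if dropped:
        logger.info("dropped aliased design columns: %s", dropped)
    Y = normalized.to_numpy().T  # channels x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    genes = normalized.index
    channel_resid = pd.DataFrame(resid, index=normalized.columns, columns=genes)
    model = TechnicalModel(
        mu=pd.Series(beta[0], index=genes),
        coefficients=pd.DataFrame(beta[1:], index=names[1:], columns=genes),
        channel_residuals=channel_resid,
        residuals=_by_individual(channel_resid, sheet),
        design_columns=names,
        dropped_columns=dropped,
    )
    return model


def _by_individual(channel_resid: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    if "individual" not in sheet.columns:
        out = channel_resid.copy()
        out.index.name = "individual"
        return out
    out = channel_resid.copy()
    out.index = pd.Index(sheet["individual"].to_numpy(), name="individual")
    # an individual profiled on several channels gets the mean residual
    if out.index.has_duplicates:
        out = out.groupby(level=0).mean()
    return out.sort_index()
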