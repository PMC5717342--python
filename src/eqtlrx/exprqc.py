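"""Expression-matrix quality control: detection filtering and quantile normalization.

Microarray expression data arrive as raw probe intensities together with
per-probe, per-sample detection p-values (the probability that the observed
signal is background).  QC proceeds in two steps:

1. keep only probes that are significantly detectable (detection p <= 0.01)
   in *more than* 90% of samples;
2. quantile-normalize the retained intensities across samples and take log2.

Both thresholds are parameters; the defaults match the standard protocol for
Illumina bead arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "detection_filter", "quantile_normalize", "normalize"]


@dataclass
class ExpressionMatrix:
    """Probes x samples intensities with matching detection p-values.

    ``intensities`` and ``detection_p`` share the same index (probe ids) and
    columns (sample ids).  ``normalized`` records whether the intensities are
    quantile-normalized log2 values.
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    normalized: bool = False
    annotation: pd.Series | None = field(default=None, repr=False)  # probe -> gene symbol

    def __post_init__(self) -> None:
        if self.detection_p is not None:
            if self.detection_p.shape != self.intensities.shape:
                raise ValueError(
                    "detection_p shape %s does not match intensities %s"
                    % (self.detection_p.shape, self.intensities.shape)
                )
            if not self.detection_p.index.equals(self.intensities.index):
                raise ValueError("detection_p probe ids do not match intensities")
            dp = self.detection_p.to_numpy()
            if dp.size and (np.nanmin(dp) < 0 or np.nanmax(dp) > 1):
                raise ValueError("detection p-values must lie in [0, 1]")
        if self.intensities.columns.hasnans:
            raise ValueError("missing sample IDs in expression matrix")

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


def detection_filter(
    m: ExpressionMatrix, p_thresh: float = 0.01, frac: float = 0.90
) -> ExpressionMatrix:
    """Retain probes detected (p <= ``p_thresh``) in strictly more than ``frac`` of samples.

    The boundary is exclusive: a probe detected in exactly ``frac`` of samples
    is removed.
    """
    if m.detection_p is None:
        raise ValueError("detection_filter requires detection p-values")
    missing = m.detection_p.isna().any(axis=1)
    if missing.any():
        probe = m.detection_p.index[missing][0]
        raise ValueError(f"missing detection p-value for probe {probe!r}")
    detected_frac = (m.detection_p <= p_thresh).sum(axis=1) / m.detection_p.shape[1]
    keep = detected_frac > frac
    ann = m.annotation.loc[m.intensities.index[keep]] if m.annotation is not None else None
    return ExpressionMatrix(
        intensities=m.intensities.loc[keep],
        detection_p=m.detection_p.loc[keep],
        normalized=m.normalized,
        annotation=ann,
    )


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Classical quantile normalization of columns.

    Each column is ranked; the value at rank *i* is replaced by the mean,
    across columns, of the *i*-th order statistics.  Ties within a column
    receive the mean of the reference values at the tied ranks (implemented
    via average ranks with linear interpolation into the reference
    distribution).
    """
    x = df.to_numpy(dtype=float)
    n_rows = x.shape[0]
    order = np.sort(x, axis=0)
    reference = order.mean(axis=1)
    # average ranks per column (1-based), with ties averaged
    out = np.empty_like(x)
    from scipy.stats import rankdata

    grid = np.arange(1, n_rows + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize intensities across samples, then log2-transform.

    Raises if any intensity is non-positive, since log2 of the normalized
    values must be defined.
    """
    if (m.intensities.to_numpy() <= 0).any():
        raise ValueError("non-positive intensity encountered before log2 transform")
    qn = quantile_normalize(m.intensities)
    if (qn.to_numpy() <= 0).any():
        raise ValueError("non-positive normalized intensity before log2 transform")
    return ExpressionMatrix(
        intensities=np.log2(qn),
        detection_p=m.detection_p,
        normalized=True,
        annotation=m.annotation,
    )
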