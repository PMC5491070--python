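"""Scaled body mass index (SMI): size-adjusted body condition.

SMI standardises each individual's body mass to the mass it would have at a
reference tarsus length L0:

    SMI_i = mass_i * (L0 / tarsus_i) ** b

where b is the standardised major axis (SMA) slope of ln(mass) on
ln(tarsus).  The SMA slope equals the OLS slope divided by |r| (equivalently,
sd(ln mass)/sd(ln tarsus) with the sign of r).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_tables import SampleMetadata

__all__ = ["sma_slope", "scaled_mass_index", "body_condition"]


def sma_slope(log_mass, log_length) -> float:
    """Standardised major axis slope of `log_mass` on `log_length`."""
    x = np.asarray(log_length, dtype=float)
    y = np.asarray(log_mass, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 aligned observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in log mass or log length")
    r = np.corrcoef(x, y)[0, 1]
    if r == 0 or not np.isfinite(r):
        raise ValueError("correlation is zero; SMA slope undefined")
    b_ols = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    return float(b_ols / abs(r))


def scaled_mass_index(mass, length, L0: float, b: float):
    """mass * (L0 / length) ** b, elementwise; all inputs must be positive."""
    mass = np.asarray(mass, dtype=float)
    length = np.asarray(length, dtype=float)
    if np.any(mass <= 0) or np.any(length <= 0) or L0 <= 0:
        raise ValueError("mass, length and L0 must be positive")
    out = mass * (L0 / length) ** b
    return float(out) if out.ndim == 0 else out


def body_condition(meta: SampleMetadata, L0: float = None) -> pd.DataFrame:
    """Per-sample SMI from the metadata's mass and tarsus columns.

    Samples missing either measurement are excluded.  `L0` defaults to the
    mean tarsus of the included samples.  Returns a frame indexed by
    sample_id with columns individual_id, body_mass, tarsus, smi.
    """
    df = meta.df.dropna(subset=["body_mass", "tarsus"])
    if len(df) < 3:
        raise ValueError("need >= 3 samples with both mass and tarsus")
    b = sma_slope(np.log(df["body_mass"]), np.log(df["tarsus"]))
    if L0 is None:
        L0 = float(df["tarsus"].mean())
    smi = scaled_mass_index(df["body_mass"].to_numpy(),
                            df["tarsus"].to_numpy(), L0, b)
    out = df[["individual_id", "body_mass", "tarsus"]].copy()
    out["smi"] = smi
    out.attrs["L0"] = L0
    out.attrs["sma_slope"] = b
    return out
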