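"""Accessibility footprinting on paired methylation arrays.

A CpG that is accessible in native chromatin gains methylation when
nuclei are exposed to the M.SssI methyltransferase; the untreated
(no-enzyme) arm reports native methylation.  Per probe and sample,

    Acc = beta_treated - beta_untreated

so Acc lies in [-1, 1] and methylation is the untreated-arm β alone.
Between-condition differences (ΔAcc, ΔMeth) are means over the resistant
group minus means over the sensitive group by default — positive ΔAcc
reads "more accessible in the resistant condition".  The subtraction
order is exposed as ``sign_convention`` because the field's verbal
conventions differ; flipping it negates every delta and mirrors the
up/down calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

SIGNIFICANCE_THRESHOLD = 0.15

DIRECTIONS = ("up", "down", "ambiguous", "none")


def compute_accessibility(beta_sssi: pd.DataFrame, beta_noe: pd.DataFrame) -> pd.DataFrame:
    """Per-probe, per-sample accessibility: treated minus untreated β."""
    if not beta_sssi.index.equals(beta_noe.index) or list(beta_sssi.columns) != list(
        beta_noe.columns
    ):
        raise InputError("treated and untreated arms must share probes and samples")
    return beta_sssi - beta_noe


def condition_delta(
    values: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    sign_convention: str = "b_minus_a",
) -> pd.Series:
    """Per-probe difference of group means: group_b (resistant) minus
    group_a (sensitive) under the default convention."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise InputError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise InputError("groups must be disjoint")
    missing = (set(group_a) | set(group_b)) - set(values.columns)
    if missing:
        raise InputError(f"samples absent from table: {sorted(missing)}")
    if sign_convention not in ("b_minus_a", "a_minus_b"):
        raise InputError(f"unknown sign convention {sign_convention!r}")
    delta = values[group_b].mean(axis=1) - values[group_a].mean(axis=1)
    return -delta if sign_convention == "a_minus_b" else delta


def call_significant(delta: pd.Series, threshold: float = SIGNIFICANCE_THRESHOLD) -> pd.Series:
    """Boundary-inclusive magnitude flag: |delta| >= threshold."""
    if threshold <= 0:
        raise InputError("threshold must be positive")
    return delta.abs() >= threshold


def classify_probe_direction(
    delta_acc: float, delta_meth: float, sig_acc: bool, sig_meth: bool
) -> str:
    """Direction of regulatory change at one probe.

    "up" — significantly increased accessibility and/or decreased
    methylation, with no significant signal the other way; "down" is the
    mirror image; opposing significant signals are "ambiguous"; no
    significant signal is "none".
    """
    up = (sig_acc and delta_acc > 0) or (sig_meth and delta_meth < 0)
    down = (sig_acc and delta_acc < 0) or (sig_meth and delta_meth > 0)
    if up and down:
        return "ambiguous"
    if up:
        return "up"
    if down:
        return "down"
    return "none"


@dataclass
class EpiDifferentialResult:
    """Per-probe differential table plus the count of probes dropped for
    missing values."""

    table: pd.DataFrame  # delta_acc, delta_meth, sig_acc, sig_meth, direction
    n_dropped_missing: int


def epi_differential(
    beta_sssi: pd.DataFrame,
    beta_noe: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    threshold: float = SIGNIFICANCE_THRESHOLD,
    sign_convention: str = "b_minus_a",
) -> EpiDifferentialResult:
    """Full probe-level differential: ΔAcc, ΔMeth, significance, direction.

    Probes with any missing β in either arm are dropped (counted in the
    result).  Methylation is the untreated arm alone.
    """
    acc = compute_accessibility(beta_sssi, beta_noe)
    complete = ~(beta_sssi.isna().any(axis=1) | beta_noe.isna().any(axis=1))
    n_dropped = int((~complete).sum())
    acc = acc.loc[complete]
    meth = beta_noe.loc[complete]

    delta_acc = condition_delta(acc, group_a, group_b, sign_convention)
    delta_meth = condition_delta(meth, group_a, group_b, sign_convention)
    sig_acc = call_significant(delta_acc, threshold)
    sig_meth = call_significant(delta_meth, threshold)

    # vectorized form of classify_probe_direction
    up = (sig_acc & (delta_acc > 0)) | (sig_meth & (delta_meth < 0))
    down = (sig_acc & (delta_acc < 0)) | (sig_meth & (delta_meth > 0))
    direction = np.where(up & down, "ambiguous", np.where(up, "up", np.where(down, "down", "none")))

    table = pd.DataFrame(
        {
            "delta_acc": delta_acc,
            "delta_meth": delta_meth,
            "sig_acc": sig_acc,
            "sig_meth": sig_meth,
            "direction": direction,
        }
    )
    return EpiDifferentialResult(table=table, n_dropped_missing=n_dropped)
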