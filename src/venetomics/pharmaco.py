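"""BH3-profiling quantification and dose-response summaries.

Mitochondrial depolarization is read out as loss of TMRE fluorescence and
expressed on a two-control scale: 0% at the vehicle (DMSO) signal and
100% at the full-depolarization (FCCP) signal.  Values are deliberately
not clamped — readings outside roughly [-10, 110]% are flagged as QC
warnings rather than hidden.  Dose-response tables are summarized by a
four-parameter logistic fit (top, bottom, Hill slope, IC50) and by a
normalized area under the viability curve on the log10-dose axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import InputError
from .simulate import four_pl

QC_RANGE = (-10.0, 110.0)


def depolarization_percent(
    tmre_peptide: float | np.ndarray, tmre_dmso: float, tmre_fccp: float
) -> float | np.ndarray:
    """Percent depolarization on the DMSO(0)–FCCP(100) scale, unclamped."""
    if tmre_dmso <= tmre_fccp:
        raise InputError(
            "DMSO (vehicle) signal must exceed the FCCP (full depolarization) signal"
        )
    pct = 100.0 * (tmre_dmso - np.asarray(tmre_peptide, dtype=float)) / (tmre_dmso - tmre_fccp)
    out_of_range = (pct < QC_RANGE[0]) | (pct > QC_RANGE[1])
    if np.any(out_of_range):
        warnings.warn(
            f"{int(np.sum(out_of_range))} depolarization value(s) outside "
            f"[{QC_RANGE[0]}, {QC_RANGE[1]}]%",
            stacklevel=2,
        )
    if np.isscalar(tmre_peptide):
        return float(pct)
    return pct


def summarize_priming(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-condition, per-peptide mean and SD of percent depolarization.

    ``measurements`` is the long TMRE table produced by the simulator (or
    an equivalent export): condition, peptide, concentration_um,
    replicate, tmre_signal, with "DMSO" and "FCCP" rows providing the
    per-condition controls (averaged over replicates).  Cells with a
    single replicate report SD 0 and are flagged.
    """
    required = {"condition", "peptide", "concentration_um", "replicate", "tmre_signal"}
    missing = required - set(measurements.columns)
    if missing:
        raise InputError(f"measurement table lacks columns: {sorted(missing)}")

    rows = []
    for condition, sub in measurements.groupby("condition", sort=True):
        dmso = sub.loc[sub["peptide"] == "DMSO", "tmre_signal"].mean()
        fccp = sub.loc[sub["peptide"] == "FCCP", "tmre_signal"].mean()
        if np.isnan(dmso) or np.isnan(fccp):
            raise InputError(f"condition {condition!r} lacks DMSO/FCCP controls")
        peptides = sub[~sub["peptide"].isin(["DMSO", "FCCP"])]
        for (pep, conc), cell in peptides.groupby(["peptide", "concentration_um"], sort=True):
            pct = depolarization_percent(cell["tmre_signal"].to_numpy(), dmso, fccp)
            rows.append(
                (
                    condition,
                    pep,
                    conc,
                    len(cell),
                    float(np.mean(pct)),
                    float(np.std(pct, ddof=1)) if len(cell) > 1 else 0.0,
                    len(cell) == 1,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "peptide",
            "concentration_um",
            "n",
            "mean_depolarization",
            "sd_depolarization",
            "single_replicate",
        ],
    )


@dataclass
class FourPLFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    converged: bool
    message: str = ""

    def predict(self, doses: np.ndarray) -> np.ndarray:
        return four_pl(doses, self.top, self.bottom, self.ic50, self.hill)


def fit_four_pl(doses, responses) -> FourPLFit:
    """Least-squares four-parameter logistic fit on the log10-dose axis.

    Initialized from the data: bottom = min response, top = max response,
    IC50 = dose nearest the half-range response, Hill = 1.  Flat curves
    are flagged non-identifiable instead of raising; so is any failure of
    the optimizer.
    """
    doses = np.asarray(list(doses), dtype=float)
    responses = np.asarray(list(responses), dtype=float)
    if doses.shape != responses.shape:
        raise InputError("doses and responses must have the same length")
    if len(np.unique(doses)) < 4:
        raise InputError("need at least 4 distinct doses")
    if np.any(doses <= 0):
        raise InputError("doses must be positive")

    span = responses.max() - responses.min()
    if span <= 1e-9 * max(1.0, abs(responses.max())):
        return FourPLFit(
            top=float(responses.mean()),
            bottom=float(responses.mean()),
            ic50=float(np.nan),
            hill=float(np.nan),
            converged=False,
            message="flat response curve: IC50 not identifiable",
        )

    half = responses.min() + span / 2.0
    ic50_init = doses[np.argmin(np.abs(responses - half))]

    def model(log_dose, top, bottom, log_ic50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_dose - log_ic50)))

    p0 = [responses.max(), responses.min(), np.log10(ic50_init), 1.0]
    try:
        popt, _ = curve_fit(model, np.log10(doses), responses, p0=p0, maxfev=20_000)
    except (RuntimeError, ValueError) as exc:
        return FourPLFit(
            top=float(np.nan),
            bottom=float(np.nan),
            ic50=float(np.nan),
            hill=float(np.nan),
            converged=False,
            message=f"fit did not converge: {exc}",
        )
    top, bottom, log_ic50, hill = popt
    return FourPLFit(
        top=float(top),
        bottom=float(bottom),
        ic50=float(10.0**log_ic50),
        hill=float(hill),
        converged=True,
    )


def auc_viability(doses, responses) -> float:
    """Normalized area under the response curve on the log10-dose axis.

    Doses are sorted (duplicates averaged); the trapezoidal area is
    divided by (log10-dose range x response scale), where the scale is
    auto-detected as 100 for percent responses (max > 1.5) and 1 for
    fractional ones, giving a value in [0, 1]: 1 = no kill anywhere,
    0 = complete kill everywhere.
    """
    doses = np.asarray(list(doses), dtype=float)
    responses = np.asarray(list(responses), dtype=float)
    if doses.shape != responses.shape:
        raise InputError("doses and responses must have the same length")
    if len(doses) < 2:
        raise InputError("need at least 2 doses")
    if np.any(doses <= 0):
        raise InputError("doses must be positive")

    table = pd.DataFrame({"dose": doses, "response": responses}).groupby("dose", sort=True).mean()
    x = np.log10(table.index.to_numpy())
    y = table["response"].to_numpy()
    if len(x) < 2 or x[-1] == x[0]:
        raise InputError("need at least 2 distinct doses")
    scale = 100.0 if np.nanmax(y) > 1.5 else 1.0
    area = np.trapezoid(y, x)
    return float(area / ((x[-1] - x[0]) * scale))
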