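"""Knockdown dose-response modelling.

Relative target-mRNA level after injection of x µM siRNA is modelled as an
exponential decay

    y(x) = a * exp(-b * x)

with amplitude ``a`` (model value at dose 0, dimensionless ratio) and decay
rate ``b`` (per µM). The fit is exact log-linear least squares: ordinary
least squares of ln(y) on x, so a = exp(intercept) and b = -slope. The
reported correlation R is the magnitude of the Pearson correlation between
ln(y) and the fitted line. The median effective concentration is the dose at
which the fitted model predicts a relative mRNA level of 0.5:

    EC = ln(a / level) / b,   level = 0.5 by default.

Relative expression from raw qPCR data uses the delta-delta-Ct convention
with an assumed amplification efficiency of 2 (perfect doubling per cycle),
normalized to a reference gene and to a buffer-injected control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DosePoint:
    """One (dose, relative mRNA) observation; conc in µM, rel_mrna a
    unitless treated/control ratio (> 0 for fitting)."""

    conc: float
    rel_mrna: float


@dataclass(frozen=True)
class DecayFit:
    """Fitted y = a*exp(-b*x): amplitude a, rate b (per µM), correlation R
    (magnitude, log scale), and the number of points n."""

    a: float
    b: float
    R: float
    n: int

    def predict(self, conc: float) -> float:
        return self.a * math.exp(-self.b * conc)


def relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Delta-delta-Ct relative expression ratio, assuming efficiency 2.

    Returns 2^-((Ct_tgt,s - Ct_ref,s) - (Ct_tgt,c - Ct_ref,c))."""
    cts = (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError(f"non-finite Ct value in {cts}")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def fit_decay(points: Sequence[DosePoint]) -> DecayFit:
    """Log-linear least-squares fit of the exponential knockdown model.

    Requires at least 3 points over at least 2 distinct concentrations, all
    with rel_mrna > 0. Deterministic (closed form)."""
    if len(points) < 3:
        raise ValueError(f"need >= 3 points, got {len(points)}")
    for p in points:
        if p.rel_mrna <= 0:
            raise ValueError(f"rel_mrna must be > 0 for the log-linear fit: {p}")
    x = np.array([p.conc for p in points], dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct concentrations")
    logy = np.log([p.rel_mrna for p in points])
    res = stats.linregress(x, logy)
    return DecayFit(
        a=float(np.exp(res.intercept)),
        b=float(-res.slope),
        R=float(abs(res.rvalue)),
        n=len(points),
    )


def effective_concentration(fit: DecayFit, level: float = 0.5) -> float:
    """Dose (µM) at which the fitted model predicts rel_mrna == level.

    Unique solution of a*exp(-b*x) = level; requires decay (b > 0) and a
    reachable threshold (a > level > 0)."""
    if level <= 0:
        raise ValueError("level must be > 0")
    if fit.b <= 0:
        raise ValueError(f"no decay (b = {fit.b}); effective concentration undefined")
    if fit.a <= level:
        raise ValueError(
            f"threshold unreachable: amplitude a = {fit.a} <= level {level}"
        )
    return math.log(fit.a / level) / fit.b


def read_dose_csv(path: str | Path, ct_mode: bool = False) -> list[DosePoint]:
    """Read a dose-response table.

    Default: columns ``conc_uM, rel_mrna``. With ``ct_mode``: columns
    ``sample_id, conc_uM, ct_target, ct_ref, ct_target_control,
    ct_ref_control``; rel_mrna is computed per row by delta-delta-Ct and the
    definitional control point (0 µM, 1.0) is appended."""
    df = pd.read_csv(path)
    if ct_mode:
        required = ["conc_uM", "ct_target", "ct_ref", "ct_target_control", "ct_ref_control"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
        pts = [
            DosePoint(
                conc=float(r.conc_uM),
                rel_mrna=relative_expression(
                    r.ct_target, r.ct_ref, r.ct_target_control, r.ct_ref_control
                ),
            )
            for r in df.itertuples()
        ]
        pts.append(DosePoint(conc=0.0, rel_mrna=1.0))
        return pts
    missing = [c for c in ("conc_uM", "rel_mrna") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [DosePoint(conc=float(r.conc_uM), rel_mrna=float(r.rel_mrna)) for r in df.itertuples()]


def residuals(fit: DecayFit, points: Sequence[DosePoint]) -> pd.DataFrame:
    """Per-point predictions and residuals (linear and log scale)."""
    rows = []
    for p in points:
        pred = fit.predict(p.conc)
        rows.append(
            {
                "conc_uM": p.conc,
                "rel_mrna": p.rel_mrna,
                "predicted": pred,
                "residual": p.rel_mrna - pred,
                "log_residual": math.log(p.rel_mrna) - math.log(pred),
            }
        )
    return pd.DataFrame(rows)
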