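"""Agreement between automatic and manual (reference) measurements:
Bland–Altman bias and limits of agreement, and the MAPE-based precision
score used to summarize per-variable accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UsageError


@dataclass
class PairedMeasurements:
    """Matched automatic and manual series for one variable."""

    variable: str
    auto: np.ndarray
    manual: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.auto = np.asarray(self.auto, dtype=np.float64)
        self.manual = np.asarray(self.manual, dtype=np.float64)
        if self.auto.shape != self.manual.shape or self.auto.ndim != 1:
            raise ValueError("auto and manual must be 1-D arrays of equal length")
        if self.auto.size < 1:
            raise ValueError("need at least one pair")
        if not (np.all(np.isfinite(self.auto)) and np.all(np.isfinite(self.manual))):
            raise ValueError("paired measurements must be finite")

    @property
    def n(self) -> int:
        return int(self.auto.size)


@dataclass
class AgreementResult:
    """Bland–Altman summary: bias = mean(auto - manual), limits of
    agreement = bias -/+ 1.96 SD of the differences, 95% CI of the bias,
    and the per-point (mean, difference) pairs for plotting."""

    bias: float
    loa_low: float
    loa_high: float
    ci95_bias: tuple[float, float]
    n: int
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)


def bland_altman(pairs: PairedMeasurements) -> AgreementResult:
    """Standard Bland–Altman statistics on auto - manual differences.

    Uses the sample (n-1) standard deviation and the conventional 1.96
    multiplier for the limits of agreement; the 95% CI of the bias is
    bias +/- 1.96 * sd / sqrt(n).
    """
    if pairs.n < 2:
        raise ValueError("Bland–Altman analysis needs at least 2 pairs")
    d = pairs.auto - pairs.manual
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    ci = 1.96 * sd / np.sqrt(pairs.n)
    return AgreementResult(
        bias=bias,
        loa_low=bias - half,
        loa_high=bias + half,
        ci95_bias=(bias - ci, bias + ci),
        n=pairs.n,
        means=(pairs.auto + pairs.manual) / 2.0,
        diffs=d,
    )


def mape_percent(pairs: PairedMeasurements) -> float:
    """Mean absolute percentage error of auto against manual."""
    if np.any(pairs.manual == 0):
        raise UsageError(
            f"{pairs.variable}: manual reference contains zero values; "
            "percentage error undefined"
        )
    return float(100.0 * np.mean(np.abs(pairs.auto - pairs.manual) / np.abs(pairs.manual)))


def precision_percent(pairs: PairedMeasurements) -> float:
    """Precision score 100 - MAPE, clipped below at 0.

    Scale-invariant: rescaling both series by any positive constant
    leaves it unchanged.
    """
    return max(0.0, 100.0 - mape_percent(pairs))


def precision_ci(
    pairs: PairedMeasurements, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI of the precision score (seeded)."""
    rng = np.random.default_rng(seed)
    n = pairs.n
    ape = 100.0 * np.abs(pairs.auto - pairs.manual) / np.abs(pairs.manual)
    if np.any(pairs.manual == 0):
        raise UsageError("manual reference contains zero values")
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        stats[b] = max(0.0, 100.0 - float(ape[idx].mean()))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def pair_measurements(
    auto: pd.DataFrame, manual: pd.DataFrame, variable: str, units: str = ""
) -> PairedMeasurements | None:
    """Join two measurement tables on image_id for one variable; rows
    where either side is missing are dropped.  Returns None when no
    overlap remains."""
    if variable not in auto.columns or variable not in manual.columns:
        return None
    a = auto[["image_id", variable]].dropna()
    m = manual[["image_id", variable]].dropna()
    merged = a.merge(m, on="image_id", suffixes=("_auto", "_manual"))
    if len(merged) == 0:
        return None
    return PairedMeasurements(
        variable=variable,
        auto=merged[f"{variable}_auto"].to_numpy(),
        manual=merged[f"{variable}_manual"].to_numpy(),
        units=units,
    )


def agreement_report(
    auto_csv, manual_csv, out_dir, n_boot: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Per-variable agreement summary between two measurement CSVs.

    Writes ``agreement_summary.csv`` plus one Bland–Altman plot-data CSV
    (columns mean, diff) per variable under ``out_dir``; returns the
    summary frame.  Raises :class:`UsageError` when the files share no
    (image_id, variable) key.
    """
    from .io_formats import read_measurements

    auto = read_measurements(auto_csv)
    manual = read_measurements(manual_csv)
    variables = [
        c
        for c in auto.columns
        if c in manual.columns
        and c not in ("image_id", "region", "plane", "units", "flags")
    ]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for var in variables:
        pairs = pair_measurements(auto, manual, var)
        if pairs is None:
            continue
        prec = precision_percent(pairs)
        lo, hi = precision_ci(pairs, n_boot=n_boot, seed=seed)
        row = {"variable": var, "n": pairs.n, "precision_percent": prec,
               "precision_ci_low": lo, "precision_ci_high": hi}
        if pairs.n >= 2:
            ba = bland_altman(pairs)
            row.update(
                bias=ba.bias, loa_low=ba.loa_low, loa_high=ba.loa_high,
                ci95_bias_low=ba.ci95_bias[0], ci95_bias_high=ba.ci95_bias[1],
            )
            safe = var.replace(" ", "_").replace("/", "-")
            pd.DataFrame({"mean": ba.means, "diff": ba.diffs}).to_csv(
                out_dir / f"bland_altman_{safe}.csv", index=False
            )
        rows.append(row)
    if not rows:
        raise UsageError("no overlapping (image_id, variable) keys between the files")
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "agreement_summary.csv", index=False)
    return summary
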