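"""Absolute qPCR quantification of nifH gene copies.

A standard curve Ct = slope*log10(copies) + intercept is fitted to a
ten-fold dilution series by ordinary least squares; sample Ct values are
inverted through the curve to copies per reaction, scaled by dilution
and suspension factors, normalized to copies per gram of soil or root
fresh weight, and summarized on the log10 scale. Group contrasts use a
Welch t-test (two habitats) or the Games-Howell post hoc test (more).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import compact_letter_display, games_howell, welch_t


@dataclass
class StandardCurve:
    """Fitted Ct vs log10(copies) line.

    efficiency = 10**(-1/slope) - 1; a perfect assay doubles product
    every cycle, i.e. slope = -1/log10(2) ~ -3.3219 and efficiency 1.0.
    """

    slope: float
    intercept: float
    r2: float
    ct_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("invalid standard curve: slope must be negative")

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def predict_ct(self, log10_copies: float) -> float:
        return self.intercept + self.slope * log10_copies

    def copies_from_ct(self, ct) -> np.ndarray:
        return np.power(10.0, (np.asarray(ct, dtype=float) - self.intercept) / self.slope)


def fit_standard_curve(dilution: pd.DataFrame) -> StandardCurve:
    """OLS fit of Ct on log10(copies) for a dilution series.

    Requires >= 3 points spanning >= 2 decades of copy number.
    """
    copies = dilution["copies"].to_numpy(dtype=float)
    ct = dilution["ct"].to_numpy(dtype=float)
    if len(copies) < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    if (copies <= 0).any():
        raise ValueError("standard copies must be positive")
    lg = np.log10(copies)
    if lg.max() - lg.min() < 2.0:
        raise ValueError("dilution series must span at least 2 log10")
    fit = stats.linregress(lg, ct)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        ct_range=(float(ct.min()), float(ct.max())),
    )


@dataclass
class QuantResult:
    sample: str
    habitat: str
    copies_per_g: float
    log10_copies_per_g: float
    ci_half_width: float  # 95% t-based, log10 scale, across runs
    n_replicates: int
    extrapolated: bool


def absolute_quantify(
    ct_table: pd.DataFrame,
    curve: StandardCurve,
    sample_habitat: dict[str, str] | None = None,
    dilution_factor: float = 1.0,
    mass_g: float = 1.0,
    suspension_factor: float = 1.0,
    guard_band_ct: float = 1.0,
) -> list[QuantResult]:
    """Convert replicate Ct measurements to copies per gram.

    copies/g = 10**((Ct - intercept)/slope) * dilution_factor *
    suspension_factor / mass_g. Replicates (duplicates within runs) are
    aggregated as the mean of per-run log10 estimates; the confidence
    half-width is t-based across runs. Ct values outside the standard
    curve's Ct range +- `guard_band_ct` flag the result as extrapolated.
    """
    if mass_g <= 0 or dilution_factor <= 0 or suspension_factor <= 0:
        raise ValueError("mass and scaling factors must be positive")
    results = []
    lo = curve.ct_range[0] - guard_band_ct
    hi = curve.ct_range[1] + guard_band_ct
    for sample, grp in ct_table.groupby("sample", sort=True):
        extrap = bool(((grp["ct"] < lo) | (grp["ct"] > hi)).any())
        per_run = []
        for _, run_grp in grp.groupby("run", sort=True):
            copies_rxn = curve.copies_from_ct(run_grp["ct"])
            per_g = copies_rxn * dilution_factor * suspension_factor / mass_g
            per_run.append(float(np.mean(np.log10(per_g))))
        per_run = np.asarray(per_run)
        mean_log = float(per_run.mean())
        if len(per_run) > 1 and per_run.std(ddof=1) > 0:
            hw = float(
                stats.t.ppf(0.975, len(per_run) - 1)
                * per_run.std(ddof=1)
                / np.sqrt(len(per_run))
            )
        else:
            hw = 0.0
        results.append(
            QuantResult(
                sample=str(sample),
                habitat=(sample_habitat or {}).get(str(sample), ""),
                copies_per_g=10.0**mean_log,
                log10_copies_per_g=mean_log,
                ci_half_width=hw,
                n_replicates=len(grp),
                extrapolated=extrap,
            )
        )
    return results


def quant_table(results: list[QuantResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def compare_abundances(
    results: list[QuantResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Group contrast of log10 copies/g between habitats.

    Two habitats: Welch t-test. More: Games-Howell post hoc pairs. The
    returned table carries a compact letter display (groups sharing a
    letter are not significantly different at `alpha`).
    """
    groups: dict[str, list[float]] = {}
    for r in results:
        groups.setdefault(r.habitat, []).append(r.log10_copies_per_g)
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two habitats")
    if len(names) == 2:
        _, p = welch_t(groups[names[0]], groups[names[1]])
        pairs = pd.DataFrame(
            [{"group1": names[0], "group2": names[1], "p": p, "test": "welch_t"}]
        )
    else:
        pairs = games_howell({g: np.asarray(groups[g]) for g in names})
        pairs["test"] = "games_howell"
    letters = compact_letter_display(pairs, names, alpha=alpha)
    pairs.attrs["letters"] = letters
    return pairs
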