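"""Median-effect dose-response fitting and combination-index scoring.

The median-effect model relates dose D to fraction affected fa through
``fa = 1 / (1 + (Dm / D)^m)``; on log-log axes ``log(fa/(1-fa))`` is
linear in ``log D`` with slope m and x-intercept log Dm, so fitting is
ordinary least squares on the linearized form.

For a fixed-ratio combination measured as a third curve, the combination
index at effect level fa is ``CI = d1/Dx1 + d2/Dx2`` (mutually exclusive
form, no interaction term), where (d1, d2) split the combination's total
dose at fa by the mixing ratio and Dx_i is the single-agent dose giving
fa.  CI < 1 calls synergy, CI > 1 antagonism.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from oncoint.errors import InputError

#: numeric tolerance around CI = 1 for the additive call
_ADDITIVE_TOL = 1e-9

CALL_SYNERGY = "synergy"
CALL_ADDITIVE = "additive"
CALL_ANTAGONISM = "antagonism"


def median_effect_fa(dose, dm: float, m: float):
    """Fraction affected at ``dose`` for median-effect parameters (Dm, m)."""
    if dm <= 0 or m <= 0:
        raise InputError("Dm and m must be positive")
    dose = np.asarray(dose, dtype=float)
    return 1.0 / (1.0 + (dm / dose) ** m)


def effect_dose(fa, dm: float, m: float):
    """Inverse of :func:`median_effect_fa`: dose giving fraction affected fa."""
    fa = np.asarray(fa, dtype=float)
    if np.any((fa <= 0) | (fa >= 1)):
        raise InputError("fa must lie strictly inside (0, 1)")
    return dm * (fa / (1.0 - fa)) ** (1.0 / m)


@dataclass(frozen=True)
class MedianEffectFit:
    drug_id: str
    dm: float
    m: float
    r: float
    n_points: int


def fit_median_effect(
    doses: Sequence[float],
    fa: Sequence[float],
    drug_id: str = "",
    clip: bool = False,
) -> MedianEffectFit:
    """Least-squares median-effect fit on the linearized log-odds form.

    Rows with fa outside (0, 1) are excluded with a warning, or clipped
    into [0.01, 0.99] when ``clip=True``.  At least three usable rows are
    required.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if len(doses) != len(fa):
        raise InputError("doses and fa must have equal length")
    if np.any(doses <= 0):
        raise InputError("doses must be positive")
    if clip:
        clipped = np.clip(fa, 0.01, 0.99)
        if np.any(clipped != fa):
            warnings.warn("fa values clipped into [0.01, 0.99] before log-odds")
        fa = clipped
    usable = (fa > 0) & (fa < 1)
    if not usable.all():
        warnings.warn(f"{int((~usable).sum())} rows with fa outside (0,1) excluded from fit")
    doses, fa = doses[usable], fa[usable]
    if len(doses) < 3:
        raise InputError("median-effect fit needs at least 3 rows with fa in (0, 1)")
    x = np.log10(doses)
    y = np.log10(fa / (1.0 - fa))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise InputError("fitted slope m is non-positive; dose-response not increasing")
    dm = float(10.0 ** (-res.intercept / m))
    # perfectly flat y (all fa equal) gives rvalue nan; report 0
    r = float(res.rvalue) if np.isfinite(res.rvalue) else 0.0
    return MedianEffectFit(drug_id=drug_id, dm=dm, m=m, r=r, n_points=int(len(doses)))


@dataclass(frozen=True)
class CIResult:
    pair_id: str
    fa: float
    d1: float
    d2: float
    dx1: float
    dx2: float
    ci: float
    call: str


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    fit_combo: MedianEffectFit,
    ratio: tuple[float, float] = (1.0, 1.0),
    fa_levels: Sequence[float] = (0.5, 0.75, 0.9),
) -> list[CIResult]:
    """Combination index at each requested effect level.

    ``ratio`` is the fixed (drug1, drug2) dose ratio of the combination;
    the combination's total dose at fa (from its own median-effect fit)
    is split by the ratio into d1 and d2.  CI = d1/Dx1 + d2/Dx2.
    """
    r1, r2 = float(ratio[0]), float(ratio[1])
    if r1 <= 0 or r2 <= 0:
        raise InputError("dose ratio components must be positive")
    f1 = r1 / (r1 + r2)
    pair_id = f"{fit1.drug_id}+{fit2.drug_id}"
    out = []
    for fa in fa_levels:
        fa = float(fa)
        if not 0 < fa < 1:
            raise InputError(f"fa level {fa} outside (0, 1)")
        dx1 = float(effect_dose(fa, fit1.dm, fit1.m))
        dx2 = float(effect_dose(fa, fit2.dm, fit2.m))
        total = float(effect_dose(fa, fit_combo.dm, fit_combo.m))
        d1 = total * f1
        d2 = total - d1
        ci = d1 / dx1 + d2 / dx2
        if ci < 1.0 - _ADDITIVE_TOL:
            call = CALL_SYNERGY
        elif ci > 1.0 + _ADDITIVE_TOL:
            call = CALL_ANTAGONISM
        else:
            call = CALL_ADDITIVE
        out.append(
            CIResult(pair_id=pair_id, fa=fa, d1=d1, d2=d2, dx1=dx1, dx2=dx2, ci=ci, call=call)
        )
    return out


def additive_combo_fit(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    ratio: tuple[float, float] = (1.0, 1.0),
    ci: float = 1.0,
    drug_id: str | None = None,
) -> MedianEffectFit:
    """Construct the combination fit a CI of ``ci`` would imply.

    Exact when both agents share the same slope m (then the additive
    total dose is itself a median-effect curve); used to plant known-CI
    combinations in synthetic data and tests.
    """
    if abs(fit1.m - fit2.m) > 1e-9:
        warnings.warn("additive combo is exactly median-effect only for equal slopes")
    r1, r2 = float(ratio[0]), float(ratio[1])
    f1 = r1 / (r1 + r2)
    m = 0.5 * (fit1.m + fit2.m)
    harmonic = 1.0 / (f1 / fit1.dm + (1.0 - f1) / fit2.dm)
    return MedianEffectFit(
        drug_id=drug_id or f"{fit1.drug_id}+{fit2.drug_id}",
        dm=ci * harmonic,
        m=m,
        r=1.0,
        n_points=0,
    )


def plot_curves(
    fits: Sequence[MedianEffectFit],
    ci_results: Sequence[CIResult] = (),
    png_path=None,
    doses=None,
):
    """Overlay single-agent and combination curves with CI annotations."""
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 4.5))
    ax = fig.add_subplot(111)
    if doses is None:
        dms = [f.dm for f in fits]
        doses = np.geomspace(min(dms) / 64.0, max(dms) * 64.0, 100)
    for f in fits:
        ax.semilogx(doses, 1.0 - median_effect_fa(doses, f.dm, f.m), label=f.drug_id)
    if ci_results:
        note = ", ".join(f"CI(fa={c.fa:g})={c.ci:.2f}" for c in ci_results)
        ax.annotate(note, xy=(0.02, 0.04), xycoords="axes fraction", fontsize=8)
    ax.set_xlabel("dose")
    ax.set_ylabel("surviving fraction")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if png_path is not None:
        fig.savefig(png_path, dpi=120)
    return fig
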