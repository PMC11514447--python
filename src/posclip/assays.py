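"""Quantitative assay models: one-site binding, one-phase decay,
unwinding velocity, and qPCR relative quantification.

Models
------
One-site binding (fluorescence polarization, total-ligand approximation):

    FP(c) = FP_free + (FP_bound - FP_free) * c / (K_D + c)

One-phase decay (relative abundance after transcriptional shut-off):

    y(t) = (1 - plateau) * exp(-k t) + plateau,   t_1/2 = ln 2 / k

Unwinding: the velocity is the slope of the linear part of a
fluorescence progress curve; the linear region is selected as the
longest contiguous window (after the signal leaves baseline) whose
linear fit reaches a configured r^2.

qPCR follows the comparative-Ct method with amplification efficiency
fixed at 2 per cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class KdFit:
    kd: float  # nM
    fp_free: float
    fp_bound: float
    se_kd: float
    r_squared: float
    converged: bool
    flag: str = ""


@dataclass
class DecayFit:
    k: float  # per hour
    plateau: float
    t_half: float  # hours; inf when effectively stable
    se_t_half: float
    converged: bool
    flag: str = ""


@dataclass
class VelocityFit:
    velocity: float  # signal units per minute
    window: tuple  # (t_start, t_end) of the selected linear span
    r_squared: float
    flag: str = ""


def _one_site(c, kd, fp_free, fp_bound):
    return fp_free + (fp_bound - fp_free) * c / (kd + c)


def fit_one_site(concentrations, polarization) -> KdFit:
    """Least-squares one-site binding fit.

    Initialized at fp_free = min reading, fp_bound = max reading, and
    K_D = the concentration nearest the half-maximal signal.  Never
    raises on optimizer failure: ``converged`` is False when the fit
    fails, the readings are flat, or the fitted K_D exceeds 10x the
    largest concentration (flag ``weak binding``).
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(polarization, dtype=float)
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    span = y.max() - y.min()
    if span <= 0:
        return KdFit(np.nan, float(y.mean()), float(y.mean()), np.nan, 0.0,
                     False, "flat readings")
    half = y.min() + span / 2
    kd0 = float(c[np.argmin(np.abs(y - half))])
    kd0 = max(kd0, c[c > 0].min() if (c > 0).any() else 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            _one_site, c, y, p0=[kd0, y.min(), y.max()],
            bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return KdFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, "fit failed")
    kd, fp_free, fp_bound = popt
    resid = y - _one_site(c, *popt)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
    se_kd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    if kd > 10 * c.max():
        return KdFit(float(kd), float(fp_free), float(fp_bound), se_kd, float(r2),
                     False, "weak binding")
    return KdFit(float(kd), float(fp_free), float(fp_bound), se_kd, float(r2), True)


def compare_kd(groups: dict) -> dict:
    """One-way ANOVA of replicate K_D values across conditions.

    ``groups`` maps condition name to a list of :class:`KdFit`.  Groups
    containing a non-converged fit are flagged and excluded with a
    warning.  Returns ``{"f": F, "p": p, "excluded": [...]}``.
    """
    usable, excluded = {}, []
    for name, fits in groups.items():
        if any(not f.converged for f in fits):
            logger.warning("compare_kd: excluding group %r (non-converged fit)", name)
            excluded.append(name)
            continue
        usable[name] = [f.kd for f in fits]
    if len(usable) < 2:
        raise ValueError("need at least 2 converged groups for ANOVA")
    if any(len(v) < 2 for v in usable.values()):
        raise ValueError("need at least 2 replicates per group")
    f, p = stats.f_oneway(*usable.values())
    return {"f": float(f), "p": float(p), "excluded": excluded}


def _decay(t, k, plateau):
    return (1.0 - plateau) * np.exp(-k * t) + plateau


STABLE_K = 1e-3  # per hour; below this the transcript is reported stable


def fit_one_phase_decay(series: pd.DataFrame) -> DecayFit:
    """Pooled one-phase decay fit with y(0) fixed at 1.

    ``series`` needs columns ``time_h`` and ``relative_abundance``
    (replicates pooled into a single fit).  Constraints: k >= 0 and
    plateau in [0, 1).  t=0 must be present (the normalization
    reference).  A rate below ``STABLE_K`` reports an infinite half-life
    with flag ``stable``.
    """
    t = series["time_h"].to_numpy(dtype=float)
    y = series["relative_abundance"].to_numpy(dtype=float)
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 timepoints")
    if not np.any(t == 0):
        raise ValueError("decay series must include the t=0 reference point")
    k0 = 0.5
    nz = (t > 0) & (y > 1e-6) & (y < 1)
    if nz.any():
        k0 = float(np.clip(np.median(-np.log(y[nz]) / t[nz]), 1e-4, 50.0))
    # fit with and without a plateau and keep the AICc-preferred model;
    # a free plateau the data cannot support would otherwise trade off
    # against k and inflate the half-life error
    candidates = []
    try:
        popt, pcov = optimize.curve_fit(
            _decay, t, y, p0=[k0, 0.0],
            bounds=([0.0, 0.0], [np.inf, 1.0 - 1e-9]), maxfev=10000,
        )
        candidates.append((popt, pcov, 2))
    except (RuntimeError, ValueError):
        pass
    try:
        popt0, pcov0 = optimize.curve_fit(
            lambda tt, k: _decay(tt, k, 0.0), t, y, p0=[k0],
            bounds=([0.0], [np.inf]), maxfev=10000,
        )
        candidates.append((([popt0[0], 0.0]), np.pad(pcov0, ((0, 1), (0, 1))), 1))
    except (RuntimeError, ValueError):
        pass
    if not candidates:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, False, "fit failed")

    def aicc(params, n_par):
        ssr = float(((y - _decay(t, params[0], params[1])) ** 2).sum())
        n = len(y)
        if n - n_par - 1 <= 0:
            return np.inf
        return n * np.log(max(ssr, 1e-300) / n) + 2 * n_par \
            + 2 * n_par * (n_par + 1) / (n - n_par - 1)

    popt, pcov, _ = min(candidates, key=lambda c: aicc(c[0], c[2]))
    k, plateau = popt
    if k < STABLE_K:
        return DecayFit(float(k), float(plateau), np.inf, np.nan, True, "stable")
    t_half = np.log(2) / k
    se_k = np.sqrt(pcov[0, 0]) if np.isfinite(pcov[0, 0]) else np.nan
    se_t_half = float(np.log(2) / k**2 * se_k)  # delta method
    return DecayFit(float(k), float(plateau), float(t_half), se_t_half, True)


# ---------------------------------------------------------------------------
# qPCR


def relative_quantification(ct_table: pd.DataFrame, efficiency: float = 2.0,
                            calibrator_time: float = 0.0) -> pd.DataFrame:
    """Comparative-Ct relative levels against the t=0 calibrator.

    ``ct_table`` needs columns ``sample`` (or ``time_h``), ``ct_target``
    and ``ct_reference``.  Relative level = E^-(dCt_sample -
    dCt_calibrator) with dCt = Ct_target - Ct_reference and E the
    amplification efficiency (2 by default).  The calibrator is the row
    whose ``time_h`` equals ``calibrator_time`` (or the sample named
    ``"calibrator"``).  Missing reference Ct values raise, naming the
    sample.
    """
    df = ct_table.copy()
    key = "time_h" if "time_h" in df.columns else "sample"
    bad = df[df["ct_reference"].isna() | df["ct_target"].isna()]
    if len(bad):
        raise ValueError(f"missing Ct values for samples: {bad[key].tolist()}")
    dct = df["ct_target"] - df["ct_reference"]
    if key == "time_h":
        cal = dct[df[key] == calibrator_time]
    else:
        cal = dct[df[key] == "calibrator"]
    if not len(cal):
        raise ValueError("no calibrator sample found")
    df["relative_level"] = efficiency ** -(dct - float(cal.iloc[0]))
    return df


def rip_enrichment(ct_ip, ct_input, ct_igg, ct_igg_input, efficiency: float = 2.0):
    """Fold enrichment of an immunoprecipitation over the IgG control,
    both normalized to their inputs:

        fold = E^-[(Ct_IP - Ct_input) - (Ct_IgG - Ct_IgG_input)]
    """
    vals = [ct_ip, ct_input, ct_igg, ct_igg_input]
    arrs = [np.asarray(v, dtype=float) for v in vals]
    if any(np.any(np.isnan(a)) for a in arrs):
        raise ValueError("missing Ct value in RIP table")
    d_ip = arrs[0] - arrs[1]
    d_igg = arrs[2] - arrs[3]
    return efficiency ** -(d_ip - d_igg)


# ---------------------------------------------------------------------------
# unwinding velocity


def unwinding_velocity(progress: pd.DataFrame, min_points: int = 4,
                       r2_min: float = 0.999) -> VelocityFit:
    """Slope of the linear part of an unwinding progress curve.

    If the whole curve is linear at ``r2_min`` it is used directly.
    Otherwise the baseline (mean/sd of the first ``min_points`` readings)
    defines the end of the lag phase — the first reading above baseline
    + 3 sd — and all contiguous windows of >= ``min_points`` readings
    starting there or later are scanned; the longest window with
    r^2 >= ``r2_min`` wins (ties: earliest).  If none qualifies the
    best-r^2 window of ``min_points`` readings is used and flagged.
    Flat or monotone-decreasing signals give velocity 0 with a flag.
    """
    t = progress["time_min"].to_numpy(dtype=float)
    y = progress["signal"].to_numpy(dtype=float)
    n = len(t)
    if n < min_points:
        raise ValueError(f"need at least {min_points} observations")
    order = np.argsort(t)
    t, y = t[order], y[order]

    if np.ptp(y) == 0:
        return VelocityFit(0.0, (float(t[0]), float(t[-1])), 0.0, "flat signal")
    full = stats.linregress(t, y)
    if full.rvalue**2 >= r2_min:
        if full.slope <= 0:
            return VelocityFit(0.0, (float(t[0]), float(t[-1])),
                               float(full.rvalue**2), "non-increasing signal")
        return VelocityFit(float(full.slope), (float(t[0]), float(t[-1])),
                           float(full.rvalue**2))

    base = y[:min_points]
    thr = base.mean() + 3 * base.std(ddof=0)
    above = np.flatnonzero(y > thr)
    # the last pre-rise reading sits on the lag/linear breakpoint and may
    # belong to the linear segment, so windows may start one point early
    start0 = max(int(above[0]) - 1, 0) if above.size else 0

    best = None  # (length, start, slope, r2)
    for i in range(start0, n - min_points + 1):
        for j in range(i + min_points, n + 1):
            res = stats.linregress(t[i:j], y[i:j])
            r2 = res.rvalue**2
            if r2 >= r2_min:
                cand = (j - i, -i, res.slope, r2, i, j)
                if best is None or cand[:2] > best[:2]:
                    best = cand
    if best is not None:
        _, _, slope, r2, i, j = best
        if slope <= 0:
            return VelocityFit(0.0, (float(t[i]), float(t[j - 1])), float(r2),
                               "non-increasing signal")
        return VelocityFit(float(slope), (float(t[i]), float(t[j - 1])), float(r2))

    # fallback: best-r^2 minimal window
    fb = None
    for i in range(0, n - min_points + 1):
        res = stats.linregress(t[i:i + min_points], y[i:i + min_points])
        r2 = res.rvalue**2
        if fb is None or r2 > fb[0]:
            fb = (r2, i, res.slope)
    r2, i, slope = fb
    flag = "no linear window at requested r2"
    if slope <= 0:
        return VelocityFit(0.0, (float(t[i]), float(t[i + min_points - 1])),
                           float(r2), "non-increasing signal")
    return VelocityFit(float(slope), (float(t[i]), float(t[i + min_points - 1])),
                       float(r2), flag)
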