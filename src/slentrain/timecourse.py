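"""Sliding-window entrainment time course and linear mixed models of learning.

The 0.5 s duplet segments of all phases are concatenated chronologically
(2 min Random, 2 min long Structured, 5 min of short Structured blocks).
A 2-min window slides in 1 s steps; each window holds 16 candidate 7.5 s
epochs (15 segments each). A window is valid if at least 8 of its 16
epochs are artifact-free; the ITC at the duplet rate is computed over the
valid epochs, averaged over a chosen electrode set, invalid windows are
linearly interpolated, and the course is smoothed with a centred 30 s
moving average (shrinking at the edges, mean-preserving on linear trends).

Learning during the long Structured stream is quantified with a linear
mixed model without fixed intercept and with per-subject random intercepts
and slopes: itc ~ -1 + time + (1 + time | subject); the group comparison
adds per-group intercepts and a slope difference:
itc ~ -1 + time * group + (1 + time | subject).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as t_dist

from .preproc import EpochSet, LONG_EPOCH_DUPLETS

DUPLET_HZ = 2.0
WINDOW_S = 120.0
STEP_S = 1.0
SMOOTH_S = 30.0
MIN_VALID_EPOCHS = 8
EPOCHS_PER_WINDOW = 16


@dataclass
class TimecourseResult:
    """Single-subject (or per-subject stacked) smoothed ITC time course."""

    itc_t: np.ndarray  # time points (possibly NaN at untrimmed edges)
    times_s: np.ndarray  # window centres, origin = first segment onset
    electrodes: np.ndarray
    window_s: float = WINDOW_S
    step_s: float = STEP_S
    smoothed: bool = True

    def to_frame(self, subject: str) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject": subject, "time_s": self.times_s, "itc": self.itc_t}
        )


@dataclass
class LMMResult:
    """Fixed-effect estimates of a fitted mixed model."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci95: np.ndarray  # (k, 2)
    p: np.ndarray
    random_effect_cov: np.ndarray
    formula: str
    converged: bool
    n_obs: int = 0
    n_subjects: int = 0

    def summary_dict(self) -> dict:
        return {
            "formula": self.formula,
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_subjects": int(self.n_subjects),
            "effects": {
                name: {
                    "beta": float(b),
                    "se": float(s),
                    "ci95": [float(lo), float(hi)],
                    "p": float(pv),
                }
                for name, b, s, (lo, hi), pv in zip(
                    self.names, self.beta, self.se, self.ci95, self.p
                )
            },
        }


def _target_bin_phase(epochs: np.ndarray, srate: float, freq: float) -> np.ndarray:
    """Phase at one DFT bin for each epoch/channel (direct projection)."""
    n = epochs.shape[-1]
    k = freq * n / srate
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"{freq} Hz is off-bin for {n} samples at {srate} Hz")
    basis = np.exp(-2j * np.pi * round(k) * np.arange(n) / n)
    x = epochs - epochs.mean(axis=-1, keepdims=True)
    return np.angle(x @ basis)


def sliding_itc(
    duplet_epochs: EpochSet,
    electrodes: np.ndarray,
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
    target_hz: float = DUPLET_HZ,
    smooth_s: float = SMOOTH_S,
) -> TimecourseResult:
    """Duplet-rate ITC in sliding 2-min windows over the chronological segments.

    Uses all duplet segments in chronological order (the first structured
    minute therefore mixes random-phase data, as the windowing implies).
    Epoch normalisation matches the static analysis: average reference and
    unit global SD per 7.5 s epoch.
    """
    electrodes = np.asarray(electrodes, dtype=int)
    if electrodes.size == 0:
        raise ValueError("electrode set is empty")
    segs = duplet_epochs
    n_seg = segs.n_epochs
    seg_len = segs.epochs.shape[2]
    srate = segs.srate_hz
    seg_dur = seg_len / srate
    per_window = int(round(window_s / seg_dur))  # 240
    step = int(round(step_s / seg_dur))  # 2
    n_windows = (n_seg - per_window) // step + 1
    if n_windows < 1:
        raise ValueError("recording shorter than one window")

    # precompute the 16 subdivision epochs for every possible 7.5 s start
    # (starts on the segment grid); an epoch is usable iff its 15 segments
    # are all valid
    values = np.full(n_windows, np.nan)
    times = np.empty(n_windows)
    data = segs.epochs
    valid = segs.valid

    epoch_cache: dict[int, np.ndarray | None] = {}

    def epoch_phase(start: int) -> np.ndarray | None:
        """Phase map (electrodes,) at target bin for epoch starting at segment `start`."""
        if start in epoch_cache:
            return epoch_cache[start]
        block = slice(start, start + LONG_EPOCH_DUPLETS)
        if not valid[block].all() or (start + LONG_EPOCH_DUPLETS) > n_seg:
            epoch_cache[start] = None
            return None
        ep = np.concatenate(data[block], axis=1)  # channels x 1875
        ep = ep - ep.mean(axis=0, keepdims=True)
        sd = ep.std()
        if sd == 0:
            epoch_cache[start] = None
            return None
        ph = _target_bin_phase(ep[electrodes] / sd, srate, target_hz)
        epoch_cache[start] = ph
        return ph

    for w in range(n_windows):
        w0 = w * step
        phases = []
        for k in range(EPOCHS_PER_WINDOW):
            ph = epoch_phase(w0 + k * LONG_EPOCH_DUPLETS)
            if ph is not None:
                phases.append(ph)
        times[w] = (w0 + per_window / 2.0) * seg_dur
        if len(phases) >= MIN_VALID_EPOCHS:
            ph = np.stack(phases)
            itc = np.abs(np.exp(1j * ph).mean(axis=0))
            values[w] = itc.mean()

    values = _interp_nan(values)
    if smooth_s:
        values = _boxcar_smooth(values, int(round(smooth_s / step_s)) | 1)
    return TimecourseResult(values, times, electrodes, window_s, step_s, bool(smooth_s))


def _interp_nan(x: np.ndarray) -> np.ndarray:
    """Linear interpolation of interior NaNs; leading/trailing NaNs remain."""
    x = x.copy()
    idx = np.flatnonzero(~np.isnan(x))
    if idx.size == 0:
        return x
    interior = np.arange(idx[0], idx[-1] + 1)
    x[interior] = np.interp(interior, idx, x[idx])
    return x


def _boxcar_smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average, window shrinking at edges; NaN-tolerant."""
    out = np.full_like(x, np.nan)
    h = width // 2
    for i in range(len(x)):
        lo, hi = max(0, i - h), min(len(x), i + h + 1)
        seg = x[lo:hi]
        good = ~np.isnan(seg)
        if good.any():
            out[i] = seg[good].mean()
    return out


#: internal time rescaling for numerically balanced mixed-model fits; slopes
#: of order 1e-3 ITC/s otherwise leave the random-slope variance ~1e-6 times
#: the intercept variance and the Hessian near-singular. Estimates are
#: converted back to per-second units after fitting.
TIME_SCALE_S = 100.0


def _fit_mixedlm(
    endog: np.ndarray,
    exog: np.ndarray,
    names: list[str],
    groups: np.ndarray,
    exog_re: np.ndarray,
    formula: str,
    scale_cols: list[int] | None = None,
) -> LMMResult:
    if scale_cols:
        exog = exog.copy()
        exog[:, scale_cols] /= TIME_SCALE_S
        exog_re = exog_re.copy()
        exog_re[:, 1] /= TIME_SCALE_S
    model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True, method=["lbfgs", "cg"])
            converged = bool(fit.converged)
        except Exception as err:  # noqa: BLE001 - surfaced, not swallowed
            raise RuntimeError(f"mixed model failed to fit: {err}") from err
    k = exog.shape[1]
    beta = np.asarray(fit.params)[:k].copy()
    se = np.asarray(fit.bse)[:k].copy()
    if scale_cols:
        beta[scale_cols] /= TIME_SCALE_S
        se[scale_cols] /= TIME_SCALE_S
    # between-within reference: the slope is effectively a subject-mean, so
    # Wald statistics are referred to t with n_subjects - 1 df (the normal
    # reference is visibly anti-conservative for small cohorts)
    df_t = max(len(np.unique(groups)) - 1, 1)
    z = t_dist.ppf(0.975, df_t)
    ci = np.column_stack([beta - z * se, beta + z * se])
    p = 2 * t_dist.sf(np.abs(beta / se), df_t)
    return LMMResult(
        names,
        beta,
        se,
        ci,
        p,
        np.asarray(fit.cov_re),
        formula,
        converged,
        n_obs=len(endog),
        n_subjects=len(np.unique(groups)),
    )


def fit_lmm_single(data: pd.DataFrame) -> LMMResult:
    """itc ~ -1 + time + (1 + time | subject) for one group.

    ``data`` columns: subject, time_s, itc. Time is passed through as
    given (seconds); REML estimation, Wald p-values.
    """
    df = data.dropna(subset=["itc"]).copy()
    subjects = df["subject"].unique()
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    if df.groupby("subject")["time_s"].nunique().min() < 10:
        raise ValueError("need at least 10 time points per subject")
    endog = df["itc"].to_numpy(float)
    exog = df[["time_s"]].to_numpy(float)
    exog_re = np.column_stack([np.ones(len(df)), df["time_s"].to_numpy(float)])
    return _fit_mixedlm(
        endog,
        exog,
        ["time"],
        df["subject"].to_numpy(),
        exog_re,
        "itc ~ -1 + time + (1 + time | subject)",
        scale_cols=[0],
    )


def fit_lmm_group(data: pd.DataFrame, reference_group: str = "phoneme") -> LMMResult:
    """itc ~ -1 + time * group + (1 + time | subject) across two groups.

    Expands, as R's lme4 does without intercept, to per-group intercepts,
    a time slope for the reference group, and a time x group slope
    difference for the other group (the interaction estimate).
    """
    df = data.dropna(subset=["itc"]).copy()
    groups = sorted(df["group"].unique(), key=lambda g: g != reference_group)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    other = groups[1]
    t = df["time_s"].to_numpy(float)
    g_ref = (df["group"] == reference_group).to_numpy(float)
    g_oth = (df["group"] == other).to_numpy(float)
    exog = np.column_stack([t, g_ref, g_oth, t * g_oth])
    names = ["time", f"group[{reference_group}]", f"group[{other}]",
             f"time:group[{other}]"]
    exog_re = np.column_stack([np.ones(len(df)), t])
    return _fit_mixedlm(
        df["itc"].to_numpy(float),
        exog,
        names,
        df["subject"].to_numpy(),
        exog_re,
        "itc ~ -1 + time * group + (1 + time | subject)",
        scale_cols=[0, 3],  # time and time x group columns
    )
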