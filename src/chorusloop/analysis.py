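"""Summary statistics and light model fits over response records.

The heavy inferential machinery of a full study (additive mixed models
with random smooths, random-slope logistic mixed models) is deliberately
not re-implemented here; this module provides the descriptive twins —
binned-median response-delay/period curves with bootstrap intervals,
grouped overlap-proportion tables with binomial intervals — plus a plain
fixed-effects interaction logistic fit used for parameter-recovery
checks, and a tidy export of the analysis-ready per-presentation table
for external mixed-model work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = ["CurveEstimate", "response_curves", "overlap_table",
           "fit_overlap_model", "export_model_table", "MOTIF_RANK"]

#: motif stimulation-intensity rank used for monotonicity checks.
#: Conspecific-call motifs outrank duration-matched tones (they engage the
#: latency pathway as well as generic inhibition); the top two are a
#: near-tie because peak renormalization of summed identical copies gives
#: them almost equal stimulation integrals.
MOTIF_RANK = ("silence", "tone_short", "tone_long", "synchronous",
              "overlapping", "overlap_sync")

MODEL_COLUMNS = ["subject_id", "night", "ref", "stimulus_id", "motif_kind",
                 "stimulus_delay", "response_delay", "response_period",
                 "overlapped", "restricted_overlap", "onset_time_in_trial",
                 "trigger_elaboration_z", "elaboration_z"]


@dataclass
class CurveEstimate:
    """Binned curve estimate with bootstrap confidence band."""

    delays: np.ndarray
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: np.ndarray


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    from .respmetrics import records_to_frame

    return records_to_frame(records)


def response_curves(records, n_boot: int = 200, seed: int = 0,
                    ci: float = 0.95) -> Tuple[CurveEstimate, CurveEstimate]:
    """Per-delay median response-delay and response-period curves.

    Overlapping responses are excluded (the delay to an overlapped
    stimulus has no identifiable trigger feature), as are records with
    no or spontaneous responses.  Stimulus delays are discrete in this
    design, so bins are the observed distinct delays.  With
    ``n_boot=0`` the confidence bands are NaN.  The period estimate is
    the bin delay plus the delay estimate, making the period-minus-delay
    identity exact by construction.
    """
    df = _as_frame(records)
    df = df[~df.overlapped & df.response_delay.notna()]
    if "spontaneous" in df:
        df = df[~df.spontaneous.astype(bool)]
    if not len(df):
        raise ValueError("no non-overlapping responses to summarize")
    rng = np.random.default_rng(seed)
    delays, est, lo, hi, ns = [], [], [], [], []
    q = (1 - ci) / 2
    for d, grp in df.groupby("stimulus_delay"):
        x = grp.response_delay.to_numpy()
        delays.append(d)
        est.append(np.median(x))
        ns.append(len(x))
        if n_boot > 0:
            boots = np.median(
                rng.choice(x, size=(n_boot, len(x)), replace=True), axis=1)
            lo.append(np.quantile(boots, q))
            hi.append(np.quantile(boots, 1 - q))
        else:
            lo.append(np.nan)
            hi.append(np.nan)
    delays = np.asarray(delays)
    est, lo, hi = map(np.asarray, (est, lo, hi))
    ns = np.asarray(ns)
    delay_curve = CurveEstimate(delays, est, lo, hi, ns)
    period_curve = CurveEstimate(delays, delays + est, delays + lo,
                                 delays + hi, ns)
    return delay_curve, period_curve


def overlap_table(records, by=("motif_kind", "stimulus_delay", "stimulus_id"),
                  ci: float = 0.95) -> pd.DataFrame:
    """Grouped overlap proportions (both definitions) with binomial CIs."""
    from statsmodels.stats.proportion import proportion_confint

    df = _as_frame(records)
    df = df[df.response_delay.notna()] if "response_delay" in df else df
    rows = []
    for key, grp in df.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        for col in ("overlapped", "restricted_overlap"):
            k = int(grp[col].sum())
            lo, hi = proportion_confint(k, n, alpha=1 - ci, method="wilson")
            rows.append(dict(zip(by, key), definition=col, n=n, k=k,
                             proportion=k / n, ci_low=lo, ci_high=hi))
    return pd.DataFrame(rows)


def fit_overlap_model(records, outcome: str = "overlapped"):
    """Fixed-effects logistic fit: overlap ~ motif * standardized delay.

    Treatment-coded motif (silence as reference) with a motif-by-delay
    interaction; the skeleton of the study's full mixed model, adequate
    for sign-recovery checks on simulated data.  Perfect separation is
    flagged and resolved with an L2-penalized refit.

    Returns a dict with ``params``, ``bse``, ``zvalues`` (pandas
    Series), ``separation`` (bool) and the fitted results object.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    df = _as_frame(records).copy()
    df = df[df.response_delay.notna()]
    y = df[outcome].astype(int)
    if y.nunique() < 2:
        raise ValueError("need both outcome classes to fit")
    d = df.stimulus_delay.astype(float)
    df["delay_z"] = (d - d.mean()) / d.std(ddof=1)
    X = pd.get_dummies(df[["motif_kind"]], drop_first=False, dtype=float)
    ref = "motif_kind_silence"
    if ref in X:
        X = X.drop(columns=[ref])
    for col in list(X.columns):
        X[col.replace("motif_kind_", "") + ":delay_z"] = X[col] * df.delay_z
    X.columns = [c.replace("motif_kind_", "") for c in X.columns]
    X.insert(0, "delay_z", df.delay_z)
    X = sm.add_constant(X)
    model = sm.Logit(y.to_numpy(), X)
    separation = False
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False, maxiter=200)
        if not res.mle_retvals.get("converged", True) or \
                np.any(~np.isfinite(res.bse)) or np.any(np.abs(res.params) > 15):
            separation = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separation = True
    if separation:
        with np.errstate(all="ignore"):
            res = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=False,
                                        maxiter=500)
    params = pd.Series(np.asarray(res.params), index=X.columns)
    try:
        bse = pd.Series(np.asarray(res.bse), index=X.columns)
    except Exception:
        bse = pd.Series(np.nan, index=X.columns)
    z = params / bse
    return dict(params=params, bse=bse, zvalues=z, separation=separation,
                result=res)


def export_model_table(records, path=None) -> pd.DataFrame:
    """Analysis-ready per-presentation table (one row per presentation).

    Contains the covariates of the study's overlap / response-delay
    models: delay, motif, stimulus id, onset time in trial, standardized
    trigger elaboration, subject and night.  Written as CSV when
    ``path`` is given; round-trips losslessly through ``pd.read_csv``.
    """
    df = _as_frame(records).copy()
    if "subject_id" not in df:
        df["subject_id"] = "subject"
    if "night" not in df:
        df["night"] = 1
    for src, dst in (("trigger_elaboration", "trigger_elaboration_z"),
                     ("elaboration", "elaboration_z")):
        if dst not in df:
            if src in df and df[src].std(ddof=1) > 0:
                x = df[src].astype(float)
                df[dst] = (x - x.mean()) / x.std(ddof=1)
            else:
                df[dst] = np.nan
    if "ref" not in df:
        df["ref"] = np.arange(len(df))
    if "onset_time_in_trial" not in df:
        df["onset_time_in_trial"] = np.nan
    for col in MODEL_COLUMNS:
        if col not in df:
            df[col] = np.nan
    out = df[MODEL_COLUMNS]
    if path is not None:
        out.to_csv(path, index=False)
    return out
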