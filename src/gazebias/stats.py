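"""Pre-registered and exploratory statistics for the transfer-of-bias study.

The central quantity is the horizontal fixation *barycenter* (mean
horizontal fixation position) measured before and after the biased search
training.  Per-participant pre-to-post shifts are sign-corrected so that
positive always means "toward the trained hemifield" (left-group raw shifts
are negated), then tested with one-sided one-sample t-tests.  The module
also provides the landmark-task psychometric (PSE) fit, the congruent-bias
index, early-window saccade shifts, fixation density maps, the alignment
binomial test, 500-ms median binning of gaze-target distance, the
gamma log-link learning-curve GLM, and plain OLS helper regressions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .task_engine import TrialRecord

__all__ = [
    "ShiftMeasure",
    "PsychometricFit",
    "DensityMap",
    "barycenter",
    "signed_shift",
    "image_shift_collapse",
    "one_sample_t_one_sided",
    "fit_psychometric",
    "congruent_bias",
    "early_window_shift",
    "fixation_density_map",
    "combine_maps_median",
    "alignment_test",
    "bin_gaze_target_distance",
    "standardize",
    "fit_learning_model",
    "ols_regression",
]


# ---------------------------------------------------------------------------
# shift measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftMeasure:
    """Per-participant pre-to-post change on one task.

    ``raw_shift = post - pre`` (deg); ``signed_shift`` negates the raw
    shift for left-bias participants so that positive means "toward the
    biased hemifield" in both groups.
    """

    participant: int
    task: str
    pre_value: float
    post_value: float
    bias_side: str

    @property
    def raw_shift(self) -> float:
        return self.post_value - self.pre_value

    @property
    def signed_shift(self) -> float:
        return signed_shift(self.raw_shift, self.bias_side)


def signed_shift(raw_shift: float, bias_side: str) -> float:
    """Collapse the two groups onto a common axis: negate left-group shifts."""
    if bias_side not in ("left", "right"):
        raise ValueError("bias_side must be 'left' or 'right'")
    return raw_shift if bias_side == "right" else -raw_shift


def barycenter(fixations: pd.DataFrame, weighted: bool = False) -> float:
    """Mean horizontal fixation position (deg) of a viewing record.

    The default is the unweighted mean of fixation centroids; set
    ``weighted=True`` for a fixation-duration-weighted variant.
    Returns NaN when there are no fixations.
    """
    if len(fixations) == 0:
        return float("nan")
    if weighted:
        w = fixations["duration_s"].to_numpy()
        return float(np.average(fixations["x"], weights=w))
    return float(fixations["x"].mean())


def image_shift_collapse(per_image_shifts) -> float:
    """Collapse per-image shifts to one participant value with the median
    (robust to the skewed per-image distributions the mean cannot handle)."""
    arr = np.asarray(per_image_shifts, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one image shift")
    return float(np.median(arr))


def one_sample_t_one_sided(x, direction: str = "greater") -> dict:
    """One-sample one-sided t-test of mean 0, with effect size.

    Returns t, df, p (upper-tail for ``direction='greater'``), Cohen's d
    (= mean/sd), and the one-sided 95% CI bound on the mean.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 2 or not np.all(np.isfinite(arr)):
        raise ValueError("need >= 2 finite values")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance: t statistic undefined")
    n = arr.size
    mean = arr.mean()
    se = sd / math.sqrt(n)
    t = mean / se
    df = n - 1
    tcrit = sps.t.ppf(0.95, df)
    if direction == "greater":
        p = float(sps.t.sf(t, df))
        ci_bound = mean - tcrit * se
    elif direction == "less":
        p = float(sps.t.cdf(t, df))
        ci_bound = mean + tcrit * se
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return {"t": float(t), "df": df, "p": p, "cohens_d": float(mean / sd),
            "mean": float(mean), "sd": float(sd), "ci_bound": float(ci_bound)}


# ---------------------------------------------------------------------------
# psychometric (landmark) fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsychometricFit:
    """Two-parameter logistic psychometric fit for the landmark task.

    ``P(resp right) = 1 / (1 + exp(-slope * (offset - pse)))``; the PSE is
    the bisection offset at which both responses are equiprobable.
    """

    pse: float
    slope: float
    converged: bool
    se_pse: float


def fit_psychometric(offsets, responses) -> PsychometricFit:
    """Maximum-likelihood logistic fit of P(right) against bisection offset.

    Fit as a logistic regression on (intercept, offset); then
    ``slope = b1`` and ``pse = -b0/b1``, with the PSE standard error from
    the delta method.  Complete separation is flagged as non-converged,
    with the PSE placed midway between the separating offsets.
    """
    o = np.asarray(offsets, dtype=float)
    r = np.asarray(responses, dtype=float)
    if o.shape != r.shape or o.size < 4:
        raise ValueError("offsets/responses must be equal-length, n >= 4")
    if len(np.unique(o)) < 2 or len(np.unique(r)) < 2:
        raise ValueError("need >= 2 distinct offsets and mixed responses")
    # detect complete separation: all 0s strictly below all 1s (or reverse)
    hi0 = o[r == 0].max()
    lo1 = o[r == 1].min()
    hi1 = o[r == 1].max()
    lo0 = o[r == 0].min()
    if hi0 < lo1:
        return PsychometricFit((hi0 + lo1) / 2.0, math.inf, False, float("nan"))
    if hi1 < lo0:
        return PsychometricFit((hi1 + lo0) / 2.0, -math.inf, False, float("nan"))
    X = sm.add_constant(o)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(r, X).fit(disp=0, maxiter=200)
    b0, b1 = res.params
    converged = bool(res.mle_retvals.get("converged", True)) and b1 != 0
    pse = -b0 / b1 if b1 != 0 else float("nan")
    se_pse = float("nan")
    if converged:
        grad = np.array([-1.0 / b1, b0 / b1 ** 2])
        var = float(grad @ res.cov_params() @ grad)
        se_pse = math.sqrt(var) if var >= 0 else float("nan")
    return PsychometricFit(float(pse), float(b1), converged, se_pse)


# ---------------------------------------------------------------------------
# exploratory indices
# ---------------------------------------------------------------------------

def congruent_bias(early_fixation_x, bias_side: str) -> float:
    """Congruent-bias index from fixations in the first second of viewing.

    The magnitude is ``|median horizontal position|``; the sign is positive
    when the natural early bias points to the participant's trained
    hemifield and negative otherwise.  NaN when no early fixations exist.
    """
    if bias_side not in ("left", "right"):
        raise ValueError("bias_side must be 'left' or 'right'")
    arr = np.asarray(early_fixation_x, dtype=float)
    if arr.size == 0:
        return float("nan")
    med = float(np.median(arr))
    if med == 0.0:
        return 0.0
    natural_side = "left" if med < 0 else "right"
    return abs(med) if natural_side == bias_side else -abs(med)


def early_window_shift(saccades: pd.DataFrame, endpoint_x,
                       window_s: float = 1.0) -> float:
    """Median horizontal saccade endpoint within the first ``window_s``.

    ``endpoint_x`` supplies the horizontal landing position per saccade
    (the segmentation stores amplitudes, not endpoints).  NaN when no
    saccade starts inside the window.
    """
    onset = saccades["onset_s"].to_numpy()
    ex = np.asarray(endpoint_x, dtype=float)
    if onset.shape != ex.shape:
        raise ValueError("endpoint_x must align with the saccade table")
    sel = ex[onset < window_s]
    if sel.size == 0:
        return float("nan")
    return float(np.median(sel))


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """Normalized fixation-density grid over screen coordinates (deg)."""

    grid: np.ndarray  # (ny, nx), sums to 1
    x_edges: np.ndarray
    y_edges: np.ndarray
    bandwidth: float

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def mass_right_of_midline(self) -> float:
        right = self.x_centers > 0
        return float(self.grid[:, right].sum())


def fixation_density_map(fixations: pd.DataFrame,
                         x_range: tuple[float, float] = (-24.0, 24.0),
                         y_range: tuple[float, float] = (-13.5, 13.5),
                         spacing: float = 0.25,
                         bandwidth: float = 1.0,
                         exclude_initial_s: float = 0.75,
                         flip_x: bool = False,
                         duration_weighted: bool = True) -> DensityMap:
    """Gaussian-kernel fixation density map, normalized to sum to 1.

    Fixations with onset before ``exclude_initial_s`` are dropped (removing
    the strong central fixation at trial start); ``flip_x=True`` reflects
    coordinates onto the opposite hemifield (used to pool left-bias-group
    data with the right group).  Kernels are weighted by fixation duration
    by default.  An empty input yields a uniform map with a warning.
    """
    xe = np.arange(x_range[0], x_range[1] + spacing / 2, spacing)
    ye = np.arange(y_range[0], y_range[1] + spacing / 2, spacing)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    fix = fixations[fixations["onset_s"] >= exclude_initial_s]
    if len(fix) == 0:
        warnings.warn("no fixations after initial exclusion; uniform map")
        grid = np.full((yc.size, xc.size), 1.0 / (yc.size * xc.size))
        return DensityMap(grid, xe, ye, bandwidth)
    fx = fix["x"].to_numpy() * (-1.0 if flip_x else 1.0)
    fy = fix["y"].to_numpy()
    w = fix["duration_s"].to_numpy() if duration_weighted else np.ones(len(fix))
    gx = np.exp(-0.5 * ((xc[None, :] - fx[:, None]) / bandwidth) ** 2)
    gy = np.exp(-0.5 * ((yc[None, :] - fy[:, None]) / bandwidth) ** 2)
    grid = np.einsum("f,fy,fx->yx", w, gy, gx)
    total = grid.sum()
    if total <= 0:
        warnings.warn("all fixation mass outside the grid; uniform map")
        grid = np.full_like(grid, 1.0)
        total = grid.sum()
    return DensityMap(grid / total, xe, ye, bandwidth)


def combine_maps_median(maps: list[DensityMap]) -> DensityMap:
    """Cellwise median of several density maps, renormalized to sum to 1."""
    if not maps:
        raise ValueError("need at least one map")
    ref = maps[0]
    stack = np.stack([m.grid for m in maps])
    med = np.median(stack, axis=0)
    total = med.sum()
    if total <= 0:
        med = np.full_like(med, 1.0)
        total = med.sum()
    return DensityMap(med / total, ref.x_edges, ref.y_edges, ref.bandwidth)


# ---------------------------------------------------------------------------
# alignment test
# ---------------------------------------------------------------------------

def alignment_test(avs_side, ivt_sign, bsv_sign, p0: float = 0.25) -> dict:
    """Concordance of transfer directions with the trained hemifield.

    A participant is "aligned" when the IVT and BSV shift directions *both*
    equal the AVS bias side.  Under independent fair directions the chance
    level is 0.25.  Tested with an exact one-sided binomial test against
    ``p0``.  Participants with a missing direction are excluded and counted.
    """
    avs = pd.Series(avs_side).astype(object)
    ivt = pd.Series(ivt_sign).astype(object)
    bsv = pd.Series(bsv_sign).astype(object)
    ok = avs.isin(["left", "right"]) & ivt.isin(["left", "right"]) \
        & bsv.isin(["left", "right"])
    n_excluded = int((~ok).sum())
    avs, ivt, bsv = avs[ok], ivt[ok], bsv[ok]
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no complete direction triples")
    k = int(((ivt == avs) & (bsv == avs)).sum())
    test = sps.binomtest(k, n, p0, alternative="greater")
    return {"k": k, "n": n, "proportion": k / n, "p": float(test.pvalue),
            "n_excluded": n_excluded}


# ---------------------------------------------------------------------------
# learning-curve binning and models
# ---------------------------------------------------------------------------

def bin_gaze_target_distance(trial: TrialRecord, bin_s: float = 0.5,
                             pad_to_deadline: bool = False) -> pd.DataFrame:
    """Median gaze-target distance per 500-ms bin of one trial.

    Bins cover the trial's live span; with ``pad_to_deadline=True`` (the
    plotting convention) bins after the trial end carry the last recorded
    distance forward.  Returns columns ``time_bin_center_s`` and
    ``median_distance_deg`` plus trial metadata.
    """
    trace = trial.trace
    d = np.hypot(trace.x - trial.target.x, trace.y - trial.target.y)
    d = d[trace.valid]
    t = trace.t[trace.valid]
    if t.size == 0:
        raise ValueError("trial has no valid samples")
    k = np.floor(t / bin_s).astype(int)
    rows = []
    for kk in np.unique(k):
        rows.append((bin_s * (kk + 0.5), float(np.median(d[k == kk]))))
    if pad_to_deadline:
        last = rows[-1][1]
        k_max = int(math.ceil(10.0 / bin_s))
        have = {round(r[0], 9) for r in rows}
        for kk in range(k_max):
            center = bin_s * (kk + 0.5)
            if round(center, 9) not in have:
                rows.append((center, last))
        rows.sort()
    out = pd.DataFrame(rows, columns=["time_bin_center_s", "median_distance_deg"])
    out["trial_number"] = trial.trial_number
    out["bias_label"] = trial.bias_label
    return out


def standardize(v) -> np.ndarray:
    """Mean-center and scale to unit (sample) variance."""
    arr = np.asarray(v, dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant vector")
    return (arr - arr.mean()) / sd


_TERMS = ["time_z", "trial_z", "bias", "time_z:trial_z", "time_z:bias",
          "trial_z:bias", "time_z:trial_z:bias"]


def _learning_design(df: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    X["time_z"] = df["time_z"]
    X["trial_z"] = df["trial_z"]
    X["bias"] = (df["bias_label"] == "unbiased").astype(float)
    X["time_z:trial_z"] = X["time_z"] * X["trial_z"]
    X["time_z:bias"] = X["time_z"] * X["bias"]
    X["trial_z:bias"] = X["trial_z"] * X["bias"]
    X["time_z:trial_z:bias"] = X["time_z"] * X["trial_z"] * X["bias"]
    return X


def fit_learning_model(binned: pd.DataFrame, lrt: bool = True) -> pd.DataFrame:
    """Gamma log-link GLM of binned gaze-target distance.

    ``binned`` needs columns ``median_distance_deg`` (positive),
    ``bias_label`` ('biased'/'unbiased', biased = reference level),
    ``trial_number`` and ``time_bin_center_s``; the continuous predictors
    are standardized internally.  Coefficients are reported as
    multiplicative factors (exp of the log-link estimates) for the three
    main effects and all interactions; with ``lrt=True`` each term gets a
    likelihood-ratio chi-square and p-value from a drop-one refit.

    This is the fixed-effects core of the full random-slopes mixed model;
    an external mixed-model backend can be plugged in through the same
    long-format CSV (see :mod:`gazebias.io`).
    """
    y = binned["median_distance_deg"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma GLM requires strictly positive distances")
    df = binned.copy()
    df["time_z"] = standardize(df["time_bin_center_s"])
    df["trial_z"] = standardize(df["trial_number"])
    X = _learning_design(df)
    family = sm.families.Gamma(link=sm.families.links.Log())
    full = sm.GLM(y, X, family=family).fit()
    rows = []
    for term in _TERMS:
        est = float(full.params[term])
        row = {"term": term, "factor": math.exp(est), "estimate": est,
               "se": float(full.bse[term])}
        if lrt:
            Xr = X.drop(columns=[term])
            red = sm.GLM(y, Xr, family=family).fit()
            # both log-likelihoods at the full model's dispersion (nested LRT)
            ll_full = full.model.loglike(full.params, scale=full.scale)
            ll_red = red.model.loglike(red.params, scale=full.scale)
            chi2 = 2.0 * (ll_full - ll_red)
            chi2 = max(0.0, float(chi2))
            row["chi2"] = chi2
            row["p"] = float(sps.chi2.sf(chi2, 1))
        else:
            row["p"] = float(full.pvalues[term])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["llf"] = float(full.llf)
    out.attrs["scale"] = float(full.scale)
    return out


def ols_regression(y, X: pd.DataFrame) -> pd.DataFrame:
    """OLS with classical t-tests; returns estimate, se, t, df, p per column.

    Raises on rank deficiency, naming the collinear columns.
    """
    Xd = sm.add_constant(pd.DataFrame(X).astype(float))
    yv = np.asarray(y, dtype=float)
    if yv.size <= Xd.shape[1]:
        raise ValueError("need more observations than parameters")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        corr = Xd.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; near-collinear: {worst}")
    res = sm.OLS(yv, Xd).fit()
    return pd.DataFrame({
        "estimate": res.params, "se": res.bse, "t": res.tvalues,
        "df": res.df_resid, "p": res.pvalues,
    })
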