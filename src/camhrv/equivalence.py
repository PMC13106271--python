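"""Validation statistics: TOST equivalence power with clustering correction,
cluster-bootstrap equivalence of model coefficients, and the emotion-task
change-score preprocessing.

TOST power
----------
For a one-sample two-one-sided-tests procedure with equivalence bounds
(L, U), observed mean absolute error μ and SD σ over n participants,

    SE = σ/√n_eff,   t* = t_{1−α, n_eff−1},
    power = Φ((U − t*·SE − μ)/SE) − Φ((L + t*·SE − μ)/SE),

a normal approximation of the sampling distribution with t critical values
(fractional degrees of freedom are handled natively).  Multiple recordings
per participant are folded in through the design effect
deff = 1 + (m − 1)·ICC, giving n_eff = n·m/deff.  An exact noncentral-t
variant is available behind ``method="noncentral_t"``.

Cluster bootstrap
-----------------
Participants (clusters) are resampled with replacement, all their
recordings retained; two linear models (rPPG outcome and ECG outcome on
the same predictors) are refit per resample, and Δβ = β_rPPG − β_ECG is
accumulated per coefficient.  Equivalence holds for a coefficient when at
least 90% of bootstrapped differences fall within the SESOI bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TOSTSpec",
    "EquivalenceResult",
    "ComponentWindows",
    "design_effect",
    "tost_power",
    "ols_fitter",
    "cluster_bootstrap_equivalence",
    "hr_change_scores",
    "component_means",
    "z_standardize_reference",
]


@dataclass
class TOSTSpec:
    """Inputs of a one-sample TOST power computation."""

    mu: float  # observed mean absolute error, ms
    sigma: float  # its SD, ms
    n: int  # participants
    bounds: tuple[float, float] = (-15.0, 15.0)
    alpha: float = 0.05
    m: float | None = None  # recordings per participant (clustering)
    icc: float | None = None

    def __post_init__(self) -> None:
        L, U = self.bounds
        if L >= U:
            raise ValueError("lower bound must be below upper bound")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n < 2:
            raise ValueError("need at least two participants")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if (self.m is None) != (self.icc is None):
            raise ValueError("clustering needs both m and icc")
        if self.m is not None:
            if self.m < 1:
                raise ValueError("m must be >= 1")
            if not 0 <= self.icc <= 1:
                raise ValueError("icc must be in [0, 1]")

    @property
    def n_eff(self) -> float:
        if self.m is None:
            return float(self.n)
        return self.n * self.m / design_effect(self.m, self.icc)


def design_effect(m: float, icc: float) -> float:
    """deff = 1 + (m − 1)·ICC; effective n = n·m/deff."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= icc <= 1:
        raise ValueError("icc must be in [0, 1]")
    return 1.0 + (m - 1.0) * icc


def tost_power(spec: TOSTSpec, method: str = "normal") -> float:
    """Power of the one-sample TOST at the given design; in [0, 1].

    ``method="normal"`` (default) uses the normal sampling approximation
    with t critical values; ``method="noncentral_t"`` the noncentral-t
    formulation.  An infeasible design (critical region empty:
    U − t*·SE ≤ L + t*·SE) returns power 0.
    """
    L, U = spec.bounds
    n_eff = spec.n_eff
    se = spec.sigma / np.sqrt(n_eff)
    df = n_eff - 1.0
    tcrit = stats.t.ppf(1.0 - spec.alpha, df)
    if U - tcrit * se <= L + tcrit * se:
        return 0.0  # inconclusive design: bounds exclude all mass
    if method == "normal":
        hi = stats.norm.cdf((U - tcrit * se - spec.mu) / se)
        lo = stats.norm.cdf((L + tcrit * se - spec.mu) / se)
        return float(max(0.0, hi - lo))
    if method == "noncentral_t":
        ncp_l = (spec.mu - L) / se
        ncp_u = (spec.mu - U) / se
        p_lower = stats.nct.sf(tcrit, df, ncp_l)
        p_upper = stats.nct.cdf(-tcrit, df, ncp_u)
        return float(max(0.0, p_lower + p_upper - 1.0))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class EquivalenceResult:
    """Per-coefficient cluster-bootstrap equivalence summary."""

    coefficients: list[str]
    mean_delta: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    prop_within_sesoi: dict[str, float]
    equivalent: dict[str, bool]
    n_boot: int
    seed: int
    n_failures: int = 0
    deltas: np.ndarray | None = field(default=None, repr=False)


def ols_fitter(
    df: pd.DataFrame, outcome: str, predictors: list[str]
) -> dict[str, float]:
    """Ordinary least squares with an intercept; returns named coefficients."""
    X = np.column_stack(
        [np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in predictors]
    )
    y = df[outcome].to_numpy(dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design in resample")
    names = ["intercept"] + list(predictors)
    return dict(zip(names, beta))


def cluster_bootstrap_equivalence(
    table: pd.DataFrame,
    outcome_rppg: str,
    outcome_ecg: str,
    predictors: list[str],
    cluster_id: str = "participant_id",
    sesoi: float = 15.0,
    n_boot: int = 10_000,
    seed: int = 0,
    fitter=ols_fitter,
    equivalence_prop: float = 0.90,
    max_failure_frac: float = 0.01,
) -> EquivalenceResult:
    """Cluster-bootstrap SESOI equivalence of rPPG vs ECG model coefficients.

    Each resample draws as many clusters as observed, with replacement,
    keeping every recording of a drawn cluster (duplicates get fresh ids
    implicitly by concatenation); both models are refit and
    Δβ = β_rppg − β_ecg recorded per coefficient.  A failed fit redraws the
    resample; more than ``max_failure_frac·n_boot`` failures abort.
    """
    clusters = table[cluster_id].unique()
    if clusters.size < 2:
        raise ValueError("need at least two clusters")
    rng = np.random.default_rng(seed)
    groups = {c: table[table[cluster_id] == c] for c in clusters}
    coef_names = ["intercept"] + list(predictors)
    deltas = np.empty((n_boot, len(coef_names)))
    failures = 0
    max_failures = max(1, int(np.ceil(max_failure_frac * n_boot)))
    b = 0
    while b < n_boot:
        draw = rng.choice(clusters, size=clusters.size, replace=True)
        sample = pd.concat([groups[c] for c in draw], ignore_index=True)
        try:
            beta_r = fitter(sample, outcome_rppg, predictors)
            beta_e = fitter(sample, outcome_ecg, predictors)
        except Exception:
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"more than {max_failure_frac:.0%} of bootstrap fits failed"
                )
            continue
        deltas[b] = [beta_r[c] - beta_e[c] for c in coef_names]
        b += 1

    mean_d, lo, hi, prop, equiv = {}, {}, {}, {}, {}
    for k, name in enumerate(coef_names):
        d = deltas[:, k]
        mean_d[name] = float(d.mean())
        lo[name] = float(np.percentile(d, 2.5))
        hi[name] = float(np.percentile(d, 97.5))
        prop[name] = float(np.mean(np.abs(d) <= sesoi))
        equiv[name] = prop[name] >= equivalence_prop
    return EquivalenceResult(
        coefficients=coef_names, mean_delta=mean_d, ci_low=lo, ci_high=hi,
        prop_within_sesoi=prop, equivalent=equiv, n_boot=n_boot, seed=seed,
        n_failures=failures, deltas=deltas,
    )


@dataclass
class ComponentWindows:
    """Cardiac-response component windows, seconds relative to S2 onset.

    D1/A1/D2 span the anticipation period before the picture (S2); PDP is
    the picture-display period.  Windows are disjoint, contiguous,
    half-open ``[lo, hi)``.
    """

    d1: tuple[float, float] = (-6.0, -4.0)
    a1: tuple[float, float] = (-4.0, -2.0)
    d2: tuple[float, float] = (-2.0, 0.0)
    pdp: tuple[float, float] = (0.0, 2.0)

    def items(self):
        return (("D1", self.d1), ("A1", self.a1), ("D2", self.d2), ("PDP", self.pdp))


def hr_change_scores(
    inst_hr,
    trial_start_s: float,
    s2_onset_s: float | None = None,
    baseline_s: float = 1.0,
    bin_s: float = 0.5,
    span: tuple[float, float] = (-6.0, 2.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-corrected, half-second-binned HR change scores for one trial.

    Baseline is the mean HR in ``[trial_start − baseline_s, trial_start)``.
    ``s2_onset_s`` defaults to ``trial_start + 6`` (1.5 s word + 4.5 s
    anticipation interval).  Returns ``(bin_mid_times_rel_s2, bin_means)``
    over half-open bins covering ``span`` relative to S2 onset.
    """
    if s2_onset_s is None:
        s2_onset_s = trial_start_s + 6.0
    t = inst_hr.t
    hr = inst_hr.hr_bpm
    if t[0] > trial_start_s - baseline_s + 1e-9 or t[-1] < trial_start_s:
        raise ValueError("baseline window not fully inside recording (trial flagged)")
    base_sel = (t >= trial_start_s - baseline_s) & (t < trial_start_s)
    if not base_sel.any():
        raise ValueError("baseline window has no samples (trial flagged)")
    baseline = hr[base_sel].mean()
    change = hr - baseline
    edges = np.arange(span[0], span[1] + bin_s / 2, bin_s)
    mids = (edges[:-1] + edges[1:]) / 2.0
    rel = t - s2_onset_s
    means = np.empty(mids.size)
    for i in range(mids.size):
        sel = (rel >= edges[i]) & (rel < edges[i + 1])
        means[i] = change[sel].mean() if sel.any() else np.nan
    return mids, means


def component_means(
    bin_mids: np.ndarray,
    bin_values: np.ndarray,
    windows: ComponentWindows | None = None,
) -> dict[str, float]:
    """Mean bin value per cardiac-response component.

    A bin belongs to the component whose half-open window contains its
    midpoint (a midpoint exactly on a boundary joins the later component).
    An uncovered component is flagged missing (NaN).
    """
    windows = windows or ComponentWindows()
    out: dict[str, float] = {}
    for name, (lo, hi) in windows.items():
        sel = (bin_mids >= lo) & (bin_mids < hi)
        vals = np.asarray(bin_values)[sel]
        vals = vals[~np.isnan(vals)]
        out[name] = float(vals.mean()) if vals.size else float("nan")
    return out


def z_standardize_reference(
    values: np.ndarray, ref_mean: float, ref_sd: float
) -> np.ndarray:
    """(x − ref_mean)/ref_sd — standardization by reference-dataset moments.

    rPPG scores standardized by the ECG reference moments keep their own
    location/scale (no renormalization), so coefficients from both datasets
    live on the same standardized-effect-size scale.
    """
    if ref_sd <= 0:
        raise ValueError("reference SD must be positive")
    return (np.asarray(values, dtype=float) - ref_mean) / ref_sd
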