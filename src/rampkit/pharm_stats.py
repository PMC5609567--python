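"""Receptor pharmacology statistics for alanine-scan cAMP, ELISA and
radioligand-binding data.

The central quantity is the expression-corrected change in log relative
activity between a wild-type (WT) receptor and a mutant:

    log(RA)  = log10(Emax / EC50) = log10(Emax) + pEC50
    Δlog(RA) = log(RA)_WT − [log(RA)_mut − log10(expression fraction)]

where the expression fraction is the mutant's cell-surface expression as a
fraction of WT (ELISA).  The sign convention is fixed so that a *positive*
Δlog(RA) means the mutant is impaired (loss of function) and a negative
value means gain of function.  Emax is the fitted upper asymptote in nM
cAMP and EC50 is in molar; because only differences of log(RA) are ever
reported the nM/M unit constant cancels exactly.

Standard errors are combined in quadrature (delta method for the log
transforms): SE(pEC50) enters directly, SE(log10 Emax) = SE(Emax)/(Emax·ln10),
and SE(log10 expr) = (SE(%)/%)/ln10.  The 95% CI uses the normal 1.96
multiplier by default; a Student-t multiplier is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

LN10 = math.log(10.0)

__all__ = [
    "Experiment",
    "ConcentrationResponseDataset",
    "LogisticFitResult",
    "ExpressionSummary",
    "DeltaLogRAResult",
    "CompetitionFit",
    "BindingResult",
    "fit_three_parameter_logistic",
    "fit_dataset",
    "dataset_from_frame",
    "dataset_to_frame",
    "log_relative_activity",
    "delta_log_ra",
    "delta_log_ra_from_summary",
    "delta_log_ra_per_experiment",
    "fold_potency_change",
    "normalize_elisa",
    "fit_competition",
    "relative_binding",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class Experiment:
    """One independent concentration-response experiment.

    Parameters
    ----------
    concentrations : array of float
        Agonist concentrations in molar, strictly increasing, > 0.
    responses : array of float
        cAMP responses in nM, shape ``(n_conc,)`` or ``(n_conc, n_rep)``
        for technical replicates.
    """

    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        c = self.concentrations
        if c.ndim != 1 or len(np.unique(c)) < 4:
            raise ValueError("need at least 4 distinct concentrations")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive (molar)")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.responses.shape[0] != c.shape[0]:
            raise ValueError("responses must have one row per concentration")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    @property
    def log_concentrations(self) -> np.ndarray:
        return np.log10(self.concentrations)

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten replicates to paired (log10 concentration, response)."""
        x = self.log_concentrations
        if self.responses.ndim == 1:
            return x, self.responses
        n_rep = self.responses.shape[1]
        return np.repeat(x, n_rep), self.responses.ravel()


@dataclass
class ConcentrationResponseDataset:
    """Replicated concentration-response measurements for one receptor/ligand."""

    receptor_label: str
    ligand_label: str
    experiments: list[Experiment]

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ValueError("dataset needs at least one experiment")

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)


@dataclass
class LogisticFitResult:
    """Three-parameter logistic fit of a concentration-response curve.

    ``no_curve`` flags fits whose span (emax − basal) is below three times
    the residual SD of the responses: such curves are treated as too weak
    to support a relative-activity estimate.
    """

    basal: float
    emax: float
    pec50: float
    se_basal: float
    se_emax: float
    se_pec50: float
    converged: bool
    no_curve: bool = False
    residual_sd: float = float("nan")

    @property
    def span(self) -> float:
        return self.emax - self.basal


@dataclass
class ExpressionSummary:
    """Mutant cell-surface expression as a percentage of same-experiment WT."""

    percent_of_wt: float
    se_percent: float
    n_experiments: int
    per_experiment: np.ndarray | None = None
    negative_flagged: bool = False

    def __post_init__(self) -> None:
        if self.se_percent < 0:
            raise ValueError("se_percent must be non-negative")

    @property
    def fraction(self) -> float:
        return self.percent_of_wt / 100.0


@dataclass
class DeltaLogRAResult:
    """Expression-corrected Δlog(RA) with propagated error.

    ``log_ra_mut`` is the expression-corrected mutant value; the raw
    (uncorrected) value is kept in ``log_ra_mut_raw``.  Positive
    ``delta_log_ra`` = impaired mutant.
    """

    log_ra_wt: float
    log_ra_mut: float
    delta_log_ra: float
    se_delta: float
    ci95_low: float
    ci95_high: float
    significant: bool
    log_ra_mut_raw: float = float("nan")
    available: bool = True


@dataclass
class CompetitionFit:
    """One-site competition (displacement) curve fit."""

    top: float
    bottom: float
    pic50: float
    se_top: float
    se_bottom: float
    se_span: float
    converged: bool

    @property
    def span(self) -> float:
        return self.top - self.bottom


@dataclass
class BindingResult:
    """Specific binding of a mutant relative to WT, from displacement spans."""

    pic50: float
    span: float
    percent_bound_vs_wt: float
    ci95: tuple[float, float]
    se_percent: float = float("nan")


# ---------------------------------------------------------------------------
# long-format CSV interchange
# ---------------------------------------------------------------------------

def dataset_from_frame(df, receptor_label: str = "",
                       ligand_label: str = "") -> ConcentrationResponseDataset:
    """Build a dataset from a long-format table.

    Expected columns: ``experiment_id``, ``concentration_M``,
    ``response_nM`` (one row per technical replicate).  Every
    concentration within an experiment must carry the same number of
    replicates.
    """
    experiments = []
    for _, grp in df.groupby("experiment_id", sort=True):
        counts = grp.groupby("concentration_M").size()
        if counts.nunique() != 1:
            raise ValueError("unequal replicate counts within an experiment")
        n_rep = int(counts.iloc[0])
        grp = grp.sort_values("concentration_M", kind="stable")
        conc = np.sort(grp["concentration_M"].unique())
        resp = grp["response_nM"].to_numpy().reshape(len(conc), n_rep)
        experiments.append(Experiment(conc, resp))
    return ConcentrationResponseDataset(receptor_label, ligand_label,
                                        experiments)


def dataset_to_frame(dataset: ConcentrationResponseDataset):
    """Long-format table (experiment_id, concentration_M, response_nM)."""
    import pandas as pd

    rows = []
    for e, exp in enumerate(dataset.experiments):
        resp = np.atleast_2d(exp.responses.T).T
        for c, conc in enumerate(exp.concentrations):
            for r in range(resp.shape[1]):
                rows.append({"experiment_id": e, "concentration_M": conc,
                             "response_nM": resp[c, r]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic fitting
# ---------------------------------------------------------------------------

def three_parameter_logistic(x: np.ndarray, basal: float, emax: float,
                             pec50: float) -> np.ndarray:
    """Hill-slope-1 logistic over log10 molar concentration ``x``."""
    return basal + (emax - basal) / (1.0 + 10.0 ** (-(x + pec50)))


def fit_three_parameter_logistic(experiment: Experiment,
                                 pec50_bounds: tuple[float, float] = (4.0, 14.0),
                                 ) -> LogisticFitResult:
    """Fit ``response = basal + (emax − basal)/(1 + 10^(−log10 c − pEC50))``.

    Unweighted least squares over all replicate points, Hill slope fixed
    at 1.  Standard errors come from the fit covariance.  A failed or
    unidentifiable optimisation returns ``converged=False`` rather than
    raising.
    """
    x, y = experiment.points()
    basal0, emax0 = float(np.min(y)), float(np.max(y))
    half = 0.5 * (basal0 + emax0)
    pec50_0 = float(np.clip(-x[np.argmin(np.abs(y - half))], *pec50_bounds))
    p0 = (basal0, emax0, pec50_0)
    bounds = ([-np.inf, -np.inf, pec50_bounds[0]],
              [np.inf, np.inf, pec50_bounds[1]])
    try:
        popt, pcov = optimize.curve_fit(
            three_parameter_logistic, x, y, p0=p0, bounds=bounds, maxfev=10000)
    except (RuntimeError, ValueError):
        return LogisticFitResult(*p0, np.nan, np.nan, np.nan, converged=False)
    ses = np.sqrt(np.diag(pcov))
    resid = y - three_parameter_logistic(x, *popt)
    dof = max(len(y) - 3, 1)
    residual_sd = float(np.sqrt(np.sum(resid ** 2) / dof))
    if not np.all(np.isfinite(popt)) or not np.all(np.isfinite(ses)):
        # singular covariance: pEC50 unidentifiable (e.g. flat responses)
        return LogisticFitResult(*popt, *ses, converged=False,
                                 residual_sd=residual_sd)
    basal, emax, pec50 = (float(v) for v in popt)
    no_curve = (emax - basal) <= 3.0 * residual_sd
    return LogisticFitResult(basal, emax, pec50,
                             float(ses[0]), float(ses[1]), float(ses[2]),
                             converged=True, no_curve=no_curve,
                             residual_sd=residual_sd)


def fit_dataset(dataset: ConcentrationResponseDataset) -> list[LogisticFitResult]:
    """Fit each experiment in a dataset independently."""
    return [fit_three_parameter_logistic(e) for e in dataset.experiments]


# ---------------------------------------------------------------------------
# relative activity
# ---------------------------------------------------------------------------

def log_relative_activity(fit: LogisticFitResult) -> tuple[float, float]:
    """log10(Emax/EC50) = log10(Emax) + pEC50, with its delta-method SE."""
    if fit.emax <= 0:
        raise ValueError("Emax must be positive to take log10")
    log_ra = math.log10(fit.emax) + fit.pec50
    var = fit.se_pec50 ** 2 + (fit.se_emax / (fit.emax * LN10)) ** 2
    return log_ra, math.sqrt(var)


def _unavailable() -> DeltaLogRAResult:
    nan = float("nan")
    return DeltaLogRAResult(nan, nan, nan, nan, nan, nan,
                            significant=False, available=False)


def delta_log_ra(wt: LogisticFitResult, mut: LogisticFitResult,
                 expression: ExpressionSummary,
                 ci_multiplier: float = 1.96) -> DeltaLogRAResult:
    """Expression-corrected Δlog(RA) = log(RA)_WT − corrected log(RA)_mut.

    The mutant log(RA) is corrected by subtracting log10 of the expression
    fraction (mutant surface expression / WT); the SE combines, in
    quadrature, both pEC50 SEs, both delta-method log10(Emax) SEs, and the
    delta-method SE of the log10 expression fraction.  ``significant``
    is True iff the CI excludes zero.
    """
    if expression.percent_of_wt <= 0:
        raise ValueError("expression percent must be positive")
    if not (wt.converged and mut.converged):
        return _unavailable()
    if wt.no_curve or mut.no_curve:
        return _unavailable()
    log_ra_wt, se_wt = log_relative_activity(wt)
    log_ra_mut_raw, se_mut = log_relative_activity(mut)
    frac = expression.fraction
    log_ra_mut = log_ra_mut_raw - math.log10(frac)
    se_expr = (expression.se_percent / expression.percent_of_wt) / LN10
    delta = log_ra_wt - log_ra_mut
    se_delta = math.sqrt(se_wt ** 2 + se_mut ** 2 + se_expr ** 2)
    lo, hi = delta - ci_multiplier * se_delta, delta + ci_multiplier * se_delta
    return DeltaLogRAResult(
        log_ra_wt=log_ra_wt, log_ra_mut=log_ra_mut, delta_log_ra=delta,
        se_delta=se_delta, ci95_low=lo, ci95_high=hi,
        significant=bool(lo > 0 or hi < 0), log_ra_mut_raw=log_ra_mut_raw)


def delta_log_ra_from_summary(wt_pec50: float, wt_emax: float,
                              mut_pec50: float, mut_emax: float,
                              expression_percent: float,
                              se_wt_pec50: float = 0.0, se_wt_emax: float = 0.0,
                              se_mut_pec50: float = 0.0, se_mut_emax: float = 0.0,
                              se_expression: float = 0.0,
                              ci_multiplier: float = 1.96) -> DeltaLogRAResult:
    """From-summary mode: Δlog(RA) directly from tabulated means ± SEMs."""
    wt = LogisticFitResult(0.0, wt_emax, wt_pec50, 0.0, se_wt_emax,
                           se_wt_pec50, converged=True)
    mut = LogisticFitResult(0.0, mut_emax, mut_pec50, 0.0, se_mut_emax,
                            se_mut_pec50, converged=True)
    expr = ExpressionSummary(expression_percent, se_expression, n_experiments=1)
    return delta_log_ra(wt, mut, expr, ci_multiplier=ci_multiplier)


def delta_log_ra_per_experiment(wt: ConcentrationResponseDataset,
                                mut: ConcentrationResponseDataset,
                                expression_percents: np.ndarray,
                                use_t: bool = True) -> DeltaLogRAResult:
    """Per-experiment mode: one Δlog(RA) per paired experiment, then mean ± SEM.

    Experiments are paired positionally (the assay design runs WT and
    mutant on the same plate).  ``expression_percents`` gives the mutant
    surface expression (% of WT) per experiment, or a single pooled value.
    The CI uses a Student-t multiplier on the across-experiment SEM by
    default, which is the calibrated choice for small n.
    """
    if wt.n_experiments != mut.n_experiments:
        raise ValueError("WT and mutant must have paired experiments")
    percents = np.broadcast_to(np.asarray(expression_percents, dtype=float),
                               (wt.n_experiments,))
    deltas = []
    for we, me, pct in zip(wt.experiments, mut.experiments, percents):
        fw = fit_three_parameter_logistic(we)
        fm = fit_three_parameter_logistic(me)
        if not (fw.converged and fm.converged) or fw.no_curve or fm.no_curve:
            continue
        lw, _ = log_relative_activity(fw)
        lm, _ = log_relative_activity(fm)
        deltas.append(lw - (lm - math.log10(pct / 100.0)))
    if len(deltas) < 2:
        return _unavailable()
    deltas = np.asarray(deltas)
    n = len(deltas)
    mean = float(np.mean(deltas))
    sem = float(np.std(deltas, ddof=1) / math.sqrt(n))
    mult = float(stats.t.ppf(0.975, n - 1)) if use_t else 1.96
    lo, hi = mean - mult * sem, mean + mult * sem
    return DeltaLogRAResult(
        log_ra_wt=float("nan"), log_ra_mut=float("nan"), delta_log_ra=mean,
        se_delta=sem, ci95_low=lo, ci95_high=hi,
        significant=bool(lo > 0 or hi < 0))


def fold_potency_change(wt_pec50: float, mut_pec50: float) -> float:
    """Potency ratio 10^(mutant pEC50 − WT pEC50); > 1 = mutant more potent."""
    if not (math.isfinite(wt_pec50) and math.isfinite(mut_pec50)):
        raise ValueError("pEC50 values must be finite")
    return 10.0 ** (mut_pec50 - wt_pec50)


# ---------------------------------------------------------------------------
# ELISA expression
# ---------------------------------------------------------------------------

def normalize_elisa(plate) -> ExpressionSummary:
    """Summarise mutant surface expression from ELISA plate readings.

    ``plate`` is a pandas DataFrame with columns ``experiment_id``,
    ``role`` (one of ``wt``/``mut``/``background``), ``a490``, ``a650``,
    ``a595``.  Per well the chromogenic ratio (A490 − A650)/A595 is
    formed; per experiment the background mean is subtracted from the WT
    and mutant means and the corrected mutant signal is expressed as a
    percentage of the corrected WT.  Percentages are then averaged across
    experiments (mean ± SEM).
    """
    plate = plate.copy()
    if (plate["a595"] <= 0).any():
        raise ValueError("A595 must be positive in every well")
    roles = set(plate["role"].unique())
    if not {"wt", "mut", "background"} <= roles:
        raise ValueError("plate needs wt, mut and background wells")
    plate["ratio"] = (plate["a490"] - plate["a650"]) / plate["a595"]
    percents = []
    for _, grp in plate.groupby("experiment_id", sort=True):
        means = grp.groupby("role")["ratio"].mean()
        bg = means["background"]
        wt_corr = means["wt"] - bg
        mut_corr = means["mut"] - bg
        if wt_corr == 0:
            raise ValueError("corrected WT signal is zero; cannot normalise")
        percents.append(100.0 * mut_corr / wt_corr)
    percents = np.asarray(percents)
    n = len(percents)
    sem = float(np.std(percents, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return ExpressionSummary(
        percent_of_wt=float(np.mean(percents)), se_percent=sem,
        n_experiments=n, per_experiment=percents,
        negative_flagged=bool(np.any(percents < 0)))


# ---------------------------------------------------------------------------
# radioligand binding
# ---------------------------------------------------------------------------

def _competition_model(x, top, bottom, pic50):
    # x = log10 of unlabelled-ligand concentration (M); decreasing sigmoid
    return bottom + (top - bottom) / (1.0 + 10.0 ** (x + pic50))


def fit_competition(table) -> CompetitionFit:
    """Fit a one-site competition curve to displacement data.

    ``table`` is a DataFrame with ``concentration_M`` and ``counts``
    columns (an optional boolean ``nonspecific`` column marks the
    top-concentration wells that define non-specific binding; they are
    fitted together with the rest).  The span (top − bottom) is the
    specific binding; its SE uses the full covariance of the asymptotes.
    """
    conc = np.asarray(table["concentration_M"], dtype=float)
    y = np.asarray(table["counts"], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 displacement concentrations")
    x = np.log10(conc)
    p0 = (float(np.max(y)), float(np.min(y)),
          float(np.clip(-np.median(x), 4.0, 14.0)))
    try:
        popt, pcov = optimize.curve_fit(
            _competition_model, x, y, p0=p0,
            bounds=([-np.inf, -np.inf, 4.0], [np.inf, np.inf, 14.0]),
            maxfev=10000)
    except (RuntimeError, ValueError):
        return CompetitionFit(*p0, np.nan, np.nan, np.nan, converged=False)
    var_span = pcov[0, 0] + pcov[1, 1] - 2.0 * pcov[0, 1]
    return CompetitionFit(
        top=float(popt[0]), bottom=float(popt[1]), pic50=float(popt[2]),
        se_top=float(np.sqrt(pcov[0, 0])), se_bottom=float(np.sqrt(pcov[1, 1])),
        se_span=float(np.sqrt(max(var_span, 0.0))), converged=True)


def relative_binding(wt_table, mut_table,
                     ci_multiplier: float = 1.96) -> BindingResult:
    """Mutant specific binding as a percentage of WT, from curve spans.

    The ratio SE uses the delta method on the two span estimates; the CI
    is ``percent ± 1.96·SE``.
    """
    wt = fit_competition(wt_table)
    mut = fit_competition(mut_table)
    if not (wt.converged and mut.converged):
        raise ValueError("competition fit did not converge")
    if wt.span <= 0:
        raise ValueError("WT span is zero or negative; ratio undefined")
    percent = 100.0 * mut.span / wt.span
    rel_var = ((mut.se_span / mut.span) ** 2 if mut.span != 0 else 0.0) + \
              (wt.se_span / wt.span) ** 2
    se_percent = abs(percent) * math.sqrt(rel_var)
    ci = (percent - ci_multiplier * se_percent,
          percent + ci_multiplier * se_percent)
    return BindingResult(pic50=mut.pic50, span=mut.span,
                         percent_bound_vs_wt=percent, ci95=ci,
                         se_percent=se_percent)
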