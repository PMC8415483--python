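"""BRET time-course processing and dose–response analysis.

Pipeline: raw dual-wavelength traces → BRET ratio (I530/I480) → per-well
baseline correction (each well's own pre-stimulation mean is subtracted) →
vehicle subtraction (timepoint-wise mean of vehicle wells) → ΔBRET.  Plateau
responses per concentration feed a four-parameter logistic fit reporting
logEC50, span, Hill slope and bottom.  Also implements the cAMP-reporter
inhibition readout (luminescence compared 7 min after β-adrenergic
stimulation) and per-genotype average trace differences vs a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, NoBaselineError, NonPositiveLuminescenceError, ShapeMismatchError
from .io import BretTrace


@dataclass
class RatioSeries:
    """BRET ratio (I530/I480) versus time for one well."""

    time_s: np.ndarray
    bret_ratio: np.ndarray
    well: str = ""
    treatment: str = ""
    concentration: float = float("nan")
    stimulation_time_s: float = 0.0


@dataclass
class DeltaBretSeries:
    """Stimulus-induced BRET change after baseline and vehicle correction.

    By construction the pre-stimulation mean of ``delta_bret`` is zero (to
    numerical precision) on noise-free input.
    """

    time_s: np.ndarray
    delta_bret: np.ndarray
    baseline_window: tuple[float, float]
    vehicle_wells: list[str]
    well: str = ""
    treatment: str = ""
    concentration: float = float("nan")
    stimulation_time_s: float = 0.0


@dataclass
class DoseResponseFit:
    """Four-parameter logistic fit: bottom + span/(1 + 10^((logEC50 − log c)·hill)).

    ``converged`` False means no start converged and the parameters are
    unusable; ``identifiable`` False flags a fit whose span is statistically
    indistinguishable from zero, in which case logEC50 is meaningless.
    """

    logec50: float
    span: float
    hill: float
    bottom: float
    se: dict = dataclass_field(default_factory=dict)
    converged: bool = False
    identifiable: bool = True
    rss: float = float("nan")
    rmse: float = float("nan")
    n: int = 0


def bret_ratio(trace: BretTrace) -> RatioSeries:
    """Elementwise acceptor/donor ratio I530/I480 of one trace."""
    bad = np.nonzero(trace.I480 <= 0)[0]
    if bad.size:
        raise NonPositiveLuminescenceError(
            f"well {trace.well}: I480 <= 0 at t={trace.time_s[bad[0]]:g} s"
        )
    return RatioSeries(
        time_s=trace.time_s.copy(),
        bret_ratio=trace.I530 / trace.I480,
        well=trace.well,
        treatment=trace.treatment,
        concentration=trace.concentration,
        stimulation_time_s=trace.stimulation_time_s,
    )


def _baseline_corrected(series: RatioSeries, t_stim: float) -> np.ndarray:
    pre = series.time_s < t_stim
    if not pre.any():
        raise NoBaselineError(f"well {series.well}: no timepoints before {t_stim} s")
    return series.bret_ratio - series.bret_ratio[pre].mean()


def delta_bret(
    stim: RatioSeries,
    vehicle: RatioSeries | list[RatioSeries],
    stimulation_time_s: float | None = None,
) -> DeltaBretSeries:
    """Baseline-correct and vehicle-subtract one well's ratio series.

    Each series is first corrected by subtracting its own pre-stimulation mean
    ratio (all samples before the stimulation time), removing per-well
    constant offsets; the (mean) baseline-corrected vehicle is then subtracted
    timepoint-wise.  Vehicle series must share the stimulated well's time grid
    to within half a sample interval.
    """
    vehicles = vehicle if isinstance(vehicle, list) else [vehicle]
    if not vehicles:
        raise ValueError("at least one vehicle series required")
    t_stim = stimulation_time_s if stimulation_time_s is not None else stim.stimulation_time_s
    dt = np.median(np.diff(stim.time_s)) if len(stim.time_s) > 1 else 1.0
    for v in vehicles:
        if len(v.time_s) != len(stim.time_s) or np.any(np.abs(v.time_s - stim.time_s) > dt / 2):
            raise ShapeMismatchError(
                f"vehicle well {v.well} not on the time grid of well {stim.well}"
            )
    stim_corr = _baseline_corrected(stim, t_stim)
    veh_corr = np.mean([_baseline_corrected(v, t_stim) for v in vehicles], axis=0)
    pre = stim.time_s < t_stim
    return DeltaBretSeries(
        time_s=stim.time_s.copy(),
        delta_bret=stim_corr - veh_corr,
        baseline_window=(float(stim.time_s[pre].min()), float(stim.time_s[pre].max())),
        vehicle_wells=[v.well for v in vehicles],
        well=stim.well,
        treatment=stim.treatment,
        concentration=stim.concentration,
        stimulation_time_s=t_stim,
    )


def percent_of_max(responses: dict, reference) -> dict:
    """Express responses as percentage of the reference condition's response."""
    if reference not in responses:
        raise KeyError(f"reference condition {reference!r} not in responses")
    ref = responses[reference]
    if ref == 0:
        raise ZeroDivisionError(f"reference condition {reference!r} has zero response")
    return {k: 100.0 * v / ref for k, v in responses.items()}


def _4pl(logc: np.ndarray, bottom: float, span: float, logec50: float, hill: float) -> np.ndarray:
    return bottom + span / (1.0 + 10.0 ** ((logec50 - logc) * hill))


def fit_4pl(
    concentrations,
    responses,
    hill_bounds: tuple[float, float] = (0.3, 3.0),
    n_starts: int = 7,
) -> DoseResponseFit:
    """Least-squares four-parameter logistic fit of response vs concentration.

    Concentrations (molar) may repeat across replicates; zero/vehicle entries
    are excluded (they live on −∞ of the log axis and only inform baselines
    upstream).  The fit is multi-started from a grid of initial logEC50 values
    spanning the tested range; span is bounded non-negative and the Hill slope
    to ``hill_bounds``.  Parameter standard errors come from the local
    covariance at the optimum.  At least 4 distinct concentrations required.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ShapeMismatchError("concentrations and responses differ in length")
    keep = conc > 0
    conc, resp = conc[keep], resp[keep]
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct positive concentrations")
    logc = np.log10(conc)

    span0 = float(resp.max() - resp.min())
    bottom0 = float(resp.min())
    scale = max(abs(resp).max(), 1e-30)
    lo = [-np.inf, 0.0, logc.min() - 3.0, hill_bounds[0]]
    hi = [np.inf, np.inf, logc.max() + 3.0, hill_bounds[1]]

    best = None
    for start in np.linspace(logc.min() - 1, logc.max() + 1, n_starts):
        p0 = [bottom0, max(span0, 1e-6 * scale), start, 1.0]
        try:
            popt, pcov = curve_fit(
                _4pl, logc, resp, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((resp - _4pl(logc, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        return DoseResponseFit(
            logec50=float("nan"), span=float("nan"), hill=float("nan"),
            bottom=float("nan"), converged=False, identifiable=False, n=len(resp),
        )
    popt, pcov, rss = best
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    se = dict(zip(["bottom", "span", "logec50", "hill"], (float(x) for x in perr)))
    span_hat = float(popt[1])
    identifiable = bool(
        span_hat > 1e-6 * scale
        and np.isfinite(se["logec50"])
        and (not np.isfinite(se["span"]) or span_hat > 2 * se["span"] or se["span"] == 0)
    )
    dof = max(len(resp) - 4, 1)
    return DoseResponseFit(
        logec50=float(popt[2]),
        span=span_hat,
        hill=float(popt[3]),
        bottom=float(popt[0]),
        se=se,
        converged=True,
        identifiable=identifiable,
        rss=rss,
        rmse=float(np.sqrt(rss / dof)),
        n=len(resp),
    )


def plateau_response(series: DeltaBretSeries, n_points: int = 5) -> float:
    """Mean ΔBRET over the last ``n_points`` post-stimulation samples."""
    post = series.time_s >= series.stimulation_time_s
    vals = series.delta_bret[post]
    if vals.size == 0:
        raise ValueError(f"well {series.well}: no post-stimulation samples")
    return float(vals[-n_points:].mean())


def dose_response_from_traces(
    traces: list[BretTrace],
    plateau_points: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a plate of traces to (concentration, plateau ΔBRET) pairs.

    Vehicle wells (concentration NaN or 0) define the vehicle reference; each
    remaining well contributes one plateau response.  Returns parallel arrays
    suitable for :func:`fit_4pl`.
    """
    ratios = [bret_ratio(tr) for tr in traces]
    vehicles = [r for r, tr in zip(ratios, traces) if tr.is_vehicle]
    if not vehicles:
        raise ValueError("no vehicle wells in trace set")
    conc, resp = [], []
    for r, tr in zip(ratios, traces):
        if tr.is_vehicle:
            continue
        d = delta_bret(r, vehicles)
        conc.append(tr.concentration)
        resp.append(plateau_response(d, plateau_points))
    return np.asarray(conc), np.asarray(resp)


def iso_inhibition(
    agonist_time_s,
    agonist_lum,
    control_time_s,
    control_lum,
    t_iso: float,
    eval_offset_s: float = 420.0,
) -> float:
    """cAMP-reporter inhibition at a fixed delay after β-adrenergic stimulation.

    Evaluates both luminescence traces at the sample nearest ``t_iso +
    eval_offset_s`` (default 420 s = 7 min) and returns ``1 − L_agonist /
    L_control``.  Nearest-sample evaluation is used rather than interpolation:
    at 85 s sampling the timing error is under half a sample and the readout
    stays exactly reproducible.
    """
    target = t_iso + eval_offset_s
    ta = np.asarray(agonist_time_s, dtype=float)
    tc = np.asarray(control_time_s, dtype=float)
    if ta.max() < target or tc.max() < target:
        raise ValueError(f"traces do not cover t_iso + {eval_offset_s:g} s = {target:g} s")
    la = float(np.asarray(agonist_lum, dtype=float)[np.argmin(np.abs(ta - target))])
    lc = float(np.asarray(control_lum, dtype=float)[np.argmin(np.abs(tc - target))])
    if lc <= 0:
        raise NonPositiveLuminescenceError(f"control luminescence {lc} <= 0 at evaluation time")
    return 1.0 - la / lc


def average_difference_vs_reference(
    series_by_genotype: dict[str, DeltaBretSeries],
    reference: str,
) -> dict[str, float]:
    """Mean post-stimulation ΔBRET difference of each genotype vs a reference.

    All series must share the reference's time grid; the scalar per genotype
    is the plain mean over post-stimulation timepoints of (genotype ΔBRET −
    reference ΔBRET), the quantity summarized on radial comparison plots.
    """
    if reference not in series_by_genotype:
        raise KeyError(f"reference genotype {reference!r} missing")
    ref = series_by_genotype[reference]
    post = ref.time_s >= ref.stimulation_time_s
    if not post.any():
        raise ValueError("no post-stimulation timepoints")
    out = {}
    for g, s in series_by_genotype.items():
        if len(s.time_s) != len(ref.time_s) or np.any(s.time_s != ref.time_s):
            raise ShapeMismatchError(f"genotype {g} not on the reference time grid")
        out[g] = float(np.mean(s.delta_bret[post] - ref.delta_bret[post]))
    return out
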